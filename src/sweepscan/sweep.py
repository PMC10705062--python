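"""Windowed selective-sweep scan: Weir-Cockerham F_ST x log2 pi-ratio.

Per-site differentiation between the two contrasted groups uses the
Weir-Cockerham (1984) variance-component estimator with components *a*
(among populations), *b* (among individuals within populations) and *c*
(within individuals); the windowed statistic is the ratio of sums
sum(a) / sum(a+b+c).  Per-group nucleotide diversity is the unbiased
per-site heterozygosity 2j(m-j)/(m(m-1)) summed over a window and divided
by window length in bp.  Windows in the joint extreme tails — F_ST above
its upper quantile AND the log2 ratio pi_group1/pi_group2 beyond a tail
quantile — are flagged as selected, and flagged windows are merged into
candidate regions which are then intersected with gene annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .matrix import ChromLengths, GeneModel, GenotypeMatrix, MISSING, chrom_sort_key

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

@dataclass
class SiteFst:
    chrom: str
    pos: int
    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        if not np.isfinite(denom) or denom <= 0:
            return float("nan")
        return self.a / denom


def wc_components(
    dosage: np.ndarray, groups: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized W&C (a, b, c) per variant for r >= 2 populations.

    ``dosage`` is samples x variants; ``groups`` gives sample index arrays,
    one per population.  Sites where any population has zero non-missing
    genotypes, or mean sample size n_bar <= 1, get NaN components (callers
    skip them).
    """
    r = len(groups)
    if r < 2:
        raise ValueError("need at least 2 populations")
    m = dosage.shape[1]
    n_i = np.empty((r, m))
    p_i = np.empty((r, m))
    h_i = np.empty((r, m))
    for k, idx in enumerate(groups):
        sub = dosage[idx, :]
        obs = sub != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, sub, 0).sum(axis=0) / (2.0 * n)
            h = ((sub == 1) & obs).sum(axis=0) / n
        n_i[k] = n
        p_i[k] = p
        h_i[k] = h

    valid = (n_i > 0).all(axis=0)
    n_bar = n_i.mean(axis=0)
    valid &= n_bar > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1.0)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - (
                p_bar * (1.0 - p_bar)
                - ((r - 1.0) / r) * s2
                - h_bar / 4.0
            )
            / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def site_fst(dosages_by_pop: Sequence[np.ndarray]) -> SiteFst:
    """W&C components for one site from per-population dosage vectors."""
    cols = [np.asarray(d).reshape(-1, 1) for d in dosages_by_pop]
    dosage = np.vstack(cols)
    offs = np.cumsum([0] + [len(c) for c in cols])
    groups = [np.arange(offs[k], offs[k + 1]) for k in range(len(cols))]
    a, b, c = wc_components(dosage, groups)
    return SiteFst(chrom="", pos=0, a=float(a[0]), b=float(b[0]), c=float(c[0]))


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(dosage: np.ndarray, sample_idx: np.ndarray) -> np.ndarray:
    """Unbiased per-site pi (mean pairwise haplotype difference) per variant.

    With m non-missing alleles and alternate count j:
    pi = 2 j (m - j) / (m (m - 1)); sites with m < 2 contribute 0.
    """
    sub = dosage[sample_idx, :]
    obs = sub != MISSING
    m = 2.0 * obs.sum(axis=0)
    j = np.where(obs, sub, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (m - j) / (m * (m - 1.0))
    return np.where(m >= 2, pi, 0.0)


def window_pi(
    gm: GenotypeMatrix,
    group: Sequence[str],
    window: tuple[str, int, int],
) -> float:
    """Per-bp nucleotide diversity of one group over one genomic window."""
    if len(group) == 0:
        raise ValueError("group must be non-empty")
    chrom, start, end = window
    idx = gm.sample_indices(group)
    in_win = (
        (gm.variants["chrom"].to_numpy() == chrom)
        & (gm.variants["pos"].to_numpy() >= start)
        & (gm.variants["pos"].to_numpy() <= end)
    )
    pi = site_pi(gm.dosage[:, in_win], idx) if in_win.any() else np.array([])
    return float(pi.sum()) / float(end - start + 1)


# ---------------------------------------------------------------------------
# window grid
# ---------------------------------------------------------------------------

def tile_windows(
    chroms: ChromLengths, size: int = 40_000, step: int = 20_000
) -> list[tuple[str, int, int]]:
    """Sliding-window grid: starts 1, 1+step, ... while start <= L,
    truncated at chromosome ends."""
    if not (size >= step >= 1):
        raise ValueError("require size >= step >= 1")
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(chroms, key=chrom_sort_key):
        L = chroms[chrom]
        start = 1
        while start <= L:
            out.append((chrom, start, min(start + size - 1, L)))
            start += step
    return out


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_sites: int
    fst: float  # NaN when undefined
    pi_group1: float
    pi_group2: float
    log2_ratio: float  # NaN when either pi is 0 or no sites
    flag: str | None = None  # direction label or None


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    direction: str
    max_fst: float
    extreme_log2_ratio: float


@dataclass
class ScanThresholds:
    fst_quantile: float = 0.05  # upper-tail level for F_ST
    ratio_quantile: float = 0.05  # each-tail level for the log2 ratio
    realized_fst_cut: float | None = None
    realized_low_cut: float | None = None
    realized_high_cut: float | None = None


def scan(
    gm: GenotypeMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    chroms: ChromLengths,
    thresholds: ScanThresholds | None = None,
    *,
    size: int = 40_000,
    step: int = 20_000,
    group_labels: tuple[str, str] = ("group1", "group2"),
    breed_level: bool = False,
) -> tuple[list[WindowStat], ScanThresholds, list[CandidateRegion]]:
    """The crossover scan over a window grid.

    Per window: F_ST as ratio-of-sums of W&C components between the two
    pooled groups (or the per-population breeds when ``breed_level``),
    per-group per-bp pi, and log2(pi_group1 / pi_group2).  Realized cuts are
    the empirical quantiles over non-NA windows; a window is flagged for
    ``group_labels[0]`` iff fst >= fst cut and log2_ratio <= low cut, and
    for ``group_labels[1]`` iff fst >= fst cut and log2_ratio >= high cut.
    Flagged windows merge into candidate regions when overlapping/abutting
    with the same direction.
    """
    if thresholds is None:
        thresholds = ScanThresholds()
    g1 = list(group1)
    g2 = list(group2)
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")

    if breed_level:
        labels = gm.pop_labels()
        pops1 = sorted({gm.pops[s] for s in g1})
        pops2 = sorted({gm.pops[s] for s in g2})
        groups = [
            gm.sample_indices([s for s in g1 + g2 if gm.pops[s] == p])
            for p in pops1 + pops2
        ]
    else:
        groups = [gm.sample_indices(g1), gm.sample_indices(g2)]
    a, b, c = wc_components(gm.dosage, groups)
    abc = a + b + c
    pi1 = site_pi(gm.dosage, gm.sample_indices(g1))
    pi2 = site_pi(gm.dosage, gm.sample_indices(g2))

    chrom_arr = gm.variants["chrom"].to_numpy()
    pos_arr = gm.variants["pos"].to_numpy()
    grid = tile_windows(chroms, size=size, step=step)
    windows: list[WindowStat] = []
    # per-chromosome position index for fast range queries
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ch in dict.fromkeys(chrom_arr):
        sel = np.flatnonzero(chrom_arr == ch)
        by_chrom[str(ch)] = (pos_arr[sel].astype(np.int64), sel)

    for chrom, start, end in grid:
        if chrom in by_chrom:
            pos_c, sel = by_chrom[chrom]
            lo = int(np.searchsorted(pos_c, start, side="left"))
            hi = int(np.searchsorted(pos_c, end, side="right"))
            sites = sel[lo:hi]
        else:
            sites = np.array([], dtype=np.intp)
        valid_sites = sites[np.isfinite(abc[sites])] if len(sites) else sites
        n_sites = int(len(valid_sites))
        if n_sites:
            denom = float(abc[valid_sites].sum())
            fst = float(a[valid_sites].sum()) / denom if denom > 0 else float("nan")
        else:
            fst = float("nan")
        length = float(end - start + 1)
        w_pi1 = float(pi1[sites].sum()) / length if len(sites) else 0.0
        w_pi2 = float(pi2[sites].sum()) / length if len(sites) else 0.0
        if n_sites and w_pi1 > 0.0 and w_pi2 > 0.0:
            ratio = float(np.log2(w_pi1 / w_pi2))
        else:
            ratio = float("nan")
        windows.append(
            WindowStat(chrom, start, end, n_sites, fst, w_pi1, w_pi2, ratio)
        )

    fst_vals = np.array([w.fst for w in windows])
    ratio_vals = np.array([w.log2_ratio for w in windows])
    usable = np.isfinite(fst_vals) & np.isfinite(ratio_vals)
    if not usable.any():
        raise ValueError("no windows with defined F_ST and log2 ratio")
    fst_cut = float(
        np.quantile(fst_vals[usable], 1.0 - thresholds.fst_quantile)
    )
    low_cut = float(np.quantile(ratio_vals[usable], thresholds.ratio_quantile))
    high_cut = float(
        np.quantile(ratio_vals[usable], 1.0 - thresholds.ratio_quantile)
    )
    realized = replace(
        thresholds,
        realized_fst_cut=fst_cut,
        realized_low_cut=low_cut,
        realized_high_cut=high_cut,
    )
    lab1, lab2 = group_labels
    for w in windows:
        if not (np.isfinite(w.fst) and np.isfinite(w.log2_ratio)):
            continue
        if w.fst >= fst_cut and w.log2_ratio <= low_cut:
            w.flag = lab1
        elif w.fst >= fst_cut and w.log2_ratio >= high_cut:
            w.flag = lab2
    regions = merge_flagged_windows(windows, low_tail_labels={lab1})
    logger.info(
        "scan: %d windows, cuts fst=%.6f low=%.6f high=%.6f, "
        "%d flagged (%s=%d, %s=%d), %d regions",
        len(windows), fst_cut, low_cut, high_cut,
        sum(w.flag is not None for w in windows),
        lab1, sum(w.flag == lab1 for w in windows),
        lab2, sum(w.flag == lab2 for w in windows),
        len(regions),
    )
    return windows, realized, regions


def merge_flagged_windows(
    windows: Sequence[WindowStat], low_tail_labels: set[str] = frozenset()
) -> list[CandidateRegion]:
    """Merge overlapping/abutting flagged windows of the same direction.

    ``low_tail_labels`` names the direction(s) flagged from the low tail of
    the log2 ratio; their regions report the minimum ratio as the extreme,
    all others the maximum.
    """
    flagged = sorted(
        (w for w in windows if w.flag is not None),
        key=lambda w: (w.flag, chrom_sort_key(w.chrom), w.start),
    )
    regions: list[CandidateRegion] = []
    cur: CandidateRegion | None = None
    cur_windows: list[WindowStat] = []

    def close(region: CandidateRegion, members: list[WindowStat]) -> CandidateRegion:
        ratios = [w.log2_ratio for w in members]
        extreme = (
            min(ratios) if region.direction in low_tail_labels else max(ratios)
        )
        return replace(
            region,
            n_windows=len(members),
            max_fst=max(w.fst for w in members),
            extreme_log2_ratio=extreme,
        )

    for w in flagged:
        if (
            cur is not None
            and w.flag == cur.direction
            and w.chrom == cur.chrom
            and w.start <= cur.end + 1
        ):
            cur = replace(cur, end=max(cur.end, w.end))
            cur_windows.append(w)
        else:
            if cur is not None:
                regions.append(close(cur, cur_windows))
            cur = CandidateRegion(
                chrom=w.chrom, start=w.start, end=w.end, n_windows=1,
                direction=w.flag, max_fst=w.fst, extreme_log2_ratio=w.log2_ratio,
            )
            cur_windows = [w]
    if cur is not None:
        regions.append(close(cur, cur_windows))
    regions.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start, r.direction))
    return regions


# ---------------------------------------------------------------------------
# gene overlap
# ---------------------------------------------------------------------------

def genes_in_regions(
    regions: Sequence[CandidateRegion], genes: Iterable[GeneModel]
) -> dict[str, list[GeneModel]]:
    """Genes overlapping (>= 1 bp) candidate regions, listed per direction."""
    out: dict[str, list[GeneModel]] = {}
    genes = list(genes)
    directions = sorted({r.direction for r in regions})
    for direction in directions:
        seen: set[str] = set()
        hits: list[GeneModel] = []
        for g in genes:
            if g.gene_id in seen:
                continue
            for r in regions:
                if (
                    r.direction == direction
                    and r.chrom == g.chrom
                    and r.start <= g.end
                    and g.start <= r.end
                ):
                    hits.append(g)
                    seen.add(g.gene_id)
                    break
        out[direction] = hits
    return out
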