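"""Genotype quality control: individual missingness, MAF, exact HWE, LD pruning.

The chain mirrors the conventional SNP-array/WGS filtering stack
(``--mind`` / ``--maf`` / ``--hwe`` / ``--indep-pairwise`` semantics):

* individuals with too many missing genotypes are dropped first;
* variants failing a minor-allele-frequency floor are removed (monomorphic
  sites always fail any positive MAF);
* variants are tested for Hardy-Weinberg equilibrium with the exact
  conditional test (plain two-sided formulation, not mid-p) and dropped
  below a p-value floor;
* a greedy sliding-window LD pruner removes one member of each pair of SNPs
  whose squared Pearson dosage correlation exceeds a cutoff.

Filter order is fixed: individuals -> MAF -> HWE -> LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """Thresholds of the four-stage filter chain.

    Defaults are the conventional values for structure analysis of livestock
    WGS panels: mind 0.1, maf 0.05, HWE p 1e-6, LD 100-SNP window / 50-SNP
    step / r^2 0.2.
    """

    mind: float = 0.1
    maf: float = 0.05
    hwe_p: float = 1e-6
    ld_window: int = 100
    ld_step: int = 50
    ld_r2: float = 0.2

    def __post_init__(self) -> None:
        for name in ("mind", "maf", "hwe_p", "ld_r2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (self.ld_window >= self.ld_step >= 1):
            raise ValueError("require ld_window >= ld_step >= 1")


@dataclass
class QcReport:
    """Per-stage record counts of one QC run."""

    n_samples_in: int = 0
    n_samples_kept: int = 0
    removed_samples: list[str] = field(default_factory=list)
    n_variants_in: int = 0
    stage_variant_counts: dict[str, int] = field(default_factory=dict)

    def rows(self) -> list[tuple[str, int]]:
        out = [
            ("samples_in", self.n_samples_in),
            ("samples_kept", self.n_samples_kept),
            ("variants_in", self.n_variants_in),
        ]
        out.extend(self.stage_variant_counts.items())
        return out


# ---------------------------------------------------------------------------
# individual missingness
# ---------------------------------------------------------------------------

def filter_individuals(
    gm: GenotypeMatrix, mind: float, report: QcReport | None = None
) -> GenotypeMatrix:
    """Drop samples whose missing-genotype fraction exceeds ``mind``."""
    if not (0.0 <= mind <= 1.0):
        raise ValueError("mind must be in [0, 1]")
    if gm.n_variants == 0:
        return gm
    frac = gm.missing_mask.mean(axis=1)
    keep = frac <= mind
    if not keep.any():
        raise ValueError("individual-missingness filter removed every sample")
    removed = [s for s, k in zip(gm.samples, keep) if not k]
    if removed:
        logger.info("mind %.3g removed %d samples: %s", mind, len(removed), removed)
    if report is not None:
        report.removed_samples = removed
    return gm.subset_samples(np.flatnonzero(keep)) if removed else gm


# ---------------------------------------------------------------------------
# minor allele frequency
# ---------------------------------------------------------------------------

def filter_maf(gm: GenotypeMatrix, maf: float) -> GenotypeMatrix:
    """Keep variants with minor-allele frequency >= ``maf`` (inclusive).

    Frequency is estimated over non-missing genotypes.  Variants with every
    genotype missing are removed and logged.
    """
    p = gm.alt_allele_freq()
    all_missing = np.isnan(p)
    if all_missing.any():
        logger.info("MAF stage: %d all-missing variants removed", all_missing.sum())
    with np.errstate(invalid="ignore"):
        keep = np.minimum(p, 1.0 - p) >= maf
    keep &= ~all_missing
    return gm.subset_variants(keep)


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, the number of heterozygotes
    follows an exact (hypergeometric-type) distribution; the two-sided
    p-value sums the probabilities of all heterozygote counts no more
    probable than the observed one (plain formulation, no mid-p).

    Returns a p-value in (0, 1].
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0

    # distribution over heterozygote counts h (parity of `rare`), built by
    # the standard two-sided recurrence from the mode
    probs = np.zeros(rare + 1)
    mid = int(rare * (2 * n - rare) / (2 * n))
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    for h in range(mid, 1, -2):
        probs[h - 2] = (
            probs[h]
            * h
            * (h - 1)
            / ((rare - h + 2.0) * (2 * n - rare - h + 2.0))
        )
    for h in range(mid, rare - 1, 2):
        probs[h + 2] = (
            probs[h]
            * (rare - h)
            * (2 * n - rare - h)
            / ((h + 2.0) * (h + 1.0))
        )
    total = probs.sum()
    p_obs = probs[n_het]
    # tiny relative slack so exact probability ties survive float rounding
    p = probs[probs <= p_obs * (1.0 + 1e-9)].sum() / total
    return float(min(p, 1.0))


def hwe_filter(gm: GenotypeMatrix, hwe_p: float) -> GenotypeMatrix:
    """Drop variants with exact-HWE p-value below ``hwe_p`` (pooled samples)."""
    keep = np.ones(gm.n_variants, dtype=bool)
    for j in range(gm.n_variants):
        col = gm.dosage[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            keep[j] = False
            continue
        p = hwe_exact_p(
            int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())
        )
        keep[j] = p >= hwe_p
    return gm.subset_variants(keep)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns over complete pairs."""
    ok = (col_a != MISSING) & (col_b != MISSING)
    if ok.sum() < 2:
        return 0.0
    a = col_a[ok].astype(float)
    b = col_b[ok].astype(float)
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        return 0.0
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def _window_r2_matrix(dosage_win: np.ndarray) -> np.ndarray:
    """Pairwise complete-pairs r^2 for a samples x w dosage block.

    Pairwise deletion is expressed through mask matrix products so the whole
    window is one set of GEMMs.  Undefined pairs (fewer than 2 complete
    observations or zero variance) get r^2 = 0.
    """
    m = (dosage_win != MISSING).astype(float)
    z = np.where(dosage_win == MISSING, 0, dosage_win).astype(float)
    z2 = z * z
    n = m.T @ m  # complete-pair counts
    sa = z.T @ m  # sum of column a over rows complete in (a, b)
    sb = sa.T
    saa = z2.T @ m
    sbb = saa.T
    sab = z.T @ z
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sab - sa * sb
        var_a = n * saa - sa * sa
        var_b = n * sbb - sb * sb
        r2 = (cov * cov) / (var_a * var_b)
    r2[~np.isfinite(r2)] = 0.0
    r2[(n < 2) | (var_a <= 0) | (var_b <= 0)] = 0.0
    return r2


def ld_prune(
    gm: GenotypeMatrix, window: int, step: int, r2: float
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns kept variant indices.

    Within each window of ``window`` consecutive SNPs on one chromosome the
    highest-r^2 offending pair (r^2 > ``r2``) is located repeatedly and one
    member is removed: the one with the lower non-missing count, ties going
    to the larger coordinate.  The window then advances by ``step`` SNPs.
    Removals are idempotent across windows.
    """
    if not window >= step >= 1:
        raise ValueError("require window >= step >= 1")
    removed = np.zeros(gm.n_variants, dtype=bool)
    n_obs = (~gm.missing_mask).sum(axis=0)
    chroms = gm.variants["chrom"].to_numpy()
    # iterate window sweeps over the currently kept list until a full pass
    # makes no removal, so no offending pair survives in any final window
    changed = True
    while changed:
        changed = False
        for chrom in dict.fromkeys(chroms):  # preserves order
            idx = np.flatnonzero((chroms == chrom) & ~removed)
            start = 0
            while start < len(idx):
                win = idx[start : start + window]
                if _prune_window(gm, win, removed, n_obs, r2):
                    changed = True
                if start + window >= len(idx):
                    break
                start += step
    return np.flatnonzero(~removed)


def _prune_window(
    gm: GenotypeMatrix,
    win: np.ndarray,
    removed: np.ndarray,
    n_obs: np.ndarray,
    r2: float,
) -> bool:
    w = len(win)
    rmat = _window_r2_matrix(gm.dosage[:, win])
    np.fill_diagonal(rmat, 0.0)
    alive = ~removed[win]
    any_removed = False
    while True:
        masked = np.where(np.outer(alive, alive), rmat, 0.0)
        masked = np.triu(masked, k=1)
        flat = int(np.argmax(masked))  # ties -> smallest (row, col)
        ii, jj = divmod(flat, w)
        if masked[ii, jj] <= r2:
            return any_removed
        a, b = win[ii], win[jj]
        if n_obs[a] < n_obs[b]:
            loser = a
        elif n_obs[b] < n_obs[a]:
            loser = b
        else:  # tie: drop the larger coordinate
            loser = max(a, b)
        removed[loser] = True
        alive[ii if loser == a else jj] = False
        any_removed = True


def ld_audit(
    gm: GenotypeMatrix, window: int, r2: float, step: int | None = None
) -> int:
    """Count within-window pairs exceeding the r^2 cutoff, sliding the same
    window/step grid the pruner uses (step defaults to window // 2)."""
    if step is None:
        step = max(1, window // 2)
    chroms = gm.variants["chrom"].to_numpy()
    n_bad = 0
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            rmat = np.triu(_window_r2_matrix(gm.dosage[:, win]), k=1)
            n_bad += int((rmat > r2).sum())
            if start + window >= len(idx):
                break
            start += step
    return n_bad


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def is_snp_mask(gm: GenotypeMatrix) -> np.ndarray:
    ref_len = gm.variants["ref"].astype(str).str.len().to_numpy()
    alt_len = gm.variants["alt"].astype(str).str.len().to_numpy()
    return (ref_len == 1) & (alt_len == 1)


def apply_qc(
    gm: GenotypeMatrix,
    thresholds: QcThresholds,
    chroms: Iterable[str] | Sequence[str],
    *,
    exclude_indels: bool = True,
    report: QcReport | None = None,
) -> GenotypeMatrix:
    """Run the full chain: chromosomes -> individuals -> MAF -> HWE -> LD.

    ``chroms`` restricts the analysis to the listed chromosomes (e.g. the
    autosomes) before any filter runs.  ``exclude_indels`` drops non-SNP
    biallelic variants at the same point, keeping the downstream statistics
    SNP-based.
    """
    chroms = list(chroms)
    if not chroms:
        raise ValueError("empty chromosome set")
    if report is None:
        report = QcReport()
    report.n_samples_in = gm.n_samples
    report.n_variants_in = gm.n_variants

    out = gm.restrict_chroms(chroms)
    report.stage_variant_counts["after_chrom_restrict"] = out.n_variants
    if exclude_indels:
        out = out.subset_variants(is_snp_mask(out))
        report.stage_variant_counts["after_snp_only"] = out.n_variants

    out = filter_individuals(out, thresholds.mind, report)
    report.n_samples_kept = out.n_samples

    out = filter_maf(out, thresholds.maf)
    report.stage_variant_counts["after_maf"] = out.n_variants

    out = hwe_filter(out, thresholds.hwe_p)
    report.stage_variant_counts["after_hwe"] = out.n_variants

    kept = ld_prune(out, thresholds.ld_window, thresholds.ld_step, thresholds.ld_r2)
    out = out.subset_variants(kept)
    report.stage_variant_counts["after_ld"] = out.n_variants

    for name, count in report.rows():
        logger.info("qc %s: %d", name, count)
    return out
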