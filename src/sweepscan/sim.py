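"""Truth-labeled synthetic structured populations with implanted sweeps.

Genotypes follow the Balding-Nichols model: each variant has an ancestral
allele frequency ``p ~ Uniform(0.05, 0.95)``; population *k* with
differentiation parameter ``F_k`` draws its own frequency

    p_k ~ Beta(p (1-F_k)/F_k, (1-p)(1-F_k)/F_k)

so that ``E[p_k] = p`` and the expected between-population differentiation is
controlled by ``F_k``.  Individual dosages are ``Binomial(2, p_k)``.

A *sweep* is a genomic interval in which, for every population of the target
group, ``F_k`` is elevated so that the expected heterozygosity
``E[2 p_k (1-p_k)] = 2 p (1-p)(1-F_k)`` drops by a chosen reduction factor —
mimicking the footprint of positive selection (low within-group diversity,
high between-group differentiation) without simulating the selective process
itself.

Admixed individuals draw dosages from ``Binomial(2, sum_k q_k p_k)`` for a
known ancestry vector ``q``, providing ground truth for the ancestry model.

Sites are independent (no background LD) unless ``ld_copy_prob`` is set, in
which case each site copies its population frequencies from the previous
site with that probability — a crude first-order LD used to exercise the LD
pruner only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, ChromLengths, GenotypeMatrix, chrom_sort_key

INDIGENOUS = "indigenous"
COMMERCIAL = "commercial"


@dataclass(frozen=True)
class SweepSpec:
    """One implanted sweep interval targeting every population of a group."""

    chrom: str
    start: int
    end: int
    target_group: str
    reduction: float  # expected-heterozygosity reduction factor, >= 1

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad sweep interval [{self.start}, {self.end}]")
        if self.reduction < 1:
            raise ValueError("diversity reduction factor must be >= 1")


@dataclass(frozen=True)
class AdmixSpec:
    """``count`` admixed individuals with a shared known ancestry vector."""

    count: int
    ancestry: Mapping[str, float]  # population -> fraction, sums to 1


@dataclass
class SimConfig:
    """Study design for one simulated dataset.

    Defaults emulate the contrast the pipeline targets: eight populations
    split into an indigenous group and a commercial group, moderate
    background differentiation, and SNP density giving a few hundred sites
    per 40 kb window at whole-genome-sequencing-like marker density.
    """

    pop_sizes: dict[str, int]
    group_of: dict[str, str]
    chrom_lengths: ChromLengths
    snp_density: float = 1.0 / 400.0  # expected SNPs per bp
    baseline_F: float | dict[str, float] = 0.05
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    admixed_specs: list[AdmixSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    ld_copy_prob: float = 0.0
    seed: int = 0

    def pop_F(self, pop: str) -> float:
        if isinstance(self.baseline_F, Mapping):
            return float(self.baseline_F[pop])
        return float(self.baseline_F)

    def validate(self) -> None:
        if not self.pop_sizes:
            raise ValueError("at least one population required")
        for p, n in self.pop_sizes.items():
            if n < 1:
                raise ValueError(f"population {p}: size must be >= 1")
            if p not in self.group_of:
                raise ValueError(f"population {p} has no group assignment")
            f = self.pop_F(p)
            if not (0.0 < f < 1.0):
                raise ValueError(f"population {p}: baseline F={f} not in (0, 1)")
        for sw in self.sweep_specs:
            if sw.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {sw.chrom!r}")
            if sw.end > self.chrom_lengths[sw.chrom]:
                raise ValueError(f"sweep {sw} exceeds chromosome length")
            if sw.target_group not in set(self.group_of.values()):
                raise ValueError(f"sweep targets unknown group {sw.target_group!r}")
        for sp in self.admixed_specs:
            if sp.count < 1:
                raise ValueError("admixed count must be >= 1")
            if set(sp.ancestry) - set(self.pop_sizes):
                raise ValueError("ancestry vector names unknown population")
            if abs(sum(sp.ancestry.values()) - 1.0) > 1e-8:
                raise ValueError("ancestry fractions must sum to 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SweepTruth:
    """Simulator ground truth for recovery scoring."""

    sweep_windows: list[tuple[str, int, int, str]]  # chrom, start, end, group
    true_Q: pd.DataFrame  # samples x populations ancestry fractions
    per_pop_F: dict[str, float]
    per_site_anc_freq: np.ndarray  # aligned with the GenotypeMatrix variants


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The standard eight-population study design on a small genome.

    Four indigenous and three commercial populations of 15 individuals plus
    a small admixed cohort, 5 Mb over two chromosomes, one 400 kb sweep per
    group at 8x diversity reduction.
    """
    pops_ind = ["MMS", "FJ", "SW", "PD"]
    pops_com = ["DUR", "LAN", "YOR"]
    cfg = SimConfig(
        pop_sizes={p: 15 for p in pops_ind + pops_com},
        group_of={
            **{p: INDIGENOUS for p in pops_ind},
            **{p: COMMERCIAL for p in pops_com},
        },
        chrom_lengths=ChromLengths.from_mapping({"1": 3_000_000, "2": 2_000_000}),
        sweep_specs=[
            SweepSpec("1", 1_000_001, 1_400_000, INDIGENOUS, 8.0),
            SweepSpec("2", 400_001, 800_000, COMMERCIAL, 8.0),
        ],
        admixed_specs=[AdmixSpec(4, {"MMS": 0.5, "YOR": 0.5})],
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _sweep_F(base_F: float, reduction: float) -> float:
    """Elevated F giving an expected-heterozygosity drop by ``reduction``."""
    f = 1.0 - (1.0 - base_F) / reduction
    if f >= 1.0:
        raise ValueError(
            f"infeasible diversity reduction {reduction} at baseline F {base_F}"
        )
    return f


def _beta_freq(rng: np.random.Generator, p: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Balding-Nichols population frequency draws, elementwise in (p, F)."""
    out = p.copy()
    active = F > 1e-9
    if active.any():
        ratio = (1.0 - F[active]) / F[active]
        out[active] = rng.beta(p[active] * ratio, (1.0 - p[active]) * ratio)
    return np.clip(out, 1e-9, 1.0 - 1e-9)


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, SweepTruth]:
    """Draw one dataset; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pops = list(config.pop_sizes)

    chrom_order = sorted(config.chrom_lengths, key=chrom_sort_key)
    chroms_all: list[str] = []
    pos_all: list[np.ndarray] = []
    for chrom in chrom_order:
        L = config.chrom_lengths[chrom]
        n_sites = rng.poisson(L * config.snp_density)
        pos = np.unique(rng.integers(1, L + 1, size=n_sites))
        chroms_all.extend([chrom] * len(pos))
        pos_all.append(pos)
    positions = (
        np.concatenate(pos_all) if pos_all else np.array([], dtype=np.int64)
    )
    m = len(positions)
    chrom_arr = np.array(chroms_all)

    anc_p = rng.uniform(0.05, 0.95, size=m)

    pop_freq = np.empty((len(pops), m))
    for ki, pop in enumerate(pops):
        F_row = np.full(m, config.pop_F(pop))
        pop_freq[ki] = _beta_freq(rng, anc_p, F_row)

    # Sweeps: inside a sweep window every population of the target group
    # shares ONE elevated-F frequency draw per site — the swept haplotype is
    # common to the group, so the group's pooled heterozygosity (not just
    # each population's) drops by the reduction factor, while between-group
    # differentiation rises.
    for sw in config.sweep_specs:
        in_win = (chrom_arr == sw.chrom) & (positions >= sw.start) & (
            positions <= sw.end
        )
        if not in_win.any():
            continue
        members = [
            ki for ki, pop in enumerate(pops)
            if config.group_of[pop] == sw.target_group
        ]
        mean_base = float(
            np.mean([config.pop_F(pops[ki]) for ki in members])
        )
        f_sweep = _sweep_F(mean_base, sw.reduction)
        shared = _beta_freq(
            rng, anc_p[in_win], np.full(int(in_win.sum()), f_sweep)
        )
        for ki in members:
            pop_freq[ki, in_win] = shared

    if config.ld_copy_prob > 0.0 and m > 1:
        # first-order copying: a site inherits all population frequencies
        # from its predecessor (same chromosome) with probability ld_copy_prob
        copy = rng.random(m) < config.ld_copy_prob
        for j in range(1, m):
            if copy[j] and chrom_arr[j] == chrom_arr[j - 1]:
                pop_freq[:, j] = pop_freq[:, j - 1]

    samples: list[str] = []
    pop_of: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    q_rows: list[np.ndarray] = []
    for ki, pop in enumerate(pops):
        n = config.pop_sizes[pop]
        blocks.append(
            rng.binomial(2, pop_freq[ki][None, :], size=(n, m)).astype(np.int16)
        )
        onehot = np.zeros(len(pops))
        onehot[ki] = 1.0
        for i in range(n):
            sid = f"{pop}_{i + 1:03d}"
            samples.append(sid)
            pop_of[sid] = pop
            q_rows.append(onehot)
    for si, spec in enumerate(config.admixed_specs, start=1):
        q = np.array([spec.ancestry.get(p, 0.0) for p in pops])
        freq = q @ pop_freq
        blocks.append(
            rng.binomial(2, freq[None, :], size=(spec.count, m)).astype(np.int16)
        )
        for i in range(spec.count):
            sid = f"ADM{si}_{i + 1:03d}"
            samples.append(sid)
            pop_of[sid] = "ADMIXED"
            q_rows.append(q)

    dosage = (
        np.vstack(blocks) if blocks else np.zeros((0, m), dtype=np.int16)
    )
    if config.missing_rate > 0.0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = MISSING

    alt_choices = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4

    variants = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": positions,
            "ref": alt_choices[ref_idx],
            "alt": alt_choices[alt_idx],
            "id": [f"snp_{c}_{p}" for c, p in zip(chrom_arr, positions)],
        }
    )
    gm = GenotypeMatrix(
        samples=samples, pops=pop_of, variants=variants, dosage=dosage
    )
    truth = SweepTruth(
        sweep_windows=[
            (sw.chrom, sw.start, sw.end, sw.target_group)
            for sw in config.sweep_specs
        ],
        true_Q=pd.DataFrame(np.array(q_rows), index=samples, columns=pops),
        per_pop_F={p: config.pop_F(p) for p in pops},
        per_site_anc_freq=anc_p,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class GroupRecovery:
    group: str
    n_truth_windows: int  # grid windows overlapping a true sweep of this group
    n_called_windows: int  # grid windows overlapping a candidate region
    n_true_positive: int
    sensitivity: float | None
    precision: float | None


def _overlaps(chrom: str, start: int, end: int, intervals) -> bool:
    return any(
        c == chrom and start <= e and end >= s for c, s, e in intervals
    )


def score_recovery(
    candidates: Sequence,
    truth: SweepTruth,
    windows: Sequence,
) -> dict[str, GroupRecovery]:
    """Window-level sensitivity and precision of sweep calls, per target group.

    A grid window counts as *true* for group g if it overlaps any implanted
    sweep targeting g, and as *called* for g if it overlaps any candidate
    region with direction g.  Precision is None (NA) when nothing is called.
    """
    groups = sorted({g for *_, g in truth.sweep_windows})
    out: dict[str, GroupRecovery] = {}
    for g in groups:
        truth_iv = [
            (c, s, e) for c, s, e, tg in truth.sweep_windows if tg == g
        ]
        cand_iv = [
            (r.chrom, r.start, r.end) for r in candidates if r.direction == g
        ]
        n_truth = n_called = n_tp = 0
        for w in windows:
            is_true = _overlaps(w.chrom, w.start, w.end, truth_iv)
            is_called = _overlaps(w.chrom, w.start, w.end, cand_iv)
            n_truth += is_true
            n_called += is_called
            n_tp += is_true and is_called
        out[g] = GroupRecovery(
            group=g,
            n_truth_windows=n_truth,
            n_called_windows=n_called,
            n_true_positive=n_tp,
            sensitivity=(n_tp / n_truth) if n_truth else None,
            precision=(n_tp / n_called) if n_called else None,
        )
    return out
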