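"""Weir-Cockerham F_ST, nucleotide diversity, window grid, crossover scan."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan import (
    ChromLengths,
    GeneModel,
    MISSING,
    genes_in_regions,
    scan,
    site_fst,
    site_pi,
    tile_windows,
    window_pi,
)
from sweepscan.sweep import CandidateRegion, WindowStat, merge_flagged_windows, wc_components

from conftest import make_gm


# ---------------------------------------------------------------------------
# Weir-Cockerham estimator
# ---------------------------------------------------------------------------

def wc_longhand(dosage_pops):
    """Independent scalar transcription of the 1984 variance-component
    equations (explicit per-population loops, no vectorization)."""
    pops = [np.asarray(d) for d in dosage_pops]
    pops = [d[d != MISSING] for d in pops]
    r = len(pops)
    n_i = [len(d) for d in pops]
    if min(n_i) == 0:
        return float("nan"), float("nan"), float("nan")
    p_i = [d.sum() / (2.0 * n) for d, n in zip(pops, n_i)]
    h_i = [(d == 1).sum() / n for d, n in zip(pops, n_i)]
    n_bar = sum(n_i) / r
    if n_bar <= 1:
        return float("nan"), float("nan"), float("nan")
    n_c = (r * n_bar - sum(n * n for n in n_i) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def test_fst_fixed_difference_is_one():
    sf = site_fst([np.zeros(10, int), np.full(10, 2)])
    assert sf.theta == 1.0


def test_fst_hand_case_longhand():
    """n1=n2=2, dosages {0,1} and {1,2}: frozen longhand arithmetic."""
    sf = site_fst([np.array([0, 1]), np.array([1, 2])])
    assert sf.a == pytest.approx(0.0625, abs=1e-12)
    assert sf.b == pytest.approx(0.0, abs=1e-12)
    assert sf.c == pytest.approx(0.25, abs=1e-12)
    assert sf.theta == pytest.approx(0.2, abs=1e-12)


def test_fst_identical_populations_near_zero():
    rng = np.random.default_rng(8)
    col = rng.binomial(2, 0.5, size=20)
    sf = site_fst([col, col.copy()])
    assert sf.theta <= 0.0 or sf.theta < 1e-10  # estimator is slightly negative


@pytest.mark.parametrize("with_missing", [False, True])
def test_fst_matches_longhand_oracle_random_sites(with_missing):
    """Vectorized components equal the scalar oracle to 1e-10."""
    rng = np.random.default_rng(12)
    n = 20
    for _ in range(200):
        p1, p2 = rng.uniform(0.05, 0.95, size=2)
        d1 = rng.binomial(2, p1, size=n).astype(np.int16)
        d2 = rng.binomial(2, p2, size=n).astype(np.int16)
        if with_missing:
            d1[rng.random(n) < 0.1] = MISSING
            d2[rng.random(n) < 0.1] = MISSING
        exp = wc_longhand([d1, d2])
        sf = site_fst([d1, d2])
        for got, want in zip((sf.a, sf.b, sf.c), exp):
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)


def test_fst_r_population_support():
    """The estimator accepts r > 2 populations (breed-level mode)."""
    rng = np.random.default_rng(13)
    pops = [rng.binomial(2, p, size=12).astype(np.int16)
            for p in (0.2, 0.5, 0.8)]
    sf = site_fst(pops)
    exp = wc_longhand(pops)
    assert sf.a == pytest.approx(exp[0], abs=1e-10)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def pi_enumeration_oracle(dosages):
    """Mean pairwise difference over all haplotype pairs, by enumeration."""
    hap = []
    for d in dosages:
        if d != MISSING:
            hap += [1] * d + [0] * (2 - d)
    if len(hap) < 2:
        return 0.0
    diffs = sum(a != b for a, b in itertools.combinations(hap, 2))
    return diffs / comb(len(hap), 2)


def test_pi_single_heterozygote():
    assert site_pi(np.array([[1]]), np.array([0]))[0] == 1.0


def test_pi_m4_j2_equals_two_thirds():
    got = site_pi(np.array([[1], [1]]), np.array([0, 1]))[0]
    assert got == pytest.approx(2 / 3, abs=1e-12)
    assert got == pytest.approx(pi_enumeration_oracle([1, 1]), abs=1e-12)


def test_pi_equals_enumeration_all_configs_up_to_10_haplotypes():
    for n in range(1, 6):
        for dos in itertools.product([0, 1, 2, MISSING], repeat=n):
            got = float(
                site_pi(np.array(dos).reshape(-1, 1), np.arange(n))[0]
            )
            assert got == pytest.approx(
                pi_enumeration_oracle(dos), abs=1e-12
            ), dos


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=-1, max_value=2), min_size=1, max_size=12))
def test_pi_invariant_under_allele_label_swap(dosages):
    arr = np.array(dosages).reshape(-1, 1)
    swapped = np.where(arr == MISSING, MISSING, 2 - arr)
    idx = np.arange(len(dosages))
    assert site_pi(arr, idx)[0] == pytest.approx(
        site_pi(swapped, idx)[0], abs=1e-12
    )


def test_window_pi_per_bp_denominator():
    # one site with pi = 2/3 in a 40 kb window
    gm = make_gm(np.array([[1], [1]], dtype=np.int16), positions=[100])
    got = window_pi(gm, ["S1", "S2"], ("1", 1, 40_000))
    assert got == pytest.approx((2 / 3) / 40_000, rel=1e-9)
    assert got == pytest.approx(1.6667e-5, rel=1e-3)


# ---------------------------------------------------------------------------
# window grid
# ---------------------------------------------------------------------------

def enumerate_windows_oracle(L, size, step):
    out = []
    start = 1
    while start <= L:
        out.append((start, min(start + size - 1, L)))
        start += step
    return out


@pytest.mark.parametrize(
    "L, expected",
    [
        (100_000, [(1, 40_000), (20_001, 60_000), (40_001, 80_000),
                   (60_001, 100_000), (80_001, 100_000)]),
        (40_000, [(1, 40_000), (20_001, 40_000)]),
        (1, [(1, 1)]),
    ],
)
def test_tile_windows_enumeration(L, expected):
    got = tile_windows(ChromLengths.from_mapping({"1": L}))
    assert [(s, e) for _, s, e in got] == expected
    assert expected == enumerate_windows_oracle(L, 40_000, 20_000)


def test_tile_windows_multi_chromosome_ordering():
    grid = tile_windows(
        ChromLengths.from_mapping({"2": 50_000, "1": 30_000, "X": 25_000})
    )
    assert [g[0] for g in grid] == ["1", "1", "2", "2", "2", "X", "X"]


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def test_scan_single_site_window_equals_site_theta(k2_sim):
    """Ratio-of-sums over one site collapses to that site's theta."""
    _, gm, _ = k2_sim
    g1 = gm.samples_in_pops(["A"])
    g2 = gm.samples_in_pops(["B"])
    # isolate one polymorphic site into its own window
    j = 5
    sub = gm.subset_variants(np.array([j]))
    pos = int(sub.variants["pos"].iloc[0])
    windows, _, _ = scan(
        sub, g1, g2, ChromLengths.from_mapping({"1": pos + 1}),
        size=pos + 1, step=pos + 1,
    )
    w = windows[0]
    groups = [gm.sample_indices(g1), gm.sample_indices(g2)]
    a, b, c = wc_components(sub.dosage, groups)
    assert w.fst == pytest.approx(float(a[0] / (a + b + c)[0]), abs=1e-12)


def test_scan_antisymmetric_under_group_swap(sweep_sim):
    """Swapping groups negates the ratio and swaps the flag directions."""
    _, gm, _ = sweep_sim
    g1 = gm.samples_in_pops(["I1", "I2"])
    g2 = gm.samples_in_pops(["C1", "C2"])
    lengths = ChromLengths.from_mapping({"1": 5_000_000})
    w12, t12, _ = scan(gm, g1, g2, lengths, group_labels=("ind", "com"))
    w21, t21, _ = scan(gm, g2, g1, lengths, group_labels=("com", "ind"))
    for a, b in zip(w12, w21):
        assert a.fst == pytest.approx(b.fst, nan_ok=True, abs=1e-12)
        if np.isfinite(a.log2_ratio):
            assert a.log2_ratio == pytest.approx(-b.log2_ratio, abs=1e-9)
        assert a.flag == b.flag  # direction labels swap with the groups
    assert t12.realized_fst_cut == pytest.approx(t21.realized_fst_cut)
    assert t12.realized_low_cut == pytest.approx(-t21.realized_high_cut, abs=1e-9)


def test_scan_null_data_flags_at_most_tail_fraction():
    """No sweeps: each direction flags <= ~5% of usable windows."""
    from sweepscan import SimConfig, simulate

    cfg = SimConfig(
        pop_sizes={"A": 15, "B": 15},
        group_of={"A": "indigenous", "B": "commercial"},
        chrom_lengths=ChromLengths.from_mapping({"1": 4_000_000}),
        baseline_F=0.05,
        seed=21,
    )
    gm, _ = simulate(cfg)
    windows, _, _ = scan(
        gm, gm.samples_in_pops(["A"]), gm.samples_in_pops(["B"]),
        cfg.chrom_lengths,
    )
    usable = [w for w in windows if np.isfinite(w.fst)
              and np.isfinite(w.log2_ratio)]
    for direction in ("group1", "group2"):
        frac = sum(w.flag == direction for w in usable) / len(usable)
        assert frac <= 0.055


def test_scan_degenerate_identical_windows():
    """All windows identical: each quantile cut equals the common value and
    the inclusive >= / <= conventions flag every window (low tail wins)."""
    # one site per window, identical pattern: both groups polymorphic with
    # equal diversity (ratio 0) and a fixed between-group frequency contrast
    col = np.r_[np.ones(5), np.zeros(5), np.ones(5), np.full(5, 2)]
    dosage = np.tile(col[:, None], (1, 5)).astype(np.int16)
    pops = {f"S{i + 1}": ("A" if i < 10 else "B") for i in range(20)}
    gm = make_gm(dosage, positions=[50, 150, 250, 350, 450],
                 samples=[f"S{i + 1}" for i in range(20)], pops=pops)
    windows, th, _ = scan(
        gm, [f"S{i + 1}" for i in range(10)],
        [f"S{i + 11}" for i in range(10)],
        ChromLengths.from_mapping({"1": 500}), size=100, step=100,
    )
    fsts = {w.fst for w in windows}
    assert len(fsts) == 1
    common_fst = fsts.pop()
    assert th.realized_fst_cut == pytest.approx(common_fst, abs=1e-12)
    assert th.realized_low_cut == pytest.approx(0.0, abs=1e-12)
    assert th.realized_high_cut == pytest.approx(0.0, abs=1e-12)
    # fst >= cut and ratio <= low cut hold with equality -> low tail flags all
    assert all(w.flag == "group1" for w in windows)


def test_merge_flagged_windows():
    w1 = WindowStat("1", 1, 40_000, 5, 0.9, 1e-5, 1e-4, -3.0, "g1")
    w2 = WindowStat("1", 20_001, 60_000, 5, 0.8, 1e-5, 1e-4, -2.5, "g1")
    w3 = WindowStat("1", 100_001, 140_000, 5, 0.7, 1e-4, 1e-5, 3.0, "g2")
    regions = merge_flagged_windows([w1, w2, w3], low_tail_labels={"g1"})
    assert len(regions) == 2
    r1 = [r for r in regions if r.direction == "g1"][0]
    assert (r1.start, r1.end, r1.n_windows) == (1, 60_000, 2)
    assert r1.max_fst == pytest.approx(0.9)
    assert r1.extreme_log2_ratio == pytest.approx(-3.0)


def test_scan_recovers_implanted_sweep(sweep_sim):
    """>= 80% of implanted windows flagged for the right group; none for
    the wrong group inside the sweep."""
    cfg, gm, truth = sweep_sim
    from sweepscan import score_recovery

    windows, realized, regions = scan(
        gm,
        gm.samples_in_pops(["I1", "I2"]),
        gm.samples_in_pops(["C1", "C2"]),
        cfg.chrom_lengths,
        group_labels=("indigenous", "commercial"),
    )
    rec = score_recovery(regions, truth, windows)["indigenous"]
    assert rec.sensitivity >= 0.8
    assert rec.precision >= 0.5
    wrong = [
        w for w in windows
        if w.flag == "commercial" and w.start <= 2_200_000
        and w.end >= 2_000_001
    ]
    assert wrong == []


# ---------------------------------------------------------------------------
# gene overlap
# ---------------------------------------------------------------------------

def _reg(start, end, direction="g1"):
    return CandidateRegion("1", start, end, 1, direction, 0.9, -2.0)


def test_genes_in_regions_overlap_rules():
    genes = [
        GeneModel("G1", "G1", "1", 10_000, 50_000),
        GeneModel("G2", "G2", "1", 1, 100),
        GeneModel("G3", "G3", "1", 150_000, 400_000),  # spans two regions
    ]
    regions = [_reg(40_000, 80_000), _reg(200, 300),
               _reg(140_000, 200_000), _reg(300_000, 350_000)]
    out = genes_in_regions(regions, genes)
    assert [g.gene_id for g in out["g1"]] == ["G1", "G3"]  # G3 listed once


def test_genes_in_regions_per_direction():
    genes = [GeneModel("G1", "G1", "1", 10, 20)]
    out = genes_in_regions([_reg(1, 100, "g1"), _reg(1, 100, "g2")], genes)
    assert [g.gene_id for g in out["g1"]] == ["G1"]
    assert [g.gene_id for g in out["g2"]] == ["G1"]
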