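"""PCA, admixture EM + CV, IBS distances, neighbor joining."""

import numpy as np
import pytest

from sweepscan import MISSING
from sweepscan.structure import (
    DistanceMatrix,
    TreeNode,
    admixture_cv,
    admixture_em,
    align_q_to_truth,
    ibs_matrix,
    neighbor_joining,
    pca,
)

from conftest import make_gm


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_separates_two_populations(k2_sim):
    """At F=0.3 the first component splits the populations with no overlap."""
    _, gm, _ = k2_sim
    res = pca(gm, n_components=2)
    lab = gm.pop_labels()
    a = res.coords[lab == "A", 0]
    b = res.coords[lab == "B", 0]
    assert a.max() < b.min() or b.max() < a.min()
    assert res.explained[0] > res.explained[1]


def test_pca_identical_samples_degenerate():
    dosage = np.tile([0, 1, 2, 1], (5, 1)).astype(np.int16)
    gm = make_gm(dosage)
    res = pca(gm, n_components=2)
    assert np.allclose(res.coords, 0.0)
    assert np.allclose(res.explained, 0.0)


def test_pca_scores_centered(k2_sim):
    _, gm, _ = k2_sim
    res = pca(gm, n_components=4)
    assert np.abs(res.coords.mean(axis=0)).max() < 1e-8


def test_pca_duplicating_samples_preserves_directions(k2_sim):
    """Doubling every sample leaves per-sample scores unchanged (up to the
    common eigen-structure scaling)."""
    _, gm, _ = k2_sim
    sub = gm.subset_samples(gm.samples[:20]).subset_variants(np.arange(300))
    res1 = pca(sub, n_components=2)
    dup = make_gm(
        np.vstack([sub.dosage, sub.dosage]),
        positions=sub.variants["pos"].tolist(),
    )
    res2 = pca(dup, n_components=2)
    # scores of the duplicated halves coincide...
    assert np.allclose(res2.coords[:20], res2.coords[20:], atol=1e-8)
    # ...and correlate perfectly with the originals, component by component
    for c in range(2):
        r = np.corrcoef(res1.coords[:, c], res2.coords[:20, c])[0, 1]
        assert abs(r) > 1 - 1e-8


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------

def test_admixture_k1_closed_form(k2_sim):
    """K=1: Q is all ones and F equals the observed alternate frequency."""
    _, gm, _ = k2_sim
    sub = gm.subset_variants(np.arange(200))
    fit = admixture_em(sub, K=1, seed=0, n_restarts=1)
    assert np.allclose(fit.Q, 1.0)
    p = np.clip(sub.alt_allele_freq(), 1e-6, 1 - 1e-6)
    assert np.allclose(fit.F[0], p, atol=1e-10)


def test_admixture_loglik_monotone(k2_sim):
    _, gm, _ = k2_sim
    sub = gm.subset_variants(np.arange(300))
    fit = admixture_em(sub, K=3, seed=5, n_restarts=1, max_iter=120)
    deltas = np.diff(fit.loglik_trace)
    assert (deltas >= -1e-6).all()


def test_admixture_q_rows_sum_to_one(k2_sim):
    _, gm, _ = k2_sim
    fit = admixture_em(
        gm.subset_variants(np.arange(200)), K=2, seed=1, n_restarts=1,
        max_iter=50,
    )
    assert np.allclose(fit.Q.sum(axis=1), 1.0, atol=1e-8)
    assert fit.F.min() >= 1e-6 and fit.F.max() <= 1 - 1e-6


def test_admixture_k_exceeding_samples_is_error(k2_sim):
    _, gm, _ = k2_sim
    with pytest.raises(ValueError, match="exceeds sample count"):
        admixture_em(gm, K=gm.n_samples + 1)


def test_admixture_recovers_two_populations(k2_sim):
    """Max-ancestry assignment matches the true population for all samples."""
    _, gm, truth = k2_sim
    fit = admixture_em(gm, K=2, seed=3, n_restarts=3, max_iter=200)
    q = align_q_to_truth(fit.Q, truth.true_Q.to_numpy())
    assign = q.argmax(axis=1)
    true_assign = truth.true_Q.to_numpy().argmax(axis=1)
    assert (assign == true_assign).all()
    rmse = float(np.sqrt(((q - truth.true_Q.to_numpy()) ** 2).mean()))
    assert rmse < 0.05


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_cv_partition_arithmetic():
    dosage = np.array([[0, 1], [2, MISSING]], dtype=np.int16)
    gm = make_gm(dosage)
    # 3 observed entries over 2 folds -> fold sizes 2 and 1
    errors, best = admixture_cv(gm, [1], folds=2, seed=0, n_restarts=1,
                                max_iter=20)
    assert set(errors) == {1}


def test_cv_deterministic_given_seed(k2_sim):
    _, gm, _ = k2_sim
    sub = gm.subset_samples(gm.samples[:16]).subset_variants(np.arange(150))
    r1 = admixture_cv(sub, [2], folds=3, seed=9, n_restarts=1, max_iter=60)
    r2 = admixture_cv(sub, [2], folds=3, seed=9, n_restarts=1, max_iter=60)
    assert r1 == r2


def test_cv_prefers_true_k(k2_sim):
    _, gm, _ = k2_sim
    sub = gm.subset_variants(np.arange(600))
    errors, best = admixture_cv(sub, [1, 2], folds=3, seed=4, n_restarts=2,
                                max_iter=150)
    assert errors[2] < errors[1]
    assert best == 2


# ---------------------------------------------------------------------------
# IBS
# ---------------------------------------------------------------------------

def test_ibs_hand_cases():
    gm = make_gm(np.array([[0, 1], [0, 1], [2, MISSING]], dtype=np.int16))
    dm = ibs_matrix(gm, strict=False)
    assert dm.d[0, 1] == 0.0  # identical samples
    assert dm.d[0, 2] == 1.0  # opposite homozygotes at the only shared site

    gm2 = make_gm(np.array([[0, 1], [1, 1]], dtype=np.int16))
    dm2 = ibs_matrix(gm2)
    # shared alleles 1 + 2 of 4 -> similarity 0.75, distance 0.25
    assert dm2.d[0, 1] == pytest.approx(0.25)


def test_ibs_properties(k2_sim):
    _, gm, _ = k2_sim
    dm = ibs_matrix(gm.subset_samples(gm.samples[:12]))
    assert np.allclose(dm.d, dm.d.T)
    assert np.allclose(np.diag(dm.d), 0.0)
    assert dm.d.min() >= 0.0 and dm.d.max() <= 1.0


def test_ibs_zero_overlap_strict_error():
    gm = make_gm(np.array([[0, MISSING], [MISSING, 2]], dtype=np.int16))
    with pytest.raises(ValueError, match="zero overlapping"):
        ibs_matrix(gm, strict=True)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def random_additive_tree(n, rng):
    pool = [TreeNode(name=f"L{i}") for i in range(n)]
    while len(pool) > 2:
        j, i = sorted(rng.choice(len(pool), 2, replace=False), reverse=True)
        a, b = pool.pop(j), pool.pop(i)
        pool.append(
            TreeNode(children=[
                (a, float(rng.uniform(0.1, 2.0))),
                (b, float(rng.uniform(0.1, 2.0))),
            ])
        )
    return TreeNode(children=[
        (pool[0], float(rng.uniform(0.1, 2.0))),
        (pool[1], float(rng.uniform(0.1, 2.0))),
    ])


def test_nj_four_taxon_exact():
    """NJ is consistent on additive matrices: exact recovery."""
    tree = TreeNode(children=[
        (TreeNode(children=[(TreeNode(name="A"), 1.0),
                            (TreeNode(name="B"), 2.0)]), 1.0),
        (TreeNode(children=[(TreeNode(name="C"), 3.0),
                            (TreeNode(name="D"), 4.0)]), 0.0),
    ])
    names, d = tree.leaf_distances()
    out = neighbor_joining(DistanceMatrix(labels=names, d=d))
    names2, d2 = out.leaf_distances()
    order = [names2.index(x) for x in names]
    assert np.abs(d2[np.ix_(order, order)] - d).max() < 1e-9


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    out = neighbor_joining(DistanceMatrix(labels=["A", "B", "C"], d=d))
    lengths = {child.name: L for child, L in out.children}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)


@pytest.mark.parametrize("trial", range(10))
def test_nj_recovers_random_additive_trees(trial):
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(4, 9))
    tree = random_additive_tree(n, rng)
    names, d = tree.leaf_distances()
    out = neighbor_joining(DistanceMatrix(labels=names, d=d))
    names2, d2 = out.leaf_distances()
    order = [names2.index(x) for x in names]
    assert np.abs(d2[np.ix_(order, order)] - d).max() < 1e-9


def test_nj_matches_skbio_on_additive_matrix():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(55)
    tree = random_additive_tree(6, rng)
    names, d = tree.leaf_distances()
    ours = neighbor_joining(DistanceMatrix(labels=names, d=d))
    ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=names))
    _, d_ours = ours.leaf_distances()
    names_ours, _ = ours.leaf_distances()
    for i, a in enumerate(names_ours):
        for j, b in enumerate(names_ours):
            if i < j:
                assert d_ours[i, j] == pytest.approx(
                    ref.find(a).distance(ref.find(b)), abs=1e-8
                )


def test_nj_label_permutation_isomorphic():
    rng = np.random.default_rng(77)
    tree = random_additive_tree(6, rng)
    names, d = tree.leaf_distances()
    out1 = neighbor_joining(DistanceMatrix(labels=names, d=d))
    perm = rng.permutation(len(names))
    names_p = [names[i] for i in perm]
    out2 = neighbor_joining(
        DistanceMatrix(labels=names_p, d=d[np.ix_(perm, perm)])
    )
    n1, d1 = out1.leaf_distances()
    n2, d2 = out2.leaf_distances()
    order = [n2.index(x) for x in n1]
    assert np.abs(d2[np.ix_(order, order)] - d1).max() < 1e-9


def test_nj_rejects_asymmetric_input():
    d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(labels=["A", "B", "C"], d=d)


def test_nj_branch_lengths_non_negative(k2_sim):
    _, gm, _ = k2_sim
    dm = ibs_matrix(gm.subset_samples(gm.samples[:15]))
    tree = neighbor_joining(dm)

    def walk(node):
        for child, length in node.children:
            assert length >= 0.0
            walk(child)

    walk(tree)
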