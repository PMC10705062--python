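"""Population-structure analyses: PCA, model-based ancestry, IBS, NJ tree.

PCA operates on Patterson-standardized dosages (mean-centered, scaled by
sqrt(p(1-p))).  Ancestry fractions are estimated under the binomial
admixture model g_ij ~ Binomial(2, sum_k q_ik f_kj) by plain EM (monotone in
log-likelihood), with seeded multi-restart and K selected by masked-entry
cross-validation.  Identity-by-state distances feed a Saitou-Nei
neighbor-joining tree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-6


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    coords: np.ndarray  # samples x components
    explained: np.ndarray  # variance fraction per component
    loadings_available: bool = False


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Principal components of the standardized genotype matrix.

    Missing dosages are mean-imputed per variant before standardization;
    each column is centered and scaled by sqrt(p(1-p)) with p the sample
    alternate-allele frequency.  Zero-variance columns are excluded with a
    warning.  Component sign is fixed so the largest-magnitude score entry
    of each component is positive.
    """
    if gm.n_samples < 2 or gm.n_variants < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variants")
    x = gm.dosage.astype(float)
    miss = gm.missing_mask
    x[miss] = np.nan
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(miss)
    x[inds] = np.take(col_mean, inds[1])

    p = col_mean / 2.0
    scale = np.sqrt(p * (1.0 - p))
    usable = (scale > 0) & (x.std(axis=0) > 0)
    if not usable.all():
        warnings.warn(
            f"PCA: excluding {int((~usable).sum())} zero-variance variants",
            stacklevel=2,
        )
    if not usable.any():
        # fully degenerate input: all samples identical at every variant
        k = min(n_components, gm.n_samples)
        return PcaResult(
            coords=np.zeros((gm.n_samples, k)), explained=np.zeros(k)
        )
    x = (x[:, usable] - col_mean[usable]) / scale[usable]

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    total_var = (s**2).sum()
    explained = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    # deterministic sign: largest-magnitude entry of each component positive
    for c in range(k):
        j = int(np.argmax(np.abs(coords[:, c])))
        if coords[j, c] < 0:
            coords[:, c] = -coords[:, c]
    return PcaResult(coords=coords, explained=explained)


# ---------------------------------------------------------------------------
# admixture model (binomial EM)
# ---------------------------------------------------------------------------

@dataclass
class AncestryFit:
    K: int
    Q: np.ndarray  # samples x K ancestry fractions
    F: np.ndarray  # K x variants cluster alternate-allele frequencies
    loglik_trace: list[float] = field(default_factory=list)
    cv_error: float | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else float("-inf")


def _em_loglik(g, obs, q, f) -> float:
    p = np.clip(q @ f, _EPS, 1.0 - _EPS)
    with np.errstate(invalid="ignore"):
        ll = g * np.log(p) + (2.0 - g) * np.log(1.0 - p)
    return float(ll[obs].sum())


def _em_once(
    g: np.ndarray,
    obs: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> AncestryFit:
    n, m = g.shape
    gz = np.where(obs, g, 0.0)
    g2z = np.where(obs, 2.0 - g, 0.0)
    q = rng.dirichlet(np.ones(K), size=n)
    q = np.clip(q, _EPS, 1.0 - _EPS)
    q /= q.sum(axis=1, keepdims=True)
    f = np.clip(rng.uniform(0.05, 0.95, size=(K, m)), _EPS, 1.0 - _EPS)

    trace: list[float] = []
    # alleles observed per sample; samples with no observed entries keep a
    # (renormalized) uniform Q rather than dividing by zero
    per_row = np.maximum(2.0 * obs.sum(axis=1, keepdims=True), 1e-300)
    for _ in range(max_iter):
        p = np.clip(q @ f, _EPS, 1.0 - _EPS)
        ra = gz / p
        rb = g2z / (1.0 - p)
        # expected ancestral allele-copy counts, summed over sites / samples
        a_ik = q * (ra @ f.T)
        b_ik = q * (rb @ (1.0 - f).T)
        a_kj = f * (q.T @ ra)
        ab_kj = a_kj + (1.0 - f) * (q.T @ rb)

        q = (a_ik + b_ik) / per_row
        q = np.clip(q, _EPS, 1.0)
        q /= q.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(ab_kj > 0, a_kj / ab_kj, f)
        f = np.clip(f, _EPS, 1.0 - _EPS)

        ll = _em_loglik(g, obs, q, f)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
    return AncestryFit(K=K, Q=q, F=f, loglik_trace=trace)


def admixture_em(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_restarts: int = 5,
) -> AncestryFit:
    """Fit the K-cluster admixture model by EM, keeping the best of
    ``n_restarts`` seeded random initializations."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_samples:
        raise ValueError(f"K={K} exceeds sample count {gm.n_samples}")
    g = gm.dosage.astype(float)
    obs = ~gm.missing_mask
    if not obs.any():
        raise ValueError("no observed genotypes")
    root = np.random.default_rng(seed)
    best: AncestryFit | None = None
    for _ in range(max(1, n_restarts)):
        fit = _em_once(g, obs, K, root, max_iter, tol)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


class AdmixtureModel:
    """Thin estimator-style wrapper: ``fit`` stores ``Q_``, ``F_``, etc."""

    def __init__(self, K: int, seed: int = 0, max_iter: int = 500,
                 tol: float = 1e-4, n_restarts: int = 5):
        self.K = K
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts

    def fit(self, gm: GenotypeMatrix) -> "AdmixtureModel":
        fit = admixture_em(
            gm, self.K, seed=self.seed, max_iter=self.max_iter,
            tol=self.tol, n_restarts=self.n_restarts,
        )
        self.Q_ = fit.Q
        self.F_ = fit.F
        self.loglik_trace_ = fit.loglik_trace
        return self


def admixture_cv(
    gm: GenotypeMatrix,
    K_range,
    folds: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_restarts: int = 5,
) -> tuple[dict[int, float], int]:
    """Masked-entry cross-validation over K; returns (per-K error, best K).

    Non-missing genotype entries are partitioned into ``folds`` random sets;
    per fold the held-out entries are masked during EM and scored by the
    squared-dosage prediction error mean((g - 2 sum_k q f)^2) / 2.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    obs_idx = np.flatnonzero(~gm.missing_mask.ravel())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(obs_idx)
    fold_assign = np.arange(len(perm)) % folds  # fold per *permuted* entry

    errors: dict[int, float] = {}
    for K in K_range:
        fold_errs = []
        for f_id in range(folds):
            masked_flat = perm[fold_assign == f_id]
            dm = gm.dosage.copy()
            flat = dm.ravel()
            held_g = flat[masked_flat].astype(float)
            flat[masked_flat] = MISSING
            gm_masked = GenotypeMatrix(
                samples=list(gm.samples),
                pops=dict(gm.pops),
                variants=gm.variants.copy(),
                dosage=dm,
            )
            empty_variants = np.flatnonzero(
                (~gm_masked.missing_mask).sum(axis=0) == 0
            )
            if len(empty_variants) > 0:
                warnings.warn(
                    f"CV fold {f_id}: {len(empty_variants)} variants fully "
                    "masked; their entries are skipped",
                    stacklevel=2,
                )
            sub_seed = int(
                np.random.default_rng((seed, K, f_id)).integers(2**31)
            )
            fit = admixture_em(
                gm_masked, K, seed=sub_seed, max_iter=max_iter, tol=tol,
                n_restarts=n_restarts,
            )
            pred = 2.0 * np.clip(fit.Q @ fit.F, _EPS, 1.0 - _EPS).ravel()
            cols = masked_flat % gm.n_variants
            ok = ~np.isin(cols, empty_variants)
            err = float(np.mean((held_g[ok] - pred[masked_flat][ok]) ** 2) / 2.0)
            fold_errs.append(err)
        errors[K] = float(np.mean(fold_errs))
        logger.info("CV error K=%d: %.6f", K, errors[K])
    best_K = min(errors, key=lambda k: (errors[k], k))
    return errors, best_K


def align_q_to_truth(Q: np.ndarray, true_Q: np.ndarray) -> np.ndarray:
    """Permute columns of Q to best match a truth matrix (min RMSE)."""
    from itertools import permutations

    K = Q.shape[1]
    best_perm = min(
        permutations(range(K)),
        key=lambda perm: float(((Q[:, perm] - true_Q) ** 2).sum()),
    )
    return Q[:, best_perm]


# ---------------------------------------------------------------------------
# identity-by-state distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


def ibs_matrix(gm: GenotypeMatrix, *, strict: bool = True) -> DistanceMatrix:
    """1 - IBS allele-sharing distance between all sample pairs.

    Per pair, over sites non-missing in both samples, each site contributes
    2 - |dosage_s - dosage_t| shared alleles out of 2.  Pairs with zero
    overlapping sites are an error in strict mode, NaN otherwise.
    """
    if gm.n_samples < 2:
        raise ValueError("IBS needs at least 2 samples")
    d = gm.dosage.astype(float)
    valid = ~gm.missing_mask
    dz = np.where(valid, d, 0.0)
    v = valid.astype(float)
    # sum over shared sites of |ds - dt| via the identity
    # |x - y| with x,y in {0,1,2}: expand over one-hot dosage classes
    n_pair = v @ v.T
    abs_diff = np.zeros_like(n_pair)
    onehots = [(d == k) & valid for k in (0, 1, 2)]
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            abs_diff += abs(a - b) * (
                onehots[a].astype(float) @ onehots[b].astype(float).T
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = abs_diff / (2.0 * n_pair)
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist).any():
        if strict:
            raise ValueError("sample pair with zero overlapping genotyped sites")
    return DistanceMatrix(labels=list(gm.samples), d=dist)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Tree node: leaves carry names, children carry branch lengths."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Pairwise path-length distances between leaves (tree metric)."""
        names: list[str] = []
        dists: list[dict[str, float]] = []

        def walk(node: TreeNode) -> dict[str, float]:
            if not node.children:
                names.append(node.name or "")
                return {node.name or "": 0.0}
            merged: dict[str, float] = {}
            sub = []
            for child, length in node.children:
                below = {k: v + length for k, v in walk(child).items()}
                sub.append(below)
                merged.update(below)
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for na, da in sub[i].items():
                        for nb, db in sub[j].items():
                            dists.append({na: da, nb: db})
            return merged

        walk(self)
        n = len(names)
        idx = {nm: i for i, nm in enumerate(names)}
        mat = np.zeros((n, n))
        for pair in dists:
            (na, da), (nb, db) = pair.items()
            mat[idx[na], idx[nb]] = mat[idx[nb], idx[na]] = da + db
        return names, mat


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion go to the smallest (i, j) in current label
    order.  Negative branch lengths are clamped to zero with the deficit
    moved to the sister branch, so each joined pair keeps its summed length.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        half = dm.d[0, 1] / 2.0
        return TreeNode(children=[
            (TreeNode(name=dm.labels[0]), half),
            (TreeNode(name=dm.labels[1]), half),
        ])
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    d = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        row_sum = d.sum(axis=1)
        qmat = (m - 2) * d - row_sum[:, None] - row_sum[None, :]
        np.fill_diagonal(qmat, np.inf)
        qmin = qmat.min()
        ties = np.argwhere(np.isclose(qmat, qmin, rtol=0, atol=1e-12))
        i, j = min((a, b) for a, b in ties if a < b)
        vi = d[i, j] / 2.0 + (row_sum[i] - row_sum[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)
        new = TreeNode(children=[(nodes[i], vi), (nodes[j], vj)])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    # resolve the final three nodes around one internal vertex
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    v0 = (d01 + d02 - d12) / 2.0
    v1 = d01 - v0
    v2 = d02 - v0
    branches = [max(v, 0.0) for v in (v0, v1, v2)]
    return TreeNode(children=list(zip(nodes, branches)))


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    if vi < 0.0:
        vj += vi
        vi = 0.0
    if vj < 0.0:
        vi = max(vi + vj, 0.0)
        vj = 0.0
    return vi, vj
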