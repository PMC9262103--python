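"""Canonical correlation analysis with permutation significance testing.

CCA finds paired linear combinations P = XA and Q = YB of two data blocks
that are maximally correlated.  It is solved here by whitening each block
with the inverse square root of its covariance (eigendecomposition with a
hard relative eigenvalue floor — no silent ridge) and taking the SVD of the
whitened cross-covariance; the singular values are the canonical
correlations.

Significance uses a max-statistic permutation scheme: rows of Y are permuted
(optionally in whole exchangeability blocks, e.g. families) and the *first*
canonical correlation of each permuted fit forms the null.  Comparing every
observed correlation against this null controls the familywise error across
components, and the number of significant pairs is counted sequentially,
stopping at the first non-significant one.

Interpretation uses canonical loadings (structure coefficients): the
correlation of each canonical variable with the observed variables and with
the reduced-space factors fed into CCA.  Variance explained by a canonical
variable in a block is the mean squared observed-variable loading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import SubjectTable
from .ddr import ReducedData

__all__ = [
    "CCAModel",
    "LoadingSet",
    "PermutationResult",
    "BlockPCA",
    "fit_cca",
    "reduce_block_pca",
    "canonical_loadings",
    "permutation_test",
    "run_cca_pipeline",
]

#: relative eigenvalue floor below which a block is declared rank-deficient
EIG_FLOOR = 1e-10


@dataclass
class CCAModel:
    """Fitted canonical correlation model."""

    weights_A: np.ndarray  # p × m
    weights_B: np.ndarray  # q × m
    variables_P: np.ndarray  # N × m, canonical variables of X
    variables_Q: np.ndarray  # N × m, canonical variables of Y
    correlations: np.ndarray  # m, non-increasing, in [0, 1]
    x_mean: np.ndarray
    y_mean: np.ndarray

    @property
    def m(self) -> int:
        return self.correlations.size

    def transform(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project new data with the fitted weights (training means removed)."""
        return (X - self.x_mean) @ self.weights_A, (Y - self.y_mean) @ self.weights_B


@dataclass
class LoadingSet:
    """Canonical loadings for one block."""

    observed_loadings: np.ndarray  # variables × m
    factor_loadings: np.ndarray  # factors × m
    ve_pct: np.ndarray  # m
    observed_names: list[str]
    factor_names: list[str]


@dataclass
class PermutationResult:
    n_perm: int
    null_max_corr: np.ndarray
    p_values: np.ndarray
    n_significant: int
    alpha: float


def _inv_sqrt_cov(S: np.ndarray, name: str) -> np.ndarray:
    w, Q = np.linalg.eigh(S)
    if w[-1] <= 0 or w[0] < EIG_FLOOR * w[-1]:
        raise np.linalg.LinAlgError(
            f"{name} block is (near-)rank-deficient "
            f"(relative eigenvalue floor {EIG_FLOOR:g}); "
            "reduce its dimension further before CCA"
        )
    return (Q / np.sqrt(w)) @ Q.T


def fit_cca(X: np.ndarray, Y: np.ndarray) -> CCAModel:
    """Fit CCA via SVD of the whitened cross-covariance."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    N, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != N:
        raise ValueError("X and Y must have the same number of rows")
    if N <= p or N <= q:
        raise ValueError(
            f"need more subjects than variables per block (N={N}, p={p}, q={q})"
        )
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    Sxx = Xc.T @ Xc / (N - 1)
    Syy = Yc.T @ Yc / (N - 1)
    Sxy = Xc.T @ Yc / (N - 1)
    Kx = _inv_sqrt_cov(Sxx, "X")
    Ky = _inv_sqrt_cov(Syy, "Y")
    U, s, Vt = np.linalg.svd(Kx @ Sxy @ Ky, full_matrices=False)
    A = Kx @ U
    B = Ky @ Vt.T
    P = Xc @ A
    Q = Yc @ B
    # resolve the per-component sign indeterminacy deterministically: the
    # subject with the largest |canonical score| gets a positive score; the
    # joint (P, Q) flip leaves every canonical correlation unchanged and
    # makes canonical variables invariant to column sign-flips of the inputs
    for i in range(s.size):
        j = int(np.argmax(np.abs(P[:, i])))
        if P[j, i] < 0:
            A[:, i] *= -1.0
            B[:, i] *= -1.0
            P[:, i] *= -1.0
            Q[:, i] *= -1.0
    return CCAModel(
        weights_A=A,
        weights_B=B,
        variables_P=P,
        variables_Q=Q,
        correlations=np.clip(s, 0.0, 1.0),
        x_mean=x_mean,
        y_mean=y_mean,
    )


class BlockPCA:
    """Plain PCA used to further compress an over-wide reduced block.

    Keeps the training means and loadings so that held-out data can be
    projected into the same component space.
    """

    def __init__(self, n_components: int):
        self.n_components = int(n_components)
        self.mean_: np.ndarray | None = None
        self.components_: np.ndarray | None = None  # d × n_components
        self.singular_values_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "BlockPCA":
        X = np.asarray(X, dtype=float)
        if self.n_components > X.shape[1]:
            raise ValueError("n_components exceeds input dimension")
        self.mean_ = X.mean(axis=0)
        _, s, Vt = np.linalg.svd(X - self.mean_, full_matrices=False)
        self.components_ = Vt[: self.n_components].T
        self.singular_values_ = s[: self.n_components]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.components_ is None:
            raise RuntimeError("fit before transform")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def reduce_block_pca(reduced: ReducedData, target_dim: int) -> np.ndarray:
    """First ``target_dim`` principal-component scores of a reduced block."""
    return BlockPCA(target_dim).fit_transform(reduced.components)


def _corr_columns(scores: np.ndarray, data: np.ndarray, what: str) -> np.ndarray:
    """Pearson correlation of every data column with every score column."""
    N = scores.shape[0]
    sc = scores - scores.mean(axis=0)
    dc = data - data.mean(axis=0)
    s_sd = sc.std(axis=0)
    d_sd = dc.std(axis=0)
    out = np.zeros((data.shape[1], scores.shape[1]))
    zero = d_sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance {what} column(s); loadings set to 0",
            stacklevel=3,
        )
    ok = ~zero
    out[ok] = (dc[:, ok].T @ sc) / (N * np.outer(d_sd[ok], s_sd))
    return np.clip(out, -1.0, 1.0)


def canonical_loadings(
    model: CCAModel,
    observed: SubjectTable | None,
    factors: ReducedData | np.ndarray,
    side: str = "x",
) -> LoadingSet:
    """Canonical loadings of one block's canonical variables.

    ``observed`` carries the post-preprocessing observed variables (what CCA
    ultimately summarizes); ``factors`` the reduced-space columns that were
    fed to CCA.  ``side`` selects which block's canonical variables to use.
    When ``observed`` is None the factor columns double as observed ones.
    """
    scores = model.variables_P if side == "x" else model.variables_Q
    if isinstance(factors, ReducedData):
        fac_vals, fac_names = factors.components, list(factors.factor_labels)
    else:
        fac_vals = np.asarray(factors, dtype=float)
        fac_names = [f"factor_{i + 1}" for i in range(fac_vals.shape[1])]
    if observed is not None:
        obs_vals, obs_names = observed.values, list(observed.variable_names)
    else:
        obs_vals, obs_names = fac_vals, fac_names
    obs_load = _corr_columns(scores, obs_vals, "observed")
    fac_load = _corr_columns(scores, fac_vals, "factor")
    ve = 100.0 * (obs_load**2).mean(axis=0)
    return LoadingSet(
        observed_loadings=obs_load,
        factor_loadings=fac_load,
        ve_pct=ve,
        observed_names=obs_names,
        factor_names=fac_names,
    )


def _permuted_order(
    n: int,
    blocks: np.ndarray | None,
    scheme: str,
    rng: np.random.Generator,
) -> np.ndarray:
    if blocks is None:
        return rng.permutation(n)
    blocks = np.asarray(blocks)
    labels, inverse = np.unique(blocks, return_inverse=True)
    groups = [np.flatnonzero(inverse == g) for g in range(labels.size)]
    sizes = {len(g) for g in groups}
    if scheme == "exchange":
        if len(sizes) > 1:
            raise ValueError(
                "exchangeability blocks of unequal sizes; "
                "use scheme='within' (within-block permutation) instead"
            )
        order = np.empty(n, dtype=int)
        shuffled = [groups[i] for i in rng.permutation(len(groups))]
        pos = 0
        for src, dst in zip(shuffled, groups):
            order[dst] = src
            pos += len(src)
        return order
    if scheme == "within":
        order = np.arange(n)
        for g in groups:
            order[g] = g[rng.permutation(len(g))]
        return order
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    blocks: np.ndarray | None = None,
    rng_seed: int = 0,
    scheme: str = "exchange",
    per_component: bool = False,
) -> PermutationResult:
    """Max-statistic permutation test of the canonical correlations.

    Rows of Y are permuted ``n_perm`` times (unrestricted, or respecting
    exchangeability blocks when given); the null statistic is the first
    canonical correlation of each permuted fit.  ``p_values[i] =
    (1 + #{null >= r_i}) / (1 + n_perm)`` and ``n_significant`` counts
    components sequentially until the first non-significant one.

    With ``per_component=True`` each component is instead compared to the
    null of its own index (no familywise control).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    N = X.shape[0]
    model = fit_cca(X, Y)
    # permuting rows leaves each block's covariance unchanged, so whitening
    # can be reused and each permutation is a small SVD of the cross term
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Zx = Xc @ _inv_sqrt_cov(Xc.T @ Xc / (N - 1), "X")
    Zy = Yc @ _inv_sqrt_cov(Yc.T @ Yc / (N - 1), "Y")
    rng = np.random.default_rng(rng_seed)
    m = model.m
    null = np.zeros((n_perm, m)) if per_component else np.zeros((n_perm, 1))
    for b in range(n_perm):
        order = _permuted_order(N, blocks, scheme, rng)
        s = np.linalg.svd(Zx.T @ Zy[order] / (N - 1), compute_uv=False)
        if per_component:
            null[b] = s[:m]
        else:
            null[b, 0] = s[0]
    r = model.correlations
    if per_component:
        p = (1 + (null >= r[None, :]).sum(axis=0)) / (1 + n_perm)
        p = np.maximum.accumulate(p)  # enforce monotone step-down ordering
        null_max = null[:, 0]
    else:
        null_max = null[:, 0]
        p = (1 + (null_max[:, None] >= r[None, :]).sum(axis=0)) / (1 + n_perm)
    n_sig = 0
    for pi in p:
        if pi < alpha:
            n_sig += 1
        else:
            break
    return PermutationResult(
        n_perm=n_perm,
        null_max_corr=null_max,
        p_values=p,
        n_significant=n_sig,
        alpha=alpha,
    )


def run_cca_pipeline(
    sm_reduced: ReducedData,
    bm_reduced: ReducedData,
    bm_target_dim: int | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    sm_observed: SubjectTable | None = None,
    bm_observed: SubjectTable | None = None,
    blocks: np.ndarray | None = None,
    scheme: str = "exchange",
) -> tuple[CCAModel, dict[str, LoadingSet], PermutationResult]:
    """Reduced blocks -> (optional extra PCA on the wide block) -> CCA -> test.

    ``bm_target_dim`` applies plain PCA to the second block when its reduced
    dimension is still too large relative to the number of subjects (the
    usual situation for connectivity data).
    """
    X = sm_reduced.components
    Ymat = bm_reduced.components
    if bm_target_dim is not None and bm_target_dim < Ymat.shape[1]:
        Ymat = reduce_block_pca(bm_reduced, bm_target_dim)
    model = fit_cca(X, Ymat)
    loadings = {
        "sm": canonical_loadings(model, sm_observed, sm_reduced, side="x"),
        "bm": canonical_loadings(model, bm_observed, bm_reduced, side="y"),
    }
    perm = permutation_test(
        X,
        Ymat,
        n_perm=n_perm,
        alpha=alpha,
        blocks=blocks,
        rng_seed=rng_seed,
        scheme=scheme,
    )
    return model, loadings, perm
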