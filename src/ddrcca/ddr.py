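"""Domain-driven dimension reduction.

Each variable sub-domain is reduced by PCA, with the retained dimension
chosen automatically by a two-way cross-validated PRESS criterion:

- subject-wise: subjects are split into folds; PCA loadings are estimated on
  the held-in rows (SVD, X = U Σ Vᵀ) and evaluated on the held-out rows;
- variable-wise: within each fold, the j-th held-out column is predicted from
  the *other* held-out columns through the held-in loadings with row j
  removed, via a pseudo-inverse (removing a row of V breaks orthogonality).

The naive reconstruction error ‖X_out − X_out V_k V_kᵀ‖² decreases
monotonically with k because it uses the held-out data to reconstruct
itself; the leave-one-variable-out PRESS does not, and its minimiser
estimates the effective dimension.  The CV is repeated with different fold
randomizations and the modal estimate taken.  Chosen loadings are varimax
rotated for interpretability (an orthogonal rotation, so everything
downstream of the subspace is invariant), and the per-domain rotated
components are concatenated into the reduced data space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DomainPartition, SubjectTable

__all__ = [
    "PressCurve",
    "DomainReduction",
    "ReducedData",
    "svd_decompose",
    "project_heldout",
    "naive_press",
    "loo_reconstruct",
    "two_way_press",
    "estimate_dimension",
    "varimax_rotate",
    "run_ddr",
    "null_eigenspectrum",
]


@dataclass
class PressCurve:
    """PRESS as a function of retained dimension k, for one CV run."""

    k_values: np.ndarray
    press: np.ndarray
    naive_press: np.ndarray
    chosen_k: int


@dataclass
class DomainReduction:
    """PCA reduction of one sub-domain at its chosen dimension."""

    subdomain_label: str
    n_vars: int
    chosen_k: int
    loadings: np.ndarray  # P × k, orthonormal columns
    singular_values: np.ndarray
    rotation: np.ndarray  # k × k orthogonal
    rotated_loadings: np.ndarray  # loadings @ rotation
    rotated_components: np.ndarray  # N × k
    press_curve: PressCurve | None
    variance_explained_pct: float
    k_votes: dict[int, int] | None = None


@dataclass
class ReducedData:
    """Concatenated rotated components across sub-domains."""

    components: np.ndarray  # N × K_total
    factor_labels: list[str]
    source: list[DomainReduction]

    def to_dataframe(self, subject_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(self.components, columns=self.factor_labels)
        if subject_ids is not None:
            df.insert(0, "subject_id", list(subject_ids))
        return df


def svd_decompose(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD of a block, returned as (U_PC, singular_values, V).

    ``U_PC = U Σ`` holds the observations in PC space, so that
    ``block = U_PC Vᵀ`` exactly and ``U_PC = block V``.
    """
    block = np.asarray(block, dtype=float)
    if np.isnan(block).any():
        raise ValueError("block contains missing values")
    U, s, Vt = np.linalg.svd(block, full_matrices=False)
    return U * s, s, Vt.T


def project_heldout(X_out: np.ndarray, V_k: np.ndarray) -> np.ndarray:
    """Held-out scores on held-in loadings: ``X_out @ V_k``."""
    X_out = np.asarray(X_out, dtype=float)
    V_k = np.asarray(V_k, dtype=float)
    if X_out.shape[1] != V_k.shape[0]:
        raise ValueError("column counts do not match")
    return X_out @ V_k


def naive_press(X_out: np.ndarray, V_k: np.ndarray) -> float:
    """Squared reconstruction error of X_out projected onto span(V_k).

    Monotonically non-increasing in k: the reconstruction uses X_out itself.
    """
    resid = X_out - project_heldout(X_out, V_k) @ V_k.T
    return float(np.sum(resid * resid))


def loo_reconstruct(
    X_out: np.ndarray, V: np.ndarray, k: int, j: int
) -> np.ndarray:
    """Predict held-out column j without using column j.

    Returns column j of ``X_out[:, -j] @ pinv(V_{-j,k}ᵀ) @ V_kᵀ`` where
    ``V_{-j,k}`` is the first k columns of V with row j removed.  The
    pseudo-inverse is required because deleting a row of V breaks the
    orthogonality of its columns.
    """
    X_out = np.asarray(X_out, dtype=float)
    V = np.asarray(V, dtype=float)
    P = X_out.shape[1]
    if not 1 <= k <= P - 1:
        raise ValueError(f"k must be in 1..P-1 (got k={k}, P={P})")
    if not 0 <= j < P:
        raise ValueError(f"column index j={j} out of range")
    Vk = V[:, :k]
    V_mj = np.delete(Vk, j, axis=0)  # (P-1) × k
    pinv = np.linalg.pinv(V_mj.T)  # (P-1) × k
    X_mj = np.delete(X_out, j, axis=1)
    return X_mj @ (pinv @ Vk[j, :])


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, n_folds)]


def two_way_press(
    block: np.ndarray,
    n_folds: int = 5,
    rng_seed: int = 0,
    center_folds: bool = False,
) -> PressCurve:
    """Two-way (subject × variable) cross-validated PRESS curve.

    Subjects are split into ``n_folds`` random folds.  For each fold the
    held-in rows are decomposed by SVD; each held-out column j is then
    predicted at every candidate dimension k by :func:`loo_reconstruct`, and
    squared prediction errors are summed over variables and folds.  The
    chosen dimension is the smallest k attaining the minimum PRESS.  The
    naive curve (self-reconstruction error) is returned for diagnostics.
    """
    block = np.asarray(block, dtype=float)
    N, P = block.shape
    if P < 2:
        raise ValueError("need at least 2 variables for two-way CV")
    if N < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} subjects for {n_folds} folds")
    rng = np.random.default_rng(rng_seed)
    folds = _fold_indices(N, n_folds, rng)
    min_heldin = N - max(len(f) for f in folds)
    k_max = min(P - 1, min_heldin - 1)
    press = np.zeros(k_max)
    naive = np.zeros(k_max)
    for test_idx in folds:
        if len(test_idx) < 2:
            raise ValueError("fold with fewer than 2 subjects")
        mask = np.ones(N, dtype=bool)
        mask[test_idx] = False
        X_in = block[mask]
        X_out = block[~mask]
        if center_folds:
            mu = X_in.mean(axis=0)
            X_in = X_in - mu
            X_out = X_out - mu
        _, _, V = svd_decompose(X_in)
        for k in range(1, k_max + 1):
            Vk = V[:, :k]
            naive[k - 1] += naive_press(X_out, Vk)
            for j in range(P):
                pred = loo_reconstruct(X_out, V, k, j)
                err = X_out[:, j] - pred
                press[k - 1] += err @ err
    chosen_k = int(np.argmin(press)) + 1  # argmin returns the first minimum
    return PressCurve(
        k_values=np.arange(1, k_max + 1),
        press=press,
        naive_press=naive,
        chosen_k=chosen_k,
    )


def estimate_dimension(
    block: np.ndarray,
    n_folds: int = 5,
    n_repeats: int = 50,
    rng_seed: int = 0,
    center_folds: bool = False,
) -> tuple[int, dict[int, int]]:
    """Modal PRESS-chosen dimension over repeated fold randomizations.

    Repeat i uses seed ``rng_seed + i`` so runs are exactly reproducible.
    Ties between equally frequent dimensions resolve to the smallest.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    votes: dict[int, int] = {}
    for i in range(n_repeats):
        curve = two_way_press(
            block, n_folds=n_folds, rng_seed=rng_seed + i, center_folds=center_folds
        )
        votes[curve.chosen_k] = votes.get(curve.chosen_k, 0) + 1
    max_count = max(votes.values())
    best = min(k for k, c in votes.items() if c == max_count)
    return best, votes


def _varimax_criterion(L: np.ndarray) -> float:
    sq = L**2
    return float(np.sum(sq.var(axis=0)))


def varimax_rotate(
    loadings: np.ndarray,
    kaiser: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation with Kaiser row-normalization.

    Returns ``(rotated, R)`` with ``rotated = loadings @ R`` and R orthogonal.
    Column signs are fixed so each column's largest-magnitude entry is
    positive.  For k = 1 the rotation is [±1] by the sign rule.
    """
    L = np.asarray(loadings, dtype=float)
    if not np.isfinite(L).all():
        raise ValueError("non-finite loadings")
    P, k = L.shape
    if k == 1:
        s = 1.0 if L[np.argmax(np.abs(L[:, 0])), 0] >= 0 else -1.0
        return L * s, np.array([[s]])
    h = np.sqrt((L**2).sum(axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    A = L / h_safe[:, None] if kaiser else L
    R = np.eye(k)
    crit = 0.0
    for _ in range(max_iter):
        B = A @ R
        G = A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / P)
        U, s, Vt = np.linalg.svd(G)
        R = U @ Vt
        new_crit = s.sum()
        if new_crit <= crit * (1 + tol):
            break
        crit = new_crit
    # deterministic sign convention
    rotated = L @ R
    for c in range(k):
        if rotated[np.argmax(np.abs(rotated[:, c])), c] < 0:
            rotated[:, c] = -rotated[:, c]
            R[:, c] = -R[:, c]
    return rotated, R


def reduce_domain(
    block: np.ndarray,
    label: str,
    n_folds: int = 5,
    n_repeats: int = 50,
    rng_seed: int = 0,
    center_folds: bool = False,
) -> DomainReduction:
    """Reduce one sub-domain block at its estimated dimension.

    A single-variable sub-domain bypasses CV with k = 1 and contributes the
    variable itself as its factor.
    """
    block = np.asarray(block, dtype=float)
    N, P = block.shape
    _, s, V = svd_decompose(block)
    if P == 1:
        rotated, R = varimax_rotate(V[:, :1])
        return DomainReduction(
            subdomain_label=label,
            n_vars=1,
            chosen_k=1,
            loadings=V[:, :1],
            singular_values=s[:1],
            rotation=R,
            rotated_loadings=rotated,
            rotated_components=block @ rotated,
            press_curve=None,
            variance_explained_pct=100.0,
            k_votes={1: 1},
        )
    k_mode, votes = estimate_dimension(
        block, n_folds=n_folds, n_repeats=n_repeats, rng_seed=rng_seed,
        center_folds=center_folds,
    )
    last_curve = two_way_press(
        block, n_folds=n_folds, rng_seed=rng_seed, center_folds=center_folds
    )
    Vk = V[:, :k_mode]
    rotated, R = varimax_rotate(Vk)
    ve = 100.0 * float(np.sum(s[:k_mode] ** 2) / np.sum(s**2))
    return DomainReduction(
        subdomain_label=label,
        n_vars=P,
        chosen_k=k_mode,
        loadings=Vk,
        singular_values=s[:k_mode],
        rotation=R,
        rotated_loadings=rotated,
        rotated_components=block @ rotated,
        press_curve=last_curve,
        variance_explained_pct=ve,
        k_votes=votes,
    )


def run_ddr(
    table: SubjectTable,
    partition: DomainPartition,
    n_folds: int = 5,
    n_repeats: int = 50,
    rng_seed: int = 0,
    center_folds: bool = False,
) -> ReducedData:
    """Reduce every sub-domain and concatenate rotated components.

    Factor columns are labelled ``"subdomain::factor_i"`` in partition order.
    Sub-domain d draws its CV seeds from ``rng_seed + 7919 * d`` so the full
    run is reproducible from a single seed.
    """
    if np.isnan(table.values).any():
        raise ValueError("table has missing values; preprocess first")
    reductions: list[DomainReduction] = []
    for d, (label, idx) in enumerate(partition.block_indices(table.variable_names)):
        block = table.values[:, idx]
        reductions.append(
            reduce_domain(
                block,
                label,
                n_folds=n_folds,
                n_repeats=n_repeats,
                rng_seed=(rng_seed + 7919 * d) % (2**31),
                center_folds=center_folds,
            )
        )
    components = np.column_stack([r.rotated_components for r in reductions])
    labels = [
        f"{r.subdomain_label}::factor_{i + 1}"
        for r in reductions
        for i in range(r.chosen_k)
    ]
    return ReducedData(components=components, factor_labels=labels, source=reductions)


def null_eigenspectrum(
    block: np.ndarray,
    n_shuffles: int = 100,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, int | None]:
    """Eigen-spectrum of a block against its column-permuted null.

    Shuffling the rows of each column independently preserves each column's
    moments but destroys correlation: the null spectrum shows the background
    noise level.  ``crossing_index`` is the first (1-based) component where
    the null meets or exceeds the actual spectrum; components beyond it are
    indistinguishable from noise.
    """
    block = np.asarray(block, dtype=float)
    N = block.shape[0]
    rng = np.random.default_rng(rng_seed)

    def spectrum(X: np.ndarray) -> np.ndarray:
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        eig = np.zeros(X.shape[1])
        eig[: s.size] = s**2 / (N - 1)
        return eig

    eigspec = spectrum(block)
    null = np.zeros_like(eigspec)
    for _ in range(n_shuffles):
        shuffled = np.column_stack(
            [rng.permutation(block[:, j]) for j in range(block.shape[1])]
        )
        null += spectrum(shuffled)
    null /= n_shuffles
    crossing = None
    for i in range(eigspec.size):
        if null[i] >= eigspec[i]:
            crossing = i + 1
            break
    return eigspec, null, crossing
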