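"""Cross-validated stability analysis of the reduction + CCA pipeline.

Training canonical correlations overfit: the weights are chosen to maximize
correlation in-sample.  The honest assessment refits the whole pipeline on
each training fold (dimension re-estimated, loadings re-learned), projects
the held-out subjects through the *training* rotated loadings and canonical
weights, and measures the held-out canonical correlations.  Folds respect
family structure — subjects sharing a family are never split across folds —
so within-family dependence cannot leak across the train/test boundary.

Loading stability is summarized by how often each variable (or factor)
appears in the top-T loadings across folds, with the mean and SD of its
loading over the folds where it appeared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cca import (
    BlockPCA,
    CCAModel,
    LoadingSet,
    PermutationResult,
    canonical_loadings,
    fit_cca,
    permutation_test,
)
from .data import DomainPartition, SubjectTable
from .ddr import DomainReduction, ReducedData, run_ddr

__all__ = [
    "FoldResult",
    "StabilityReport",
    "family_kfold",
    "project_test_factors",
    "cv_canonical_correlations",
    "run_stability",
]


@dataclass
class FoldResult:
    fold_index: int
    train_model: CCAModel
    cv_correlations: np.ndarray
    train_perm: PermutationResult
    cv_perm: PermutationResult
    train_loadings: dict[str, LoadingSet]
    test_subject_ids: list[str]
    sm_chosen_k: dict[str, int] = field(default_factory=dict)
    bm_chosen_k: dict[str, int] = field(default_factory=dict)


@dataclass
class StabilityReport:
    folds: list[FoldResult]
    occurrence: dict[str, pd.DataFrame]  # keys like "sm_observed", "bm_factor"
    top_t: int
    min_occurrence: int
    n_components: int  # components aggregated across folds

    def filtered(self, key: str) -> pd.DataFrame:
        df = self.occurrence[key]
        return df[df["occurrence"] >= self.min_occurrence].reset_index(drop=True)


def family_kfold(
    subject_ids: list[str],
    family_ids: list[str],
    n_folds: int = 5,
    rng_seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split subjects into folds without breaking families.

    Families are assigned whole, largest first, each to the currently
    smallest fold (ties broken at random, seeded).  Returns a list of
    (train_indices, test_indices) pairs.
    """
    if len(subject_ids) != len(family_ids):
        raise ValueError("one family id per subject required")
    n = len(subject_ids)
    rng = np.random.default_rng(rng_seed)
    fams: dict[str, list[int]] = {}
    for i, f in enumerate(family_ids):
        fams.setdefault(str(f), []).append(i)
    if max(len(m) for m in fams.values()) > n / n_folds:
        warnings.warn(
            "a family is larger than the target fold size; it is still "
            "assigned whole, so folds will be uneven",
            stacklevel=2,
        )
    # shuffle before the stable sort so equal-sized families are in random order
    items = list(fams.items())
    order = rng.permutation(len(items))
    items = [items[i] for i in order]
    items.sort(key=lambda kv: -len(kv[1]))
    fold_members: list[list[int]] = [[] for _ in range(n_folds)]
    for _, members in items:
        sizes = np.array([len(f) for f in fold_members])
        smallest = np.flatnonzero(sizes == sizes.min())
        target = int(rng.choice(smallest))
        fold_members[target].extend(members)
    splits = []
    for f in range(n_folds):
        test = np.sort(np.array(fold_members[f], dtype=int))
        train = np.sort(
            np.array([i for g in range(n_folds) if g != f for i in fold_members[g]],
                     dtype=int)
        )
        splits.append((train, test))
    return splits


def project_test_factors(
    test_block: SubjectTable | np.ndarray,
    train_reduction: list[DomainReduction],
    partition: DomainPartition | None = None,
) -> ReducedData:
    """Project held-out data through training rotated loadings.

    Per sub-domain, test components = test_block · rotated_loadings(train);
    concatenated in the same order and labelling as the training reduction.
    When ``test_block`` is a :class:`SubjectTable`, ``partition`` locates
    each sub-domain's columns; a bare array must already be column-ordered
    to match the concatenated training blocks.
    """
    comps = []
    if isinstance(test_block, SubjectTable):
        if partition is None:
            raise ValueError("partition required with a SubjectTable test block")
        blocks = dict(partition.block_indices(test_block.variable_names))
        for red in train_reduction:
            idx = blocks.get(red.subdomain_label)
            if idx is None or idx.size != red.n_vars:
                raise ValueError(
                    f"variable mismatch in sub-domain {red.subdomain_label!r}"
                )
            comps.append(test_block.values[:, idx] @ red.rotated_loadings)
    else:
        arr = np.asarray(test_block, dtype=float)
        start = 0
        for red in train_reduction:
            stop = start + red.n_vars
            comps.append(arr[:, start:stop] @ red.rotated_loadings)
            start = stop
        if start != arr.shape[1]:
            raise ValueError("variable mismatch: column count differs from training")
    labels = [
        f"{r.subdomain_label}::factor_{i + 1}"
        for r in train_reduction
        for i in range(r.chosen_k)
    ]
    return ReducedData(
        components=np.column_stack(comps), factor_labels=labels,
        source=train_reduction,
    )


def cv_canonical_correlations(
    train_model: CCAModel,
    X_test_factors: np.ndarray,
    Y_test_factors: np.ndarray,
) -> np.ndarray:
    """Held-out canonical correlations using training weights.

    ``P̃ = X_test A_train``, ``Q̃ = Y_test B_train``; returns the per-pair
    Pearson correlation, in [-1, 1] (not forced non-negative).
    """
    P, Q = train_model.transform(X_test_factors, Y_test_factors)
    out = np.zeros(train_model.m)
    for i in range(train_model.m):
        p, q = P[:, i], Q[:, i]
        if p.std() == 0 or q.std() == 0:
            warnings.warn(
                f"degenerate variance in projected canonical variable {i + 1}; "
                "correlation recorded as 0",
                stacklevel=2,
            )
            out[i] = 0.0
        else:
            out[i] = np.corrcoef(p, q)[0, 1]
    return out


def _top_t(names: list[str], loadings: np.ndarray, t: int) -> list[tuple[str, float]]:
    order = np.argsort(-np.abs(loadings))[:t]
    return [(names[i], float(loadings[i])) for i in order]


def _aggregate(
    per_fold: list[list[dict]],
    n_folds: int,
) -> pd.DataFrame:
    """Occurrence counts and loading mean/SD from per-fold top-T lists."""
    rows: dict[tuple[int, str], list[float]] = {}
    for fold_lists in per_fold:
        for comp_i, entries in enumerate(fold_lists):
            for name, value in entries:
                rows.setdefault((comp_i + 1, name), []).append(value)
    records = []
    for (comp, name), vals in sorted(rows.items()):
        records.append(
            {
                "component": comp,
                "item": name,
                "occurrence": len(vals),
                "loading_mean": float(np.mean(vals)),
                "loading_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    df = pd.DataFrame(
        records,
        columns=["component", "item", "occurrence", "loading_mean", "loading_sd"],
    )
    if not df.empty and (df["occurrence"] > n_folds).any():
        raise AssertionError("occurrence exceeded the number of folds")
    return df


def run_stability(
    table_sm: SubjectTable,
    table_bm: SubjectTable,
    partition_sm: DomainPartition,
    partition_bm: DomainPartition,
    n_folds: int = 5,
    n_repeats: int = 10,
    bm_target_dim: int | None = None,
    n_perm: int = 199,
    alpha: float = 0.05,
    top_t: int = 20,
    min_occurrence: int = 2,
    rng_seed: int = 0,
    center_folds: bool = False,
) -> StabilityReport:
    """Family-respecting k-fold CV of the full reduction + CCA pipeline.

    For each fold: dimension reduction is refit on the training subjects
    only (dimensions re-estimated), held-out subjects are projected through
    training loadings, CCA is fit on training factors, and permutation tests
    are run on both training and held-out canonical variables.  Canonical
    components are matched across folds by index and sign-aligned to the
    first fold via their observed SM loading vectors before aggregation.
    """
    if table_sm.subject_ids != table_bm.subject_ids:
        raise ValueError("SM and BM tables must cover the same subjects")
    fam = table_sm.family_ids or table_sm.subject_ids  # singletons if absent
    splits = family_kfold(table_sm.subject_ids, fam, n_folds, rng_seed)
    folds: list[FoldResult] = []
    top_lists: dict[str, list[list[dict]]] = {
        "sm_observed": [], "sm_factor": [], "bm_observed": [], "bm_factor": [],
    }
    ref_sm_loadings: np.ndarray | None = None
    for f, (train_idx, test_idx) in enumerate(splits):
        sm_tr = table_sm.select_subjects(train_idx)
        sm_te = table_sm.select_subjects(test_idx)
        bm_tr = table_bm.select_subjects(train_idx)
        bm_te = table_bm.select_subjects(test_idx)
        seed_f = (rng_seed + 104729 * (f + 1)) % (2**31)
        red_sm = run_ddr(sm_tr, partition_sm, n_folds=n_folds,
                         n_repeats=n_repeats, rng_seed=seed_f,
                         center_folds=center_folds)
        red_bm = run_ddr(bm_tr, partition_bm, n_folds=n_folds,
                         n_repeats=n_repeats, rng_seed=seed_f + 1,
                         center_folds=center_folds)
        test_sm = project_test_factors(sm_te, red_sm.source, partition_sm)
        test_bm = project_test_factors(bm_te, red_bm.source, partition_bm)
        X_tr, X_te = red_sm.components, test_sm.components
        Y_tr, Y_te = red_bm.components, test_bm.components
        if bm_target_dim is not None and bm_target_dim < Y_tr.shape[1]:
            pca = BlockPCA(bm_target_dim).fit(Y_tr)
            Y_tr, Y_te = pca.transform(Y_tr), pca.transform(Y_te)
        model = fit_cca(X_tr, Y_tr)
        train_perm = permutation_test(
            X_tr, Y_tr, n_perm=n_perm, alpha=alpha, rng_seed=seed_f + 2
        )
        cv_corr = cv_canonical_correlations(model, X_te, Y_te)
        P_te, Q_te = model.transform(X_te, Y_te)
        cv_perm = _projected_permutation_test(
            P_te, Q_te, cv_corr, n_perm=n_perm, alpha=alpha, rng_seed=seed_f + 3
        )
        loadings = {
            "sm": canonical_loadings(model, sm_tr, red_sm, side="x"),
            "bm": canonical_loadings(model, bm_tr, red_bm, side="y"),
        }
        # sign-align components to fold 0 by their observed SM loading vectors
        signs = np.ones(model.m)
        if ref_sm_loadings is None:
            ref_sm_loadings = loadings["sm"].observed_loadings
        else:
            m_common = min(model.m, ref_sm_loadings.shape[1])
            for i in range(m_common):
                a = loadings["sm"].observed_loadings[:, i]
                b = ref_sm_loadings[:, i]
                c = float(np.corrcoef(a, b)[0, 1]) if a.std() and b.std() else float(
                    np.dot(a, b)
                )
                if c < 0:
                    signs[i] = -1.0
            for ls in loadings.values():
                ls.observed_loadings *= signs
                ls.factor_loadings *= signs
        folds.append(
            FoldResult(
                fold_index=f,
                train_model=model,
                cv_correlations=cv_corr,
                train_perm=train_perm,
                cv_perm=cv_perm,
                train_loadings=loadings,
                test_subject_ids=[table_sm.subject_ids[i] for i in test_idx],
                sm_chosen_k={r.subdomain_label: r.chosen_k for r in red_sm.source},
                bm_chosen_k={r.subdomain_label: r.chosen_k for r in red_bm.source},
            )
        )
        for key, (ls, names_attr, load_attr) in {
            "sm_observed": (loadings["sm"], "observed_names", "observed_loadings"),
            "sm_factor": (loadings["sm"], "factor_names", "factor_loadings"),
            "bm_observed": (loadings["bm"], "observed_names", "observed_loadings"),
            "bm_factor": (loadings["bm"], "factor_names", "factor_loadings"),
        }.items():
            names = getattr(ls, names_attr)
            mat = getattr(ls, load_attr)
            top_lists[key].append(
                [_top_t(names, mat[:, i], top_t) for i in range(model.m)]
            )
    n_components = min(len(fold_lists) for lists in top_lists.values()
                       for fold_lists in lists)
    occurrence = {
        key: _aggregate(
            [[fold_lists[i] for i in range(n_components)] for fold_lists in lists],
            n_folds,
        )
        for key, lists in top_lists.items()
    }
    return StabilityReport(
        folds=folds,
        occurrence=occurrence,
        top_t=top_t,
        min_occurrence=min_occurrence,
        n_components=n_components,
    )


def _projected_permutation_test(
    P: np.ndarray,
    Q: np.ndarray,
    observed: np.ndarray,
    n_perm: int,
    alpha: float,
    rng_seed: int,
) -> PermutationResult:
    """Permutation test of already-projected canonical variables.

    Held-out rows of Q̃ are permuted against P̃; the null statistic is the
    maximum per-pair correlation across components, compared one-sidedly
    against each observed (signed) held-out correlation.
    """
    rng = np.random.default_rng(rng_seed)
    N, m = P.shape
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    p_sd = Pc.std(axis=0)
    q_sd = Qc.std(axis=0)
    ok = (p_sd > 0) & (q_sd > 0)
    null = np.zeros(n_perm)
    for b in range(n_perm):
        order = rng.permutation(N)
        corr = np.zeros(m)
        corr[ok] = (Pc[:, ok] * Qc[order][:, ok]).mean(axis=0) / (
            p_sd[ok] * q_sd[ok]
        )
        null[b] = corr.max()
    p = (1 + (null[:, None] >= observed[None, :]).sum(axis=0)) / (1 + n_perm)
    n_sig = 0
    for pi in p:
        if pi < alpha:
            n_sig += 1
        else:
            break
    return PermutationResult(
        n_perm=n_perm, null_max_corr=null, p_values=p,
        n_significant=n_sig, alpha=alpha,
    )
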