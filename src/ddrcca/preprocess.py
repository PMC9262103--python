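"""Quality control, normalization, de-confounding and sign alignment.

The preprocessing chain for a subjects × variables table is fixed as

    QC -> median imputation -> rank-based inverse-normal transform
       -> de-confounding -> sign-flip alignment

QC removes ill-conditioned variables (mostly-missing, constant, or
near-constant).  The inverse-normal transform maps each column's ranks onto
Blom scores, giving every variable an approximately standard-normal marginal.
De-confounding replaces each variable by its OLS residual on an intercept
plus the confound columns.  Sign-flipping negates variables that correlate
negatively with a designated benchmark variable (e.g. household income) so
that larger values consistently mean "better" outcomes; flipping signs
changes neither covariance eigenvalues nor any downstream dimension choice
or canonical correlation, only the signs of the corresponding loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import SubjectTable


@dataclass
class QCReport:
    removed_variables: list[tuple[str, str]]
    retained_count: int


@dataclass
class SignFlipRecord:
    benchmark_variable: str
    flipped_variables: list[str]
    manual_flips: list[str] = field(default_factory=list)


def qc_filter(table: SubjectTable) -> tuple[SubjectTable, QCReport]:
    """Drop mostly-missing, constant and near-constant variables.

    A column is removed when (in this order of reported reason):

    - more than 50% of its entries are missing (``missing_gt_50pct``),
    - the standard deviation of its non-missing entries is 0 (``zero_sd``),
    - its modal value accounts for more than 95% of non-missing entries
      (``gt_95pct_identical``).
    """
    if table.n_variables < 1:
        raise ValueError("table has no columns")
    removed: list[tuple[str, str]] = []
    keep: list[str] = []
    n = table.n_subjects
    for j, name in enumerate(table.variable_names):
        col = table.values[:, j]
        obs = col[~np.isnan(col)]
        if (n - obs.size) / n > 0.5:
            removed.append((name, "missing_gt_50pct"))
            continue
        if obs.size == 0 or np.std(obs) == 0:
            removed.append((name, "zero_sd"))
            continue
        _, counts = np.unique(obs, return_counts=True)
        if counts.max() / obs.size > 0.95:
            removed.append((name, "gt_95pct_identical"))
            continue
        keep.append(name)
    if not keep:
        raise ValueError("empty table: QC removed every variable")
    report = QCReport(removed_variables=removed, retained_count=len(keep))
    return table.select_variables(keep), report


def impute_missing(table: SubjectTable) -> SubjectTable:
    """Replace missing entries by the column median of non-missing entries.

    The missingness mask is retained for provenance.
    """
    values = table.values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        nan = np.isnan(col)
        if nan.any():
            if nan.all():
                raise ValueError(
                    f"column {table.variable_names[j]!r} is entirely missing"
                )
            col[nan] = np.median(col[~nan])
    return table.with_values(values)


def inverse_normal_transform(table: SubjectTable) -> SubjectTable:
    """Rank-based inverse-normal (Blom) transform, column-wise.

    Each column is replaced by ``Phi^-1((r - 3/8) / (n + 1/4))`` where ``r``
    is the within-column rank (ties get average ranks).  Rank order within a
    column is preserved.
    """
    values = table.values
    if np.isnan(values).any():
        raise ValueError("missing entries present; impute before transforming")
    n = values.shape[0]
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        if np.std(col) == 0:
            raise ValueError(
                f"constant column {table.variable_names[j]!r}; "
                "should have been removed by QC"
            )
        ranks = stats.rankdata(col, method="average")
        out[:, j] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return table.with_values(out)


def _confound_design(
    confounds: SubjectTable, square: tuple[str, ...] = ()
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept | z-scored confounds (+ squared copies)]."""
    cols = [confounds.values[:, j] for j in range(confounds.n_variables)]
    names = list(confounds.variable_names)
    for name in square:
        c = confounds.column(name)
        sq = (c - c.mean()) ** 2
        cols.append(sq)
        names.append(f"{name}^2")
    Z = np.column_stack(cols)
    sd = Z.std(axis=0)
    if (sd == 0).any():
        bad = [names[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant confound columns: {bad}")
    Z = (Z - Z.mean(axis=0)) / sd  # conditioning only; residuals unaffected
    design = np.column_stack([np.ones(Z.shape[0]), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        for j in range(1, design.shape[1]):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
                collinear.append(names[j - 1])
        raise ValueError(f"rank-deficient confound matrix; collinear: {collinear}")
    return design, names


def deconfound(
    table: SubjectTable,
    confounds: SubjectTable,
    square: tuple[str, ...] = (),
) -> SubjectTable:
    """Replace each variable by its OLS residual on the confounds.

    An intercept is always included, so residuals are mean-zero and
    orthogonal to every confound column.  ``square`` names confounds whose
    squared, re-centered copies are appended to the design.
    """
    if table.subject_ids != confounds.subject_ids:
        raise ValueError("tables must cover the same subjects in the same order")
    design, _ = _confound_design(confounds, square)
    beta, *_ = np.linalg.lstsq(design, table.values, rcond=None)
    residuals = table.values - design @ beta
    return table.with_values(residuals)


def sign_flip(
    table: SubjectTable,
    benchmark: str,
    manual_flips: tuple[str, ...] = (),
) -> tuple[SubjectTable, SignFlipRecord]:
    """Align variable polarity against a benchmark variable.

    Every variable with strictly negative pairwise-complete Pearson
    correlation with the benchmark is negated; afterwards every variable in
    ``manual_flips`` is negated (a variable flipped twice is back to its
    original sign).  The record lists the set of variables whose final sign
    differs from the input.
    """
    if benchmark not in table.variable_names:
        raise KeyError(f"benchmark {benchmark!r} not in table")
    if benchmark in manual_flips:
        raise ValueError("benchmark variable cannot be manually flipped")
    unknown = [v for v in manual_flips if v not in table.variable_names]
    if unknown:
        raise KeyError(f"manual flips not in table: {unknown}")
    bench = table.column(benchmark)
    auto: set[str] = set()
    for j, name in enumerate(table.variable_names):
        if name == benchmark:
            continue
        col = table.values[:, j]
        ok = ~np.isnan(col) & ~np.isnan(bench)
        if ok.sum() < 2 or np.std(col[ok]) == 0 or np.std(bench[ok]) == 0:
            warnings.warn(
                f"cannot correlate {name!r} with benchmark; leaving sign as is",
                stacklevel=2,
            )
            continue
        r = np.corrcoef(col[ok], bench[ok])[0, 1]
        if r < 0:
            auto.add(name)
    flipped = auto.symmetric_difference(manual_flips)
    values = table.values.copy()
    for name in flipped:
        j = table.variable_names.index(name)
        values[:, j] = -values[:, j]
    record = SignFlipRecord(
        benchmark_variable=benchmark,
        flipped_variables=sorted(flipped),
        manual_flips=list(manual_flips),
    )
    return table.with_values(values), record


def preprocess_pipeline(
    table: SubjectTable,
    confounds: SubjectTable | None = None,
    benchmark: str | None = None,
    manual_flips: tuple[str, ...] = (),
    square: tuple[str, ...] = (),
) -> tuple[SubjectTable, dict]:
    """Full chain: QC -> impute -> inverse-normal -> de-confound -> sign-flip.

    Returns the processed table plus a report dict with the QC and sign-flip
    records (``None`` where a step was not applicable).
    """
    table, qc = qc_filter(table)
    table = impute_missing(table)
    table = inverse_normal_transform(table)
    if confounds is not None:
        table = deconfound(table, confounds, square=square)
    record = None
    if benchmark is not None:
        table, record = sign_flip(table, benchmark, manual_flips)
    return table, {"qc": qc, "sign_flip": record}
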