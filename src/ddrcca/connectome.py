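"""Connectivity-matrix specifics.

A stack of per-subject symmetric region × region connectivity matrices is
unfolded into a subjects × edges table in which each region contributes its
full matrix row as one sub-domain, so every undirected edge appears in
exactly two sub-domains (this redundancy is absorbed by the per-region
dimension reduction).  Utilities here also cover the Tikhonov-regularized
partial-correlation step that produces such matrices from region time
series, and the signed per-region "CCA strength" summary of edge-level
canonical loadings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import DomainPartition, SubjectTable

__all__ = [
    "ConnectivityStack",
    "StrengthMap",
    "tikhonov_partial_correlation",
    "stack_to_table",
    "edge_loading_matrix",
    "cca_strength",
]

SYMMETRY_TOL = 1e-6


@dataclass
class ConnectivityStack:
    """N subject-wise R × R symmetric matrices with region labels."""

    matrices: np.ndarray  # N × R × R
    region_labels: list[str]
    subject_ids: list[str] | None = None
    family_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be N × R × R")
        R = self.matrices.shape[1]
        if len(self.region_labels) != R:
            raise ValueError("one label per region required")
        asym = np.abs(self.matrices - self.matrices.transpose(0, 2, 1)).max()
        if asym > SYMMETRY_TOL:
            raise ValueError(f"asymmetric matrix in stack (max deviation {asym:g})")
        if self.subject_ids is None:
            self.subject_ids = [str(i) for i in range(self.matrices.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]

    def mean_matrix(self) -> np.ndarray:
        return self.matrices.mean(axis=0)

    @classmethod
    def from_directory(cls, path, region_labels=None) -> "ConnectivityStack":
        """Read one whitespace-delimited R × R matrix per subject file."""
        files = sorted(
            f for f in Path(path).glob("*.txt") if f.name != "regions.txt"
        )
        if not files:
            raise FileNotFoundError(f"no .txt matrices under {path}")
        mats = [np.loadtxt(f) for f in files]
        R = mats[0].shape[0]
        if region_labels is None:
            region_labels = [f"region_{i + 1}" for i in range(R)]
        return cls(
            matrices=np.stack(mats),
            region_labels=list(region_labels),
            subject_ids=[f.stem for f in files],
        )

    def to_directory(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for sid, mat in zip(self.subject_ids, self.matrices):
            np.savetxt(path / f"{sid}.txt", mat, fmt="%.10g")
        (path / "regions.txt").write_text("\n".join(self.region_labels) + "\n")


@dataclass
class StrengthMap:
    """Signed per-region summary of edge canonical loadings."""

    positive_strength: np.ndarray  # R, >= 0
    negative_strength: np.ndarray  # R, <= 0
    region_labels: list[str]


def tikhonov_partial_correlation(timeseries: np.ndarray, rho: float) -> np.ndarray:
    """Regularized partial correlation between region time series.

    The covariance is shrunk by ``rho`` times the mean diagonal before
    inversion; partial correlations come from the normalized negated
    precision, with unit diagonal.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("timeseries must be T × R with T > 1")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    cov = np.cov(ts, rowvar=False)
    reg = cov + rho * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
    try:
        prec = np.linalg.inv(reg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular covariance; use rho > 0 for regularization"
        ) from exc
    d = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    return (pcorr + pcorr.T) / 2.0


def edge_column_name(region: str, partner: str) -> str:
    return f"{region}--{partner}"


def stack_to_table(stack: ConnectivityStack) -> tuple[SubjectTable, DomainPartition]:
    """Unfold a connectivity stack into a subjects × edges table.

    One column per ordered (region, partner) pair — each region's full
    matrix row — so each undirected edge appears in two sub-domains, and
    each column is assigned to its region's sub-domain.  Diagonal entries
    are retained; when they are constant across subjects (e.g. always 1)
    the QC zero-sd rule removes them downstream.
    """
    N, R = stack.n_subjects, stack.n_regions
    values = stack.matrices.reshape(N, R * R)
    names = [
        edge_column_name(stack.region_labels[r], stack.region_labels[s])
        for r in range(R)
        for s in range(R)
    ]
    mapping = {
        edge_column_name(stack.region_labels[r], stack.region_labels[s]):
            stack.region_labels[r]
        for r in range(R)
        for s in range(R)
    }
    table = SubjectTable(
        values=values,
        variable_names=names,
        subject_ids=list(stack.subject_ids),
        family_ids=stack.family_ids,
    )
    return table, DomainPartition(mapping=mapping, labels=list(stack.region_labels))


def edge_loading_matrix(
    loadings: np.ndarray,
    loading_names: list[str],
    region_labels: list[str],
) -> np.ndarray:
    """Assemble a symmetric R × R loading matrix from edge-column loadings.

    The two column copies of each undirected edge are averaged; edges whose
    columns were removed (e.g. constant diagonals dropped by QC) are 0.
    """
    R = len(region_labels)
    idx = {name: i for i, name in enumerate(loading_names)}
    M = np.zeros((R, R))
    W = np.zeros((R, R))
    for r in range(R):
        for s in range(R):
            name = edge_column_name(region_labels[r], region_labels[s])
            i = idx.get(name)
            if i is not None:
                M[r, s] += loadings[i]
                W[r, s] += 1.0
    M = M + M.T
    W = W + W.T
    out = np.zeros((R, R))
    np.divide(M, W, out=out, where=W > 0)
    return out


def cca_strength(
    loading_matrix: np.ndarray,
    mean_corr_signs: np.ndarray,
    top_n: int = 20,
    region_labels: list[str] | None = None,
) -> StrengthMap:
    """Per-region positive and negative CCA strength.

    Loadings are modulated by the sign of the group-mean correlation for
    each edge (a negatively correlated edge contributes its loading with
    flipped sign), the diagonal is excluded, and for every region the top
    ``top_n`` positive and negative modulated entries of its row are
    averaged.  Fewer than ``top_n`` available -> mean of those available;
    none -> 0.
    """
    L = np.asarray(loading_matrix, dtype=float)
    S = np.sign(np.asarray(mean_corr_signs, dtype=float))
    if L.shape != S.shape or L.shape[0] != L.shape[1]:
        raise ValueError("loading matrix and sign matrix must be square and equal")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    R = L.shape[0]
    if region_labels is None:
        region_labels = [f"region_{i + 1}" for i in range(R)]
    modulated = L * S
    pos = np.zeros(R)
    neg = np.zeros(R)
    for r in range(R):
        row = np.delete(modulated[r], r)
        p = np.sort(row[row > 0])[::-1][:top_n]
        n = np.sort(row[row < 0])[:top_n]
        pos[r] = p.mean() if p.size else 0.0
        neg[r] = n.mean() if n.size else 0.0
    return StrengthMap(
        positive_strength=pos, negative_strength=neg,
        region_labels=list(region_labels),
    )
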