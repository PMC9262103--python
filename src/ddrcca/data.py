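"""Tabular containers and plain-text I/O.

Two containers run through the whole pipeline: :class:`SubjectTable`, a
subjects × variables numeric matrix with names, optional subject/family
identifiers and a missingness mask, and :class:`DomainPartition`, the mapping
from variable names to functional sub-domain labels that defines the blocks
on which dimension reduction operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: strings accepted as missing values in input CSVs
NA_VALUES = ("", "NA", "NaN", "nan", "N/A")

RESERVED_COLUMNS = ("subject_id", "family_id")


@dataclass
class SubjectTable:
    """Subjects × variables real matrix with metadata.

    ``values`` is a float array where missing entries are ``NaN``;
    ``missing_mask`` records where values were missing on input so that
    provenance survives imputation.
    """

    values: np.ndarray
    variable_names: list[str]
    subject_ids: list[str]
    family_ids: list[str] | None = None
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        self.variable_names = [str(v) for v in self.variable_names]
        self.subject_ids = [str(s) for s in self.subject_ids]
        n, p = self.values.shape
        if len(self.variable_names) != p:
            raise ValueError(
                f"{len(self.variable_names)} variable names for {p} columns"
            )
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if len(set(self.variable_names)) != p:
            raise ValueError("duplicate variable names")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        if self.family_ids is not None:
            self.family_ids = [str(f) for f in self.family_ids]
            if len(self.family_ids) != n:
                raise ValueError("family_ids must have one entry per subject")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    def with_values(self, values: np.ndarray) -> "SubjectTable":
        """Same metadata, new matrix of identical shape."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return replace(self, values=values, missing_mask=self.missing_mask.copy())

    def select_variables(self, names: list[str]) -> "SubjectTable":
        idx = [self.variable_names.index(n) for n in names]
        return SubjectTable(
            values=self.values[:, idx],
            variable_names=list(names),
            subject_ids=list(self.subject_ids),
            family_ids=None if self.family_ids is None else list(self.family_ids),
            missing_mask=self.missing_mask[:, idx],
        )

    def select_subjects(self, indices: np.ndarray) -> "SubjectTable":
        indices = np.asarray(indices)
        return SubjectTable(
            values=self.values[indices],
            variable_names=list(self.variable_names),
            subject_ids=[self.subject_ids[i] for i in indices],
            family_ids=None
            if self.family_ids is None
            else [self.family_ids[i] for i in indices],
            missing_mask=self.missing_mask[indices],
        )

    def to_dataframe(self, include_ids: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        if include_ids:
            df.insert(0, "subject_id", self.subject_ids)
            if self.family_ids is not None:
                df.insert(1, "family_id", self.family_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SubjectTable":
        df = df.copy()
        if "subject_id" in df.columns:
            subject_ids = [str(s) for s in df.pop("subject_id")]
        else:
            subject_ids = [str(i) for i in range(len(df))]
        family_ids = None
        if "family_id" in df.columns:
            family_ids = [str(f) for f in df.pop("family_id")]
        values = df.to_numpy(dtype=float)
        return cls(
            values=values,
            variable_names=[str(c) for c in df.columns],
            subject_ids=subject_ids,
            family_ids=family_ids,
        )


def read_table(path) -> SubjectTable:
    """Read a subjects × variables CSV.

    The first row holds variable names; optional ``subject_id`` and
    ``family_id`` columns are extracted as metadata.  Missing entries may be
    encoded by any string in :data:`NA_VALUES`.  A non-numeric cell outside
    that vocabulary raises with its row and column.
    """
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    names = [h.strip() for h in header]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate column names in {path}: {dupes}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    df.columns = names
    out = {}
    for name in names:
        if name in RESERVED_COLUMNS:
            out[name] = df[name].to_numpy()
            continue
        raw = df[name].str.strip().to_numpy(dtype=object)
        values = np.empty(raw.size, dtype=float)
        for i, cell in enumerate(raw):
            if cell in NA_VALUES:
                values[i] = np.nan
                continue
            try:
                # float() round-trips %.17g output exactly
                values[i] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at data row {i}, "
                    f"column {name!r} in {path}"
                ) from None
        out[name] = values
    return SubjectTable.from_dataframe(pd.DataFrame(out))


def write_table(table: SubjectTable, path) -> None:
    """Write a table to CSV at full double precision (round-trip exact)."""
    table.to_dataframe().to_csv(path, index=False, float_format="%.17g", na_rep="NA")


@dataclass
class DomainPartition:
    """Mapping from variable name to sub-domain label.

    ``labels`` fixes the order in which sub-domain blocks are processed and
    concatenated; it defaults to first appearance order in ``mapping``.
    """

    mapping: dict[str, str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}
        if not self.labels:
            seen: list[str] = []
            for v in self.mapping.values():
                if v not in seen:
                    seen.append(v)
            self.labels = seen
        else:
            self.labels = [str(l) for l in self.labels]
            present = set(self.mapping.values())
            empty = [l for l in self.labels if l not in present]
            if empty:
                raise ValueError(f"empty sub-domains: {empty}")

    @classmethod
    def from_csv(cls, path) -> "DomainPartition":
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
        if df.shape[1] != 2:
            raise ValueError("domain dictionary must have exactly two columns")
        var_col, dom_col = df.columns
        return cls(mapping=dict(zip(df[var_col], df[dom_col])))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"variable": list(self.mapping), "subdomain": list(self.mapping.values())}
        ).to_csv(path, index=False)

    def block_indices(self, variable_names: list[str]) -> list[tuple[str, np.ndarray]]:
        """Column index blocks, in label order, for the given variables.

        Every variable must belong to exactly one sub-domain; sub-domains with
        no variables among ``variable_names`` are dropped.
        """
        unknown = [v for v in variable_names if v not in self.mapping]
        if unknown:
            raise KeyError(f"variables missing from domain dictionary: {unknown[:5]}")
        blocks = []
        for label in self.labels:
            idx = np.array(
                [i for i, v in enumerate(variable_names) if self.mapping[v] == label],
                dtype=int,
            )
            if idx.size:
                blocks.append((label, idx))
        if not blocks:
            raise ValueError("no variables matched any sub-domain")
        return blocks

    def restrict(self, variable_names: list[str]) -> "DomainPartition":
        mapping = {v: self.mapping[v] for v in variable_names}
        labels = [l for l in self.labels if l in set(mapping.values())]
        return DomainPartition(mapping=mapping, labels=labels)
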