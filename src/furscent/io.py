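"""Reading, writing and validation of aligned peak tables and sample metadata.

A GC-MS fingerprint study starts from an aligned peak table: one row per
swab sample, one column per compound (labelled by its retention time in
minutes), holding nonnegative peak abundances.  Alignment itself happens
upstream; this module only consumes its output, joins it with per-sample
metadata (colony, age class, family membership) and enforces the joint
invariants that every downstream statistic relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("furscent")

#: allowed unit states of an abundance matrix, in pipeline order
UNIT_STATES = ("raw", "relative_percent", "log_relative")

#: allowed age classes
AGE_CLASSES = ("mother", "pup")

_ROW_SUM_TOL = 1e-6


class FingerprintError(ValueError):
    """Raised when an input table or dataset violates a contract."""


@dataclass(frozen=True)
class AbundanceMatrix:
    """Samples x compounds matrix of nonnegative peak abundances.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample labels, one per row.
    compound_ids : list of str
        Unique compound labels (retention-time strings, minutes), one per
        column.  Treated as opaque strings; numeric ordering is only used
        for display.
    values : ndarray of shape (n_samples, n_compounds)
        Nonnegative abundances.  A zero means the peak was not detected.
    unit_state : {"raw", "relative_percent", "log_relative"}
        Where the matrix sits in the preprocessing pipeline.
    """

    sample_ids: list[str]
    compound_ids: list[str]
    values: np.ndarray
    unit_state: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "sample_ids", list(self.sample_ids))
        object.__setattr__(self, "compound_ids", list(self.compound_ids))
        self.validate()

    def validate(self) -> None:
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.compound_ids):
            raise FingerprintError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.compound_ids)} compounds"
            )
        if len(set(self.sample_ids)) != n:
            raise FingerprintError("duplicate sample_ids in abundance matrix")
        if len(set(self.compound_ids)) != m:
            raise FingerprintError("duplicate compound_ids in abundance matrix")
        if self.unit_state not in UNIT_STATES:
            raise FingerprintError(f"unknown unit_state {self.unit_state!r}")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise FingerprintError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"compound {self.compound_ids[j]!r}"
            )
        if self.unit_state == "relative_percent":
            sums = self.values.sum(axis=1)
            bad = np.nonzero((sums > 0) & (np.abs(sums - 100.0) > _ROW_SUM_TOL))[0]
            if bad.size:
                raise FingerprintError(
                    f"relative_percent row {self.sample_ids[bad[0]]!r} sums to "
                    f"{sums[bad[0]]!r}, expected 100"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.compound_ids)

    def with_values(self, values: np.ndarray, unit_state: str) -> "AbundanceMatrix":
        return replace(self, values=values, unit_state=unit_state)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample study design: colony, age class and family membership.

    Wraps a DataFrame with columns ``sample_id``, ``colony`` and optionally
    ``age_class`` and ``family_id``.  A family is a mother-offspring unit
    (occasionally a trio with twins); all its members share one colony and
    it contains at most one mother.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        object.__setattr__(self, "table", t)
        self.validate()

    def validate(self) -> None:
        t = self.table
        for col in ("sample_id", "colony"):
            if col not in t.columns:
                raise FingerprintError(f"metadata missing required column {col!r}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FingerprintError(f"duplicated sample_id {dup!r} in metadata")
        if "age_class" in t.columns:
            bad = t["age_class"].dropna()
            bad = bad[~bad.isin(AGE_CLASSES)]
            if len(bad):
                raise FingerprintError(f"unknown age_class {bad.iloc[0]!r}")
        if "family_id" in t.columns:
            withfam = t[t["family_id"].notna()]
            for fam, grp in withfam.groupby("family_id"):
                if grp["colony"].nunique() > 1:
                    raise FingerprintError(
                        f"family {fam!r} spans colonies {sorted(grp['colony'].unique())}"
                    )
                if "age_class" in grp.columns and (grp["age_class"] == "mother").sum() > 1:
                    raise FingerprintError(f"family {fam!r} has more than one mother")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def column(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise FingerprintError(f"metadata has no column {name!r}")
        return self.table[name].to_numpy()

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        """Rows for ``sample_ids``, in that order."""
        idx = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise FingerprintError(f"samples missing from metadata: {missing[:5]}")
        return SampleMetadata(idx.loc[sample_ids].reset_index())


@dataclass(frozen=True)
class ValidatedDataset:
    """An abundance matrix with row-aligned metadata."""

    matrix: AbundanceMatrix
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        if self.matrix.sample_ids != self.metadata.sample_ids:
            raise FingerprintError("matrix and metadata sample order disagree")


# ---------------------------------------------------------------------------
# readers / writers

def _read_delimited(path) -> pd.DataFrame:
    # sep=None sniffs among comma/tab/semicolon; decimal point only
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except pd.errors.ParserError as exc:
        raise FingerprintError(f"malformed delimited file {path}: {exc}") from exc


def read_peak_table(path, dialect: str = "wide") -> AbundanceMatrix:
    """Read an aligned peak table from delimited text.

    ``wide``: first column ``sample_id``, remaining headers compound labels.
    ``long``: columns ``sample_id``, ``compound_id``, ``abundance``; cells
    absent from the file are taken as 0 (peak not detected).
    """
    df = _read_delimited(path)
    if dialect == "wide":
        first = df.columns[0]
        if first != "sample_id":
            raise FingerprintError(
                f"wide peak table must start with a 'sample_id' column, got {first!r}"
            )
        df = df.set_index("sample_id")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise FingerprintError(
                f"ragged or missing cell at sample {df.index[i]!r}, "
                f"compound {df.columns[j]!r} (line {i + 2})"
            )
        mat = AbundanceMatrix([str(s) for s in df.index],
                              [str(c) for c in df.columns], values, "raw")
    elif dialect == "long":
        needed = {"sample_id", "compound_id", "abundance"}
        if not needed.issubset(df.columns):
            raise FingerprintError(
                f"long peak table needs columns {sorted(needed)}, got {list(df.columns)}"
            )
        dup = df.duplicated(subset=["sample_id", "compound_id"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise FingerprintError(
                f"duplicate entry for sample {row['sample_id']!r}, "
                f"compound {row['compound_id']!r}"
            )
        neg = df["abundance"] < 0
        if neg.any():
            line = int(np.nonzero(neg.to_numpy())[0][0]) + 2  # header = line 1
            raise FingerprintError(f"negative abundance at line {line}")
        wide = df.pivot(index="sample_id", columns="compound_id", values="abundance")
        wide = wide.fillna(0.0)
        mat = AbundanceMatrix([str(s) for s in wide.index],
                              [str(c) for c in wide.columns],
                              wide.to_numpy(dtype=float), "raw")
    else:
        raise FingerprintError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")
    return mat


def write_peak_table(matrix: AbundanceMatrix, path, dialect: str = "wide") -> None:
    """Inverse of :func:`read_peak_table` (lossless at 10 significant digits)."""
    if dialect == "wide":
        matrix.to_frame().to_csv(path, float_format="%.10g")
    elif dialect == "long":
        long = matrix.to_frame().stack().rename("abundance").reset_index()
        long.columns = ["sample_id", "compound_id", "abundance"]
        long = long[long["abundance"] != 0]
        long.to_csv(path, index=False, float_format="%.10g")
    else:
        raise FingerprintError(f"unknown dialect {dialect!r}")


def read_metadata(path) -> SampleMetadata:
    """Read a sample metadata table (sample_id, colony[, age_class, family_id])."""
    df = _read_delimited(path)
    keep = [c for c in ("sample_id", "colony", "age_class", "family_id") if c in df.columns]
    df = df[keep].astype({c: "string" for c in keep}).astype(object)
    df = df.where(pd.notna(df), None)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.table.to_csv(path, index=False)


def validate_dataset(matrix: AbundanceMatrix, metadata: SampleMetadata) -> ValidatedDataset:
    """Intersect matrix and metadata samples and align metadata to matrix order.

    Samples present in only one of the two tables are dropped with a log
    note; an empty intersection is an error.
    """
    meta_ids = set(metadata.sample_ids)
    keep = [s for s in matrix.sample_ids if s in meta_ids]
    if not keep:
        raise FingerprintError("no overlapping samples between matrix and metadata")
    dropped_matrix = [s for s in matrix.sample_ids if s not in meta_ids]
    dropped_meta = sorted(meta_ids - set(matrix.sample_ids))
    if dropped_matrix:
        logger.info("validate_dataset: dropped %d matrix samples without metadata: %s",
                    len(dropped_matrix), dropped_matrix[:10])
    if dropped_meta:
        logger.info("validate_dataset: dropped %d metadata rows without matrix samples: %s",
                    len(dropped_meta), dropped_meta[:10])
    if keep != matrix.sample_ids:
        rows = [matrix.sample_ids.index(s) for s in keep]
        matrix = AbundanceMatrix(keep, matrix.compound_ids,
                                 matrix.values[rows], matrix.unit_state)
    return ValidatedDataset(matrix, metadata.subset(keep))


def write_result_table(table: pd.DataFrame, path) -> None:
    """Write a result table as CSV, floats at >=8 significant digits."""
    if table.columns.empty:
        raise FingerprintError("result table has no columns")
    try:
        table.to_csv(path, index=False, float_format="%.8g")
    except OSError as exc:
        raise FingerprintError(f"cannot write result table to {path}: {exc}") from exc


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
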