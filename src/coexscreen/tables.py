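"""Tidy long-format measurement tables and their CSV dialect.

A :class:`MeasurementTable` holds one row per (sample, gene) measurement,
keyed by strain, condition, time point and replicate, together with a
``value_kind`` marker saying whether values are qPCR Ct cycles, relative
expression, fold change relative to the cell mean, or log2 fold change.
Missing measurements are absent rows, never sentinel numbers.

The on-disk dialect is plain UTF-8 CSV with the fixed header
``sample_id,strain,condition,timepoint_h,replicate,gene,value,value_kind``;
``sample_id`` is derivable as ``strain|condition|timepoint|replicate`` and is
checked for consistency on read.  Writing then reading a valid table is the
identity, including missing-row structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec, SampleKey, format_timepoint
from .errors import TableParseError, VocabularyError

log = logging.getLogger(__name__)

VALUE_KINDS = ("ct", "relative_expression", "fold_change", "log2_fold_change")

#: Column order of the on-disk CSV dialect.
CSV_HEADER = ["sample_id", "strain", "condition", "timepoint_h", "replicate", "gene", "value", "value_kind"]

#: In-memory key/value columns (sample_id and value_kind are derived).
DATA_COLUMNS = ["strain", "condition", "timepoint_h", "replicate", "gene", "value"]

DEFAULT_CT_CAP = 40.0


@dataclass
class MeasurementTable:
    """Long-format per-sample, per-gene measurements of one value kind."""

    data: pd.DataFrame
    value_kind: str
    provenance: str = ""

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise TableParseError(
                f"unknown value_kind {self.value_kind!r}; expected one of {VALUE_KINDS}"
            )
        df = self.data.copy()
        missing = [c for c in DATA_COLUMNS if c not in df.columns]
        if missing:
            raise TableParseError(f"measurement data missing columns {missing}")
        df = df[DATA_COLUMNS].reset_index(drop=True)
        df["strain"] = df["strain"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["gene"] = df["gene"].astype(str)
        df["timepoint_h"] = df["timepoint_h"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        self.data = df
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self, design: DesignSpec | None = None, ct_cap: float = DEFAULT_CT_CAP) -> None:
        """Check structural invariants; raise TableParseError/VocabularyError."""
        df = self.data
        dup = df.duplicated(subset=["strain", "condition", "timepoint_h", "replicate", "gene"])
        if dup.any():
            row = df[dup].iloc[0]
            raise TableParseError(
                "duplicate measurement for sample "
                f"{row.strain}|{row.condition}|{format_timepoint(row.timepoint_h)}|{row.replicate} "
                f"gene {row.gene}"
            )
        v = df["value"].to_numpy()
        if not np.all(np.isfinite(v)):
            raise TableParseError("non-finite measurement values")
        if self.value_kind == "ct":
            if len(v) and (v.min() <= 0 or v.max() > ct_cap):
                raise TableParseError(f"Ct values must lie in (0, {ct_cap}]")
        elif self.value_kind in ("relative_expression", "fold_change"):
            if len(v) and v.min() < 0:
                bad = df.loc[df["value"] < 0].iloc[0]
                raise TableParseError(
                    f"negative {self.value_kind} value {bad.value} for gene {bad.gene}"
                )
        if (df["replicate"] < 1).any():
            raise TableParseError("replicate indices must be positive integers")
        if design is not None:
            self._check_vocabulary(design)

    def _check_vocabulary(self, design: DesignSpec) -> None:
        allowed_genes = set(design.gene_panel) | {design.internal_standard}
        for column, allowed in (
            ("strain", set(design.strains)),
            ("condition", set(design.conditions)),
            ("gene", allowed_genes),
        ):
            unknown = set(self.data[column].unique()) - allowed
            if unknown:
                raise VocabularyError(
                    f"{column} label(s) {sorted(unknown)} not present in the design"
                )
        known_t = set(float(t) for t in design.timepoints_h)
        unknown_t = set(self.data["timepoint_h"].unique()) - known_t
        if unknown_t:
            raise VocabularyError(f"timepoint_h value(s) {sorted(unknown_t)} not in the design")

    # -- convenience --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def with_data(self, df: pd.DataFrame, value_kind: str | None = None,
                  provenance: str | None = None) -> "MeasurementTable":
        return MeasurementTable(
            data=df,
            value_kind=self.value_kind if value_kind is None else value_kind,
            provenance=self.provenance if provenance is None else provenance,
        )

    def to_wide(self) -> pd.DataFrame:
        """Samples-by-genes matrix (MultiIndex rows); absent rows become NaN."""
        return (
            self.data.set_index(["strain", "condition", "timepoint_h", "replicate", "gene"])["value"]
            .unstack("gene")
        )

    @classmethod
    def from_records(cls, records, value_kind: str, provenance: str = "") -> "MeasurementTable":
        """Build a table from (SampleKey, gene, value) triples."""
        rows = [
            {"strain": k.strain, "condition": k.condition, "timepoint_h": k.timepoint_h,
             "replicate": k.replicate, "gene": g, "value": v}
            for k, g, v in records
        ]
        df = pd.DataFrame(rows, columns=DATA_COLUMNS)
        return cls(data=df, value_kind=value_kind, provenance=provenance)


def _derive_sample_ids(df: pd.DataFrame) -> pd.Series:
    return (
        df["strain"] + "|" + df["condition"] + "|"
        + df["timepoint_h"].map(format_timepoint) + "|" + df["replicate"].astype(str)
    )


def write_table(table: MeasurementTable, path) -> None:
    """Serialize to the CSV dialect with full float precision (round-trip safe)."""
    df = table.data.copy()
    df.insert(0, "sample_id", _derive_sample_ids(df))
    df["value_kind"] = table.value_kind
    df["timepoint_h"] = df["timepoint_h"].map(lambda t: repr(float(t)))
    df["value"] = df["value"].map(lambda v: repr(float(v)))
    df[CSV_HEADER].to_csv(path, index=False)
    log.info("wrote %d rows (%s) to %s", len(df), table.value_kind, path)


def read_table(path, expected_value_kind: str | None = None,
               design: DesignSpec | None = None) -> MeasurementTable:
    """Parse and validate a measurement table from the CSV dialect.

    Errors name the offending line (header = line 1).  When a design is
    supplied, strain/condition/gene/timepoint labels are checked against it.
    """
    try:
        raw = pd.read_csv(
            path,
            dtype={"sample_id": str, "strain": str, "condition": str, "gene": str,
                   "value_kind": str},
            float_precision="round_trip",
        )
    except Exception as exc:
        raise TableParseError(f"{path}: cannot parse CSV: {exc}") from exc
    if list(raw.columns) != CSV_HEADER:
        raise TableParseError(
            f"{path}: line 1: malformed header {list(raw.columns)}; expected {CSV_HEADER}"
        )
    lineno = raw.index + 2  # header occupies line 1

    for col in ("timepoint_h", "value"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            raise TableParseError(
                f"{path}: line {lineno[bad][0]}: non-numeric {col} {raw[col][bad].iloc[0]!r}"
            )
        if coerced.isna().any():
            raise TableParseError(f"{path}: line {lineno[coerced.isna()][0]}: empty {col}")
        raw[col] = coerced
    rep = pd.to_numeric(raw["replicate"], errors="coerce")
    bad_rep = rep.isna() | (rep != rep.round())
    if bad_rep.any():
        raise TableParseError(f"{path}: line {lineno[bad_rep][0]}: replicate must be an integer")
    raw["replicate"] = rep.astype(int)

    kinds = raw["value_kind"].unique()
    if len(kinds) > 1:
        raise TableParseError(f"{path}: mixed value_kind values {sorted(kinds)}")
    kind = kinds[0] if len(kinds) else (expected_value_kind or "relative_expression")
    if kind not in VALUE_KINDS:
        raise TableParseError(f"{path}: unknown value_kind {kind!r}")
    if expected_value_kind is not None and len(kinds) and kind != expected_value_kind:
        raise TableParseError(
            f"{path}: value_kind is {kind!r}, expected {expected_value_kind!r}"
        )

    expected_ids = _derive_sample_ids(raw)
    bad = raw["sample_id"] != expected_ids
    if bad.any():
        raise TableParseError(
            f"{path}: line {lineno[bad][0]}: sample_id {raw['sample_id'][bad].iloc[0]!r} "
            f"does not match its key fields ({expected_ids[bad].iloc[0]!r})"
        )

    dup = raw.duplicated(subset=["sample_id", "gene"])
    if dup.any():
        raise TableParseError(
            f"{path}: line {lineno[dup][0]}: duplicate row for sample "
            f"{raw['sample_id'][dup].iloc[0]!r} gene {raw['gene'][dup].iloc[0]!r}"
        )

    try:
        table = MeasurementTable(data=raw[DATA_COLUMNS], value_kind=kind,
                                 provenance=f"read from {path}")
        table.validate(design=design)
    except (TableParseError, VocabularyError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc
    log.info("read %d rows (%s) from %s", len(table), kind, path)
    return table
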