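"""Reference-gene qPCR quantification: Ct to relative expression.

Relative expression of a target against the internal-standard transcript in
the same sample follows the classic comparative-Ct form,

    x = E ** (Ct_reference - Ct_target)

with amplification efficiency E = 2 (perfect doubling per cycle) by
default, i.e. ``2 ** -dCt`` for ``dCt = Ct_target - Ct_reference``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec
from .errors import DomainError, InsufficientDataError, QuantificationError
from .tables import DATA_COLUMNS, DEFAULT_CT_CAP, MeasurementTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean / sd / n over replicate relative-expression values."""

    mean: float
    sd: float
    n: int


def relative_expression(ct_target: float, ct_reference: float,
                        efficiency: float = 2.0, ct_cap: float = DEFAULT_CT_CAP) -> float:
    """Expression of the target relative to the internal standard.

    Strictly decreasing in ``ct_target``; adding the same offset to both Cts
    leaves the result unchanged.
    """
    if not (1.0 < efficiency <= 2.0):
        raise DomainError(f"efficiency must lie in (1, 2], got {efficiency}")
    for name, ct in (("ct_target", ct_target), ("ct_reference", ct_reference)):
        if not math.isfinite(ct) or not (0.0 < ct <= ct_cap):
            raise DomainError(f"{name}={ct} outside (0, {ct_cap}]")
    return float(efficiency ** (ct_reference - ct_target))


def quantify_table(ct_table: MeasurementTable, design: DesignSpec,
                   efficiency: float = 2.0) -> MeasurementTable:
    """Convert a Ct table to relative expression against the internal standard.

    Every sample that carries target measurements must also carry the
    internal-standard gene; the standard itself is dropped from the output.
    Missing target Cts stay missing (absent rows).
    """
    if ct_table.value_kind != "ct":
        raise DomainError(f"quantify_table expects value_kind='ct', got {ct_table.value_kind!r}")
    if not (1.0 < efficiency <= 2.0):
        raise DomainError(f"efficiency must lie in (1, 2], got {efficiency}")
    std = design.internal_standard
    df = ct_table.data
    keys = ["strain", "condition", "timepoint_h", "replicate"]
    std_ct = df[df["gene"] == std].set_index(keys)["value"]
    targets = df[df["gene"] != std]
    merged = targets.merge(std_ct.rename("std_ct"), how="left", left_on=keys, right_index=True)
    orphans = merged["std_ct"].isna()
    if orphans.any():
        bad = merged.loc[orphans, keys].drop_duplicates()
        ids = [f"{r.strain}|{r.condition}|{r.timepoint_h:g}|{r.replicate}" for r in bad.itertuples()]
        raise QuantificationError(
            f"sample(s) without internal standard {std!r}: {ids}"
        )
    out = merged.copy()
    out["value"] = np.asarray(efficiency, float) ** (out["std_ct"] - out["value"])
    out = out[DATA_COLUMNS]
    log.info("quantified %d measurements against %s (efficiency=%g)", len(out), std, efficiency)
    return MeasurementTable(data=out, value_kind="relative_expression",
                            provenance=f"quantify({ct_table.provenance})")


def summarize_replicates(values) -> ReplicateSummary:
    """Arithmetic mean and sample standard deviation (n-1 denominator; sd=0
    when n=1) over replicate values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("summarize_replicates: empty value list")
    if not np.all(np.isfinite(arr)) or (arr < 0).any():
        raise DomainError("replicate values must be finite and nonnegative")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return ReplicateSummary(mean=float(arr.mean()), sd=sd, n=int(arr.size))
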