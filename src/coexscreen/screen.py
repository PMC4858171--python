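"""Exclusion-aware pairwise co-expression screen against a reference gene.

The screen works in three stages, applied to a relative-expression table:

1. **Cell mean-centring** — within every (gene, condition, time point) cell
   the value of each strain is divided by the arithmetic mean of that cell
   across all strains with data (wild type included).  This expresses each
   measurement as *fold change relative to the mean* and removes the
   environmental (condition and time) signal, so that any remaining
   covariation between two genes is genotypic.
2. **log2 transform** — fold changes are log2-transformed (with a positive
   floor substituted for zeros) before correlation.
3. **Pearson screen** — every candidate gene is correlated against the
   reference gene over the samples admissible for the pair.  Samples from a
   gene's *own* insertional mutant are excluded, because the insertion
   trivially abolishes its expression there; by default the exclusion is the
   union over both pair members.  An extra leave-strain-out set supports
   robustness checks (does a single genotype drive a correlation?).

The two-sided p-value follows the exact t transform
``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .design import DesignSpec
from .errors import ConstantInputError, DomainError, InsufficientDataError, VocabularyError
from .tables import MeasurementTable

log = logging.getLogger(__name__)

#: Reported for |r| = 1, where the t transform diverges.
SMALLEST_POSITIVE = float.fromhex("0x0.0000000000001p-1022")  # 5e-324

EXCLUSION_MODES = ("union", "per_gene")


# ---------------------------------------------------------------------------
# normalization stages


def mean_center(table: MeasurementTable, design: DesignSpec | None = None) -> MeasurementTable:
    """Fold change relative to the cell mean.

    Within each (gene, condition, timepoint) cell, each value is divided by
    the arithmetic (linear-scale) mean of the cell across all strains with
    data.  Cells with fewer than two strains, and all-zero cells, yield
    missing outputs.  The across-strain mean of every surviving cell's fold
    changes is exactly 1.
    """
    if table.value_kind != "relative_expression":
        raise DomainError(f"mean_center expects relative_expression, got {table.value_kind!r}")
    if design is not None:
        table.validate(design=design)
    df = table.data
    grouped = df.groupby(["gene", "condition", "timepoint_h"], sort=False)
    n_strains = grouped["strain"].transform("nunique")
    cell_mean = grouped["value"].transform("mean")
    degenerate = n_strains < 2
    zero_mean = (~degenerate) & (cell_mean == 0)
    if zero_mean.any():
        cells = df.loc[zero_mean, ["gene", "condition", "timepoint_h"]].drop_duplicates()
        log.warning("mean_center: %d all-zero cell(s) emitted as missing: %s",
                    len(cells), cells.to_records(index=False).tolist())
    keep = ~degenerate & ~zero_mean
    out = df[keep].copy()
    out["value"] = df.loc[keep, "value"] / cell_mean[keep]
    log.info("mean_center: %d -> %d rows (%d dropped from degenerate/zero cells)",
             len(df), len(out), int((~keep).sum()))
    return MeasurementTable(data=out, value_kind="fold_change",
                            provenance=f"mean_center({table.provenance})")


def log2_transform(table: MeasurementTable, floor: float = 2.0 ** -10) -> MeasurementTable:
    """log2 of fold changes, substituting ``floor`` for values below it.

    The floor keeps knockout-like zeros informative instead of dropping
    them; missing rows stay missing.
    """
    if floor <= 0:
        raise DomainError(f"floor must be positive, got {floor}")
    if table.value_kind != "fold_change":
        raise DomainError(f"log2_transform expects fold_change, got {table.value_kind!r}")
    out = table.data.copy()
    out["value"] = np.log2(np.maximum(out["value"].to_numpy(), floor))
    return MeasurementTable(data=out, value_kind="log2_fold_change",
                            provenance=f"log2(floor={floor:g}, {table.provenance})")


# ---------------------------------------------------------------------------
# exclusion and correlation


def exclusion_mask(gene: str, design: DesignSpec, extra_leave_out=()) -> set[str]:
    """Strains whose samples are inadmissible for *gene*: its own profiled
    insertional mutant (if among the design's strains) plus any explicit
    leave-out set.  Genes whose mutant was not profiled contribute nothing."""
    if gene not in design.gene_panel:
        raise VocabularyError(f"gene {gene!r} is not in the design's gene panel")
    unknown = set(extra_leave_out) - set(design.strains)
    if unknown:
        raise VocabularyError(f"leave-out strain(s) {sorted(unknown)} not in the design")
    mask = set(extra_leave_out)
    own = design.own_mutant(gene)
    if own is not None:
        mask.add(own)
    return mask


@dataclass(frozen=True)
class PearsonResult:
    """Core Pearson statistics for one gene pair."""

    r: float
    r2: float
    p: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Sample Pearson correlation with the two-sided t-transform p-value.

    Pairwise-complete filtering is applied first; n >= 3 and non-constant
    vectors are required.  |r| = 1 reports the smallest representable
    positive p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("pearson expects two equal-length 1-d vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"pearson needs n >= 3 paired values, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    r = float(min(1.0, max(-1.0, r)))
    if abs(r) == 1.0 or p <= 0.0:
        p = SMALLEST_POSITIVE
    return PearsonResult(r=r, r2=r * r, p=float(p), n=n)


@dataclass(frozen=True)
class CorrelationResult:
    """One candidate gene correlated against the reference gene."""

    gene: str
    reference: str
    r: float
    r2: float
    p: float
    n: int
    excluded_strains: tuple[str, ...] = ()
    exclusion_reasons: dict = field(default_factory=dict, compare=False)
    note: str = ""

    @property
    def ok(self) -> bool:
        return np.isfinite(self.r)


def _sort_key(res: CorrelationResult):
    finite = np.isfinite(res.r2)
    return (0 if finite else 1, -(res.r2 if finite else 0.0), res.gene)


def correlate_vs_reference(log_table: MeasurementTable, design: DesignSpec,
                           leave_out=(), pair_exclusion: str = "union",
                           ) -> list[CorrelationResult]:
    """Correlate every panel gene against the reference gene.

    For each gene g, the samples used are the design samples minus the pair's
    exclusion set, intersected with rows where both g and the reference are
    non-missing (pairwise-complete).  ``pair_exclusion='union'`` removes both
    genes' own mutants; ``'per_gene'`` removes only g's.  Results are sorted
    by r² descending with a lexicographic gene tie-break; the reference gene
    itself appears as a control row with r² = 1.  Per-gene degeneracies
    (constant vectors, too few samples) become flagged rows, not aborts.
    """
    if log_table.value_kind != "log2_fold_change":
        raise DomainError(
            f"correlate_vs_reference expects log2_fold_change, got {log_table.value_kind!r}"
        )
    if pair_exclusion not in EXCLUSION_MODES:
        raise DomainError(f"pair_exclusion must be one of {EXCLUSION_MODES}")
    leave_out = set(leave_out)
    ref = design.reference_gene
    wide = log_table.to_wide()
    if ref not in wide.columns:
        raise VocabularyError(f"reference gene {ref!r} has no measurements in the table")
    strains = wide.index.get_level_values("strain")
    ref_vals = wide[ref]
    ref_mask = exclusion_mask(ref, design)

    def reasons_for(gene_mask: set[str], excl: set[str]) -> dict[str, str]:
        out = {}
        for s in sorted(excl):
            if s in gene_mask:
                out[s] = "own_mutant_of_gene"
            elif s in ref_mask and pair_exclusion == "union":
                out[s] = "own_mutant_of_reference"
            else:
                out[s] = "leave_out"
        return out

    results: list[CorrelationResult] = []

    # Reference-vs-itself control row.
    self_excl = ref_mask | leave_out
    self_rows = ~strains.isin(self_excl) & ref_vals.notna().to_numpy()
    results.append(CorrelationResult(
        gene=ref, reference=ref, r=1.0, r2=1.0, p=SMALLEST_POSITIVE,
        n=int(self_rows.sum()), excluded_strains=tuple(sorted(self_excl)),
        exclusion_reasons=reasons_for(ref_mask, self_excl), note="self",
    ))

    for g in design.gene_panel:
        if g == ref or g not in wide.columns:
            continue
        own = exclusion_mask(g, design)
        excl = own | leave_out
        if pair_exclusion == "union":
            excl |= ref_mask
        rows = ~strains.isin(excl) & wide[g].notna().to_numpy() & ref_vals.notna().to_numpy()
        x = wide[g].to_numpy()[rows]
        y = ref_vals.to_numpy()[rows]
        common = dict(gene=g, reference=ref, excluded_strains=tuple(sorted(excl)),
                      exclusion_reasons=reasons_for(own, excl))
        try:
            st = pearson(x, y)
        except (InsufficientDataError, ConstantInputError) as exc:
            results.append(CorrelationResult(
                r=float("nan"), r2=float("nan"), p=float("nan"),
                n=int(rows.sum()), note=type(exc).__name__, **common))
            continue
        results.append(CorrelationResult(r=st.r, r2=st.r2, p=st.p, n=st.n, **common))

    results.sort(key=_sort_key)
    log.info("correlated %d genes against %s (pair_exclusion=%s, leave_out=%s)",
             len(results) - 1, ref, pair_exclusion, sorted(leave_out))
    return results


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabular view of screen results (one row per gene)."""
    return pd.DataFrame([
        {"gene": r.gene, "reference": r.reference, "r": r.r, "r2": r.r2, "p": r.p,
         "n": r.n, "excluded_strains": ",".join(r.excluded_strains), "note": r.note}
        for r in results
    ])


# ---------------------------------------------------------------------------
# estimator layer


class CellMeanCenterer(BaseEstimator, TransformerMixin):
    """Stateless transformer: relative expression -> fold change relative to
    the (gene, condition, timepoint) cell mean."""

    def __init__(self, design: DesignSpec | None = None):
        self.design = design

    def fit(self, X: MeasurementTable, y=None):
        if not isinstance(X, MeasurementTable):
            raise DomainError("X must be a MeasurementTable")
        return self

    def transform(self, X: MeasurementTable) -> MeasurementTable:
        return mean_center(X, design=self.design)


class Log2FoldChange(BaseEstimator, TransformerMixin):
    """Stateless transformer: fold change -> log2 fold change with a floor."""

    def __init__(self, floor: float = 2.0 ** -10):
        self.floor = floor

    def fit(self, X: MeasurementTable, y=None):
        if self.floor <= 0:
            raise DomainError(f"floor must be positive, got {self.floor}")
        return self

    def transform(self, X: MeasurementTable) -> MeasurementTable:
        return log2_transform(X, floor=self.floor)


class CoexpressionScreen(BaseEstimator):
    """Full screen as a fit-shaped estimator.

    ``fit`` accepts a MeasurementTable of kind relative_expression (the
    centring and log2 stages are applied internally), fold_change (log2
    applied), or log2_fold_change (used as-is), and exposes the ranked
    correlation results as fitted attributes.

    Parameters
    ----------
    design : DesignSpec
        Experimental design; its ``reference_gene`` anchors the screen.
    leave_out : iterable of str
        Strains removed from every pair (leave-strain-out robustness).
    pair_exclusion : {"union", "per_gene"}
        Whether the reference gene's own mutant is excluded from all pairs.
    log2_floor : float
        Floor substituted for zero fold changes before log2.

    Attributes
    ----------
    results_ : list of CorrelationResult, sorted by r² descending.
    results_frame_ : pandas.DataFrame view of ``results_``.
    reference_ : the reference gene used.
    """

    def __init__(self, design: DesignSpec | None = None, leave_out=(),
                 pair_exclusion: str = "union", log2_floor: float = 2.0 ** -10):
        self.design = design
        self.leave_out = leave_out
        self.pair_exclusion = pair_exclusion
        self.log2_floor = log2_floor

    def fit(self, X: MeasurementTable, y=None):
        if self.design is None:
            raise DomainError("CoexpressionScreen requires a design")
        if not isinstance(X, MeasurementTable):
            raise DomainError("X must be a MeasurementTable")
        table = X
        if table.value_kind == "relative_expression":
            table = mean_center(table, design=self.design)
        if table.value_kind == "fold_change":
            table = log2_transform(table, floor=self.log2_floor)
        self.results_ = correlate_vs_reference(
            table, self.design, leave_out=self.leave_out,
            pair_exclusion=self.pair_exclusion)
        self.results_frame_ = results_frame(self.results_)
        self.reference_ = self.design.reference_gene
        return self

    def top_genes(self, k: int = 3) -> list[str]:
        """The k highest-r² candidate genes (control row excluded)."""
        ranked = [r.gene for r in self.results_ if r.note != "self" and r.ok]
        return ranked[:k]
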