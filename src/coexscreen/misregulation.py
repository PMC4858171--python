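"""Per-mutant misregulation profiles at a threefold cutoff.

For each mutant strain and each panel gene, the screen averages the
strain's fold-change values over all of its condition x time samples (16
in the default design) and flags the gene *down* when the mean falls below
1/cutoff, *up* above the cutoff, and *none* otherwise (boundary values are
not flagged).  Averaging over all samples makes the profile reflect the
general behaviour of a gene in the mutant, robust to misregulation in a
single condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .design import DesignSpec
from .errors import DomainError, InsufficientDataError, VocabularyError
from .tables import MeasurementTable
from sklearn.base import BaseEstimator

from .screen import mean_center

log = logging.getLogger(__name__)

MEAN_TYPES = ("linear", "geometric")


@dataclass(frozen=True)
class MisregulationProfile:
    """Mean fold change of one gene over one strain's samples."""

    strain: str
    gene: str
    mean_fold_change: float
    n_points: int
    flag: str = "none"
    note: str = ""


def _mean(values: np.ndarray, mean_type: str) -> float:
    if mean_type == "linear":
        return float(values.mean())
    if mean_type == "geometric":
        if (values == 0).any():
            return 0.0
        return float(np.exp2(np.log2(values).mean()))
    raise DomainError(f"mean_type must be one of {MEAN_TYPES}")


def strain_mean(fc_table: MeasurementTable, strain: str, gene: str,
                mean_type: str = "linear") -> MisregulationProfile:
    """Unflagged profile: mean over all non-missing fold changes of
    (strain, gene) across conditions and time points."""
    if fc_table.value_kind != "fold_change":
        raise DomainError(f"strain_mean expects fold_change, got {fc_table.value_kind!r}")
    df = fc_table.data
    vals = df.loc[(df["strain"] == strain) & (df["gene"] == gene), "value"].to_numpy()
    if vals.size == 0:
        raise InsufficientDataError(f"no fold-change data for strain {strain!r}, gene {gene!r}")
    return MisregulationProfile(strain=strain, gene=gene,
                                mean_fold_change=_mean(vals, mean_type),
                                n_points=int(vals.size))


def flag_misregulation(profile: MisregulationProfile, cutoff: float = 3.0) -> MisregulationProfile:
    """Attach the up/down/none flag at a fold cutoff (strict inequalities)."""
    if cutoff <= 1:
        raise DomainError(f"cutoff must exceed 1, got {cutoff}")
    m = profile.mean_fold_change
    if m < 1.0 / cutoff:
        flag = "down"
    elif m > cutoff:
        flag = "up"
    else:
        flag = "none"
    return replace(profile, flag=flag)


def screen_all(fc_table: MeasurementTable, design: DesignSpec, cutoff: float = 3.0,
               mean_type: str = "linear") -> list[MisregulationProfile]:
    """One flagged profile per (mutant strain, panel gene); the wild type is
    omitted (it still contributed to the centring means upstream).  Cells
    without data become flagged note rows, not aborts.  Deterministic
    ordering: strain-major, gene-minor, both in design order."""
    if cutoff <= 1:
        raise DomainError(f"cutoff must exceed 1, got {cutoff}")
    if fc_table.value_kind != "fold_change":
        raise DomainError(f"screen_all expects fold_change, got {fc_table.value_kind!r}")
    fc_table.validate(design=design)
    profiles = []
    for strain in design.mutant_strains:
        for gene in design.gene_panel:
            try:
                prof = strain_mean(fc_table, strain, gene, mean_type=mean_type)
            except InsufficientDataError:
                profiles.append(MisregulationProfile(
                    strain=strain, gene=gene, mean_fold_change=float("nan"),
                    n_points=0, flag="none", note="no_data"))
                continue
            profiles.append(flag_misregulation(prof, cutoff=cutoff))
    n_flagged = sum(p.flag != "none" for p in profiles)
    log.info("misregulation screen: %d profiles, %d flagged at cutoff %g",
             len(profiles), n_flagged, cutoff)
    return profiles


def profiles_frame(profiles: list[MisregulationProfile]):
    import pandas as pd

    return pd.DataFrame([
        {"strain": p.strain, "gene": p.gene, "mean_fold_change": p.mean_fold_change,
         "n_points": p.n_points, "flag": p.flag, "note": p.note}
        for p in profiles
    ])


class MisregulationScreen(BaseEstimator):
    """Fit-shaped misregulation screen.

    ``fit`` accepts a relative-expression table (centred internally) or a
    fold-change table, and exposes the flagged profiles as fitted
    attributes ``profiles_`` and ``profiles_frame_``.
    """

    def __init__(self, design: DesignSpec | None = None, cutoff: float = 3.0,
                 mean_type: str = "linear"):
        self.design = design
        self.cutoff = cutoff
        self.mean_type = mean_type

    def fit(self, X: MeasurementTable, y=None):
        if self.design is None:
            raise DomainError("MisregulationScreen requires a design")
        if not isinstance(X, MeasurementTable):
            raise DomainError("X must be a MeasurementTable")
        table = X
        if table.value_kind == "relative_expression":
            table = mean_center(table, design=self.design)
        self.profiles_ = screen_all(table, self.design, cutoff=self.cutoff,
                                    mean_type=self.mean_type)
        self.profiles_frame_ = profiles_frame(self.profiles_)
        return self

    def flagged(self, flag: str | None = None) -> list[MisregulationProfile]:
        """Profiles carrying a flag (optionally restricted to 'up' or 'down')."""
        wanted = ("up", "down") if flag is None else (flag,)
        return [p for p in self.profiles_ if p.flag in wanted]
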