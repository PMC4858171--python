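"""Experimental-design vocabulary for factorial mutant x nitrogen x time panels.

A :class:`DesignSpec` names everything the pipeline needs to interpret a
measurement table: the strains profiled (one of which is the wild type),
the nitrogen conditions, the harvest time points, the gene panel with its
correlation reference gene and qPCR internal standard, and the partial map
from a candidate gene to the insertional mutant in which it is interrupted.

The default design (:func:`default_design`) is the 9-strain, 4-condition,
4-time-point layout of the screen this package implements: 144 cultures,
each assayed for a 12-gene panel by qRT-PCR.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .errors import DesignValidationError


class SampleKey(NamedTuple):
    """Identity of one harvested culture."""

    strain: str
    condition: str
    timepoint_h: float
    replicate: int


def _require_str_labels(values: Iterable, field: str) -> tuple:
    out = []
    for v in values:
        if isinstance(v, float):
            raise ValueError(
                f"{field}: label {v!r} parsed as a number; quote decimal labels "
                "like '54.10' so trailing zeros survive"
            )
        out.append(str(v))
    return tuple(out)


def _check_unique(values, field: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise ValueError(f"{field}: duplicate label {v!r}")
        seen.add(v)


class DesignSpec(BaseModel):
    """Vocabulary and structure of one factorial expression experiment."""

    model_config = ConfigDict(frozen=True)

    strains: tuple[str, ...]
    wild_type: str
    conditions: tuple[str, ...]
    timepoints_h: tuple[float, ...]
    gene_panel: tuple[str, ...]
    reference_gene: str
    internal_standard: str = "UBQL"
    gene_to_mutant: dict[str, str] = {}

    @field_validator("strains", "conditions", "gene_panel", mode="before")
    @classmethod
    def _coerce_labels(cls, v, info):
        return _require_str_labels(v, info.field_name)

    @field_validator("wild_type", "reference_gene", "internal_standard", mode="before")
    @classmethod
    def _coerce_scalar(cls, v):
        if isinstance(v, float):
            raise ValueError(f"label {v!r} parsed as a number; quote it")
        return str(v)

    @field_validator("gene_to_mutant", mode="before")
    @classmethod
    def _coerce_map(cls, v):
        if v is None:
            return {}
        return {str(k): str(val) for k, val in dict(v).items()}

    @model_validator(mode="after")
    def _invariants(self):
        for field in ("strains", "conditions", "gene_panel", "timepoints_h"):
            _check_unique(getattr(self, field), field)
        if not self.strains or not self.conditions or not self.timepoints_h or not self.gene_panel:
            raise ValueError("strains, conditions, timepoints_h and gene_panel must be non-empty")
        if any(t <= 0 for t in self.timepoints_h):
            raise ValueError("timepoints_h must be positive hours")
        if self.wild_type not in self.strains:
            raise ValueError(f"wild_type {self.wild_type!r} is not among strains")
        if self.reference_gene not in self.gene_panel:
            raise ValueError(f"reference_gene {self.reference_gene!r} is not in gene_panel")
        unknown = set(self.gene_to_mutant) - set(self.gene_panel)
        if unknown:
            raise ValueError(f"gene_to_mutant keys not in gene_panel: {sorted(unknown)}")
        # The restriction of gene -> mutant to profiled strains must be
        # injective: two panel genes cannot claim the same profiled mutant.
        profiled = [m for m in self.gene_to_mutant.values() if m in self.strains]
        _check_unique(profiled, "gene_to_mutant (profiled mutants)")
        return self

    @property
    def mutant_strains(self) -> tuple[str, ...]:
        """All strains except the wild type, in design order."""
        return tuple(s for s in self.strains if s != self.wild_type)

    def own_mutant(self, gene: str) -> str | None:
        """Profiled mutant strain in which *gene* is interrupted, if any."""
        m = self.gene_to_mutant.get(gene)
        return m if m in self.strains else None


def build_design(**fields) -> DesignSpec:
    """Construct a :class:`DesignSpec`, re-raising pydantic failures as
    :class:`DesignValidationError` with the violated invariant in the message."""
    try:
        return DesignSpec(**fields)
    except ValidationError as exc:  # pragma: no cover - thin re-wrap
        raise DesignValidationError(str(exc)) from exc


def default_design() -> DesignSpec:
    """The 9 x 4 x 4 screen design: wild type 704, six ammonium-insensitive
    (AI) mutants, two chlorate-sensitive-in-ammonium (CSA) mutants, four
    nitrogen contexts, four harvest times, and a 12-gene candidate panel.

    Two panel slots (``CG_A``, ``CG_B``) are configurable placeholders for
    first-subset candidates whose identity is not fixed by the design.
    """
    return DesignSpec(
        strains=("704", "cyg56", "cdp1", "20.40", "54.10", "258.90", "259.89", "N10", "N24"),
        wild_type="704",
        conditions=("NO3_4mM", "NH4_8mM", "NO3_4mM+NH4_8mM", "NO3_4mM+NH4_1mM"),
        timepoints_h=(0.5, 1.0, 3.0, 24.0),
        gene_panel=(
            "CYG56", "CDP1", "20.40CG1", "258.90CG", "CG_A", "CG_B",
            "42.49CG1", "42.49CG2", "85.37CG", "106.20CG1", "106.20CG2", "209.82CG",
        ),
        reference_gene="CYG56",
        internal_standard="UBQL",
        gene_to_mutant={
            "CYG56": "cyg56",
            "CDP1": "cdp1",
            "20.40CG1": "20.40",
            "258.90CG": "258.90",
            "42.49CG1": "42.49",
            "42.49CG2": "42.49",
            "85.37CG": "85.37",
            "106.20CG1": "106.20",
            "106.20CG2": "106.20",
            "209.82CG": "209.82",
        },
    )


def enumerate_design(design: DesignSpec, replicates: int = 1) -> list[SampleKey]:
    """Full factorial sample list: strains x conditions x timepoints x replicates.

    Deterministic design-order sequence (strain-major, replicate-minor); its
    length is the product of the four cardinalities.
    """
    if not isinstance(replicates, int) or replicates < 1:
        raise DesignValidationError(f"replicates must be a positive integer, got {replicates!r}")
    return [
        SampleKey(s, c, float(t), r)
        for s in design.strains
        for c in design.conditions
        for t in design.timepoints_h
        for r in range(1, replicates + 1)
    ]


def format_timepoint(t: float) -> str:
    """Render a time point without a spurious trailing ``.0`` (24.0 -> "24")."""
    return format(float(t), "g")


def sample_id(key: SampleKey) -> str:
    """Canonical ``strain|condition|timepoint|replicate`` identifier."""
    return f"{key.strain}|{key.condition}|{format_timepoint(key.timepoint_h)}|{key.replicate}"


def load_design(path) -> DesignSpec:
    """Read a DesignSpec from a YAML/JSON config file.

    Accepts either the design fields at top level or nested under a
    ``design`` key (the layout used by generator configs).
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise DesignValidationError(f"{path}: config must be a mapping")
    fields = doc.get("design", doc)
    fields = {k: v for k, v in fields.items() if k in DesignSpec.model_fields}
    return build_design(**fields)
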