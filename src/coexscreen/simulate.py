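"""Synthetic factorial expression data with the structure the screen assumes.

The generator is a phenomenological log-linear model.  Each sample/gene
cell receives a log2 expression value

    log2 x = baseline(g) + condition(g, c) + time(g, t) + genotype(g, s) + noise

with Gaussian noise on the log2 scale (multiplicative lognormal on the
linear scale).  A gene measured in the insertional mutant that interrupts
it ignores all of the above and sits at a fixed knockout floor, emulating
loss of its transcript.  Values are clipped below at a detection floor.

``genotype_effects`` is where co-regulation is planted: shifting the
reference gene and a set of targets together in one strain creates the
shared-regulator signal the correlation screen is designed to detect.
:func:`null_config`/:func:`null_dataset` strip all genotype structure so the
screen's false-positive behaviour can be calibrated.
"""

from __future__ import annotations

import importlib.resources
import logging

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .design import DesignSpec, enumerate_design
from .errors import DesignValidationError, DomainError
from .tables import DATA_COLUMNS, DEFAULT_CT_CAP, MeasurementTable

log = logging.getLogger(__name__)


def _str_float_map(v):
    return {str(k): float(val) for k, val in dict(v or {}).items()}


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic-data model.

    Effects are sparse nested maps gene -> {label: log2 shift}; any pair not
    listed contributes zero.  ``noise_sd_log2`` is the standard deviation of
    the log2-scale Gaussian noise; ``detection_floor`` is the smallest
    reportable relative expression; ``knockout_floor_log2`` is the log2
    value a gene takes in its own mutant.
    """

    model_config = ConfigDict(frozen=True)

    design: DesignSpec
    baseline_log2: dict[str, float] = {}
    condition_effects: dict[str, dict[str, float]] = {}
    time_effects: dict[str, dict[float, float]] = {}
    genotype_effects: dict[str, dict[str, float]] = {}
    knockout_floor_log2: float = -10.0
    noise_sd_log2: float = 0.5
    detection_floor: float = 2.0 ** -10
    seed: int = 0

    @field_validator("baseline_log2", mode="before")
    @classmethod
    def _v_baseline(cls, v):
        return _str_float_map(v)

    @field_validator("condition_effects", "genotype_effects", mode="before")
    @classmethod
    def _v_nested(cls, v):
        return {str(g): _str_float_map(inner) for g, inner in dict(v or {}).items()}

    @field_validator("time_effects", mode="before")
    @classmethod
    def _v_time(cls, v):
        return {
            str(g): {float(t): float(e) for t, e in dict(inner or {}).items()}
            for g, inner in dict(v or {}).items()
        }

    @model_validator(mode="after")
    def _invariants(self):
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if self.detection_floor <= 0:
            raise ValueError("detection_floor must be > 0")
        genes = set(self.design.gene_panel)
        for name, eff in (("baseline_log2", self.baseline_log2),
                          ("condition_effects", self.condition_effects),
                          ("time_effects", self.time_effects),
                          ("genotype_effects", self.genotype_effects)):
            unknown = set(eff) - genes
            if unknown:
                raise ValueError(f"{name} references unknown gene(s) {sorted(unknown)}")
        for g, inner in self.condition_effects.items():
            bad = set(inner) - set(self.design.conditions)
            if bad:
                raise ValueError(f"condition_effects[{g}] references unknown condition(s) {sorted(bad)}")
        for g, inner in self.time_effects.items():
            bad = set(inner) - set(float(t) for t in self.design.timepoints_h)
            if bad:
                raise ValueError(f"time_effects[{g}] references unknown timepoint(s) {sorted(bad)}")
        for g, inner in self.genotype_effects.items():
            bad = set(inner) - set(self.design.strains)
            if bad:
                raise ValueError(f"genotype_effects[{g}] references unknown strain(s) {sorted(bad)}")
        return self


def build_generator_config(**fields) -> GeneratorConfig:
    try:
        return GeneratorConfig(**fields)
    except ValidationError as exc:
        raise DesignValidationError(str(exc)) from exc


def _noise_free_log2(config: GeneratorConfig, include_genotype: bool) -> np.ndarray:
    """Deterministic (samples x genes) log2 matrix, before noise and knockouts."""
    design = config.design
    samples = enumerate_design(design, 1)
    genes = design.gene_panel
    out = np.zeros((len(samples), len(genes)))
    conds = [k.condition for k in samples]
    tps = [k.timepoint_h for k in samples]
    strains = [k.strain for k in samples]
    for j, g in enumerate(genes):
        col = np.full(len(samples), config.baseline_log2.get(g, 0.0))
        ce = config.condition_effects.get(g)
        if ce:
            col += np.array([ce.get(c, 0.0) for c in conds])
        te = config.time_effects.get(g)
        if te:
            col += np.array([te.get(t, 0.0) for t in tps])
        if include_genotype:
            ge = config.genotype_effects.get(g)
            if ge:
                col += np.array([ge.get(s, 0.0) for s in strains])
        out[:, j] = col
    return out


def _assemble(config: GeneratorConfig, include_genotype: bool, provenance: str) -> MeasurementTable:
    design = config.design
    samples = enumerate_design(design, 1)
    genes = design.gene_panel
    n_s, n_g = len(samples), len(genes)

    log2 = _noise_free_log2(config, include_genotype)
    # One PRNG stream per dataset; C-order (sample-major, gene-minor) draws.
    rng = np.random.default_rng(config.seed)
    if config.noise_sd_log2 > 0:
        log2 = log2 + rng.normal(0.0, config.noise_sd_log2, size=(n_s, n_g))
    values = np.maximum(np.exp2(log2), config.detection_floor)

    if include_genotype:
        strain_arr = np.array([k.strain for k in samples])
        ko_value = max(2.0 ** config.knockout_floor_log2, config.detection_floor)
        for j, g in enumerate(genes):
            mutant = design.own_mutant(g)
            if mutant is not None:
                values[strain_arr == mutant, j] = ko_value

    df = pd.DataFrame({
        "strain": np.repeat([k.strain for k in samples], n_g),
        "condition": np.repeat([k.condition for k in samples], n_g),
        "timepoint_h": np.repeat([k.timepoint_h for k in samples], n_g),
        "replicate": np.repeat([k.replicate for k in samples], n_g),
        "gene": np.tile(genes, n_s),
        "value": values.ravel(),
    }, columns=DATA_COLUMNS)
    log.info("simulated %d samples x %d genes (seed=%d, %s)",
             n_s, n_g, config.seed, provenance)
    return MeasurementTable(data=df, value_kind="relative_expression", provenance=provenance)


def generate_dataset(config: GeneratorConfig) -> MeasurementTable:
    """Simulate the full factorial dataset (value_kind=relative_expression).

    Identical config (including seed) gives a bit-identical table.  Knockout
    cells (a gene in its own profiled mutant) are noise-free at the knockout
    floor; everything else is clipped below at the detection floor.
    """
    return _assemble(config, include_genotype=True,
                     provenance=f"generate_dataset(seed={config.seed})")


def null_dataset(config: GeneratorConfig) -> MeasurementTable:
    """As :func:`generate_dataset` but with genotype effects and knockouts
    removed: only condition, time and noise remain, so no genotypic
    co-regulation exists by construction."""
    return _assemble(config, include_genotype=False,
                     provenance=f"null_dataset(seed={config.seed})")


def ct_layer(table: MeasurementTable, reference_ct: float = 20.0,
             internal_standard: str = "UBQL", ct_cap: float = DEFAULT_CT_CAP) -> MeasurementTable:
    """Emulate the raw qPCR signal behind a relative-expression table.

    Each gene's Ct is ``reference_ct - log2(relative_expression)`` and every
    sample additionally carries the internal-standard gene at ``reference_ct``
    exactly.  Cts above ``ct_cap`` (non-detects) become absent rows.
    """
    if table.value_kind != "relative_expression":
        raise DomainError(f"ct_layer expects relative_expression, got {table.value_kind!r}")
    if reference_ct <= 0 or reference_ct > ct_cap:
        raise DomainError(f"reference_ct must lie in (0, {ct_cap}]")
    df = table.data
    if (df["value"] <= 0).any():
        raise DomainError("ct_layer requires strictly positive expression values")
    out = df.copy()
    out["value"] = reference_ct - np.log2(out["value"].to_numpy())
    n_dropped = int((out["value"] > ct_cap).sum())
    out = out[(out["value"] > 0) & (out["value"] <= ct_cap)]
    std = (
        df[["strain", "condition", "timepoint_h", "replicate"]]
        .drop_duplicates()
        .assign(gene=internal_standard, value=float(reference_ct))
    )
    out = pd.concat([out, std], ignore_index=True)[DATA_COLUMNS]
    if n_dropped:
        log.info("ct_layer: %d measurements above ct_cap=%g emitted as missing", n_dropped, ct_cap)
    return MeasurementTable(data=out, value_kind="ct",
                            provenance=f"ct_layer({table.provenance})")


def paper_like_config(seed: int | None = None) -> GeneratorConfig:
    """The shipped default configuration: ammonium induction of the reference
    gene and CDP1, a strong shared-regulator downshift in strain 54.10
    (reference, CDP1, 42.49CG1) with a mild shift of 85.37CG, stable genes
    untouched, and knockouts in the four profiled own-mutants."""
    ref = importlib.resources.files("coexscreen").joinpath("data/paper_like.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    cfg = dict(doc.get("generator", {}))
    cfg["design"] = doc["design"]
    if seed is not None:
        cfg["seed"] = int(seed)
    return build_generator_config(**cfg)


def null_screen_config(n_genes: int = 1000, noise_sd_log2: float = 0.5,
                       seed: int = 0) -> GeneratorConfig:
    """A calibration config: the default strain/condition/time layout with a
    panel of the reference gene plus ``n_genes`` effect-free null genes."""
    base = paper_like_config().design
    panel = (base.reference_gene,) + tuple(f"NULL{i:05d}" for i in range(n_genes))
    design = DesignSpec(
        strains=base.strains, wild_type=base.wild_type, conditions=base.conditions,
        timepoints_h=base.timepoints_h, gene_panel=panel,
        reference_gene=base.reference_gene, internal_standard=base.internal_standard,
        gene_to_mutant={base.reference_gene: "cyg56"},
    )
    return build_generator_config(design=design, noise_sd_log2=noise_sd_log2, seed=seed)


def load_generator_config(path, seed: int | None = None) -> GeneratorConfig:
    """Read a generator config (design + generator sections) from YAML/JSON."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "design" not in doc:
        raise DesignValidationError(f"{path}: generator config needs a 'design' section")
    cfg = dict(doc.get("generator", {}))
    cfg["design"] = doc["design"]
    if seed is not None:
        cfg["seed"] = int(seed)
    return build_generator_config(**cfg)
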