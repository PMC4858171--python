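# Default synthetic-data configuration for the 9-strain x 4-condition x
# 4-time-point candidate-gene screen.  Directions of the planted effects are
# fixed by the biology the generator emulates (ammonium induction of the
# reference gene and CDP1, a shared-regulator downshift in strain 54.10,
# stable control genes); the magnitudes are package defaults.
design:
  strains: ["704", "cyg56", "cdp1", "20.40", "54.10", "258.90", "259.89", "N10", "N24"]
  wild_type: "704"
  conditions: ["NO3_4mM", "NH4_8mM", "NO3_4mM+NH4_8mM", "NO3_4mM+NH4_1mM"]
  timepoints_h: [0.5, 1, 3, 24]
  gene_panel: ["CYG56", "CDP1", "20.40CG1", "258.90CG", "CG_A", "CG_B",
               "42.49CG1", "42.49CG2", "85.37CG", "106.20CG1", "106.20CG2", "209.82CG"]
  reference_gene: "CYG56"
  internal_standard: "UBQL"
  gene_to_mutant:
    CYG56: "cyg56"
    CDP1: "cdp1"
    "20.40CG1": "20.40"
    "258.90CG": "258.90"
    "42.49CG1": "42.49"
    "42.49CG2": "42.49"
    "85.37CG": "85.37"
    "106.20CG1": "106.20"
    "106.20CG2": "106.20"
    "209.82CG": "209.82"
generator:
  baseline_log2: {}
  condition_effects:
    CYG56: {"NH4_8mM": 2.0, "NO3_4mM+NH4_8mM": 1.5, "NO3_4mM+NH4_1mM": 1.0}
    CDP1: {"NH4_8mM": 2.0, "NO3_4mM+NH4_8mM": 1.5, "NO3_4mM+NH4_1mM": 1.0}
  time_effects:
    CYG56: {"24": -1.0}
    CDP1: {"24": -1.0}
  genotype_effects:
    CYG56: {"54.10": -3.0}
    CDP1: {"54.10": -3.0}
    "42.49CG1": {"54.10": -3.0}
    "85.37CG": {"54.10": -1.0}
  knockout_floor_log2: -10.0
  noise_sd_log2: 0.5
  detection_floor: 0.0009765625
  seed: 0
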