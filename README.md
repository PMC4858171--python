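# coexscreen

Candidate-gene co-expression screening for factorial qRT-PCR panels.

`coexscreen` implements, as a tested and reusable pipeline, the screen used
to find genes co-regulated with a reference gene across a factorial
**mutant × nitrogen-condition × time-course** expression experiment — the
strategy that identifies shared upstream regulators among candidate genes
for ammonium/nitric-oxide signalling in *Chlamydomonas reinhardtii*. It is
aimed at groups running qRT-PCR candidate panels over insertional-mutant
collections who want the normalization, exclusion rules and statistics of
the screen to be explicit, validated and repeatable.

## The method

Given relative expression `x(g, s, c, t)` of gene *g* in strain *s*,
condition *c*, time *t* (one of 9 strains × 4 nitrogen contexts × 4 harvest
times = 144 samples in the default design):

1. **Cell mean-centring.** Within every (gene, condition, time) cell the
   value of each strain is divided by the arithmetic mean of the cell
   across all strains, giving *fold change relative to the mean*:
   `f = x / mean_strains(x)`. This removes the environmental (condition and
   time) signal, so residual covariation between genes is genotypic.
2. **log2 transform** of the fold changes (zeros floored at 2⁻¹⁰).
3. **Exclusion-aware Pearson screen.** Each candidate *g* is correlated
   with the reference gene over all samples admissible for the pair:
   samples from a gene's *own* insertional mutant are excluded (the
   insertion trivially abolishes its expression there), by default as the
   union over both pair members. The two-sided p-value uses the exact
   transform `t = r·√((n−2)/(1−r²))` on `n−2` df. A leave-strain-out option
   tests whether a single genotype drives a correlation.
4. **Misregulation profiling.** Per (mutant, gene), the mean fold change
   over all of the strain's samples (16 in the default design) is flagged
   `down` below 1/3 and `up` above 3 (strict inequalities).

The package also provides comparative-Ct quantification against an
internal-standard transcript (`x = E^(Ct_ref − Ct_target)`, E = 2 by
default), replicate summaries, percent-of-control and pooled-variance
Student-t reporting, and a seeded synthetic-data generator
(`paper_like.yaml`) that plants knockouts, condition/time effects and a
shared-regulator signal so every stage is testable without downloads.

## Worked example

```python
import coexscreen as cx

cfg = cx.paper_like_config(seed=11)          # 9 strains x 4 conditions x 4 times, 12 genes
expr = cx.generate_dataset(cfg)              # 1728 relative-expression measurements

screen = cx.CoexpressionScreen(design=cfg.design).fit(expr)
print(screen.results_frame_[["gene", "r2", "p", "n", "excluded_strains"]].head(6))
```

```
    gene       r2             p   n excluded_strains
   CYG56 1.000000 4.940656e-324 128            cyg56
42.49CG1 0.779452  3.505743e-43 128            cyg56
    CDP1 0.703081  8.917434e-31 112       cdp1,cyg56
 85.37CG 0.161269  2.625329e-06 128            cyg56
42.49CG2 0.036863  2.992094e-02 128            cyg56
258.90CG 0.015111  1.966262e-01 112     258.90,cyg56
```

The first row is the reference-vs-itself control (r² = 1 by construction;
n = 128 because the reference gene's own mutant contributes no admissible
samples). The three genes planted with the shared-regulator effect
(42.49CG1, CDP1, 85.37CG) occupy the top three r² ranks; stable genes sit
near zero. `n` differs across rows because exclusions are per pair.

```python
ms = cx.MisregulationScreen(design=cfg.design, cutoff=3.0).fit(expr)
print(ms.profiles_frame_.query("strain == '54.10' and flag != 'none'"))
```

```
strain     gene  mean_fold_change  n_points flag
 54.10    CYG56          0.170254        16 down
 54.10     CDP1          0.152261        16 down
 54.10 42.49CG1          0.121164        16 down
```

Each mean uses the strain's 16 condition × time samples; the planted
strong downshifts in strain 54.10 cross the threefold cutoff.

The same workflow is available from the shell:

```bash
coexscreen simulate --seed 11 --out sim.csv
coexscreen validate sim.csv --design design.yaml
coexscreen correlate --in sim.csv --design design.yaml --leave-out 54.10 --out corr.tsv
coexscreen misregulation --in sim.csv --design design.yaml --out misreg.tsv
```

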