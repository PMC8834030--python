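# agesom

Self-organizing-map (SOM) "portrayal" of paired gene-expression and
DNA-methylation cohorts across the human lifespan.

Brain tissue changes its transcriptional and epigenetic programs from
birth to old age: developmental modules switch off, metabolic and
inflammatory modules switch on, and promoter methylation mostly moves in
the opposite direction to expression. `agesom` is a toolkit for studying
these dynamics at the level of *gene modules* rather than single genes.
It is aimed at computational biologists who have preprocessed gene x
sample matrices (log-scale expression intensities, Infinium-style
methylation beta values with CpG/TSS annotation) and ordered age-group
metadata.

## Method

Genes are clustered into **metagenes** on a 40 x 40 grid by a batch
self-organizing map trained on their centralized profiles over samples
(Δe for expression; Δm = centralized log₂ methylated/unmethylated
promoter odds for methylation, obtained from beta values by the logit
transform m = log₂(β/(1−β)) after averaging CpGs in the promoter window
[−1500, +500] bp around the TSS). Each sample's **portrait** is the grid
of metagene values at that sample. On top of the fitted map the package
provides:

- **Spot modules** — connected grid regions of jointly over-expressed /
  hyper-methylated metagenes, segmented from the node-wise maximum over
  age-group mean portraits, with per-group Δe/Δm profiles and labels
  ordered by the age of peak activity ("A" earliest).
- **Sample-level views** — pairwise correlation maps (PCM) between
  portraits, correlation similarity nets, supporting maps (population,
  variance, t-statistic significance, portrait entropy, wTO between spot
  profiles, invariant-gene region) and per-sample mean/variance/entropy
  summaries whose age course traces the "hourglass" shape.
- **Gene-set analysis** — Fisher overrepresentation of sets in spots
  (BH-adjusted), sample-wise gene-set Z profiles
  GSZ(s) = (⟨Δ⟩_set − ⟨Δ⟩_all) / (sd_all/√n_set), smoothed gene-density
  maps, and entropy-based **spot-melting** scores quantifying how a set
  compact in one map disperses in the independently trained other map
  (a signature of expression–methylation decoupling).
- **Coupling classification** — Pearson correlation of group-ordered
  (M, E) trajectories into repressed (r ≤ −0.5), repressive-complex-like
  (r ≥ +0.5) and decoupled categories.
- **Chromatin-state strata** — per state (TssA, TssP, Tx, Enh…, RepPC),
  genes split into fetal-only / overlap / adult-only strata and profiled
  as gene sets on both layers.
- **Extension SOM (exSOM)** — projection of secondary cohorts onto the
  frozen primary map (node value = mean over the node's member genes),
  with cross-cohort correlation maps and river-flow assignment of
  secondary samples to primary age groups.

A synthetic-cohort generator plants gene modules with known age courses
(monotone, U/inverse-U, early/late peaks) and known promoter-methylation
coupling, so every stage can be validated against ground truth.

## Worked example

```python
from agesom import (
    SOMPortrayal, expression_fixture_spec, generate_cohort,
    group_mean_portraits, detect_spots, spot_profiles,
)
from agesom.preprocess import centralize

cohort = generate_cohort(expression_fixture_spec(seed=1))
matrix = centralize(cohort.expression)          # delta-e values
model = SOMPortrayal(rows=40, cols=40, epochs=50, seed=1).fit(matrix)
groups = cohort.metadata["group"].to_dict()
gp = group_mean_portraits(model.portraits(), groups, cohort.scheme)
spots = detect_spots(model, gp, cohort.scheme)
print(spots.report().to_string(index=False))
per_group, _ = spot_profiles(spots, matrix, groups, cohort.scheme)
print(per_group.round(2).to_string())
```

prints

```
spot  n_nodes  n_genes peak_group
   A       51      179    newborn
   B       57      199    newborn
   C       67      186       baby
   D       66      184     infant
   E       51      185   teenager
   F       62      189      adult
   G       45      174 late_adult

   newborn  baby  infant  teenager  adult  late_adult
A     2.01  1.19    0.41     -0.41  -1.21       -1.99
B     2.02 -0.40   -1.60     -1.61  -0.40        1.99
C    -0.21  2.03   -0.20     -0.55  -0.54       -0.54
D    -0.54 -0.21    2.01     -0.19  -0.55       -0.53
E    -0.54 -0.53   -0.20      2.00  -0.19       -0.54
F    -0.55 -0.55   -0.53     -0.18   2.01       -0.19
G    -2.03 -1.20   -0.40      0.42   1.20        2.01
```

Seven spot modules are segmented from the simulated cohort. Spot A is
the developmental module (high in newborns, declining monotonically by
~4 log₂ units across life); C–F are transient activation programs whose
peaks sweep from babies to adults; G rises monotonically with age; B is
the U-shaped reversal module, active at both ends of life. Each profile
value is the mean Δe (log₂ units relative to the gene's lifetime mean)
over the spot's member genes and the group's samples.

The same workflow runs from the shell:

```bash
agesom simulate --config src/agesom/data/expression_fixture.yaml --out cohort/ --seed 1
agesom run --config run.yaml     # full pipeline, TSV outputs + run.log
```

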