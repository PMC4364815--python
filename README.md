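# popcompare

Comparative population-genetic analysis of codominant microsatellite data
for co-distributed cohorts (e.g. sympatric shorebird species sampled at
shared sites).  The package implements the full analysis chain a landscape
genetics study of this kind needs:

* **Diversity** — per-locus/per-population allelic richness *A*, rarefied
  allelic richness *A*<sub>R</sub> (expected allele count in a subsample of
  *g* genes, default *g* = 4), observed heterozygosity *H*<sub>O</sub>, and
  Nei's unbiased expected heterozygosity
  u*H*<sub>E</sub> = 2n/(2n−1)·(1 − Σ p<sub>i</sub>²).
* **Hardy–Weinberg exact tests** — Monte Carlo estimate of the exact
  (Levene conditional) p-value by a Markov chain over genotype arrays, with
  batch-mean standard errors and Holm (sequential Bonferroni) correction;
  a full-enumeration oracle is included for small tables.  Island-wide
  testing across pooled sites makes the test sensitive to Wahlund effects.
* **Differentiation** — pairwise F<sub>ST</sub> as the variance-component
  θ (genes as units, 0/1 allele mismatch) with permutation significance,
  and three-level hierarchical AMOVA (groups = watersheds):
  F<sub>CT</sub> = σ²<sub>a</sub>/σ²<sub>T</sub>,
  F<sub>SC</sub> = σ²<sub>b</sub>/(σ²<sub>b</sub>+σ²<sub>c</sub>),
  F<sub>ST</sub> = (σ²<sub>a</sub>+σ²<sub>b</sub>)/σ²<sub>T</sub>,
  each tested with its own permutation scheme.
* **Landscape distances** — Euclidean distances from UTM coordinates,
  cost-weighted dispersal distances (Dijkstra on an 8-connected cost
  lattice built from habitat-corridor rules), and Bray–Curtis climate
  dissimilarities.
* **MRMPA** — weighted multiple regression of the F<sub>ST</sub> matrix on
  distance/dissimilarity matrices (pair weight n<sub>i</sub>+n<sub>j</sub>),
  significance from AICc comparisons against matched row/column matrix
  permutations, all-subsets model comparison with Akaike weights,
  conditional model averaging with Burnham–Anderson adjusted SEs, and
  Shapiro–Wilk residual diagnostics.
* **Synthetic data** — a forward-time Wright–Fisher stepping-stone
  simulator (stepwise mutation, gametic migration) with presets for
  panmixia, strong isolation by distance, and hierarchical watershed
  structure, plus a matching toy landscape generator.  Every analysis runs
  end-to-end on simulated data; no download is required.

## Worked example

Simulate the three scenarios and run the numbered analyses (all write
tables under `results/`):

```sh
python analysis/01_simulate.py 1
python analysis/02_diversity.py 1
python analysis/03_differentiation.py 1
python analysis/04_landscape_ibd.py 1
python analysis/05_compare_cohorts.py 1
```

With seed 1 this prints, among other lines:

```
panmixia: mean A=3.40 A_R=2.13 H_O=0.54 uH_E=0.54; 0/10 loci deviate from HWE after Holm correction
strong_IBD: mean A=3.00 A_R=1.88 H_O=0.42 uH_E=0.43; 9/10 loci deviate from HWE after Holm correction
panmixia: pairwise theta in [-0.014, -0.002]
strong_IBD: pairwise theta in [0.118, 0.613]
  AMOVA: F_CT=0.384 (p=0.009), F_SC=0.032, F_ST=0.404; 38.4% of variance among watersheds
panmixia: Euclidean IBD p=0.472; ...
strong_IBD: Euclidean IBD p=0.001; ...
```

Read: the panmictic cohort shows no island-wide heterozygote deficit, θ
indistinguishable from 0, and no isolation by distance; the structured
cohorts show the Wahlund effect (island-wide HWE deviations), θ rising
with distance (significant weighted matrix regression, p = 0.001), and —
for the watershed scenario only — a significant among-group AMOVA
component.

The same machinery is scriptable via the `popcompare` CLI
(`popcompare simulate|diversity|differentiation|landscape|mrmpa|run`);
`popcompare run --config run.yaml` executes the whole pipeline from a
declarative config with one seed controlling every stage.

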