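# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the simulator does and does not emulate, and the
numerical conventions.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Genotype model and conventions

Data are codominant diploid genotypes at a shared panel of microsatellite
loci.  Allele identity is the integer code as read (fragment length or
repeat count); no binning or recoding is applied.  Missingness is per
locus per individual and only as a whole pair — half-missing calls are a
parse error — and individuals are never dropped globally: every per-locus
statistic excludes untyped individuals locus-wise.  Coordinates are planar
meters in a single UTM zone; no geodesic correction is made, which is
adequate for study areas spanning one zone.  Population order follows the
site-metadata file everywhere, and all matrices carry explicit labels.

## Diversity statistics

* **A** — distinct alleles observed.  Per-population table values are the
  across-locus mean; cohort rows are mean ± SE across populations.
* **A_R** — single-level rarefaction: for allele gene counts N_i out of N
  total genes, the expected distinct-allele count in a random g-gene
  subsample is Σ_i [1 − C(N−N_i, g)/C(N, g)].  The default g = 4 genes
  standardizes to the smallest sample a site survey of this kind tends to
  produce (two individuals).  A population with fewer than g typed genes
  at a locus is skipped for that locus and the skip is counted in the
  report — never zero-filled.  Hierarchical (private-allele) rarefaction
  is out of scope.
* **H_O** — fraction of typed individuals whose two alleles differ.
* **uH_E** — Nei's unbiased gene diversity (2n/(2n−1))(1 − Σ p_i²),
  preferred over the plug-in estimator because per-site sample sizes are
  small and variable.

Undefined statistics propagate as explicit `NaN` markers into all reports.

## Hardy–Weinberg exact test

The null is the Levene conditional distribution of genotype arrays given
allele counts, P(array) ∝ 2^H / Π n_ij! (H heterozygotes, n_ij cell
counts).  The sampler is a random-transposition walk on the 2n gene slots:
each step swaps the contents of two uniformly chosen slots, i.e. switches
two genotypes' allele pairing while preserving allele counts exactly.
Uniform transpositions leave the uniform distribution over gene
arrangements invariant, and the array distribution induced by a uniform
arrangement *is* the Levene null, so the chain needs no accept/reject
correction.  The p-value is the fraction of sampled arrays whose
conditional probability is ≤ the observed array's (ties included, compared
in log space with absolute tolerance 1e−7; the incrementally tracked
log-weight is recomputed from scratch at every batch boundary to stop
float drift).  The Monte Carlo SE is the standard error of the batch
means.

Default schedule: 10,000 dememorization steps, 1,000 batches of 10,000
iterations — a deliberately heavy conventional schedule; the analysis
scripts use a lighter one (2,000 / 50 / 400) because the island-wide
tables here mix in far fewer steps.  Tables that are monomorphic or have
fewer than 3 individuals are "not testable" and counted as conforming.
`hwe_exact_enumeration` enumerates all arrays for small tables and is the
oracle the chain is validated against.

Multiple testing uses Holm's step-down procedure at α = 0.05.

## Differentiation

Genes are the units and the inter-gene distance is the 0/1 allele
mismatch, so sums of squares are computed from per-population allele
counts (SSD(unit) = (n − Σ_a c_a²/n)/2).  Variance components follow the
standard moment equations with unequal-sample-size coefficients; pairwise
F_ST is the two-level case of the same decomposition (a variance-component
θ), which is what the field's standard software computes under the label
"Wright's F-statistic".  The within-individual (F_IS) level is not
modelled.  Per-locus components are summed over loci before ratios are
formed; negative estimates are reported as computed, never truncated.

Reported AMOVA df are the complete-data partition (G−1, P−G, 2N−P), which
sums to 2N−1; with missing data the SS and components still use per-locus
typed-gene counts, so SS/df at a level is not exactly the mean square in
that case.  F_SC degenerates to 0 (not NaN) when no variance exists below
the group level.

Permutation schemes: pairwise F_ST shuffles individuals between the two
populations (default 100 permutations); AMOVA F_CT permutes whole
populations among groups, F_SC individuals among populations within
groups, F_ST individuals among all populations (default 10,000).  All
p-values use the (b+1)/(B+1) estimator so p = 0 is impossible.
Single-population groups are retained but contribute no permutable
structure to F_SC.

## Landscape distances

The cost raster assigns cost 1 to cells within a buffer of any suitable
feature (coastline, rivers) and a finite penalty (default 100×) elsewhere;
a finite penalty keeps all pairs connected, matching analyses that report
finite distances everywhere, while `inf` turns unsuitable habitat into a
hard barrier (unreachable pairs become NaN with a warning).  Rasterization
requires resolution ≤ half the smallest buffer so corridors cannot be
lost.  Feature vertices are sorted lexicographically before building the
geometry, making the raster independent of the file's listing order (the
intended features — a coastline, a river — are monotone polylines for
which sorting reconstructs the path).

Cost distance is Dijkstra on the 8-connected lattice with edge weight
resolution × (c_i + c_j)/2, × √2 on diagonals — the standard cost-distance
convention; on a unit raster it reduces to path length in meters, with at
most ~8.2% overshoot relative to straight-line distance (the 8-connectivity
bound).  Bit-exact parity with any particular GIS implementation is not
claimed.  Sites snap to the nearest cell center with ties broken toward
the lower index.  The raster resolution, penalty magnitude and
barrier-vs-penalty choice are all configuration, since habitat analyses
rarely publish them.

Bray–Curtis dissimilarity of site-level climate scalars is |x−y|/(x+y)
(0 when both are zero), requiring non-negative inputs.  Climate values are
site-level scalars supplied in the metadata; extraction from interpolated
climate surfaces is out of scope and is emulated by the simulator's
spatial gradients.

## MRMPA

Matrices are unrolled in the fixed lower-triangle order (0,1), (0,2), …
Pairs with any NA are dropped listwise and counted.  The pair weight is
n_i + n_j ("total samples behind the comparison"); min(n_i, n_j) is
available as an alternative rule.  Weights are normalized to mean 1 before
fitting so AICc is invariant to weight rescaling.  Fits are weighted least
squares with an intercept (statsmodels WLS for reported SEs; an equivalent
fast path is used inside permutation loops and is tested against it).

AICc = n ln(RSS_w/n) + 2k + 2k(k+1)/(n−k−1), with k counting intercept,
slopes and the error variance.  Candidate models with n ≤ k+1 (the
correction-term pole) or RSS = 0 (saturated) are dropped from the set with
a warning.

Significance: one designated predictor matrix has rows and columns
permuted by the same population permutation — permuted configurations thus
remain valid matrices — the model is refitted, and p is the proportion of
permuted fits with smaller AICc, with the +1 correction by default (the
raw proportion is available via a flag, since published analyses that
report p exactly at the α boundary evidently used it).  Exhaustive
enumeration of all k! label permutations is used for ≤ 8 populations and
counts ties with the observed AICc as non-exceedances, so p ≥ 1/k!.

The model set is all 2^p − 1 non-empty predictor subsets plus the
intercept-only model; per-predictor "total AICc weight" is the sum of
Akaike weights of models containing it.  Averaged betas are *conditional*
(over containing models), chosen because reporting non-zero averaged
coefficients next to small total weights only makes sense under
conditional averaging; zero-filled full-set averaging is exposed as a
flag.  Adjusted SEs use the Burnham–Anderson formula
Σ w'_m √(se_m² + (β_m − β̄)²).  The per-predictor permutation p in the
report permutes that predictor under the full model, each member tested in
turn; a multi-predictor model's own p is conservatively the largest of its
members' p-values.  Residuals of the AICc-best model are checked with
Shapiro–Wilk on √w-weighted residuals.

## Synthetic data

Forward-time Wright–Fisher metapopulation, chosen over coalescent
machinery for transparency and exact stepwise-mutation semantics: demes of
constant diploid size in a chain, grid or island layout; each offspring
draws two parents (each parent from a specific neighbour with probability
m per neighbour — gametic migration, which fixes the m ↔ F_ST mapping),
inherits one allele per parent per locus (free recombination), and each
transmitted allele mutates ±1 repeat with probability μ, reflecting at
repeat count 1 so values stay positive.  Burn-in defaults to 10N
generations.  Sampling is without replacement per deme, with independent
per-genotype dropout.  Founders carry `founder_alleles` equally spaced
repeat values: 1 by default (so μ = 0 provably yields a monomorphic
dataset), while the presets use 8 to provide realistic standing variation
within a short burn-in — emulating populations at mutation–drift
equilibrium without simulating the full approach to it.

Presets (the study conditions for all calibration and power checks):

* `panmixia` — one deme of 160, 200 generations, sampled into 4
  pseudo-populations of 20; μ = 5e−4, 10 loci.
* `strong_IBD` — 8 demes in a chain, nearest-neighbour m = 0.01, deme size
  50 (burn-in 500), μ = 5e−4, 10 loci, 20 sampled per deme.
* `hierarchical_watersheds` — the same chain in 4 groups of 2 with
  within-group m = 0.05 and between-group migration reduced tenfold.

The landscape generator places demes 50 km apart a few kilometers inland
of a north–south coastline (so the 10-km coastal buffer forms a connected
corridor), and draws climate scalars from linear spatial gradients plus
Gaussian noise (precipitation 400 + 40/step ± 15 mm; isothermality
55 − 1.5/step ± 0.8), so climate dissimilarity correlates with distance as
the landscape models assume.

What the simulator does **not** emulate: selection, linkage,
varying deme sizes, genotyping artefacts beyond random dropout (no allelic
dropout bias, no null alleles), and real geography (a straight coastline,
no rivers by default).  Passing calibration and power checks therefore
demonstrates the statistics are correct and well calibrated under the
stated model — not that any particular empirical dataset meets that model.

The finite-island expectation F_ST ≈ 1/(1 + 4N(m+μ)(d/(d−1))²) serves
only as a coarse oracle band (±50%) for the simulator, since drift
variance at these sizes is large.

## Problem sizes used by the test suite and acceptance script

Chosen once as a balance of statistical resolution and desk-scale runtime:

* HWE chain validation: schedule 3,000 / 60 / 500 against full enumeration
  on 2-allele tables to n = 50 and 3-allele tables at n = 12; null
  calibration with 500 simulated arrays at n = 30, 3 alleles.
* Null calibration of permutation tests: 200 replicates × 199 permutations
  of a panmictic deme (size 120, 5 loci, 120 generations) sampled into 8
  pseudo-populations — 8 rather than 4 so the group-permutation space of
  the F_CT test is rich enough (105 distinct partitions) for its p-values
  to approximate the uniform distribution a Kolmogorov–Smirnov check can
  assess.
* Power checks: 50 seeds per preset, 199 permutations per test.
* `scripts/acceptance.py`: 999 permutations for single-predictor and AMOVA
  tests, 499 for the 3-predictor model set, HWE calibration over 20
  panmictic cohorts with a light chain (500 / 20 / 100).

## Known limitations

* The AMOVA df convention under missing data (above) is a documented
  approximation; per-locus df bookkeeping would complicate the report for
  little gain at these missingness levels.
* The Guo–Thompson-style chain mixes slowly for tables with many rare
  alleles at large n; the batch-mean SE is reported precisely so users can
  judge chain error, and the enumeration oracle covers small tables.
* Least-cost distances inherit lattice discretization error (≤ ~8.2% on
  uniform cost surfaces) and depend on the configured resolution/penalty.
* MRMPA permutation p-values for highly collinear predictors (e.g. a
  climate gradient that is itself linear in distance) test conditional
  signal and can be large even when the marginal association is strong;
  this is a property of the method, not a defect.
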