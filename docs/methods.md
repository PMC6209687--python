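# Methods

`glacialdemog` implements a multilocus pipeline for inferring the
Quaternary demographic history of a temperate forest tree from a small
number of sequenced loci, and for testing how its genetic variation
relates to geography and ecology. The design target is a study of
21 populations x 5 diploid individuals of a temperate oak, sequenced at
two phased single-copy nuclear genes (336 and 434 bp after removing
recombinant segments; 210 gene copies each) and a concatenation of four
plastid regions (1814 bp; 105 copies, maternally inherited).

## Sequence statistics

For a locus with `n` gene copies and `L` aligned sites the package
reports segregating sites `S`, distinct haplotypes `Nh`, haplotype
diversity `Hd = n(1 - Σ p_i²)/(n-1)`, per-site nucleotide diversity
`π` (mean pairwise difference count / L), the per-site Watterson
estimator `θ_W = S/(a_{n-1} L)` with `a_{n-1} = Σ_{i<n} 1/i`, and
Tajima's D with the standard `e1/e2` normalisation. Tajima's D is
undefined (NA) at `S = 0` in the human-facing statistics stage; the ABC
stage instead maps every statistic of a monomorphic locus to 0 so that
all mass-simulated rows are usable. This divergence is deliberate.

Missing bases (`N`) are excluded pairwise-complete from difference and
segregating-site counts, and sequences that differ only at `N` positions
collapse into one haplotype (conservative call). Alignment gaps are a
fifth informative character state by default; the ABC stage discards
gap-containing columns instead, matching the different tolerance of
mass simulation to indels.

The MFDM neutrality test uses the maximum count `e` of derived alleles
over polarizable segregating sites and reports `p = min(1, 2(n-e)/(n-1))`
— the tail probability of so unbalanced a basal split under neutrality.
Polarization comes from a user-supplied ancestral sequence; the
synthetic generator emits the true ancestral sequences so the test is
exercisable end to end. Sites whose ancestral state is missing, or
absent from the sample, are skipped.

The minimum number of recombination events `Rm` follows Hudson-Kaplan:
all biallelic site pairs exhibiting four gametes define incompatibility
intervals, which are reduced greedily (sort by right endpoint, keep the
first non-overlapping interval each time; endpoint sharing allowed,
since a crossover falls strictly between sites). Note that under a
finite-site mutation model homoplasy can create four-gamete patterns
without recombination, so `Rm > 0` on simulated non-recombining data is
possible at high per-site mutation rates; the infinite-sites guarantee
`Rm = 0` is recovered when `μL`-per-site is small.

## AMOVA

Molecular variance is decomposed Excoffier-style from squared pairwise
distances (distance = count of differing sites, the convention used by
Arlequin for sequence data). One-level: among/within populations with
`Φ_ST`; two-level: among groups / among populations within groups /
within populations with `Φ_CT`, `Φ_SC`, `Φ_ST`. Significance is by
permutation — sequences among populations for `Φ_ST`, sequences among
populations within groups for `Φ_SC`, whole populations among groups
for `Φ_CT` — with the observed configuration counted, so
`p ≥ 1/(permutations+1)`; 1000 permutations by default. Negative
variance components are reported as computed; the percentage
decomposition floors negatives at zero before normalising (both views
are available). A dataset with zero molecular variance yields
`Φ = NA` rather than 0/0. Pairwise `F_ST` matrices are two-population
one-level AMOVAs per pair; negative estimates are retained.

## Coalescent simulation

Seven demographic scenarios are parameterized as ordered anchors
(backward time in generations, diploid size) with exponential
interpolation between anchors and constant size beyond the last:
constant size (S1); exponential decline (S2: `Na > Ne`) or growth (S3:
`Na < Ne`) from `Ta` to the present; expansion to `Ndb` followed by
decline to `Ne` with the turning point `Tdb` in a pre-glacial
(S4: 250-1500 generations, i.e. 20-120 ka at 80 y/generation) or
post-glacial (S5: 75-275 generations, 6-22 ka) window; and the mirrored
decline-then-recovery shapes (S6, S7: `Ndb < min(Ne, Na)`). Priors are
uniform: `Ne, Na, Ndb ∈ [10³, 10⁵]` (diploid), `Ta ∈ [1.25, 3.75]x10⁴`
generations (1-3 Ma at 80 y/generation), `μ_cp ∈ [5, 7]x10⁻⁸` and
`μ_nr ∈ [1, 3]x10⁻⁷` per site per generation, with scenario ordering
constraints enforced by rejection; `Ne` is deliberately unconstrained
against `Na`. The post-glacial `Tdb` window spans mid-Holocene to LGM
response times; it is a package choice (flagged in the configuration)
since only the pre-glacial window is externally fixed.

Genealogies are drawn by the standard n-coalescent with time-varying
size: with `k` lineages the pair-coalescence rate is
`k(k-1)/2 / Nc(t)`, where `Nc(t) = 2 N(t) m` is the effective
chromosome count and `m` the locus's inheritance multiplier (1 for
nuclear diploid loci, 0.5 for the maternally inherited plastid genome
of a monoecious tree — a package default, configurable). Waiting times
invert the integrated rate in closed form within each exponential
epoch. The sampler is validated against msprime (KS tests on TMRCA
distributions under three-epoch exponential demographies) and against
analytic pair-coalescence expectations; it exists because mass
simulation for ABC needs ~10⁵-10⁶ independent single-population
genealogies per run, and a special-purpose sampler is an order of
magnitude faster than general machinery at that call granularity.

Mutations follow HKY (default `κ = 2`, equal base frequencies, both
configurable per locus group) applied by uniformization: mutation
events are dropped on branches at the maximal per-state rate and
resolved through a jump matrix with compensating self-transitions, so
the realized mean substitution rate at stationarity is exactly `μ`.
Checked against the JC69 closed form, stationary base composition, and
direct substitution counts. One shared rate per locus group per
simulation; no within-locus recombination; no migration or internal
structure in the scenario simulations (structure generation lives only
in the synthetic-data module, keeping the inference engine's
no-structure assumption explicit).

## Approximate Bayesian computation

Five summary statistics per locus group (plastid, nuclear), averaged
across the group's loci and concatenated plastid-first into a fixed
10-vector: the unbiased sample variance of pairwise difference counts
(VPD), Tajima's D, the number of private segregating sites (PSS,
interpreted for a single-deme sample as singleton segregating sites —
rarest-nucleotide count exactly 1), and the mean (MNS) and sample
variance (VNS) of the rarest-nucleotide count over segregating sites.

The reference table allocates simulations equally across scenarios and
stores per-column means and SDs; distances are Euclidean on
SD-standardized statistics (MAD was considered and rejected: SD
standardization is the common ABC default and is stable at ≥10⁴ rows).
Scenario choice accepts the `⌈tolerance·N⌉` closest rows (tolerance
0.01 by default, acceptance-set size exact by construction). The
*direct* estimate is the scenario frequency among accepted rows with
normal-approximation binomial 95% CIs; the *logistic* estimate fits a
multinomial logit of scenario on (statistics − observation) over the
accepted rows and evaluates it at the origin, with CIs from the
asymptotic covariance (observed Fisher information; a mild L2 ridge
keeps the fit finite under perfect separation, and a single-scenario
acceptance set short-circuits to a point mass).

Parameter estimation is rejection within the chosen scenario followed
by local-linear regression adjustment with Epanechnikov weights in
distance; sizes and times are adjusted on the log scale and
back-transformed, mutation rates on the raw scale. The posterior mode
is the peak of a Gaussian kernel density (Silverman bandwidth) over the
adjusted draws. A singular regression design falls back to
rejection-only with a warning.

Calibration uses pseudo-observed datasets (PODs) drawn from each
scenario's *prior* (the posterior-conditioned alternative is not
implemented): type I error is the fraction of focal-scenario PODs in
which the focal scenario does not achieve the highest posterior
probability; type II is the mean over competing scenarios of the
fraction of their PODs the focal scenario wins. RMAE is the median over
PODs of `|estimate − truth|/truth` for the posterior-median estimator.
The goodness-of-fit check simulates PODs from posterior draws, reports
per-statistic two-sided tail probabilities with the `(1+x)/(1+n)`
convention, and emits PCA projections (fitted on the standardized
reference table) of PODs and observation for plotting.

A caveat the calibration itself exposes: under these wide uniform
priors the seven scenarios overlap heavily in the 10-statistic space —
a prior draw of S4 with `Ne ≈ Na` is nearly indistinguishable from S1
or S3, and S4 differs from S5 only through the `Tdb` window. Prior-POD
type I error for S4 is therefore large (~0.8 at desk scale), and a
gradient-boosted classifier trained on the labeled reference table does
no better, showing the limit is in the problem geometry, not the
rejection machinery. Type II error, by contrast, is small (~0.06-0.08):
competing-scenario PODs rarely masquerade as S4.

## Landscape associations

Geographic distances are great circles on a spherical Earth
(R = 6371.0 km). Ecological distance is "scaled Euclidean": each
variable z-standardized across populations (sample SD; range-scaling
available by flag) before the Euclidean norm — zero-variance variables
are dropped with a warning. The Mantel statistic is the Pearson
correlation over strictly-upper-triangle entries; permutations relabel
rows and columns of the second matrix simultaneously, and p-values are
two-tailed with the observed configuration counted (999 permutations by
default). The partial Mantel statistic is the first-order partial
correlation `r_AB·C`, permuting A and recomputing; exact collinearity
of the control (`|r| = 1`) is a degenerate-control error since the
statistic is then 0/0, and a constant control matrix reduces to the
simple Mantel test by convention.

Stepwise regression starts from the full candidate model and greedily
adds/drops single predictors by AIC (`n ln(RSS/n) + 2k` for the
Gaussian linear model; the Huber robust fit — IRLS with MAD scale —
uses the analogous criterion on its converged weighted RSS, a standard
pragmatic analog since RLM has no true likelihood). Aliased columns
(design condition number > 10⁸) are dropped with a warning before
search; per-predictor univariate fits are emitted alongside the winning
model. Note the selection operates at AIC's native strictness: a pure-
noise predictor survives with probability ≈ P(χ²₁ > 2) ≈ 0.16, so with
several candidate decoys the intercept-only model is the modal but not
the overwhelming outcome — a property of stepAIC itself, verified in
the test suite.

## Synthetic studies

The generator emulates the full study design: scenario-driven
genealogies (default an expansion-then-decline history with
`Ne = 1.2x10⁴`, `Ndb = 3.5x10⁴`, `Na = 10⁴`, `Ta = 2.5x10⁴`,
`Tdb = 900` generations, `μ_nr = 1.7x10⁻⁷`, `μ_cp = 6x10⁻⁸` — moderate
sizes chosen so per-site nuclear diversity lands in the 0.001-0.02
range typical of low-polymorphism nuclear genes in temperate oaks), a
21x5 sampling layout, the three-locus design with 5 presence/absence
indel columns overwritten in the plastid alignment, and optionally a
two-cluster split: two demes of constant size `Ne` exchanging no
migrants that merge at a configurable split time (default 3600
generations, ≈ 290 ka) into an ancestor following the global scenario.
An optional plastid-fixation mode samples one maternal lineage per
population and fixes it, reproducing the one-haplotype-per-population
pattern that forces chloroplast `F_ST = 1`; it is off by default so ABC
statistics remain well-behaved.

Populations sit on a jittered grid spanning ~10° x 8°, assigned to grid
cells at random so geography is independent of cluster membership
unless made otherwise. Eight ecological covariates (five bioclimatic,
three soil) are generated with *orthogonalized* noise — a QR
decomposition makes the idiosyncratic components exactly uncorrelated
across variables — plus a shared spatial gradient scaled by
`ibd_strength` (inducing ecology-geography correlation) and a
cluster-linked shift scaled by `ibe_strength`: temperature seasonality
(BIO4) rises by `3 sd x ibe_strength` in cluster 2 and precipitation
seasonality (BIO15) doubles its spread at full strength, the direction
of niche contrast the generator is meant to emulate. The 3-sd
proportionality constant is set so that full-strength ecological
structure is detectable through the z-scaled 8-variable Euclidean
distance in a Mantel test against nuclear `F_ST` — a 1.5-sd shift on
one of eight variables washes out after rescaling.

What the generator does *not* emulate: real WorldClim covariate
distributions or their mutual correlations, within-cluster isolation by
distance in the genetic data (demes are panmictic), sequencing or
phasing error, gene flow after the cluster split, and selection.
Passing pipeline tests on synthetic data therefore demonstrates the
statistical machinery, not robustness to those real-data features.

## Problem sizes and numerical conventions

Mass-simulation stages default to desk scale: 10⁵-row reference tables
(equal allocation across S1-S7), 1% tolerance, 50-200 PODs per scenario
for calibration, 1000 AMOVA and 999 Mantel permutations. The
full-study-scale 7x10⁶-row table is configuration-reachable but not a
default. When a reference table is very small (~10³ rows) the
acceptance tolerance should be widened (we use 0.1 instead of 0.01) so
the local-linear adjustment retains at least ~100 accepted draws —
fewer accepted rows than regression covariates degenerates the
adjustment. The acceptance script (`scripts/acceptance.py`) rebuilds the
10⁵-row table and the S4 calibration from scratch under a caller-
supplied seed. Seeds flow through `numpy.random.Generator` everywhere;
reference-table builds spawn one child generator per scenario so
allocations are reproducible independently of scenario order. Ties in
scenario choice resolve to the first scenario in table order (argmax);
KDE modes are evaluated on a 512-point grid over the draw range.
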