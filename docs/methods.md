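# Methods

## Model and procedure

The analysis asks whether the connectivity signature of a common NMDAR
(*GRIN2A*) risk variant resembles the signature of pharmacological NMDAR
blockade, and whether the resemblance is concentrated where the cellular
substrate of the hypothesised mechanism — NMDARs on parvalbumin
interneurons disinhibiting glutamatergic cells (E/I imbalance) — is most
expressed.

**First level.** Connectivity between two regions is the Pearson
correlation of their time series, Fisher-z-transformed
(`z = atanh(clip(r, ±(1−1e−7)))`; the clip keeps degenerate synthetic
inputs finite). No additional denoising is applied: the package consumes
post-preprocessing ROI time series.

**Second level.** Per edge, an OLS GLM with predictors
`[1, allele_count, gender, dose]` yields the genetic effect matrix **B**
(the allele-dose coefficient; a dominant 0/{1,2} recode is available for
exploratory use). Drug effects are paired contrasts of within-condition
session differences, tested with paired t-tests (df = n−1). t-statistics
use residual df = n − rank(X); an "one-sample t-test on the coefficients"
formulation is equivalent under OLS and is implemented as the standard GLM
t. p-values are two-sided by default, one-sided in verification mode, and
floored at the smallest positive double so exact fits stay representable.

**Expression ranking.** Microarray-like samples are assigned to the region
containing their coordinate (nearest labelled voxel within 2 mm — the
common imaging-transcriptomics tolerance — when they fall in background).
Aggregation is donor-first: z-score each gene within donor, average samples
within region per donor, average regions across donors, z-score across
regions (population sd). This order prevents donors with more samples, or
donor-specific intensity scales, from dominating; ranking is provably
invariant to affine rescaling of any one donor's intensities. The combined
score is the mean z over the marker genes (default GRIN1/PV/SLC17A7, the
GRIN2A swap is a parameter); ties break by region order; regions without
samples are flagged and ranked last. Probe-to-gene aggregation is assumed
done upstream (one column per gene).

**Curve and AUC.** Regions are sorted by rank; at each step the
lowest-expressing region is dropped and the lower triangles of both effect
matrices over the remaining regions are Pearson-correlated, down to 3
regions. AUC is the unit-spacing sum of the r values (a trapezoid rule is
available; it differs only at the endpoints). A constant edge vector at
some size records r = 0 with a warning rather than failing. Inference:
genotype labels are permuted across patients — gender and dose stay with
their subjects, matching a null of genotype exchangeability — and the GLM,
curve and AUC are recomputed per permutation. p uses the add-one estimator
(1 + #extreme)/(1 + n_perm), which cannot return zero, with directions
fixed a priori (greater for ketamine-like contrasts, less for midazolam >
placebo) and BH correction across the three contrasts. The permutation
engine exploits the row-major lower-triangle layout (edges of the top-k
regions are a prefix of the ranked edge vector) to compute all curve sizes
from cumulative sums, in chunks bounded to ~64 MB.

**Network level.** The set-level response of a subject is the mean
Fisher-z over all edges spanning a network pair (within-network for a pair
with itself); the same GLM or paired t-test is applied to that scalar.
Because OLS is linear in the response, the set-level effect equals the mean
of per-edge effects — a transparent, calibrated substitute for toolbox-
specific omnibus statistics whose exact form is not published. Edges with
uncorrected p < 0.05 are listed post hoc. Data-driven networks come from
average-linkage hierarchical clustering with distance 1 − corr between
regions' connectivity profiles (both self-columns masked), cut at k
(default 10); within- plus between-network tests (k(k+1)/2, singleton
within-tests skipped as edgeless) enter BH. Seed profiles are per-target
GLMs with BH over the 105 targets, replacing voxelwise cluster inference,
which is out of scope.

**Symptoms.** Domain sums of −1/0/+1 items enter a multivariate GLM; Wilks
Λ = det(E)/det(E+H) for the single-df allele hypothesis with covariates,
converted exactly (Rao, single-df case) via F = ((1−Λ)/Λ)·((v_e−p+1)/p) on
(p, v_e−p+1) df. Degrees of freedom are computed from first principles
(v_e = n − rank(X)); published clinical dfs are internally inconsistent by
±1–2, so exact df matching is not attempted. Post-hoc partial correlations
residualize both variables on [1, covariates] (df = n − c − 2).

## Synthetic-data generator

The generator emulates the statistical structure of the three datasets the
analysis assumes; defaults are the emulated study conditions: 146 patients,
142 controls, 28 all-male crossover subjects (6 sessions each), C-allele
frequency 27.7% sampled i.i.d. from HWE, 106 regions, 200 timepoints.
Values the emulated study does not report are fixed placeholders documented
here: gender ~ Bernoulli(0.5); dose ~ Gamma(2, 3) truncated at 30 mg/day
with a 10% never-medicated fraction (nuisance structure only); 6 donors
with ~3 samples per region each and donor-specific lognormal intensity
scales over an evenly spaced latent regional expression gradient.

Time series are zero-mean multivariate normal draws whose correlation
matrix is the identity plus planted perturbations, projected to the nearest
valid correlation matrix (eigenvalue clip at 1e−6, diagonal renormalized) —
for small deltas the projection is the identity and planted effects stay
linear in allele count. Planted structure has three parts:

* a **shared signal block** over the configured signal regions: per-allele
  increment `delta_allele` (default 0.15) for patients and
  `delta_ket`/`delta_mdz` (±0.20) for post-infusion sessions, all
  multiplied by one common heterogeneous edge-weight pattern
  (U(0.5, 1.5), drawn once per seed). The shared pattern is what makes the
  genetic and drug effect matrices agree edge-by-edge inside the block;
* optional **idiosyncratic backgrounds** off the block (independent
  between the genetic and each drug effect; default sd 0 — the studies
  that need full-matrix dilution use 0.03), emulating the unrelated
  whole-brain effects that keep real full-matrix correlations moderate;
* optional uniform **set effects** (e.g. +0.2 per allele on all
  SPT×ASM edges) for the network analyses.

Symptom sums follow `a − b·allele + c·edge + noise` for the
qualitative-language subcategory (b = 0.8, c = 2.0, noise sd 1), rounded
and clipped to ±7 (7 items per subcategory); all other domain/subcategory
sums are genotype-independent noise. Crossover order effects are not
simulated (pre/post differencing cancels session-constant offsets).

What the generator does **not** model: hemodynamic autocorrelation or
scanner drift (white noise suffices to exercise the statistics),
non-Gaussian BOLD artefacts, realistic anatomical geometry of the block
atlas, population structure beyond HWE, or item-level symptom psychometrics.
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under the assumed model, not robustness to real-data
violations of it.

## Validation studies and problem sizes

`connsig.validation` contains the simulation studies run by the acceptance
suite and `scripts/acceptance.py`. Sizes were chosen once so that a full
pass completes in minutes on one CPU while keeping the Monte-Carlo error of
each fraction small:

* permutation calibration: 200 null datasets, 80 patients, 30 regions,
  100 timepoints, 200 permutations — type-I rate at α = 0.05 and KS
  uniformity of p;
* enrichment: 100 seeds at full 106-region scale, signal in the top-20
  ranked regions, backgrounds 0.03, 200 permutations — fraction of seeds
  with rising curves (last vs first 30 points) and AUC rejections;
* recovery: 50 seeds, 30 regions, 500 timepoints — allele-coefficient bias
  (the atanh nonlinearity contributes ≈2% at these effect sizes) and
  ket-vs-mdz sign recovery;
* networks/symptoms: 50 seeds at 106 regions, 500 timepoints, planted
  +0.2/allele SPT↔ASM and −0.15/allele STG↔TO set effects; null
  calibrations with 200 runs each.

## Numerical choices and limitations

Fisher-z clip 1e−7; p-value floor `np.finfo(float).tiny`; BH via
statsmodels; Levene's test in its mean-centred variant via scipy;
correlation-matrix eigenvalue floor 1e−6; rank ties broken by region order;
curve degenerate sizes recorded, not fatal; pipeline reports are
timestamp-free JSON with SHA-256 manifests so identical configs reproduce
byte-identical bundles. Known limitations: the set-level statistic is the
edge-mean scalar, not an omnibus multivariate F, so printed F statistics of
toolbox FNC analyses are not comparable; no analytic null for the AUC is
offered (permutation only); voxel-level inference is out of scope; and the
106-region label table is a synthetic emulation of the Conn/Harvard-Oxford
parcellation (48 cortical structures and 5 subcortical structures per
hemisphere) that preserves the region count and the names used in the
network definitions.
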