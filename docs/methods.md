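# Methods

`difms` re-implements, as a tested and reusable pipeline, the analysis of a
direct-infusion FT-ICR mass-spectrometry metabolomics experiment on marine
copepods (*Calanus* spp.) held without food under factorial warming and
CO2-enrichment treatments, together with the carbonate-chemistry
characterization of the experimental seawater. Every stage runs against a
synthetic-data generator with known ground truth, so the whole pipeline is
testable without any external download.

## Experimental structure being emulated

Six treatment groups: pre-experimental animals (t0) acclimated at 8 °C or
10 °C, and post-experimental animals (t5) after five food-free days at
2 temperatures × 2 pCO2 levels (ambient ≈380 μatm, or 1000 μatm), with 10
biological replicates per group (60 biological samples), plus pooled QC
samples. Each sample yields a polar and a nonpolar extract; each extract is
measured in positive mode in three technical replicates, as overlapping SIM
windows — seven wide windows tiling m/z 70–590 for the polar extract, and
windows ramping from 100 Da to ~190 Da width tiling m/z 120–1200 for the
nonpolar extract.

## Synthetic-data generator

The generator (`difms.synthetic_data`) draws, per metabolite and adduct
ion:

* m/z = theoretical adduct m/z × (1 + ε), ε ~ Normal(0, ppm_error_sd·1e-6);
  default ppm_error_sd = 0.5 ppm, the mass-accuracy scale of an FT-ICR
  instrument at ~1e5 resolving power.
* intensity = group mean × sample dilution × measurement noise. The
  dilution factor is log-normal with median 1 (default log-SD 0.3), so PQN
  recovery is identifiable; measurement noise is unit-mean log-normal with
  CV 0.2, a figure standing in for combined technical and residual
  biological variation in a pooled-animal extract.
* isotopologues at natural-abundance intensity ratios from a single shared
  isotope table: the 13C M+1 peak at +1.00336 Da scaled by
  nC·(0.0107/0.9893), and for Li+ adducts a 6Li partner at −1.00088 Da at
  0.0759/0.9241 ≈ 8.2% of the parent.
* hard dropout: any generated peak below an intensity threshold (default
  2000, against library base intensities of 5e4–8e5) is omitted. The real
  missingness mechanism of the instrument is not described anywhere we can
  cite; a hard threshold is the simplest mechanism that produces the
  intensity-dependent missingness KNN imputation assumes, and it is flagged
  here as a stand-in rather than a validated model.

The default effect model encodes the study's outcome: a time-point
(starvation) effect on a named subset of metabolites — amino acids and
derivatives mostly falling, aspartate/methionine/tryptophan and
trimethyllysine rising, EPA- and DHA-containing species falling, 20:1/22:1
species rising — with |log2 FC| drawn once per metabolite from
Uniform(0.5, 2), and exactly null temperature and CO2 effects. QC samples
are generated from the pooled mean of all biological samples.

A feature-level shortcut (`simulate_intensity_matrix`) generates an
already-aligned matrix (default 500 anonymous features, 20% affected,
baselines log-uniform over 10^3.5–10^6) for statistical-power and
calibration studies where the peak-list machinery is irrelevant.

What the generator does **not** emulate: FT-ICR transients, peak shape,
resolution or space-charge effects; correlated metabolite panels
(features are independent given the design); drift over an injection
sequence; electrospray matrix effects. Passing tests therefore demonstrate
correctness of the pipeline's algorithms under the stated statistical
model, not instrument-level fidelity.

## SIM stitching

Window merging trims `edge_trim` (default 2.5 Da) from each window end,
splits residual overlaps at their midpoint (lower window keeps m/z strictly
below the boundary) and merges same-peak duplicates straddling a junction
within the replicate tolerance. Technical-replicate filtering pools the
stitched replicates, clusters peaks within `replicate_ppm` (default
1.5 ppm) and keeps peaks present in ≥ `min_reps` (default 2 of 3)
replicates — the standard replicate filter of SIM-stitching workflows; the
retained m/z is the intensity-weighted mean and the intensity the mean over
replicates in which the peak occurs. Cross-sample alignment is
single-linkage clustering on the pooled sorted m/z values with a
consecutive-gap threshold of `align_ppm` (default 1.5 ppm, the widest
annotation tolerance used downstream); each sample contributes at most one
peak per feature (nearest to the cluster mean, ties to the lower m/z), and
features present in fewer than `min_sample_frac` (default 0.5) of the
samples of every treatment group are dropped. Absent cells are missing
(NA), never zero, through every serialization.

## Preprocessing

Order of operations: PQN on raw intensities → KNN imputation → glog. The
reference spectrum for PQN is the feature-wise median over biological
samples (QCs excluded); each sample's dilution factor is the median
quotient against the reference over mutually observed cells. KNN imputation
(k = 5) fills each missing cell with the mean of the k nearest samples that
observed the feature, nearness being plain Euclidean distance over mutually
observed features. The generalized logarithm g(x) = log((x + √(x²+λ))/2)
is then applied cell-wise. λ is chosen on QC technical replicates (or
pooled within-group replicates when no QCs exist) by minimizing the squared
coefficient of variation of the per-feature technical SDs after transform —
zero when every feature has the same spread. The normalization by the mean
SD matters: without it, a huge λ shrinks all transformed variances at once
and wins trivially. The search is a bounded scalar minimization over
log10 λ. Note the objective is flat over the entire log-like region when
noise is purely multiplicative (any λ ≪ min(x)² gives g ≈ log + constant),
so the *regime* of the returned λ is meaningful, not its digits.
Imputation-before-normalization is exposed as a switch for sensitivity
checks.

## Multivariate statistics

PCA is a mean-centered SVD; per-component variance shares are σᵢ²/Σσ², and
each retained component's scores are tested across treatment groups by
one-way ANOVA with Tukey HSD pairwise comparisons. PLS-DA is a NIPALS PLS1
regression of mean-centered glog intensities on a −1/+1 class code;
prediction thresholds ŷ at 0 (an exact tie goes to the class whose
training score mean is nearer). Validation uses venetian-blinds
cross-validation — sample i in fixed input order joins fold i mod n_folds
(default 7 folds) — reporting the percent classification error; the latent
variable count is the smallest achieving the minimal CV error. Model
significance is a label-permutation test on the CV error,
p = (1 + #{permuted error ≤ observed}) / (n_perm + 1) with n_perm = 999 by
default; the permutation statistic is the CV error itself because that is
the figure reported alongside each model. Influential signals are ranked by
VIP (mean squared VIP = 1 by construction) and refined by forward selection
in decreasing VIP order while the CV error does not increase; the scan also
stops once the error reaches zero, where tie-admission would wave through
arbitrary features. Caveat worth knowing: with deterministic venetian
folds, the null distribution of the CV error is not exactly invariant to
the *arrangement* of labels over the fixed sample order, so permutation
p-values are calibrated to within a few percent rather than exactly —
acceptable for the screening role they play here.

## Univariate statistics

Per-feature two-sample t-tests on the normalized, imputed (but
un-transformed) matrix: Welch by default (the safer choice when the
variance assumption is unstated; pooled-variance Student's t is a config
switch). Benjamini–Hochberg step-up q-values; significance is strict
q < 0.05. Percent change is reported for the second group relative to the
first.

## Annotation

All masses derive from one isotope table (AME2020/IUPAC). Formula
enumeration searches C, H, N, O, P, S compositions (defaults C≤60, H≤120,
N≤15, O≤30, P≤6, S≤4) whose positive-mode adduct ion (M+H, M+Na, M+K, M+Li
by default) lies within a ppm tolerance of the observed m/z — 1.0 ppm in
polar contexts and 1.5 ppm in nonpolar contexts by default. The nested
search prunes on partial mass and solves the hydrogen count from the mass
residual, making it exhaustive without iterating H. Candidates must have
RDBE ≥ 0 and integer RDBE (even-electron ions); the nitrogen rule is
deliberately not enforced as a filter because electrospray adducts
complicate it. Candidates are matched against a small curated compound
table packaged as TSV (~100 metabolites and lipids, including every
metabolite named in the study's figures); live KEGG/LipidMaps queries are
out of scope, so database-version-dependent match counts are not
reproduced. Isotope verification seeks the 6Li partner of Li+ adducts at
−1.00088 Da (expected relative intensity 8.2%) and the 13C M+1 partner,
passing within a factor-of-2 intensity band by default.

Taurine-lipid annotation tests fragments for mass-consistency with a fixed
backbone — taurine condensed with a C20H34O2 unit (306 Da nominal), i.e.
taurine + C20H34O2 − H2O by default, with the non-condensed sum as a
switch since the linkage chemistry is unresolved — combined with loss of a
catalogued fatty acyl (14:0 … 22:6; free fatty acid by default, acyl
−H2O as a switch). It reports mass consistency only, not structure.

## Carbonate chemistry

The experimental seawater is characterized from (S, T, pH, pCO2) at 0 dbar:
CO2* = K0·fCO2 with the Weiss (1974) fugacity correction, carbonate
speciation from the measured pH, TA as carbonate + borate + water + minor
acid-base terms, and Ω = [Ca²⁺][CO₃²⁻]/Ksp. Constants: Lueker et al.
(2000) K1/K2 on the total scale, Dickson (1990a, b) KS/KB, Perez & Fraga
(1987) KF, Millero (1995) KW, Mucci (1983) Ksp, Uppström boron, and Ca,
sulfate and fluoride scaling with S/35. The reported pH is fed directly to
total-scale constants; the meter was NBS-calibrated and no scale conversion
is documented, so the direct interpretation — which is what a default run
of a standard CO2-system calculator does — is the default here, and it
reproduces the published TA/Ω table to ~0.1%. A round-trip check recovers
pH from (DIC, TA) by bracketed root finding and closes to < 1e-6.

## Problem sizes used in the test suite

The packaged tests exercise the factorial design at reduced replication
(3–5 biological replicates per group for peak-list-level tests) and the
feature-level generator at its defaults (500 features, 10 + 10 samples) or
1000 features for FDR calibration (200 simulation repeats); permutation
calibration uses 200 null datasets × 99 permutations. These sizes give the
stochastic checks comfortable margins while keeping the default suite
quick on a single CPU.

## Known limitations

* The counts of detected signals in the real study (2487 polar / 1771
  nonpolar, and downstream significant-signal counts) depend on
  instrument-level thresholds that are not recoverable from the published
  record; they are treated as qualitative patterns, not targets.
* Dropout is a hard threshold; real missingness is stochastic near the
  detection limit.
* The permutation scheme, fold count and important-signal criterion of the
  original analysis are unstated; the defaults here are documented choices
  and are configurable.
* Only two-class PLS-DA is provided (all reported models are pairwise);
  no O-PLS, no multi-class coding.
* The carbonate module is surface-only (0 dbar) and omits nutrient
  alkalinity terms, which were not reported.
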