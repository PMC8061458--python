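# Methods

`methcompass` re-implements, as a tested library, a cross-study quality
control and variability analysis workflow for Illumina Infinium
HumanMethylation450K (HM450K) DNA-methylation arrays: BeadArray control-metric
QC, array-wide signal assessment, harmonization of free-text sample metadata,
model-based sample predictions (epigenetic age, sex, blood cell fractions,
genotype-based replicate detection), age-reliability filtering, and a
two-step quantile-variance procedure for identifying non-informative and
tissue-specific CpG probes. Because real cross-study inputs are tens of
thousands of IDAT files, the package ships a synthetic-data module that
emulates their statistical structure with planted ground truth; every stage
is validated against that truth or against independent oracles.

## Quality control model

**Control metrics.** Each of the 17 BeadArray controls is a ratio
`aggregate(numerator group) / aggregate(denominator group)` of control-probe
intensities, passed when the value is at or above a threshold. Conventions:
the sample's mean extension-green control intensity serves as the background
term; a `+1` offset is applied to a denominator that would otherwise be 0;
pass = 1 / fail = 0 in the binary outcome matrix. The registry of
numerator/denominator groups and thresholds is an editable YAML file seeded
from the BeadArray Controls Reporter definitions (staining 5, extension 5,
hybridization 1, target removal 1, bisulfite conversion 1, specificity 1,
non-polymorphic 5, restoration 0 with a documented FFPE alternative of 1),
because revising thresholds is an intended use, not a code change. The two
target-removal metrics are background/target ratios, so the registry permits
the BACKGROUND sentinel in the numerator as well as the denominator. Missing
control data fails conservatively (with a warning) rather than passing.

**Intrinsic dimension.** PCA of the centered binary outcome matrix, followed
per retained component by a sequential (type-I) ANOVA of component scores on
the 17 outcome columns in registry order. Because scores are exact linear
functions of the centered columns, the sequential fractions per component sum
to one; each control's overall contribution is the component-variance-weighted
sum. The "majority subset" greedily accumulates controls until a configurable
fraction (default 0.95) of the retained variance is covered. Sequential
rather than marginal sums of squares is a deliberate, documented choice; the
fixed registry order makes it deterministic.

**Sample and study failure.** A sample fails when it fails any control or
when both its log2 median methylated and unmethylated intensities fall below
a threshold (default 11, in log2 intensity units). Study failure fractions
f_st are reported for every study; the >60% flag list excludes studies with
<= 10 samples (the size filter affects flagging only, so both the full and
filtered views remain available). Label enrichment among failed samples uses
two-sided exact binomial tests against the cohort label frequency with
Benjamini-Hochberg adjustment, declaring enrichment only on the
over-represented side at adjusted p < 1e-3.

## Normalization

The noob model treats an observed intensity as signal plus background,
`X = S + B`, `S ~ Exponential(alpha)`, `B ~ Normal(mu, sigma^2)`; out-of-band
probe intensities estimate the background alone. Parameters are fit by
method of moments (mu, sigma from the out-of-band pool; `1/alpha =
max(mean(observed) - mu, floor)` with floor 10 intensity units) — closed-form
and stable, with maximum likelihood left as an extension. The corrected
intensity is the conditional mean `E[S | X = x] = m + sigma *
phi(m/sigma)/Phi(m/sigma)` with `m = x - mu - sigma^2 alpha`, evaluated via
`log_ndtr` so it neither overflows nor underflows; it is strictly positive
and order-preserving, and is verified against a numerical-quadrature oracle
to 1e-6 relative error. Dye-bias equalization rescales the red channel by
the green/red control-probe mean ratio.

Beta-values use the conventional `meth / (meth + unmeth + 100)`; M-values are
`log2(b/(1-b))` with b clamped to `[1e-6, 1 - 1e-6]` (the logit base does not
affect the study-adjustment algebra; base 2, offset 100 and the clamp are all
configurable). Study adjustment subtracts per-study means per probe on the
M scale and restores the probe's grand mean (sample-size weighted), removing
batch location shifts without re-centering tissues; refitting study
indicators after adjustment yields coefficients below 1e-8. Missing
Beta-values impute at the sample's array-wide median.

## Metadata harmonization

SOFT-style blocks parse into ordered key:value records (characteristics
lines split once on the first colon). A TSV rule table maps text onto a
controlled vocabulary: case-insensitive regular expressions with
word-boundary anchoring (so "normal" does not fire inside "abnormal"),
priorities, and presence vs numeric capture semantics. Sex, age and storage
are single-valued — conflicting matches at equal priority withhold the value
rather than guess, because metadata inaccuracy is a first-class failure mode
here; tissue and disease/group accumulate all matches. Ages normalize to
years (months / 12, weeks / 52). The shipped table covers the tissue,
disease/group, sex, age and storage phrasings that the synthetic corpus
emits plus common GEO variants; it is data, not code, and is meant to be
extended.

## Model-based predictions

The epigenetic clock is a sparse linear model on Beta-values with the
piecewise log-linear age calibration `F(age) = log((age+1)/(adult+1))` for
`age <= adult` (default adult = 20) and `(age - adult)/(adult + 1)` above;
predictions invert F. Published coefficient files are pluggable TSV inputs;
up to 10% missing clock probes impute at the cohort median beta, more is a
per-sample error. Sex calls compare median log2 total (meth+unmeth)
intensity over X vs Y probes; the difference cutoff is -2 with a +/-0.25
dead zone yielding "undetermined" near the boundary. Cell fractions solve
`min ||b - R w||^2` subject to `w >= 0`, `sum(w) <= 1`, exactly, by
non-negative least squares on an augmented system in which a slack component
converts the inequality to a simplex equality enforced by a penalty row.
Replicate detection links samples whose SNP-probe betas differ by less than
tau = 0.1 mean absolute difference and takes connected components — a
deliberately simple distance-threshold stand-in for mixture-model genotype
identity calling; the first sample id per group is its representative.

## Age reliability workflow

Concordance of mined chronological vs predicted epigenetic age is summarized
by mean absolute difference (MAD), squared Pearson correlation and Spearman
rho. Studies qualify for age imputation when their within-study MAD over
complete, non-cancer tissue pairs is <= 10 years; studies with fewer than 3
complete pairs are ineligible rather than trivially passing. Imputation
replaces only missing chronological ages (never mined ones) in eligible
non-cancer tissue samples, with provenance flags. Age-acceleration outliers
use inclusive bounds (>= +15, <= -15 years). Variance attribution is a
sequential ANOVA of epigenetic age on chronological age, study, cancer
status and sample type, in that order, with percent variance and F-test
p-values per term; it is cross-checked against statsmodels' type-I ANOVA in
the test suite.

## Variability analysis

Per tissue, on study-adjusted autosomal Beta-values:

1. **Sample filter** — drop samples failing any control, or below the
   within-study 5th percentile on *both* signal channels; then drop
   non-representative replicates.
2. **Covariate probe filter** — per probe, a sequential ANOVA on age, sex and
   cell fractions (one fraction dropped; they live on the simplex),
   vectorized across probes via a shared orthonormal design basis. A probe is
   dropped when any covariate reaches >= 10% variance with BH-adjusted
   p < 0.01 (adjustment across probes within covariate). Constant covariates
   (e.g. sex in sperm) are skipped with a warning.
3. **Two-step selection** — the intersection of (i) the extreme decile of
   per-probe variance and (ii) the extreme decile of variance within the
   probe's mean-Beta bin (10 bins of width 0.1). Union is available behind a
   flag for sensitivity analysis. Quantile membership is rank-based: the
   `ceil(0.1 n)` most extreme probes with ties broken by probe id. A
   thresholded quantile cannot say how many threshold-tied probes enter,
   whereas rank selection is deterministic, matches a brute-force
   sort-per-bin oracle exactly, and reproduces fixed selection sizes.
4. **Cross-tissue combination** — shared low-variance probes pass the low
   filter in *every* tissue and have cross-tissue range of tissue means
   < 0.01; tissue-specific probes pass the high filter in exactly one tissue
   (evaluated among each tissue's retained probes), ranked by descending
   variance with the top 2000 kept.
5. **Region enrichment** — binomial tests of the selection's CpG-island and
   gene-region class counts against background fractions, BH-adjusted,
   significant at adjusted p < 1e-3, with direction reported.

Bins are computed on the covariate-filtered matrices (filtering precedes
binning), and the autosomal restriction is applied via the annotation table
before any variance computation.

## Dimensionality reduction

Feature hashing maps each probe id deterministically (BLAKE2 of
`seed:probe_id`) to one of d buckets (default 1000) with a random sign; a
sample's hashed vector is the signed per-bucket sum of its Beta-values.
Signed hashing keeps inner products unbiased, so the PCA geometry of the
projected data is trustworthy; the transform is linear and the projection
spec (d, seed, signed) is serialized with outputs. PCA is centered, with the
sign convention that each component's largest-magnitude loading is positive.
Group comparisons along a component use the variance ratio with a two-sided
F-test.

## Synthetic data: what it emulates, and what it does not

The generator fans one global seed into named sub-streams (samples,
controls, signals, panel, metadata, models, effects) so each product
regenerates independently and byte-identically. Probe "architecture"
(baselines, variances, effect sizes, genotypes, annotation classes) comes
from the shared `effects` stream so all products agree on the planted
structure.

Default scenario (the conditions every full-scale check runs under): seven
tissues (adipose, blood, brain, buccal, liver, nasal, sperm), 3 studies per
tissue with 40-60 samples each (~150/tissue), 20 000 CpG probes plus 60 SNP
probes. Intensities follow the normexp model (background mean 400/500 and sd
80/100 for green/red, mean signal 8000 — typical log2 median signals near
11.4, realistically straddling the failure threshold of 11 when signal is
scaled down). Study batch effects are N(0, 0.2) shifts on the M scale;
background probes get bimodal baseline means and N(0, 0.4) per-tissue
M-scale offsets.

Planted structure, with the reasoning behind the sizes:

* **200 shared low-variance probes** — baseline beta 0.005-0.03 (identical
  across tissues), noise sd 0.001-0.003, island/promoter-weighted
  annotation. Near-zero betas are where M-scale study shifts move means
  least, so the < 0.01 cross-tissue range genuinely holds after adjustment
  (the averaged per-study multiplier perturbs a mean of b by about 0.2 b).
  The count keeps the planted set below the low-mean bin's decile capacity,
  so recovery is capacity-limited by design nowhere.
* **300 tissue-specific probes per tissue** — sd 0.25 in their tissue,
  background-like elsewhere; open-sea/gene-body-weighted annotation.
* **1900 globally variable probes** — sd drawn once per probe from
  U(0.10, 0.22) and held constant across tissues. They overfill the top
  variance decile in every tissue so the selection boundary falls inside
  this cohort; because their true variances are heterogeneous and
  tissue-constant, boundary membership is consistent across tissues and
  "high in exactly one tissue" false positives are confined to a thin
  estimation-noise band. (With a single shared variance the boundary ranking
  is pure noise and such false positives dominate — the heterogeneous design
  is what makes tissue-specificity a recoverable property.)
* **2400 covariate-driven probes** (12% of the array, inside the 8-40%
  removal band the filter targets): 1200 age-linear (slope 0.0008-0.0016
  beta/year), 600 sex-shifted (0.03-0.06), 600 exact mixtures of a 3-cell
  reference with Dirichlet(6, 3, 1) fractions. Effect sizes put the
  covariate share of variance in the 25-60% range against noise sd 0.025.
* **24 clock probes** carrying beta = 0.5 + 0.08 F(age), so the generated
  clock (coefficients 1/(K * 0.08), intercept -0.5/0.08) is exact on
  noise-free betas by construction.
* **300 X / 100 Y probes** whose intensity scaling (female Y at 2% signal,
  male X at 55%) separates the median-intensity sex call; **60 SNP probes**
  with per-donor genotype betas near 0.05/0.5/0.95, shared by replicate
  samples.

Metadata records are SOFT-style blocks with varied phrasings; token coverage
defaults to 76% for tissue (62-90% for the other categories), and the
tokened value is recorded per record so harmonization can be scored exactly.

Not emulated: binary IDAT files, type I/II probe chemistry differences,
probe-level genomic autocorrelation, realistic cross-reactive or polymorphic
probes, ontology-grade metadata messiness, and cancer-vs-normal structure.
Passing tests therefore demonstrate that the algorithms implement their
definitions and recover planted structure under realistic noise — not that
the thresholds are optimal for any particular real cohort.

## Numerical choices and degenerate inputs

* Background draws are censored at zero (a scanner cannot report negative
  intensities); at the default mu/sigma ratios the effect is negligible.
* Beta-to-M round trips are exact on the clamped range by construction; the
  generator and the normalize module share the same clamp.
* Tie-breaks: probe id everywhere a ranking is needed (two-step selection,
  top-k truncation, replicate representatives), making all selections
  invariant to sample and probe order.
* Empty mean-bins are skipped (no probe can qualify from them); an all-equal
  variance matrix selects the first decile by probe id.
* Degenerate inputs raise rather than guess: constant outcome matrices,
  zero-variance out-of-band pools, rank-deficient references, single-sample
  storage conditions, fully missing samples.

## Problem sizes

Full-scale checks run the shipped seven-tissue scenario (7 x ~150 x 20 000);
statistical recovery checks use 1e5 draws (normexp), 1000 samples (control
failure rates), 200 hash seeds (unbiasedness), and 100 replicates
(enrichment type-I error). Component unit tests use smaller cohorts of the
same shape.

## Known limitations

* The registry's group definitions reconstruct the standard BeadArray
  formulas; site-specific manifests may group probes differently.
* The vocabulary table is a working subset of a full curation vocabulary;
  real GEO text will need additional rules (the table format is the
  extension point).
* Study adjustment removes location shifts only; scale and probe-specific
  batch effects, and cross-study normalization generally, are out of scope.
* The replicate detector's fixed distance threshold is cruder than
  mixture-model genotype calling and can merge relatives at permissive tau.
* Tissue-specificity is operationalized as "passes the high filter in
  exactly one tissue"; other operationalizations (e.g. variance-ratio tests)
  are plausible and would select overlapping but not identical sets.
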