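# Methods

`stereoquant` implements the quantitative analysis used to find protein
complexes in an enriched membrane preparation: label-free quantitation of a
purification series, immunoaffinity-purification (AP-MS) statistics, and
targeted parallel-reaction-monitoring (PRM) peptide quantitation.  This note
records the models, the parameters that matter, and the choices made where
the procedure was genuinely open.

## Label-free quantitation

**riBAQ.** iBAQ intensities estimate a protein's molar amount (summed
peptide intensity over the number of theoretically observable peptides).
riBAQ divides each protein's iBAQ by the summed iBAQ of all non-contaminant
proteins detected in the same sample, giving a molar-fraction estimate that
is invariant to per-sample loading and instrument response.  Contaminant
status is a boolean row flag taken from the search-engine export; flagged
rows are excluded from both the denominator and the output.  Missing values
are represented as absent (`NaN`), never zero: a protein is *detected* in a
sample iff a positive intensity is present, which keeps
detected-in-N-of-M filters well defined.  Zero intensities on input are
coerced to missing for the same reason.

**Isoform apportionment.** When several isoforms share a protein-group row,
the group riBAQ is split per sample in proportion to the summed intensity
of the peptides unique to each isoform; shared peptides quantify the group
but never enter the shares.  Shares are computed per sample (the
fractionation changes isoform composition across fractions); a sample with
no detected isoform-unique peptide yields missing isoform values rather
than zeros.  A global (pooled across samples) share computation is
available via pooling the evidence table beforehand.

**log2 / median normalization.** For differential testing, riBAQ values are
log2-transformed and each sample's median detected value is subtracted, so
every sample's median is zero.  The operation is idempotent and removes
global per-run scale factors.

## Enrichment-slope profiling

Across the ordered purification fractions (S1, P2, M3, P6, S7; integer
index 0..4, unit spacing) a protein co-enriching with the target membranes
gains abundance roughly log-linearly.  The *enrichment slope* is the
ordinary-least-squares slope of log10 riBAQ on fraction index, fit over
detected fractions only (no imputation).  Proteins detected in fewer than
`min_detected` fractions (default 3 of 5; the companion 4-of-6 rule is the
same parameter) are omitted.  Results are ranked steepest-first with ties
broken by protein id.  The log base is configurable; ranking is
base-invariant and a base change simply multiplies all slopes by a
constant, so log10 was chosen for readability (slope 1 = tenfold per
step).

The transmembrane diagnostic sorts proteins by slope and averages the
binary TM-helix annotation over consecutive non-overlapping blocks of 50;
the final partial block is averaged over its actual size.  A rising block
mean toward steep slopes indicates genuine membrane enrichment.

## Profile clustering

Proteins detected in every profiled sample are row-standardized (subtract
the row mean, divide by the row *sample* (n−1) standard deviation —
configurable; constant rows are excluded with a warning) and clustered
with Gaussian mixture models.  Models are fit for every combination of
component count `k` in `k_range` and covariance structure (diagonal, full,
tied, spherical), each with 10 k-means++ restarts from a fixed seed, and
the lowest-BIC model is selected.  Two numerical choices matter:

* the covariance regularizer is scaled to 1e-2 of the data variance —
  with a tiny absolute regularizer, near-singular one-point components
  produce unbounded likelihoods and win BIC selection spuriously;
* rows are fit in sorted protein-id order, which makes the result
  deterministic and invariant to the input row permutation.

Clusters are then annotated with the mean enrichment slope of their
members and reindexed in descending slope order, so cluster 1 always
contains the steepest co-enriching profiles.  BIC selection is consistent
only for adequate sample sizes; below roughly 100–200 complete profiles
the selected `k` on diffuse data can legitimately exceed the generative
component count.

## Immunoaffinity-purification statistics

Two complementary readouts identify bait partners, mirroring the two ways
the control runs can be used:

1. **Binary control subtraction** (`filter_specific`): keep proteins
   detected in at least `min_specific` specific-antibody runs (default 4
   of 6) and at most `max_control` control runs (default 0).
2. **Continuous enrichment** (`enrichment_ratio` + `moderated_t_test` +
   `bh_fdr`): the per-protein ratio of mean eluate riBAQ to mean
   starting-extract (total) riBAQ, with run means taken over detected
   runs only (configurable zero imputation for sensitivity analysis).
   Control-detected proteins are retained here.  Proteins found only in
   the eluate get a censored lower-bound ratio against the smallest
   detected total riBAQ and are reported as a segregated category rather
   than placed on the continuum with a pseudo-count.

**Moderated t-test.** Per-protein two-sample tests on the log2/median-
normalized matrix use empirical-Bayes variance moderation: pooled residual
variances s²_g (df = n1+n2−2 over detected runs) are assumed to follow
s0²·F(d_g, d0); the prior (s0², d0) is estimated by matching the mean and
variance of log s² through digamma/trigamma moments, with d0 obtained by
Newton inversion of the trigamma function.  The posterior variance is the
df-weighted blend (d0·s0² + d_g·s²_g)/(d0+d_g) and the statistic is
referred to a t distribution on d0+d_g df (normal when d0 = ∞).  Rows are
kept whenever both groups contain a detected value and at least one
residual df remains; all-constant rows are omitted with a warning.  d0→0
recovers the ordinary pooled t-test; d0→∞ gives a z-like statistic with
fixed s0² (both limits are exposed via `prior_df`/`prior_s2` and tested).
FDR control is Benjamini–Hochberg step-up with enforced monotonicity.

**Stoichiometry.** Unadjusted stoichiometry is prey/bait riBAQ in the
eluate (mol/mol, run-mean).  The adjusted form multiplies by the
bait/prey riBAQ ratio in the total, which estimates what fraction of the
prey pool is bait-bound.  The bait scores exactly 1 under both
definitions; preys missing from totals get a missing adjusted value.

## Targeted (PRM) quantitation

Fragment-ion chromatograms for one peptide/run are summed pointwise
(linear interpolation onto the densest grid when grids differ).  The
candidate peak is located deterministically — a surrogate for the manual
curation a chromatogram GUI affords: the summed trace is smoothed with a
5-point moving mean, the apex is the smoothed global maximum (restricted
to twice the fallback tolerance around the reference retention time when
one is supplied), and boundaries extend to where the smoothed trace falls
below max(noise floor, 1% of apex).  The 1% relative cutoff keeps the
truncation error of a Gaussian peak below 0.3% of its area.  A peak is
accepted iff (1) three or more co-eluting fragments contribute — a
fragment co-elutes when its own global apex lies within one peak
half-width of the summed apex and it rises above the noise floor inside
the boundaries; (2) at least two data points span the peak; and (3) a
matched MS2 spectrum falls inside the boundaries.  When criterion 3
fails, the fallback accepts iff the apex is within 2.0 min (inclusive) of
an identified peak for the same peptide in another sample *and* the set
of contributing fragment labels equals that peak's (subset matching is
configurable).  Rejected peaks are zero-filled: area exactly 0, with the
failing criteria recorded.  Accepted peaks are integrated by the
trapezoid rule against a zero baseline (a local-baseline option was
considered and left out; the generators produce baseline-free traces and
the zero baseline is the conservative choice for low-background PRM).

**Experiment normalization.** Each bait peptide's area in an experiment is
divided by that peptide's mean across experiments; the per-peptide factors
are averaged across bait peptides to give the experiment factor, and all
downstream areas are divided by their experiment's factor.  For a
complete bait matrix the factors average exactly 1.  **IP/total** is the
mean normalized specific-eluate area over the mean normalized
starting-material area, with a two-tailed pooled-variance t-test (and 95%
CI for the mean difference) comparing specific against control eluates;
replicates are pooled equally.

**Fraction bookkeeping.** A fraction's total PRM intensity is its per-µg
intensity times its total protein (µg); percentages are taken against the
reference fraction (the post-nuclear supernatant) and rounded to integers
for the report, and per-µg fold enrichments between fractions are
reported to one significant figure.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions for every recovery test.

*Purification series* (defaults: 500 proteins, 10% membrane class, 5
fractions): log-normal baseline abundances (log10 mean 6, σ 1.5), the
membrane class gains 0.6 log10 units per fraction (σ 0.15 across
proteins; background slopes centered at 0), per-observation log10
measurement noise 0.25, logistic detection dropout (midpoint log10 4.5,
steepness 2), 5% contaminants, and isoform groups whose group row is the
sum of two same-class members, backed by shared plus isoform-unique
peptides.  Under these conditions the fitted slopes recover the assigned
slopes with Spearman ρ ≈ 0.9, and the membrane-minus-background median
slope difference recovers the configured slope within a few percent.

*Immunoaffinity eluates* (defaults: 6 specific + 6 control runs): the
bait is captured fully and partners at their capture efficiencies, both
concentrated ~10⁴-fold relative to availability; nonspecific carry-over
is sampled per run from an abundance-share-weighted Bernoulli process —
identically for specific and control runs, which is the premise of
computational control subtraction — at a carried-over fraction of 1e-5 of
availability, so the eluate is bait-dominated while the abundant extract
proteins dominate the controls.  Replicate noise is multiplicative
log-normal (σ 0.3).  The canonical fixture plants the bait and five
partners in the 15th–50th abundance percentiles: the regime the method
targets, where the complex is far rarer than the background.

*PRM chromatograms*: co-eluting Gaussian fragments with shared apex and
width (σ 0.1 min) on a 0.05-min grid, folded-normal additive noise, one
matched MS2 event near the apex with probability 0.9, and analytic
per-fragment areas (A·σ·√2π) kept as ground truth.

Not emulated: raw spectra and the m/z dimension, retention-time drift
across runs, peptide chemistry (missed cleavages, modifications),
correlated (batch) noise, and intensity-dependent variance beyond the
log-normal model.  Passing the recovery tests therefore demonstrates the
correctness of the estimators under the stated generative model, not
robustness to acquisition artifacts that real instruments add.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale problems chosen
to exercise every code path: 500-protein purification series, 200-protein
IP fixtures, 1,000 random filter instances at 12 proteins × 12 runs, and
an enumerated grid of 918 slope cases.  Every stochastic step draws from
one seeded `numpy` generator per call; identical configurations produce
byte-identical output tables, and the CLI records parameters, seed, and
output checksums in a per-stage manifest.

## Known limitations

* The moderated test assumes independent, roughly normal log2 intensities
  within groups; strong missingness-by-intensity couples detection to the
  quantity under test and is only partially mitigated by fitting over
  detected runs.
* The censored "≥" enrichment ratio for eluate-only proteins depends on
  the smallest detected total riBAQ and should be read as a bound, not an
  estimate.
* BIC model selection for profile clustering is unreliable below ~100
  complete profiles.
* Peak qualification is a deterministic surrogate for expert curation;
  heavily overlapping peptides or saturated detectors would need manual
  review.
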