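# Methods

## Decoding model

The decoder is the classical motor-imagery stack. Epoched EEG
(`[T × C × N]`, time × channels × trials) is band-pass filtered with a
4th-order Butterworth filter applied forward–backward (zero phase), per
trial and channel, then cropped to the analysis window (default
1.0–3.5 s after stimulus onset; filtering precedes cropping so filter
transients fall partly outside the window). Filtering is applied to
epoched rather than continuous data because the containers are epoched;
edge effects are mitigated by the filter's odd-reflection padding.

**CSP.** For each class the trial-concatenated covariance is computed:
every trial is mean-centered per channel, all trials of the class are
concatenated along time, and the population covariance (1/T_total) of the
resulting `C × T_total` signal is taken — this normalization is exactly
invariant to duplicating trials. The spatial filters `W` solve

    Wᵀ Σ₁ W = D,   Wᵀ Σ₂ W = I − D,

obtained from the symmetric generalized eigenproblem
`Σ₁ w = λ (Σ₁+Σ₂) w` (scipy's `eigh`), with eigenvalues `d = diag(D)`
sorted descending and ties broken by ascending original eigenvector index.
Each filter is scaled so its largest-magnitude entry is positive — a pure
reporting convention, since variances are sign-invariant. Activation
patterns for topographic export are `inv(W)ᵀ`; `pattern_table` zero-pads
channels outside the analysis montage. A rank-deficient composite
covariance raises with advice to pass an optional ridge
(`ridge · trace/C · I`), which is off by default.

The first *m* and last *m* filters are kept: `m = 2` for subject-specific
training, `m = 3` for pooled subject-independent training (more data
supports more filters). The per-trial feature is the log of the
sum-normalized variance of the projected signal, invariant to per-trial
amplitude scaling.

**Filter-bank CSP.** The multi-resolution bank holds 15 bands: 8–30 Hz,
the four rhythm bands 4–7 / 8–13 / 13–30 / 30–40 Hz, and two interleaved
6-Hz ladders (7–13 … 31–37 and 10–16 … 34–40 Hz). Each band contributes
2 filter pairs (4 features), i.e. 60 candidate features. Selection is
mutual-information best-individual-feature selection: features are ranked
by the plug-in discrete mutual information with the class label after
equal-frequency binning into `⌈√N⌉` bins (capped at 16, configurable);
walking down the ranking, each feature pulls in its CSP complement (the
mirrored filter of the same band), and the walk stops after `k` distinct
pairs (`k ∈ {6, 10, 20}`, default 10). The discrete plug-in estimator was
chosen over kernel density estimates because it admits an exact brute-force
oracle; the estimator is configurable. `k` counts *pairs* rather than raw
ranked features so that `k = F/2` always selects the full feature set,
which also matches the convention of counting "feature pairs".

**Classifier.** Binary LDA with the pooled within-class covariance
(samples centered by their own class mean, 1/n normalization) shrunk
toward `ν·I`, `ν = trace/F`, by the analytic Ledoit–Wolf intensity
`γ ∈ [0, 1]` (sklearn's estimator; any consistent Ledoit–Wolf-type
estimator is acceptable and the fitted γ is recorded on the model). Then
`w = Σ̃⁻¹(μ₂−μ₁)` with the boundary at the midpoint of the projected
class means; equal priors are assumed (the datasets are balanced) but are
configurable. Decision scores of exactly zero break deterministically to
the first class. Note γ saturates near 0.5, not 1, at exactly n = 2
because the two mean-centered samples have identical scatters.

## Chance-level thresholds and selective pooling

The chance level of a balanced binary classifier evaluated on `n` trials
is 0.5 only asymptotically. The adjusted confidence interval

    p̃ ± z₁₋α/₂ √( p̃(1−p̃) / (n+4) ),   p̃ = 0.5

(the "+4" is the small-sample adjustment of the Wald interval) gives, at
α = 0.05 and n = 100, the band [0.4039, 0.5961]. The upper limit is the
pooling threshold: a subject enters the source pool only if their
subject-specific accuracy is **strictly greater** ("greater than" is taken
literally; boundary-equal accuracies are excluded). `n` is the number of
test trials of the current protocol, both classes combined; the z-quantile
is the exact standard-normal inverse CDF with no continuity correction.
All records entering one pool must share `n`, otherwise the threshold is
ill-defined and the construction raises.

Pool membership is computed once per dataset from full subject-specific
runs with the single-band CSP + shrinkage-LDA pipeline (the pool criterion
is always CSP-based, regardless of which feature method is being
evaluated), then reused across leave-one-subject-out folds; the evaluated
subject is removed per fold, not re-thresholded. Folds with an empty
effective pool are reported as missing and excluded from the mean with a
warning rather than silently skipped. Every fold's training manifest
(the subject ids actually concatenated) is retained in the result table
for audit.

A subtlety worth stating: the subject-specific records used for pooling
are computed on each subject's own train/test split — the same split later
used as the transfer test set. This mirrors the staged procedure of
computing SS performance first (S2) and building pools from it (S3), and
means the pool criterion has seen the test subjects' data *when deciding
membership of other subjects' folds only*; the evaluated subject itself is
always excluded from its own training pool.

Sub-trial analyses draw `n_sub/2` trials per class without replacement,
preserving trial order; the convention is three independent draws with
seeds derived from a base seed, reporting the mean. Paired strategy
comparisons use the two-sided Wilcoxon signed-rank test, zero differences
dropped, exact null for small samples (scipy's policy); an all-zero
difference vector returns p = 1 with a warning.

For cross-dataset evaluation both datasets must first be harmonized to the
shared 20-channel motor-cortex montage in identical order
(`select_channels`); a mismatch raises before any training. One pipeline
is trained on the (pooled) source dataset and scored per subject of the
target dataset; no fold exclusion is needed since the cohorts are
disjoint.

### Computational note

Leave-one-subject-out with single-band CSP uses an algebraic shortcut:
because per-class scatter matrices are additive across subjects, each
fold's pooled covariances are assembled by summing cached per-subject
scatters of data that was band-passed and cropped exactly once. The fold
result is bit-identical to re-filtering and re-concatenating (verified in
the test suite); filter-bank mode takes the generic path.

## Synthetic data generator

The generator exists so every stage — preprocessing, CSP, feature
selection, shrinkage LDA, pooling, transfer evaluation — can be exercised
end to end without EEG downloads. Per trial it sums:

* **background**: 1/f-shaped noise, independent per channel in the
  spectral domain, then spatially mixed so neighboring electrodes
  correlate ≈ 0.5 (Gaussian kernel over an idealized 10-20 grid,
  correlation length 0.85 grid units), normalized to unit per-channel
  variance and scaled by the subject's `noise_sd`;
* **two mu-band sources** (sinusoids at the subject's `alpha_peak_hz`
  with random phase and mild log-normal amplitude jitter) projected
  through Gaussian scalp topographies centered near C3 and C4
  (spread `topo_sigma`, per-subject center offsets).

ERD is planted by multiplying the amplitude of the source *contralateral*
to the imagined hand by `(1 − erd_depth)`; the "ipsilateral" anomaly
profile swaps which source attenuates, reproducing the rare subject whose
spatial patterns are mirrored and who therefore scores well
subject-specifically while poisoning pooled filters.

Subject skill is the single dial `erd_depth ∈ [0, 1]`: 0 yields classes
that are statistically indistinguishable (subject-specific accuracy at
chance), 0.5–0.9 yields high accuracy. Populations mix three profile
kinds:

* **good** (default 70%): `erd_depth ~ U(0.5, 0.9)`, contralateral,
  source-center jitter sd 0.45 grid units;
* **poor** (default 20%, reflecting the reported 10–30% of users without
  decodable patterns): `erd_depth ~ U(0, 0.1)` plus a strong
  (4× amplitude), anatomically displaced (jitter sd 1.2), barely modulated
  mu rhythm and 1.3× background noise. This models the atypical
  sensorimotor-rhythm organization described for BCI-inefficient users;
  mechanically, their high-variance non-discriminative rhythm is what
  rotates pooled whitening and degrades all-subjects training — without
  it, poor performers would be statistically benign and subject selection
  would have nothing to gain;
* **ipsilateral** (default 10%): good-range depth, mirrored laterality.

The amplitude constant (0.55 relative to unit noise) and the poor-profile
factors were fixed once, as generator design, so that the `erd_depth`
grades span chance to near-ceiling decoding and the three kinds produce
the qualitative population structure above. Counts follow
largest-remainder apportionment of the mixture; all per-subject parameters
(depth, peak frequency 9–12 Hz, noise 0.9–1.1, topography) are drawn from
one master seed, and every subject/split has an independent
`SeedSequence([seed, …])` stream, so any part of a dataset can be
regenerated alone and a spec is bit-reproducible. Defaults are 20
subjects, 50 train + 50 test trials per class, 128 Hz, 4-s epochs, and the
20-channel motor-cortex montage.

What the generator does **not** emulate: eye/muscle artifacts, volume
conduction from a realistic head model, non-stationarity across sessions,
beta-band ERD, rhythm harmonics, and real inter-subject covariance
structure. Passing tests therefore show that the pipeline implements the
intended algorithms and that selective pooling behaves as designed *under
this generative model*; they do not certify accuracy levels on real EEG.

## Problem sizes in the test and acceptance runs

Analytic checks (thresholds, CSP/MIBIF/LDA oracle equivalences) run at the
sizes stated in their tests (50–100 random instances, 4–8 channels). The
pooling-benefit study uses 20 populations of 20 subjects (60% good, 30%
poor, 10% ipsilateral; 50 trials/class/split), requiring SI-α=0.05 mean
accuracy ≥ SI-All mean in at least 80% of populations. Skill recovery
uses 10 cohorts of 10 subjects (half `erd_depth = 0`, half ≥ 0.5) and
requires ≥ 90% agreement between pool membership and planted skill. These
sizes keep the full suite in the minutes range on one CPU while leaving
each check statistically meaningful.

## Known limitations

* The fixture format stores amplitudes as arbitrary units; reference
  schemes and unit scaling of real recordings are not modeled.
* Optional EDF/BrainVision ingestion is delegated to an `mne` adapter
  (`epochs_from_mne`); continuous-recording event extraction, artifact
  rejection and re-referencing are out of scope.
* Filter-bank LOSOCV re-filters per fold (no per-band scatter cache);
  it is correct but substantially slower than single-band mode.
* The MI estimator's binning rule affects selection for tiny trial
  counts; the bin count is configurable where that matters.
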