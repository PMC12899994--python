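# Methods

`ictalkit` implements a calibrated, interpretable ensemble pipeline for
patient-independent seizure detection from multichannel scalp EEG, together
with a synthetic-cohort generator that makes every stage testable without
clinical recordings. This note documents the model, the parameters that
matter, the numerical choices, and what the synthetic world does and does
not establish.

## Signal model and conditioning

Recordings are 23-channel, 256 Hz scalp EEG in a 10–20 bipolar montage.
Sessions recorded at other rates are polyphase-resampled to 256 Hz; when a
subject has several sessions, only channels common to all of them are kept,
in the first session's order.

Conditioning follows the order band-pass → notch → common average reference
→ per-channel z-score → segmentation:

* **Band-pass** 0.5–40 Hz, fourth-order Butterworth applied
  forward–backward (zero phase, effective order 8).
* **Notch** at the line frequency and its first harmonic (60/120 Hz, or
  50/100 Hz for European recordings), realized as a 2 Hz-wide fourth-order
  band-stop. The narrow notch rings for seconds, so filtering uses long
  odd-extension padding (16 s); the first/last few seconds of a session
  still carry edge transients, which is immaterial for the 10 min+ sessions
  the pipeline targets.
* **CAR** subtracts the instantaneous across-channel mean.
* **Normalization** per channel over the continuous recording:
  x′ = (x − μ)/(σ + ε) with ε = 1e−8 guarding flat channels.
* **Segmentation** into 5 s windows (1280 samples) with 50 % overlap
  (2.5 s hop), fully contained in the recording. A window is labelled
  seizure when at least 50 % of it lies inside an annotated interval
  (half-open [onset, offset) convention; overlapping annotations are merged
  at parse time).

## Feature bank

32 descriptors per channel and window:

* **Time domain (13):** mean, variance, skewness, kurtosis (biased moment
  estimators, defined as 0 for constant input), line length Σ|Δx|,
  zero-crossing rate, Hjorth activity/mobility/complexity (first
  differences, unscaled by fs; mobility and complexity guarded to 0 for
  constant input), RMS, IQR, peak-to-peak, and the mean Teager–Kaiser
  energy ψ[n] = x[n]² − x[n−1]x[n+1].
* **Spectral (17):** Welch PSD (256-sample Hann segments, 50 % overlap);
  absolute and relative powers for delta (0.5–4), theta (4–8), alpha
  (8–13), beta (13–30), gamma (30–40 Hz); theta/alpha, beta/alpha and
  (beta+gamma)/(alpha+theta) ratios; spectral entropy normalized to [0,1]
  over 0.5–40 Hz; median frequency and 95 % spectral edge (first PSD bin
  reaching the cumulative quantile); 1/f slope by ordinary least squares of
  log10 PSD on log10 f over 1–40 Hz. All-zero windows return zeros.
* **Nonlinear (2):** sample entropy (m = 2, r = 0.2·SD, Chebyshev
  distance, self-matches excluded, natural log; capped at log(#template
  pairs) when no matches exist, and defined as 0 for constant signals) and
  permutation entropy (order 4, delay 1, normalized by log 4!).

Cross-channel summaries add the maximum RMS over channels, per-band
hemispheric lateralization (L−R)/(L+R+ε) with channels assigned left/right
by the parity of their first electrode's 10–20 index (midline excluded),
and the mean absolute relative-power difference between adjacent bands.
With 23 channels this yields 746 named columns (`{CHANNEL}__{feature}` plus
globals).

The per-window seizure-overlap fraction is carried as metadata but is **not**
a model input by default: it is a function of the label and would leak it.
A config switch can include it for replication studies.

## Harmonization

Per training fold: non-finite entries are imputed with column medians;
entries beyond five column SDs are winsorized to the 0.1/99.9 percentiles;
values are cast to float32; missing expected columns are zero-filled.
Pearson-correlation pruning then drops, in canonical column order, any
column with |r| ≥ 0.95 against an earlier kept column (computed on at most
20 000 seeded rows; zero-variance columns are kept). Negatives are
undersampled to at most 20:1 against positives. All statistics are frozen
on the training subjects and re-applied to held-out rows. A two-component
PCA on standardized features is available as a structural diagnostic only.

## Models, LOSO protocol, calibration

Six named configurations, each a StandardScaler + classifier pipeline:
three boosted configs (200 rounds, learning rate 0.1; depth 6 with 0.8
row/column subsampling; a 31-leaf variant with L2 = 0.1; a depth-6 variant
with L2 = 3.0), two bagged forests (100 trees, sqrt features,
min_samples_split 10, min_samples_leaf 5, balanced class weights) and a
logistic baseline (C = 1, lbfgs, 1000 iterations). The boosted configs
weight positive samples by min(neg/pos, 100). The named configs mirror the
XGBoost/LightGBM/CatBoost parameterizations they stand for; they are
realized with scikit-learn's (histogram) gradient-boosting estimators, the
only boosted-tree implementations guaranteed in the runtime environment.

`LosoExperiment.fit()` runs leave-one-subject-out cross-validation: for
each held-out subject, cleaning, collinearity pruning, balancing, scaling
and model fitting use the remaining subjects only. A stratified 20 % of the
balanced training rows is held out to fit an isotonic regression mapping
raw scores to probabilities (identity with a warning if the split is
single-class); the calibrator is applied to the held-out subject without
refitting. Per-fold randomness derives from the global seed plus a CRC of
the subject id, so a fold's artifacts are bit-reproducible and provably
independent of the held-out subject's rows (the leakage-guard test corrupts
those rows and asserts bitwise-identical predictions).

## Events and clinical metrics

Calibrated per-segment probabilities are median-filtered (window 5 by
default, the midpoint of the admissible 3–11 range; edge handling reflects
and duplicates the boundary sample, so an isolated spike at the very first
or last segment of a session can survive smoothing — interior spikes
cannot), thresholded at 0.5, and grouped into events as maximal runs of at
least three consecutive positive segments. A true seizure counts as
detected if any predicted event overlaps it in time; each true event counts
once. Event sensitivity = detected/true events; specificity and precision
are segment-level counts; event F1 combines event-level precision with
event sensitivity. False alarms are predicted events with no true overlap,
reported per 24 h of monitoring; the zero-FA frontier selects, per patient,
the model of highest event sensitivity among those with FA/24 h = 0.
Metrics with zero denominators are reported as undefined, not as 0.

## Explainability

SHAP values are computed by an exact path-dependent TreeSHAP implementation
(numba-compiled; conditional expectations weighted by training node
covers). `base_value + Σ_j ϕ_ij` reproduces the model output — the margin
(log-odds) for boosted models, the positive-class probability for forests —
to float precision; the test suite checks the recursion against a
brute-force Shapley enumeration over tree-path feature subsets. Tree
descent is performed on float32-rounded inputs to match scikit-learn's
prediction-time cast. Global importance is the mean absolute SHAP value per
feature, ties broken by name.

The LIME-style surrogate is self-contained: 1000 seeded Gaussian
perturbations around the sample (per-feature SD from the training fold;
zero-variance features unperturbed), RBF proximity weights with kernel
width 0.75·√p on standardized distance, and a ridge (α = 1) surrogate;
features are ranked by |coefficient|.

SHAP–LIME agreement is reported with two statistics: the asymmetric
consistency |S∩L|/|L| and the Jaccard index |S∩L|/|S∪L| (top-10 sets by
default). Both are computed because the asymmetric form is sometimes quoted
where Jaccard numbers are actually reported; Jaccard is the headline
statistic here. Channel topography sums importances per channel and
min–max normalizes to [0,1] (a constant vector maps to all ones). Ablation
re-runs the LOSO protocol on top-k feature subsets (k ∈ {5,…,30}); ranking
stability is summarized by top-20 selection counts and per-subject
coverage across folds and models.

## Statistics

FA equivalence uses a one-sided one-sample t-test of mean FA/24 h against
the 0.5/day clinical bound; with (numerically) zero variance the degenerate
rule p = 0 (mean < limit) / p = 1 (otherwise) applies, which is the correct
limit for a pipeline with strictly zero false alarms. Bootstrap CIs use
5000 seeded percentile resamples of the mean. Wilcoxon signed-rank
(zero differences dropped, exact for small n — verified against full 2^n
sign enumeration) and Mann–Whitney U compare AUC distributions. Calibration
quality uses equal-width decile binning for ECE plus the Brier score.
Ranking agreement is tested against a permutation null (1000 relabelings of
feature identities, add-one p-value).

## Synthetic world

The generator states one fixed world (chosen once, before any acceptance
measurement): 6 seizure-positive and 3 seizure-free subjects, one 600 s
session each, 23 channels at 256 Hz. Real monitoring sessions run 30 min to
2 h; 600 s keeps a full cohort run (generation → features → 6-fold LOSO)
within a single-CPU test budget while preserving every structural property
the pipeline relies on (multi-subject grouping, ~10 % seizure-segment
prevalence inside the 8–12 % band via 3 seizures of 15–25 s per subject,
seizure-free subjects for false-alarm assessment).

Background activity is 1/f Gaussian noise (slope 1) plus a narrowband
alpha (8–13 Hz) component at 20 µV RMS. Seizures add, on three focus
channels (25 % amplitude elsewhere), a 4.5–7.5 Hz theta burst with
amplitude modulation and a raised broadband noise floor, cosine-tapered
over 1 s edges; gains are expressed in background-SD units with gain 1
meaning no injection. All randomness derives from one seed via spawned
per-subject streams.

What a green synthetic run establishes: the plumbing, protocol and
statistics are correct, leakage-free and reproducible, and the feature bank
separates the stated ictal signature. What it does not establish: clinical
performance. The generator has no artifacts (eye blinks, EMG, electrode
pops), no inter-subject morphology variability beyond random seeds, no
montage heterogeneity, and its seizures are far more stereotyped than real
ictal patterns — so absolute sensitivities/FA rates on synthetic data do
not transfer to patient data.

## Known limitations

* EDF support covers the subset the package writes (integer rates, 16-bit,
  equal-length 1 s records); EDF+ annotations embedded in the signal file
  are not parsed (annotation tables are separate CSVs).
* The collinearity pass is per-fold (leakage-safe) by default; a global
  pass is a config option and changes kept-feature lists.
* Path-dependent SHAP uses training-cover expectations; importances are
  relative to the training distribution of each fold.
* Event latency is reported descriptively from event start times; it is
  not an asserted invariant of the labelling rule.
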