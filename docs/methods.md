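# Methods

This note documents the models, numerical choices and limitations of
`eegharx`, in the order the pipeline runs.

## Synthetic EEG generator

**What it emulates.** Activity-dependent spectral structure on a
six-channel 10-20 montage (Fz, C1, C2, T7, T8, Oz) with optional EOG/EMG
reference channels. Each activity is an `ActivityProfile`: a map
region → band → target relative power (five bands tiling 0.5–44 Hz; four
regions F/C/T/O), with the five fractions per region summing to 1. Within
each 10-s epoch every channel is a sum of five band-limited Gaussian
components — white noise band-pass filtered with a zero-phase order-8
Butterworth and rescaled so each component's sample variance matches the
profile's target — so the channel's region attains the target relative
powers by construction.

**Synthesis band insets.** The delta component is synthesised over 1–4 Hz
and gamma over 30–43 Hz (analysis bands stay 0.5–4 and 30–44). Without the
insets, spectral leakage of the Hamming-tapered Welch estimator pushes part
of the delta power below the 0.5 Hz analysis edge (where it counts toward
no band) and filter skirts above 44 Hz both bias the recovered relative
powers and erode the epoch signal-to-noise ratio. The filter order 8 (not
the order 4 used for preprocessing filters) keeps clean-epoch SNR near
30–32 dB, comfortably above the 25 dB rejection threshold; with order 4 the
gamma skirt above 44 Hz leaves clean epochs straddling the threshold.

**Homologous pairs.** C1/C2 (and T7/T8) share each band's source up to an
independent component carrying 10% of the power
(`pair_independent_fraction`). Fully independent left/right realizations
would give a mean pdBSI near 0.27 at these epoch and segment lengths — the
index averages |R−L|/(R+L) of two chi-square-distributed PSD estimates, which
is far from zero even for statistically identical sides — whereas the
shared-source construction yields the intended near-symmetric baseline
(measured ≈ 0.11–0.12). A per-profile `asymmetry` parameter scales the
right-hand side's variance by 1 + asymmetry to create known pdBSI > 0.

**Epoch-to-epoch variability.** Each epoch's region targets are jittered
with zero-mean Gaussian noise (`rp_jitter`, default std 0.03 on the
fractions, renormalized). This emulates biological nonstationarity: without
it, every feature with any between-class margin becomes a perfect separator
and tree ensembles spread their dependence arbitrarily across correlated
proxies, which makes per-instance explanations unrepresentative of how such
models behave on real data.

**Artifacts and defaults.**

| parameter | default | rationale |
|---|---|---|
| sampling rate | 250 Hz | common clinical EEG rate; Nyquist well above the 44 Hz gamma edge |
| amplitude | 20 µV RMS per channel | scalp-EEG magnitude |
| mains | 5 µV, 60 Hz | removed by the notch before SNR estimation |
| blinks | 12/min, 400 ms raised cosine, 60 µV; gains Fz 1.0, C 0.3, T 0.1, O 0.05, EOG 4.0 | front-dominant ocular topography; EOG records the source |
| EMG bursts | 2/min, 300 ms, 30–100 Hz, 3 µV RMS; gains T 0.9–1.0, others 0.05, EMG 3.0 | temporal-muscle topography; at ≥ 8 µV the out-of-band part of the bursts alone would push clean epochs below the 25 dB screen |
| motion | fraction 0.1 of epochs, +30 µV broadband noise | sized to land far below the SNR threshold (≈ 1–10 dB) |
| class composition | 793/408/267/243 epochs reading/walking/working/resting | the study composition |

The generator does **not** attempt physiological EEG morphology: no 1/f
background, spindles, transients or nonstationary rhythms beyond the
per-epoch jitter. Consequently, passing tests demonstrate that the pipeline
recovers planted spectral structure and rejects planted artifacts — not
that it would reach any particular accuracy on real recordings. The default
profiles are deliberately well separated; held-out accuracy near 1.0 is a
property of that design.

## Preprocessing

Fixed stage order, logged at run time: 60 Hz band-stop → ICA artifact
removal → 10-s epoching → SNR rejection → 0.5–44 Hz band-pass. The SNR is
estimated on the pre-band-pass path, since the band-pass would remove
exactly the out-of-band noise being measured.

* **Filters** — zero-phase (forward-backward) order-4 Butterworth, SOS
  form. Band edges must lie strictly inside (0, Nyquist). Zero-phase
  filtering preserves epoch timing (cross-correlation peak at lag 0).
* **ICA** — scikit-learn FastICA over the non-reference channels,
  components whose absolute Pearson correlation with any reference channel
  (EOG/EMG) exceeds 0.7 are zeroed before remixing. With no reference
  channels the stage is a logged no-op; automatic component classification
  is out of scope.
* **SNR** — 10·log10(P_in/P_out) per epoch, with P_in the mean per-channel
  Welch power in 0.5–44 Hz and P_out the mean power above 44 Hz to Nyquist.
  Zero out-of-band power gives +∞ (epoch kept). Threshold 25 dB. This
  estimator is a declared, self-contained definition: it is computable from
  the signal alone and monotone in injected broadband noise.
* **Epoching** — consecutive, non-overlapping, aligned to annotation
  starts; trailing remainders are dropped rather than padded.

## Spectral features

Welch PSD per channel: Hamming taper, 2-s segments (0.5 Hz resolution —
resolving the 0.5 Hz delta edge), 10% inter-segment overlap, density
scaling (integral ≈ variance; Parseval is tested at 5%). The description of
the estimator as a "10 percent Hamming window" is read as Hamming taper
with 10% overlap; segment length is a package choice.

Band powers integrate the PSD with the trapezoid rule over [f_low, f_high],
inserting interpolated band-edge points so adjacent bands tile the axis
with no panel counted twice. For bin-membership sums (pdBSI) shared edges
belong to the upper band; the uppermost band includes 44 Hz. Region powers
average channels in the power domain: C = mean(C1, C2), T = mean(T7, T8),
F = Fz, O = Oz, G = mean of all six (G carries relative-power features
only). pdBSI is computed per homologous pair — (C2, C1) and (T8, T7) — per
band and broadband; bins with R + L = 0 are skipped with the bin count
reduced. Zero-denominator ratios and zero-power regions yield missing
values and the epoch's row is dropped with a logged count.

The table has 49 feature columns in a fixed order (25 RP across five
regions, 10 per-band pdBSI, 2 broadband pdBSI, 12 ratios across F/C/T/O)
plus the activity label.

## Selection, training, evaluation

* ANOVA-F per feature from its definition (between-group over within-group
  mean squares); constant features score 0, zero-within-variance separators
  score +∞ and rank first; ties break by column order. Scoring is fitted on
  the training partition only — selecting on pooled data is a leakage bug
  and is tested by constructing a feature informative only in the test
  rows.
* Stratified 80/20 split and stratified k-fold CV (k = 10), both
  deterministic under seeds.
* Tuning grids are strided sub-grids of the full ranges (RF 1–100 × 1–30,
  GBoost 1–50 × 1–14, XGBoost 1–100 × 1–30), each containing the
  configuration reported optimal for its family (98/21, 50/8, 83/10); ties
  go to fewer estimators, then shallower trees. All other hyperparameters
  stay at library defaults.
* Metrics come from the confusion matrix: one-vs-rest precision/recall/F1
  per class, multiclass accuracy as trace/total (the per-class
  (TP+TN)/total form is a binary identity; the multiclass reading is the
  standard one), support-weighted averages. Zero-denominator cells give 0
  with a logged flag. ROC is a descending threshold sweep over unique
  scores; tied scores collapse to one operating point so the trapezoid AUC
  equals the normalized Mann–Whitney U with half-credit for ties
  (asserted to 1e-9 in tests). Cross-validated ROC pools out-of-fold
  probabilities.

## Local-surrogate explainer

Continuous features are perturbed without discretization: each neighbourhood
sample is drawn feature-wise from N(instance, training-set spread) (spread =
sample std, ddof = 1; zero-spread features stay fixed), with the
unperturbed instance included at weight 1. Proximity weights are
exp(−D²/w²) with D the Euclidean distance in standardized units and
w = 0.75·√d by default. The surrogate regresses the black-box probability
of the target class (probability scale, not log-odds) on standardized
features with a proximity-weighted ridge (penalty 1.0, closed form,
unpenalized intercept); the complexity constraint is hard top-K selection
on |standardized coefficient| followed by a ridge refit on the kept set
(K = 10 by default, matching the ~10 features displayed per instance).
A singular refit (possible only at zero penalty) retries once with the
penalty raised to max(10α, 1e-6). Reported per instance: signed
coefficients, intercept, weighted R² on the perturbation sample (NaN for a
constant black box), and each feature's position relative to the training
quartiles as display text. Percent views normalize |coefficients| to
100%; raw surrogate-coefficient units are the primary output because no
external normalization of "importance percentages" is well defined.

Explanations of tree ensembles are faithful to the fitted model, not to the
generator: if the model spreads its dependence over correlated features
(e.g. central vs global gamma, which share channels), the explanation
correctly does so too.

## Problem sizes and determinism

Tests exercise the full 1,711-epoch study composition once (shared
module-scoped fixture: simulate → preprocess → features → tune → train,
about a minute) and use 8–160-epoch recordings elsewhere; explainer checks
use 2,000-sample neighbourhoods, which keep the top-3 ranking stable across
seeds in the scenarios tested. The pipeline expands one global seed into
per-stage seeds via `numpy.random.SeedSequence(seed).generate_state(6)
mod 2^31` (simulate, ica, split, tune, train, explain), so stages are
independently reproducible; re-running a config bit-reproduces evaluation
outputs.

## Known limitations

* The SNR estimator and the Welch segment length are declared package
  choices; other estimators would shift the absolute dB scale of the
  rejection threshold.
* FastICA on six channels separates one or two strong artifact sources; it
  is not a substitute for high-density ICA, and without reference channels
  no removal is attempted.
* The EDF writer emits EDF+C with 1-s records and 16-bit quantization
  (≈ 0.01–0.05 µV at typical amplitudes); recordings must span whole
  seconds at an integer sampling rate.
* pdBSI of finite-length symmetric data is biased above zero (chi-square
  estimator noise); the generator's shared-source design keeps the baseline
  near 0.1, and only the analytic bounds 0 and 1 are exact.
* The classifier accuracies reported on synthetic data say nothing about
  accuracy on real EEG; the synthetic profiles are separable by design.
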