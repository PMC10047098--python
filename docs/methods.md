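# Methods

## Pipeline model and assumptions

The package classifies one-minute ECG epochs as apneic or normal using only
waveform structure — no QRS detection, RR-interval estimation or other
fiducial extraction. The underlying physiological assumption is that
obstructive events imprint a slow (30–60 s) cyclical variation of heart
rate and R-wave amplitude on the ECG, and that a translation-stable
time–frequency representation of the raw waveform captures this without
beat segmentation. The input is assumed to be single-lead, 100 Hz, in
millivolts; minute `m` covers samples `[m·60·fs, (m+1)·60·fs)` (0-based,
half-open), and a trailing partial minute is discarded.

## Segment quality weighting

Quality is judged per recording: each 60-s epoch is summarized by its
normalized autocorrelation over 500 lags (5 s — several RR intervals), and
epochs are compared with the centered cosine similarity of their ACF
vectors, which is algebraically their Pearson correlation. An epoch's
weight is the mean similarity to the other epochs of the same recording;
the self-similarity (always 1) is excluded from the mean by default because
including it would shift every weight up by the same amount
(`weight.include_self` restores it). Epochs with weight below λ = 0.8 are
dropped, as are zero-variance or non-finite epochs. The comparison happens
after band-pass filtering, so baseline wander and power-line interference
do not dominate the ACF.

The 3–45 Hz FIR band-pass is a 101-tap Hamming windowed-sinc. It is
linear-phase and applied with reflect-padding plus group-delay compensation,
so one pass is zero-net-phase and length-preserving. The taps' mean is
subtracted so the DC gain is exactly zero (the Hamming stopband alone
leaves about −55 dB of DC leakage).

## Scattering transform

Both filter banks use analytic Morlet wavelets: a Gaussian bump at the
center frequency minus a scaled zero-frequency Gaussian so every wavelet
has exactly zero mean. Centers run geometrically from 0.4·fs (40 Hz)
down to 1/T (0.017 Hz) at Q per octave; bandwidths are chosen so adjacent
filters of a bank cross at half power, which makes the effective quality
factor equal Q. The low-pass φ is a Gaussian with frequency-domain
σ = 0.13/T Hz, i.e. a time support of roughly the invariance scale. After
construction, each bank (φ together with its ψ family) is rescaled once so
its Littlewood–Paley sum never exceeds 1 on the FFT grid. That single
normalization makes every layer — and therefore the whole cascade — provably
non-expansive, which the suite asserts as an energy inequality.

Convolutions are circular via FFT. The default boundary mode is plain
periodic convolution: it makes the energy bound exact (Parseval) and makes
a circular shift of the input an exact rotation of every intermediate
signal, which is the cleanest setting in which to verify translation
stability. A `reflect` mode (mirror-pad to twice the length, crop the
center) is available when wrap-around at epoch edges matters more than
exactness.

Only frequency-decreasing second-order paths (center of ψ_j2 below center
of ψ_j1) are kept; other paths carry negligible energy because the envelope
of a band-pass-filtered signal lives below that filter's center frequency.
With the defaults (fs = 100 Hz, T = 60 s, Q1 = 8, Q2 = 1) the bank has 90
first-order wavelets, 12 second-order wavelets and 619 paths in total
through order 2. The exact path count is a consequence of these design
rules; other scattering implementations with different frequency grids
produce different counts, which is why no specific count is asserted.

At T = 60 s the critically sampled output grid would hold a single frame
per epoch; the averaged outputs are instead summarized into 6 block means
(a 10-s hop), an oversampled grid that preserves some within-minute
temporal structure for the feature bank. `max_order` extends to 3 solely
for the energy-decay diagnostic: on 3–45 Hz band-limited noise, orders 0–2
hold ≈ 99.3% of the order-0–3 energy.

Feature extraction reads the flattened matrix row-wise: one row per 10-s
window, one column per scattering path. Features are therefore statistics
*across paths* within a window (a per-epoch pooled mode is available but
non-default).

## Feature bank conventions

* Moments use population (1/N) normalizations; kurtosis is non-excess
  (Gaussian → 3); both are flagged `nan` on zero-variance rows.
* Shannon entropy uses a 32-bin equal-width histogram and natural
  logarithms. The bin count is a package choice — entropy of a continuous
  sample has no canonical binning — and is exposed as `shannon_bins`.
* ApEn includes self-matches with denominator N−m+1; SampEn excludes
  self-matches and compares counts over the first N−m templates at both
  lengths, so a constant series scores exactly 0 in both. The embedding
  dimension defaults to m = 2 (the standard HRV choice) and the tolerance
  to r = 0.25·STD of the row, which makes both measures scale-invariant.
  A series with no length-(m+1) matches reports `inf` rather than a capped
  number. Both measures share one pair-distance computation built by
  running maxima along diagonals (O(N²) total), and the suite verifies them
  against naive loop-based implementations exactly.
* Spectral entropy normalizes the one-sided FFT periodogram (all rfft bins)
  and divides by log of the bin count, so it lies in [0, 1].
* Attention entropy takes the strict local maxima and minima as key points
  and computes the Shannon entropy of the distribution of index gaps
  between successive key points. The four-stream variant (separate
  max/min transition types, entropies averaged) is available behind
  `pair_types=True`.
* Cumulative residual entropy evaluates −Σ p(X>x_i) log p(X>x_i) with
  empirical survival probabilities at the sample points; zero-probability
  terms contribute nothing.
* z-scoring stores per-column mean and population std and is exactly
  invertible; zero-variance columns pass through unscaled with a warning.
  In every CV protocol the statistics are fitted on training rows only, and
  a test asserts that test rows never reach the fitting step.

## Validation protocols

The positive class is apnea. Hold-out draws a stratified 50/50 split
(optionally group-aware so no recording spans both halves); k-fold uses
stratified 10-fold with shuffling. Each protocol is repeated (default 10
times) with fresh seeded splits; per repeat, test predictions are pooled
into one confusion matrix, and accuracy, sensitivity, specificity,
precision, F1, Cohen's κ and rank-statistic AUC are reported as
mean ± std across repeats (std across repeats, population form). Ratios
with empty denominators are flagged `nan`, never substituted. A draw that
leaves a training fold single-class is redrawn with a logged warning.

The random forest defaults to 500 trees, √p features per split and
unlimited depth. The comparison harness runs AdaBoost, ExtraTrees,
GaussianNB, KNN, LDA, logistic regression, QDA, RF, SGD (log-loss), SVM and
XGBoost on identical repeated splits. Sequential feature selection scores
candidate subsets by seeded-RF accuracy under an internal stratified 5-fold
CV; the forward variant adds greedily, the bidirectional variant also
floats previously added features out when that improves the score. PCA
(train-fitted, variance-target component count) is available inside every
protocol.

## Synthetic data: what it emulates and what it does not

The generator is template-based: Ricker (Gaussian second-derivative) QRS
complexes at RR-driven beat times. Normal minutes modulate RR with a 4-s
respiratory sinusoid (depth 0.04) plus Gaussian beat-to-beat jitter
(SD 0.02 s) — without that jitter, long-lag ACF peaks stay unrealistically
sharp and the quality-weighting stage cannot treat the two classes as
peers. Apnea minutes modulate both RR and R-amplitude with one random-phase
sinusoid whose period is drawn once per record from [30, 60] s. Noise
components: white measurement noise, 0.3 Hz baseline wander, 50 Hz
interference, and optional broadband bursts (SD 1 mV, 5–20 s) on designated
minutes to emulate electrode motion. One integer seed fully determines the
output.

The benchmark difficulties fix the study conditions: `easy` uses RR depth
0.30, amplitude depth 0.5 and white-noise SD 0.02 mV; `hard` uses 0.10,
0.12 and 0.08 mV. Minutes are spread over 20-minute records with balanced
classes so subject-wise protocols have groups.

What passing tests show — and what they do not: the synthetic classes
differ by a clean, stationary modulation and share one QRS template, so the
pipeline separates them essentially perfectly (even at the `hard` setting
at desk scale the window-level classifier saturates). Synthetic results
therefore validate the machinery — energy bounds, oracle agreement,
leakage-free protocols, recovery of a known class structure — not the
accuracy attainable on real recordings, where morphology varies across
patients and events are irregular. P/T waves, SpO2/respiration channels and
realistic artifact taxonomies are deliberately out of scope.

## Problem sizes and numerical tolerances

The test suite runs the full pipeline at 200 labeled minutes per class
(the smallest size at which the CV estimates are stable) with 2 CV repeats,
and the energy diagnostics on 10 noise segments; these sizes are package
choices that keep the default suite fast while leaving every assertion at
its stated tolerance. Energy inequalities use relative tolerance 1e-6;
oracle comparisons use 1e-12 (or exact count identities); the
translation-stability bound is 5% relative L2 for a 0.5-s circular shift.
The complexity probe (log–log slope of runtime against N·log2 N) is
reported as a diagnostic only — it is machine-dependent and never gates.

## Known limitations

* WFDB support covers format-16 single/dual-channel records with a shared
  signal file — the Apnea-ECG layout — and rejects everything else
  explicitly. Binary WFDB writing beyond that subset is out of scope.
* Analytic (one-sided) wavelets capture about half the energy of a real
  signal's spectrum; this scales all coefficients uniformly and cancels in
  every ratio and classifier input, but absolute scattering energies should
  not be compared against implementations using two-sided conventions.
* With Q2 = 1 the second-order frequency grid is coarse; a study that needs
  finer modulation resolution can raise `scattering_Q2` (the parameter is
  exposed because reasonable values between 1 and 4 exist).
* Subject-wise hold-out is supported, but the synthetic benchmark's
  records are statistically exchangeable, so it cannot demonstrate the
  subject-generalization gap expected on real data.
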