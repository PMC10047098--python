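# apneawst

Minute-by-minute detection of obstructive sleep apnea (OSA) from a
single-lead ECG, for signal-processing researchers who want a transparent,
fully testable alternative to polysomnography scoring and to black-box deep
models. The package implements the complete chain — segment quality
weighting, wavelet scattering decomposition, an entropy-rich feature bank,
and a random-forest classification harness — and ships a synthetic ECG
generator so every stage runs and is verified without any recordings.

## Method

A recording sampled at 100 Hz is cut into 60-s epochs (one per annotated
minute) and band-pass filtered (3–45 Hz linear-phase FIR). Obstructive
events leave a slow 30–60-s cyclical variation of heart rate and R-wave
amplitude in the ECG; the pipeline detects it without any QRS detection.

**Quality weighting.** Each epoch's autocorrelation function
`X_s` is compared to every other epoch of the same recording by centered
cosine similarity

```
w_st = (X_s − X̄_s)·(X_t − X̄_t) / (‖X_s − X̄_s‖ ‖X_t − X̄_t‖)
```

(the Pearson correlation of the two ACF vectors). An epoch's weight is its
mean similarity to its peers; epochs below a threshold λ = 0.8 are dropped
as noisy — motion artifacts destroy the quasi-periodic ACF signature that
clean epochs of one patient share.

**Wavelet scattering.** Each surviving epoch is decomposed with an order-2
scattering transform built from analytic Morlet (Gabor) filter banks with
Q1 = 8 and Q2 = 1 wavelets per octave and a Gaussian low-pass φ with a
60-s invariance scale:

```
S0 f = f ∗ φ,   S1 f = |f ∗ ψ_j1| ∗ φ,   S2 f = ||f ∗ ψ_j1| ∗ ψ_j2| ∗ φ
```

over frequency-decreasing paths. The banks are Littlewood–Paley normalized,
so the transform is non-expansive (scattering energy ≤ input energy), and
orders 0–2 capture ≥ 99% of the energy an order-3 cascade would produce.
Averaged outputs are summarized into 6 time windows per epoch, and all
epochs are flattened into a `(n_epochs·6) × n_paths` matrix — one row per
10-s window.

**Features and classification.** Every row is reduced to ten measures:
mean, standard deviation, skewness, kurtosis (population forms; kurtosis
non-excess), histogram Shannon entropy, approximate entropy and sample
entropy (m = 2, Chebyshev distance, tolerance r = 0.25·STD), spectral
entropy, attention entropy (entropy of inter-extrema intervals), and
cumulative residual entropy. After per-column z-scoring (fitted on training
rows only) a random forest — compared against ten reference classifiers —
is evaluated with two repeated protocols: stratified 50/50 hold-out and
stratified 10-fold CV, reporting accuracy, sensitivity, specificity,
precision, F1, Cohen's κ and ROC AUC as mean ± std over repeats. PCA
reduction and sequential (forward or bidirectional) feature selection are
available for the same protocols.

## Worked example

```sh
cat > example.yaml <<EOF
synth_n_per_class: 20
cv_repeats: 3
seed: 7
out_dir: demo_out
EOF
apneawst run --config example.yaml
apneawst report --metrics-file demo_out/metrics.json
```

which logs the per-stage bookkeeping and prints:

```
INFO apneawst.pipeline: scatter: 39 segments -> 234 windows x 619 paths
INFO apneawst.pipeline: featurize: 234 rows x 10 features
INFO apneawst.pipeline: classify[RF]: acc 1.0000 +/- 0.0000
...
RF (kfold_10): acc 1.0000+/-0.0000  sen 1.0000+/-0.0000  spe 1.0000+/-0.0000
precision 1.0000+/-0.0000  f1 1.0000+/-0.0000  kappa 1.0000+/-0.0000  auc 1.0000+/-0.0000
```

Forty synthetic minutes were requested; one epoch fell below λ = 0.8 and
was dropped, the remaining 39 became 234 windows × 619 scattering paths,
and 10-fold CV classified every window correctly (κ = 1.0). Perfect scores
are expected here: the synthetic apnea class carries deep, clean cyclical
modulation, so it is far easier than real recordings (see
`docs/methods.md`). The `demo_out/` directory retains each intermediate
(segment weights, coefficients, features, metrics) as delimited text
stamped with the config hash and seed; rerunning the same config reproduces
them bit-identically.

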