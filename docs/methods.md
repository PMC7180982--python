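# Methods

This note documents the models behind `hfsleep`, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## The scientific setting

Five sleep stages (Awake, REM, N1, N2, N3) are scored per 30-s epoch.
EEG alone separates most stages through its sub-35 Hz rhythms, but REM and
N1 look alike there; human scorers disambiguate them with the chin EMG
(REM is atonic, N1 is not). Scalp electrodes sit over the occipitofrontal
musculature, and surface EMG is broadband (~25 Hz to several kHz) and much
larger than EEG, so a measurable fraction of EMG power appears in the EEG
above ~35 Hz when the recording is sampled fast enough (500 Hz here,
usable spectrum to 250 Hz). The package quantifies that leakage and feeds
it to a stage classifier.

## Synthetic polysomnography (`hfsleep.simulate`)

**Hypnogram.** First-order Markov chain over the five stages, default
transition matrix with sticky stages (self-transition 0.70–0.90), wake
start, and N3 reachable only through N2. A 720-epoch night (6 h) is the
default; tests and the packaged experiments use 40–500 epochs.

**EEG.** Per epoch, Gaussian noise shaped in the frequency domain to a
piecewise-flat one-sided PSD: per-stage levels (µV²/Hz) on the delta
(0.5–4), theta (4–8), alpha (8–15) and beta (15–35) bands, a
stage-independent gamma level 0.1 µV²/Hz on 35–80 Hz, and a broadband
floor 0.01 µV²/Hz up to Nyquist. Band energies downstream are therefore
analytically predictable. The default stage profiles follow the classic
picture (delta-dominant N3 at 120 µV²/Hz, alpha-rich wake, intermediate
N2); **REM and N1 share identical EEG profiles by design**, so in this
generator the two stages are distinguishable only through muscle tone —
the hardest (and most interesting) case for the classifier.

**EMG and leakage.** The chin EMG is σ_emg(stage) × unit-variance noise
band-limited to 25–250 Hz, with σ_emg = 15/1/8/3/2 µV for W/R/N1/N2/N3
(REM atonia; ordering REM < N3 ≤ N2 < N1 < Awake). A fraction *g*
(default 0.3) of the *same* noise realization, shaped by an order-2
Butterworth-magnitude high-pass with 35 Hz corner, is added to every EEG
channel. The gentle slope matters: between 35 and 80 Hz the leaked power
(~0.02 µV²/Hz at g = 0.3, N1) is comparable to the gamma activity that
masks it, while above 80 Hz it stands a factor ~2.5 above the floor. This
reproduces the empirically observed pattern that mid-band EMG content is
poorly captured by EEG while >80 Hz content is captured well, and it is
why the (150,250) Hz correlation exceeds the (35,80) Hz one in every
stage group. Epoch boundaries are cross-faded over 0.5 s to avoid
spectral splatter.

Per-bin periodogram theory fixes what correlations the generator can
produce: with leaked power *a* and independent background *b* in a band,
the EEG–EMG energy correlation within one stage is ≈ a/(a+b) (≈ 0.73 in
(80,250) Hz at g = 0.3 for an all-N1 night); across stages the σ_emg
contrast pushes pooled correlations close to 1. Thresholds in the test
suite were calibrated to these values before being frozen.

**What it does not emulate:** waveform morphology (spindles, K-complexes,
sawtooth waves), artifacts (electrode pops, sweat, movement), apnea
events, inter-subject spectral variability beyond the seed, and real
volume-conduction physics. Passing tests therefore show that the
*pipeline recovers known structure*, not that clinical accuracy would
match; the published-table metrics are reproduced from the printed
confusion matrices, never re-derived from raw clinical data.

## Preprocessing (`hfsleep.preprocess`)

A single zero-phase second-order IIR notch at 60 Hz (Q = 30, forward–
backward), nothing else. Q = 30 keeps the deviation at ±10 Hz under 1 dB,
so the 35–80 Hz analysis band is essentially untouched outside ±3 Hz.
Only the fundamental is notched; harmonics (120/180 Hz) are left alone.

## Band energies (`hfsleep.bands`)

Welch PSD with 2-s Hamming windows and 50 % overlap (0.5 Hz resolution,
adequate for the lowest band edge), integrated over half-open intervals
[low, high) on the shared grid — adjacent bands are exactly additive and
no bin is counted twice at 80 or 150 Hz. Classifier features are
log₁₀(E + 10⁻¹²); the floor keeps silent epochs finite. Band features are
computed on the current 30-s epoch only (the 90-s context belongs to the
scattering transform). The correlation study uses log energies throughout
(a `log=False` switch exists; results must state which was used).

## Scattering transform (`hfsleep.scattering`)

Order-2 scattering with analytic Gaussian-in-frequency wavelets,
geometrically spaced with Q₁ = 8 (first layer) and Q₂ = 1 (second layer)
wavelets per octave over J octaves below 0.4·fs (J = 10 at 500 Hz,
J = 7 at the pipeline's 100 Hz). Coefficients are global window averages
(one vector per 90-s context, matching one label per epoch):
S₀ = mean|x⋆φ|, S₁ = mean|x⋆ψ_λ₁|, S₂ = mean‖x⋆ψ_λ₁|⋆ψ_λ₂| for
center(λ₂) < center(λ₁). The layout is fixed: [S₀, S₁ by decreasing
center frequency, S₂ by (λ₁ asc, λ₂ asc)]; the natural-log transform with
a 10⁻¹² floor mirrors the band features.

Numerical choices:

* Each layer's bank is renormalized point-wise so its Littlewood–Paley sum
  Σ|ψ̂|² + |φ̂|² equals 1 on the grid — a tight frame, which yields the
  non-expansiveness bound ‖S(x)−S(y)‖ ≤ (1+δ)‖x−y‖ directly and makes the
  frame deviation a measured diagnostic (≈ 10⁻¹⁴) rather than a hope.
* FFT-based periodic convolutions; the window is tapered with 1-s cosine
  ramps to suppress wrap-around. The taper perturbs shifted-window
  features by at most a few percent (tested); translation tolerance of
  the operator itself is <1 % per second of shift.
* Filter outputs are subsampled to the smallest dyadic length that covers
  the filter's (6σ-truncated) frequency support twice over — identical
  invariances (homogeneity is exact), large constant-factor speedup;
  ~20 ms per 90-s window at 100 Hz.

## Fusion and classification (`hfsleep.cca`, `hfsleep.staging`)

Per-feature standardization uses training-fold statistics. CCA is solved
by ridge-stabilized whitening (relative ridge 10⁻⁴ by default; rank
deficiency is handled by the ridge, never by dropping dimensions); the
canonical correlations equal the singular values of
C_xx^{-1/2} C_xy C_yy^{-1/2}, verified in tests against an independent
generalized-eigenvalue solution to 10⁻⁸. Signs are fixed by making the
largest first-view loading positive. Fusion concatenates both projected
views (2k columns, k = min(50, dim, n−2)): channel-specific information
is preserved rather than averaged away.

The classifier is an RBF-kernel SVM (one-vs-one) with class weights
inverse to stage frequency — N1 and N3 are rare, and an unweighted SVM
collapses them. Hyperparameters are chosen on training subjects only, by
3-fold cross-validation *grouped by subject*, over C ∈ {1, 10, 100} and
kernel width γ = {0.3, 1, 3}/(d·var), scored by macro F1 (the headline
metric). The scattering input is decimated to 100 Hz in the pipeline:
classic staging information lives below 50 Hz, and the high-frequency
content enters through the three dedicated band features — which makes
the filtered/unfiltered comparison a clean ablation of exactly those
features. The first two epochs of each night (reflection-padded 90-s
context) are kept but flagged, so analyses can exclude them.

## Evaluation (`hfsleep.evaluate`)

All metrics come from the unnormalized 5×5 confusion matrix with
unrounded intermediates: ACC = trace/N; PR_p, RE_p from column/row sums
(0 when the denominator is empty); F1 their harmonic mean; κ from the
row/column-marginal chance agreement; Macro F1 the unweighted mean of the
five F1 values. Reporting rounds half away from zero — 2 decimals for
percentages, 4 for κ, integers for table cells — matching print
conventions of clinical staging tables.

## Correlation study (`hfsleep.correlation`)

Pearson r on pooled per-epoch log energies; permutation test on |r|
(two-sided — "uncorrelated" is a two-sided null) with the add-one
estimator p = (1+hits)/(1+n_perm), deterministic per seed; default 10⁶
permutations, 10³–10⁴ in desk-scale runs. The Bonferroni family is the 36
cells of one channel table (6 bands × 6 stage groups) and is guarded by an
exact cell count; correction is not pooled across channels. Bland–Altman
intervals use linear-interpolation quantiles (the numpy default rule,
fixed and documented because several conventions exist).

## Problem sizes

The packaged experiments run on one CPU: the filtered-vs-unfiltered
LOSOCV comparison uses 6 subjects × 200 epochs × 5 seeds (~10 min); the
permutation calibration 500 replicates of n = 200 with 10³ permutations
(~30 s); the leakage curve four 500-epoch nights (~1 min). Defaults for a
full synthetic study (720-epoch nights, 10⁶ permutations) remain available
through the configuration.

## Known limitations

* The scattering hyperparameters (Morlet-like Gaussians, Q₁ = 8, Q₂ = 1,
  global averaging) are standard audio-style settings, not a fit to any
  clinical dataset; other banks may do better.
* CCA fuses exactly two channels; more channels would need a multiset
  extension.
* The generator's piecewise-flat spectra make band energies predictable
  but waveforms unrealistic; do not use it to benchmark morphology-based
  scorers.
* Hypnogram misalignment is a hard error by design; recordings whose
  epoch count disagrees with the hypnogram must be fixed upstream.
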