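# Methods

This note records the modelling and numerical decisions behind `emgsyn`,
the reasoning where a choice was genuinely open, and what the synthetic
validation does and does not establish.

## Signal chain

**Amplitude path** (input to synergy extraction): 4th-order Butterworth
bandpass 20–400 Hz → full-wave rectification → 4th-order 20 Hz low-pass →
amplitude normalization → cycle segmentation by kinematic events →
linear interpolation to 100 points.

* All filters run zero-phase (forward–backward over second-order
  sections). The nominal order refers to the single-pass design; the
  effective magnitude response is its square. Zero-phase filtering keeps
  phase-event timing intact, which matters because phase boundaries are
  carried through to the 100-point axis (proportional mapping, rounded
  half-up).
* The normalization reference is the peak of each muscle's processed MVC
  envelope (`normalize.mode = "mvc"`); a within-trial-maximum fallback
  (`"trial_max"`) exists for data without MVC recordings. Any constant
  gain in the chain cancels between task and MVC trials.
* Time normalization uses linear interpolation. It is exact on linear
  segments and on inputs already sampled at 100 points, which the tests
  exploit.

**Coherence path**: bandpass → rectify → cycle segment → centered 10 ms
moving-RMS envelope at the full 2000 Hz rate. The 100-point warped
envelope cannot be used here: γ-band (30–50 Hz) content does not exist on
a 100-sample cycle axis. Moving RMS (not Hilbert) implements the
sliding-window envelope; edges are reflect-padded so output length equals
input length.

## Synergy extraction

NMF by multiplicative updates minimizing the Frobenius error, with the
factors initialized Uniform(0, max(D)). The objective is non-increasing
by construction and iteration stops at a relative objective change below
1e-6 or 1000 iterations. Each extraction runs 50 restarts whose child
seeds derive deterministically from the base seed (recorded in the output
for replay); the best-VAF solution is kept, ties going to the lowest run
index. Output convention: weight rows max-normalized, the scale folded
into the activations, so the reconstruction is unchanged to 1e-12.

VAF is **uncentered**: `1 − Σ(D−Ŵ Ĉ)²/ΣD²`. This is the muscle-synergy
convention in which perfect reconstruction scores 1 and the zero
reconstruction scores 0; a centered variant is available behind a flag.
Model order is the smallest k in 1..14 with VAF > 0.9, stopping at the
first passing k by default (`full_curve=True` evaluates the whole curve
and still selects the smallest passing k).

Because the restart pools for different `n_runs` are prefix-nested, a
larger restart budget can never return a worse VAF — a property the tests
assert.

## Templates and matching

Weight rows pooled within a condition are sorted canonically
(lexicographically) before clustering so results cannot depend on input
order. K-means is Lloyd's algorithm with squared-Euclidean objective and
`n_init` random restarts (scikit-learn backend, deterministic via the
seed); 1000 restarts at analysis time, fewer inside the Gap-statistic
loop where each fit is one of hundreds.

The Gap statistic uses B = 50 reference sets drawn uniformly over each
dimension's observed range — the simpler of the two published reference
distributions — and the one-standard-error rule with the √(1+1/B)
correction: choose the smallest k with Gap(k) ≥ Gap(k+1) − s(k+1). A
degenerate all-identical pool short-circuits to k = 1.

Cross-condition matching is greedy on descending Pearson r, one-to-one,
gated at r ≥ 0.6; candidates left over are condition-specific. Greedy
matching makes the gating semantics transparent; an optimal-assignment
(Hungarian) variant is available behind a flag. The reference condition
defaults to SG.

## Time-frequency coherence

Per-segment spectra use a 200-sample Hamming window hopped by 50 samples
(75 % overlap), zero-padded to `fft_len` = 1024. Each segment is
mean-detrended before tapering: the envelopes carry a large DC component
that would otherwise leak into the low bands. The default FFT length
gives 1.95 Hz bins so that the narrow 8–15 Hz α band spans three bins;
zero-padding refines bin *spacing* only — spectral *resolution* stays
window-limited at roughly ±10 Hz, which is the physical limit of a 100 ms
window and the reason several generator choices below exist.

Cross- and auto-spectra are smoothed by a 5×5 Hamming-weighted kernel of
unit sum (2-D convolution, reflective boundary; real and imaginary parts
separately), and coherence is `|⟨Pxy⟩|²/(⟨Pxx⟩⟨Pyy⟩)`, clipped to [0, 1]
with overshoot beyond 1e-9 treated as an error. Without smoothing a
single segment gives coherence ≡ 1 (Cauchy–Schwarz), which a regression
test pins down as the motivation for the kernel.

**Significance.** The bound `1 − α^{1/(L−1)}` is exact when L independent
segment spectra are averaged. Here the averaging is a weighted local
kernel over overlapping segments and correlated (zero-padded) bins, and
no closed form for an equivalent L survives that combination — both a
Kish effective-sample-size argument and an exact second-moment
calculation over window autocorrelations were tried and produce
thresholds whose null exceedance is an order of magnitude off. `L` is
therefore **calibrated against the estimator's own null**: coherence maps
of independent white-noise pairs (fixed internal seed, cached per
parameter set) give the null (1−α) quantile, which is inverted through
the closed form. At defaults this yields L ≈ 2.8 and a threshold of
0.859; the measured supra-threshold fraction under the null is ≈ 0.045 at
α = 0.05.

**AZ** is the *fraction* of a band's defined bins above the bound (not an
absolute count), making it invariant to trial duration. Band edges are
half-open `[low, high)` so 15 and 30 Hz are counted once.

## Group statistics

Per metric, the boxplot rule (1.5 IQR, linear-interpolation quartiles) is
applied to each subject's condition mean and flagged subjects are dropped
whole. Trimming individual cells per condition was measured to inflate
the omnibus type-I error to ~0.09 (value-dependent truncation of the
error distribution); subject-level removal keeps the harness calibrated
(~0.05) and preserves the paired design, and corresponds to case-wise
outlier screening in standard statistical packages.

Routing: if Shapiro–Wilk p > 0.05 in **all three** conditions (the
conservative reading of "normally distributed data"), repeated-measures
ANOVA with Greenhouse–Geisser correction when Mauchly's test fails,
followed by Bonferroni-corrected paired t-tests; otherwise Friedman
followed by Holm-corrected Wilcoxon signed-rank tests (normal
approximation) with effect size r = |Z|/√n over the non-zero-difference
pairs. Degenerate inputs (identical conditions) return F or χ² = 0 with
p = 1 rather than NaN.

Measured over 500 null simulations (n = 18 × 3, Gaussian): omnibus
rejection 0.056 at α = 0.05; a planted 5σ shift in one condition is
detected (omnibus plus the correct post-hoc pair) in 100/100 simulations.

## Synthetic cohorts: what they emulate

A trial is built as envelope × carrier: the planted envelope is
`Σ_i outer(W_i, C_i)` plus clipped Gaussian noise (default sd 0.02), and
each channel's carrier is independent band-limited (20–400 Hz) Gaussian
noise at unit RMS, so the rectified, low-passed output of the amplitude
path recovers the planted envelope (Pearson ≥ 0.95 per channel on
noise-free trials).

* **Weights**: per synergy, 3 dominant muscles in [0.6, 1] (row max
  exactly 1) and the rest below 0.15; rows resampled if pairwise cosine
  ≥ 0.9. Dominant sets prefer muscles not yet dominated by an earlier
  synergy, so each module keeps a distinct muscle group — without this,
  the smallest of five synergies often falls under 10 % of signal
  variance and the 90 %-VAF rule is structurally blind to it.
* **Activations**: Gaussian bumps (σ = 0.05 of the cycle ≈ 50 ms bursts)
  peaking in sequence across the cycle, with per-trial timing jitter
  (±0.02). An optional tonic baseline exists but defaults to 0 for the
  same variance-share reason.
* **Cohort**: crossover design, default 18 subjects × 3 conditions × 5
  trials (configurable; tests and the acceptance script use 6 × 3 × 1–2
  to keep runtimes in seconds). One master template set per cohort;
  condition g uses its first K_g templates with per-subject weight jitter
  (sd 0.06) — motor modules conserved across subjects and interventions,
  which is what makes pooled clustering and cross-condition matching
  meaningful. Planted K defaults: SG 3, RBG 5, ESG 2.
* **Common drive**: both channels of a pair are multiplied by
  `clip(1 + coupling·d(t), 0, ∞)` where `d` is hard-band-limited Gaussian
  noise at RMS 0.5, so coupling = 1 is near-full amplitude modulation
  with negligible clipping. The drive is masked in the frequency domain
  (not filtered): coherence is amplitude-invariant, so even a steep
  filter skirt would cohere outside the nominal band. The mask is inset
  3 Hz (capped at 20 % of bandwidth) from each band edge so that leakage
  through the 100 ms analysis window stays in-band.
* **Coupled-pair experiments** (`make_coupled_pair_trial`) hold the two
  coupled muscles at a sustained contraction — the classical condition
  for intermuscular-coherence measurement — because two muscles bursting
  under the same synergies genuinely cohere at low frequency, and at
  100 ms resolution that shared low-frequency power is inseparable from
  the α band. With this construction, β-band dominance of a β-coupled
  pair and its AZ contrast against an uncoupled pair hold in 20/20 seeds
  per band.

What the generator does **not** emulate: motor-unit action potentials,
volume conduction and electrode cross-talk, movement artefact, fatigue
drift, inter-trial amplitude non-stationarity beyond timing jitter, or
any joint-kinematics coupling. Passing tests therefore show that the
pipeline recovers the model's own structure under realistic noise — not
that real smash EMG has that structure.

## Problem sizes and determinism

The test suite runs in ≈ 2 minutes and the acceptance script in ≈ 1–2
minutes on one CPU; the heavier recovery experiments use 20 trials or 20
seeds, the statistics calibration 500 + 100 simulations, and the
end-to-end runs 6-subject cohorts. Every random quantity flows from an
explicit seed: the pipeline's master seed spawns per-stage and per-trial
child seeds deterministically, and identical seeds give byte-identical
run reports (asserted in the tests). The only fixed internal seed is the
coherence null-calibration surrogate, which is an estimator constant, not
an analysis choice.

## Known limitations

* The surrogate calibration of L assumes the coherence inputs behave like
  filtered noise envelopes under the null; strongly non-stationary
  envelopes shift the per-bin null somewhat.
* The 90 %-VAF order-selection rule is blind to synergies holding less
  than ~10 % of uncentered variance — a property of the criterion, not of
  the optimizer.
* Greedy matching can differ from optimal assignment when several
  templates correlate similarly; the Hungarian option exists for those
  cases.
* `gap_select_k` on heterogeneous real pools (subject-specific NMF noise)
  tends to over-segment relative to the planted count; on controlled
  pools with separation/spread ≥ 5 it recovers the planted k in ≥ 19/20
  seeds.
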