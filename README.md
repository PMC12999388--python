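# emgsyn

Muscle-synergy extraction and intermuscular time-frequency coherence
analysis for multi-channel surface EMG, with a synthetic-cohort generator
that provides known ground truth for every stage of the pipeline.

## The problem

During a fast whole-body movement such as a badminton smash, the nervous
system is thought to coordinate dozens of muscles through a small number of
**muscle synergies**: modules in which a fixed muscle-weighting pattern is
driven by a time-varying activation profile. Two complementary views of
this coordination are

* **synergy structure** — how many modules are active and which muscles
  each one recruits, and
* **intermuscular coherence** — frequency-band-specific correlation between
  muscle pairs' rectified-EMG envelopes, read as shared neural drive in the
  α (8–15 Hz), β (15–30 Hz) and γ (30–50 Hz) bands.

`emgsyn` implements the full analysis chain used to compare these measures
across three intervention conditions (SG, RBG, ESG) in a repeated-measures
design, and — because raw human EMG of this kind is rarely shared — a
generator of realistic synthetic cohorts in which both the synergy
structure and the planted common drive are known exactly.

## The model

The 14-muscle activation envelope matrix `D` (muscles × 100 normalized
time points) is factorized by non-negative matrix factorization:

    D(t) ≈ Σ_{i=1..Nsyn} C_i(t) · W_i

with time-invariant weight vectors `W_i ≥ 0` and activation coefficients
`C_i(t) ≥ 0`, fit by multiplicative updates from 50 random initializations
(initialized Uniform(0, max D); best-VAF solution kept). The model order
`Nsyn` is the smallest number of synergies whose variance accounted for

    VAF = 1 − SSE / SST            (SST uncentered: Σ D²)

exceeds 0.9, scanning 1–14 synergies.

Group-level synergy **templates** are found by pooling all subjects' weight
vectors within a condition and running K-means (squared-Euclidean, 1000
restarts) with the cluster count chosen by the Gap statistic
(one-standard-error rule, uniform reference sets). Templates of the
non-reference conditions are matched one-to-one to the SG reference by
descending Pearson `r` with `r ≥ 0.6` required; leftovers are
condition-specific.

**Time-frequency coherence** between two 10 ms moving-RMS envelopes is
estimated from Hamming-windowed STFT segments (200 samples, 75 % overlap)
whose cross- and auto-spectra are smoothed by a 5×5 2-D kernel `v`:

    C_xy(l, f) = |P̂_xy ⊗ v|² / ((P̂_xx ⊗ v) · (P̂_yy ⊗ v))  ∈ [0, 1]

The per-band **AZ** value is the fraction of a band's time-frequency bins
exceeding the coherence confidence bound `1 − α^{1/(L−1)}`, with the
effective segment count `L` calibrated against the estimator's Monte-Carlo
null (see `docs/methods.md`).

Condition comparisons route through Shapiro–Wilk: normal metrics get
repeated-measures ANOVA (Greenhouse–Geisser when sphericity fails) with
Bonferroni-corrected paired t-tests; non-normal metrics get Friedman with
Holm-corrected Wilcoxon signed-rank tests and effect size `r = |Z|/√n`.

## Worked example

```python
from emgsyn import RunConfig, run_all

cfg = RunConfig(out_dir="demo", seed=7, n_subjects=6, trials_per_subject=2,
                kmeans_reps=200, gap_refs=30)
report = run_all(cfg)
print({g: s["display"] for g, s in report["nsyn_group_summaries"].items()})
```

prints

```
{'SG': '3.00 ± 0.00', 'RBG': '5.00 ± 0.00', 'ESG': '2.17 ± 0.41'}
```

— the per-condition synergy counts (mean ± SD across the six synthetic
subjects) recovered by the full chain from raw synthetic EMG. The default
generator plants 3 synergies in SG, 5 in RBG and 2 in ESG, so the recovered
ordering RBG > SG > ESG reflects the planted structure. The same report
carries the template matches (e.g. three RBG templates matched to the SG
reference at `r ≈ 0.85–0.89`, two flagged group-specific), the per-band AZ
table (here β-band AZ ≈ 0.19 for the drive-coupled BB–LD pair against
≈ 0.06 for the uncoupled DEL–ABS pair in SG), and the omnibus statistics
(synergy counts: Friedman χ² = 10.0, p = 0.007).

The same stages are available as a CLI:

```sh
emgsyn synth --out cohort --seed 42 --subjects 6 --trials 2
emgsyn validate cohort/manifest.json
emgsyn run-all --seed 42 --out run
```

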