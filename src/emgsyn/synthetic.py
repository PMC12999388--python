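"""Synthetic EMG cohorts with known ground truth.

The generator plants a low-rank synergy structure (non-negative muscle
weight vectors times Gaussian-bump activation profiles), renders raw EMG as
an amplitude-modulated band-limited Gaussian carrier, and can inject a
shared band-limited amplitude modulation into muscle pairs so that
intermuscular coherence in a chosen frequency band is known by
construction.  Every stage is deterministic given its seed.

Default cohort shape mirrors a three-condition crossover study: 18 subjects,
three intervention conditions, five strokes each.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from scipy import signal

from .io import (EMGRecording, MUSCLES, PhaseEvents, write_events,
                 write_manifest, write_trial)

#: Frequency bands (Hz) of presumed shared neural drive.
BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 50.0),
}

_COS_LIMIT = 0.9
_MAX_RETRIES = 500


@dataclass
class GroundTruth:
    """Planted generative parameters for one trial."""

    weights_true: np.ndarray       # (K_true x M), rows max-normalized
    activations_true: np.ndarray   # (K_true x T_cycle)
    coherence_plan: list[tuple[tuple[str, str], str, float]] = field(
        default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights_true = np.asarray(self.weights_true, dtype=float)
        self.activations_true = np.asarray(self.activations_true, dtype=float)
        if (self.weights_true < 0).any() or (self.activations_true < 0).any():
            raise ValueError("ground-truth factors must be non-negative")
        if not np.allclose(self.weights_true.max(axis=1), 1.0):
            raise ValueError("weight rows must be max-normalized")
        for (_, band, coupling) in self.coherence_plan:
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}")
            if not 0.0 <= coupling <= 1.0:
                raise ValueError(f"coupling {coupling} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_jsonable(self) -> dict[str, Any]:
        return {
            "weights_true": self.weights_true.tolist(),
            "activations_true": self.activations_true.tolist(),
            "coherence_plan": [
                {"pair": list(p), "band": b, "coupling": c}
                for p, b, c in self.coherence_plan],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


@dataclass
class SyntheticTrial:
    recording: EMGRecording
    events: PhaseEvents
    mvc: EMGRecording
    truth: GroundTruth


def make_weights(n_muscles: int, n_synergies: int, dominant_per_synergy: int,
                 seed: int,
                 exclude_dominant: Sequence[int] = ()) -> np.ndarray:
    """Random synergy weight rows with a few dominant muscles each.

    Per row, ``dominant_per_synergy`` muscles get weights in [0.6, 1]
    rescaled so the largest is exactly 1; the rest are small (< 0.15).  Rows
    too similar (cosine >= 0.9) to an earlier row are resampled.
    ``exclude_dominant`` lists muscle indices barred from the dominant set
    (used by coupled-pair constructions where a muscle's envelope must stay
    free of strong synergy bursts).
    """
    if dominant_per_synergy > n_muscles:
        raise ValueError("dominant_per_synergy exceeds n_muscles")
    if n_synergies > n_muscles:
        raise ValueError("n_synergies exceeds n_muscles")
    allowed = [i for i in range(n_muscles) if i not in set(exclude_dominant)]
    if len(allowed) < dominant_per_synergy:
        raise ValueError("too few muscles left after exclusion")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    used: set[int] = set()
    attempts = 0
    while len(rows) < n_synergies:
        if attempts > _MAX_RETRIES:
            raise RuntimeError(
                f"could not draw {n_synergies} distinct weight rows "
                f"(cos < {_COS_LIMIT}) within {_MAX_RETRIES} attempts")
        attempts += 1
        row = rng.uniform(0.0, 0.15, size=n_muscles)
        # prefer muscles not yet dominated by an earlier synergy, so each
        # module keeps a distinct dominant muscle group (and with it a
        # non-negligible share of signal variance)
        fresh = [i for i in allowed if i not in used]
        rng.shuffle(fresh)
        stale = [i for i in allowed if i in used]
        rng.shuffle(stale)
        dom = np.array((fresh + stale)[:dominant_per_synergy])
        dom_vals = rng.uniform(0.6, 1.0, size=dominant_per_synergy)
        row[dom] = dom_vals / dom_vals.max()
        if any(_cosine(row, r) >= _COS_LIMIT for r in rows):
            continue
        rows.append(row)
        used.update(int(i) for i in dom)
    return np.vstack(rows)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def make_activations(n_synergies: int, n_points: int,
                     centers: Sequence[float], widths: Sequence[float],
                     seed: int = 0, baseline: float = 0.0) -> np.ndarray:
    """Gaussian-bump activation profiles on the normalized cycle t in [0, 1).

    Row i peaks (value 1) at ``centers[i]``; ``baseline`` adds a small
    constant floor.  The grid is t_j = j / n_points so integer-percent
    centers land exactly on grid nodes.
    """
    if len(centers) != n_synergies or len(widths) != n_synergies:
        raise ValueError("centers and widths must have length n_synergies")
    t = np.arange(n_points) / n_points
    rows = [np.exp(-(t - c) ** 2 / (2.0 * w ** 2)) + baseline
            for c, w in zip(centers, widths)]
    return np.vstack(rows)


def synthesize_envelope(truth: GroundTruth) -> np.ndarray:
    """Noisy low-rank envelope D = sum_i outer(W_i, C_i) + N(0, sd), clipped
    at zero; shape (muscles x time)."""
    W, C = truth.weights_true, truth.activations_true
    if W.shape[0] != C.shape[0]:
        raise ValueError("weights and activations disagree on synergy count")
    D = W.T @ C
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        D = D + rng.normal(0.0, truth.noise_sd, size=D.shape)
    return np.clip(D, 0.0, None)


def synthesize_raw_emg(envelope: np.ndarray, fs: float = 2000.0,
                       carrier_low: float = 20.0, carrier_high: float = 400.0,
                       seed: int = 0, duration_s: float = 1.0,
                       channels: Sequence[str] | None = None) -> EMGRecording:
    """Render raw EMG: per-channel band-limited unit-RMS Gaussian carrier
    multiplied by the envelope upsampled (linear) to the sampling rate."""
    envelope = np.asarray(envelope, dtype=float)
    if not 0 < carrier_low < carrier_high < fs / 2:
        raise ValueError(f"carrier band ({carrier_low}, {carrier_high}) "
                         f"invalid for fs={fs}")
    m, t_env = envelope.shape
    if channels is None:
        channels = list(MUSCLES[:m])
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    sos = signal.butter(4, [carrier_low, carrier_high], btype="bandpass",
                        fs=fs, output="sos")
    t_src = np.linspace(0.0, duration_s, t_env)
    t_dst = np.arange(n) / fs
    data = np.empty((m, n))
    for i in range(m):
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
        rms = np.sqrt(np.mean(carrier ** 2))
        carrier /= max(rms, np.finfo(float).tiny)
        env_up = np.interp(t_dst, t_src, envelope[i])
        data[i] = env_up * carrier
    return EMGRecording(channels=list(channels), data=data, fs=fs,
                        meta={"seed": seed})


def inject_common_drive(rec: EMGRecording, pair: tuple[str, str], band: str,
                        coupling: float, seed: int = 0) -> EMGRecording:
    """Multiply both channels of ``pair`` by an identical band-limited
    amplitude modulation 1 + coupling * d(t), |d| <= 1.

    The drive lives in the amplitude envelope (the quantity rectified-EMG
    coherence tracks), not in the carrier.  The drive is normalized to RMS
    0.5 so ``coupling=1`` means near-full amplitude modulation while the
    factor stays essentially positive (the rare negative excursion is
    clipped to zero).  All other channels are returned untouched;
    ``coupling=0`` is the identity.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; choose from {list(BANDS)}")
    if not 0.0 <= coupling <= 1.0:
        raise ValueError(f"coupling {coupling} outside [0, 1]")
    idx = [rec.channels.index(c) if c in rec.channels else None for c in pair]
    if None in idx:
        missing = [c for c, i in zip(pair, idx) if i is None]
        raise KeyError(f"unknown channel code(s) {missing}")
    out = rec.with_data(rec.data.copy())
    if coupling == 0.0:
        return out
    rng = np.random.default_rng(seed)
    lo, hi = BANDS[band]
    # Strict band limitation (hard spectral mask): coherence is
    # amplitude-invariant, so even a gentle filter skirt would cohere
    # outside the nominal band.  The mask is additionally inset from each
    # band edge (3 Hz, capped at 20% of the band width) so that spectral
    # leakage through a 100 ms analysis window stays inside the band.
    inset = min(3.0, 0.2 * (hi - lo))
    lo, hi = lo + inset, hi - inset
    spec = np.fft.rfft(rng.standard_normal(rec.n_samples))
    f = np.fft.rfftfreq(rec.n_samples, 1.0 / rec.fs)
    spec[(f < lo) | (f >= hi)] = 0.0
    drive = np.fft.irfft(spec, n=rec.n_samples)
    drive *= 0.5 / max(np.sqrt(np.mean(drive ** 2)), np.finfo(float).tiny)
    factor = np.clip(1.0 + coupling * drive, 0.0, None)
    for i in idx:
        out.data[i] = out.data[i] * factor
    return out


# --- cohort generation -----------------------------------------------------

#: Phase-boundary positions as fractions of the stroke cycle
#: (movement / take-off / backswing / ball-strike).
_PHASE_FRACTIONS = (0.0, 0.30, 0.50, 0.75, 1.0)

_DEFAULT_WIDTH = 0.05


def _default_centers(k: int) -> np.ndarray:
    """Sequential phase-locked activation peaks spread across the cycle."""
    return np.linspace(0.12, 0.88, k)


@dataclass
class GroupSpec:
    """Generative parameters for one intervention condition."""

    name: str
    k_true: int
    noise_sd: float = 0.02
    coherence_plan: list[tuple[tuple[str, str], str, float]] = field(
        default_factory=list)
    dominant_per_synergy: int = 3
    #: tonic activation floor (fraction of bump peak); zero by default so
    #: the 90%-VAF order-selection criterion sees undiluted synergy variance
    baseline: float = 0.0


def _subject_truth(spec: GroupSpec, n_muscles: int, n_points: int,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    weights = make_weights(n_muscles, spec.k_true, spec.dominant_per_synergy,
                           seed)
    centers = _default_centers(spec.k_true).tolist()
    widths = [_DEFAULT_WIDTH] * spec.k_true
    acts = make_activations(spec.k_true, n_points, centers, widths, seed,
                            baseline=spec.baseline)
    return weights, acts


def make_trial(spec: GroupSpec, seed: int, *, n_points: int = 100,
               fs: float = 2000.0, duration_s: float = 1.0,
               center_jitter: float = 0.02,
               weights: np.ndarray | None = None) -> SyntheticTrial:
    """One synthetic stroke trial (recording + events + MVC + truth)."""
    rng = np.random.default_rng(seed)
    m = len(MUSCLES)
    if weights is None:
        weights, _ = _subject_truth(spec, m, n_points, seed)
    k = weights.shape[0]
    centers = _default_centers(k) + rng.uniform(
        -center_jitter, center_jitter, size=k)
    acts = make_activations(k, n_points, centers.tolist(),
                            [_DEFAULT_WIDTH] * k, seed,
                            baseline=spec.baseline)
    truth = GroundTruth(weights_true=weights, activations_true=acts,
                        coherence_plan=list(spec.coherence_plan),
                        noise_sd=spec.noise_sd,
                        seed=int(rng.integers(2 ** 31 - 1)))
    env = synthesize_envelope(truth)

    # pad the stroke cycle with 5% quiet baseline on each side
    pad = max(1, n_points // 20)
    padded = np.concatenate(
        [np.full((m, pad), 0.01), env, np.full((m, pad), 0.01)], axis=1)
    total_s = duration_s * padded.shape[1] / n_points
    rec = synthesize_raw_emg(padded, fs=fs, seed=int(rng.integers(2 ** 31 - 1)),
                             duration_s=total_s)
    for pair, band, coupling in spec.coherence_plan:
        rec = inject_common_drive(rec, tuple(pair), band, coupling,
                                  seed=int(rng.integers(2 ** 31 - 1)))

    n = rec.n_samples
    cyc0 = int(round(pad / padded.shape[1] * n))
    cyc1 = int(round((pad + n_points) / padded.shape[1] * n)) - 1
    marks = [cyc0 + int(round(f * (cyc1 - cyc0))) for f in _PHASE_FRACTIONS]
    events = PhaseEvents(*marks)

    # MVC: sustained contraction at each muscle's peak task amplitude
    mvc_level = np.maximum(env.max(axis=1), 0.05)[:, None]
    mvc_env = np.repeat(mvc_level, 50, axis=1)
    mvc = synthesize_raw_emg(mvc_env, fs=fs,
                             seed=int(rng.integers(2 ** 31 - 1)),
                             duration_s=1.0)
    return SyntheticTrial(recording=rec, events=events, mvc=mvc, truth=truth)


def make_coupled_pair_trial(pair: tuple[str, str], band: str, coupling: float,
                            seed: int, k_true: int = 3,
                            noise_sd: float = 0.02, tonic_level: float = 0.3,
                            **trial_kwargs: Any) -> SyntheticTrial:
    """Trial purpose-built for band-specificity experiments.

    The two coupled muscles hold a sustained contraction at
    ``tonic_level`` (the classical condition for intermuscular-coherence
    measurements) instead of carrying phasic synergy bursts; the planted
    band-limited drive is then the pair's only strong shared signal, and
    coherence outside the planted band is attributable to the estimator,
    not the construction.  The remaining channels carry the usual synergy
    structure.
    """
    spec = GroupSpec("PAIR", k_true=k_true, noise_sd=noise_sd,
                     coherence_plan=[(tuple(pair), band, coupling)])
    exclude = [MUSCLES.index(c) for c in pair]
    weights = make_weights(len(MUSCLES), k_true, spec.dominant_per_synergy,
                           seed, exclude_dominant=exclude)
    weights = weights.copy()
    # steady contraction: flat weight column -> envelope = tonic floor only
    weights[:, exclude] = 0.0
    trial = make_trial(spec, seed, weights=_renorm_rows(weights),
                       **trial_kwargs)
    rng = np.random.default_rng(seed + 1)
    n = trial.recording.n_samples
    carrier_sos = signal.butter(4, [20.0, 400.0], btype="bandpass",
                                fs=trial.recording.fs, output="sos")
    for code in pair:
        i = trial.recording.channels.index(code)
        carrier = signal.sosfiltfilt(carrier_sos, rng.standard_normal(n))
        carrier /= max(np.sqrt(np.mean(carrier ** 2)),
                       np.finfo(float).tiny)
        trial.recording.data[i] = tonic_level * carrier
    out = trial.recording
    for p, b, c in spec.coherence_plan:
        out = inject_common_drive(out, tuple(p), b, c,
                                  seed=int(rng.integers(2 ** 31 - 1)))
    return SyntheticTrial(recording=out, events=trial.events,
                          mvc=trial.mvc, truth=trial.truth)


def _renorm_rows(W: np.ndarray) -> np.ndarray:
    scale = W.max(axis=1)
    scale[scale == 0] = 1.0
    return W / scale[:, None]


def generate_cohort(outdir: str | Path, n_subjects: int = 18,
                    groups: Sequence[GroupSpec] | None = None,
                    trials_per_subject: int = 5, seed: int = 0,
                    shared_templates: bool = True,
                    template_jitter_sd: float = 0.06,
                    **trial_kwargs: Any) -> dict[str, Any]:
    """Write a full synthetic cohort to ``outdir`` and return its manifest.

    Crossover design: every subject appears in every group.  With
    ``shared_templates`` (the default) one master template set is drawn per
    cohort and condition g uses its first K_g templates -- motor modules
    are conserved across subjects and interventions, as in pooled
    template clustering -- with per-subject weight jitter
    (``template_jitter_sd``); otherwise weight vectors are drawn
    independently per (subject, group).  Activation timing jitters per
    trial.  Deterministic for a fixed seed.
    """
    if groups is None:
        groups = default_groups()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(seed)
    master: np.ndarray | None = None
    if shared_templates:
        k_master = max(g.k_true for g in groups)
        master = make_weights(len(MUSCLES), k_master,
                              groups[0].dominant_per_synergy,
                              int(root_rng.integers(2 ** 31 - 1)))
    trials: list[dict[str, Any]] = []
    for gi, spec in enumerate(groups):
        for si in range(n_subjects):
            sub_seed = int(root_rng.integers(2 ** 31 - 1))
            if master is not None:
                sub_rng = np.random.default_rng(sub_seed)
                weights = np.clip(
                    master[:spec.k_true]
                    + sub_rng.normal(0.0, template_jitter_sd,
                                     size=(spec.k_true, len(MUSCLES))),
                    0.0, None)
                weights = _renorm_rows(weights)
            else:
                weights, _ = _subject_truth(spec, len(MUSCLES), 100,
                                            sub_seed)
            mvc_path = None
            for ti in range(trials_per_subject):
                trial_seed = int(root_rng.integers(2 ** 31 - 1))
                trial = make_trial(spec, trial_seed, weights=weights,
                                   **trial_kwargs)
                stem = f"sub{si + 1:02d}_{spec.name}_t{ti + 1:02d}"
                trial.recording.meta.update(
                    subject_id=f"sub{si + 1:02d}", group=spec.name,
                    trial_index=ti + 1, seed=trial_seed)
                write_trial(outdir / f"{stem}.tsv", trial.recording)
                write_events(outdir / f"{stem}_events.json", trial.events)
                if mvc_path is None:
                    mvc_path = f"sub{si + 1:02d}_{spec.name}_mvc.tsv"
                    trial.mvc.meta.update(subject_id=f"sub{si + 1:02d}",
                                          group=spec.name, kind="mvc")
                    write_trial(outdir / mvc_path, trial.mvc)
                trials.append({
                    "path": f"{stem}.tsv",
                    "events_path": f"{stem}_events.json",
                    "mvc_path": mvc_path,
                    "subject": f"sub{si + 1:02d}",
                    "group": spec.name,
                    "trial_index": ti + 1,
                    "truth": trial.truth.to_jsonable(),
                })
    manifest = {
        "seed": seed,
        "fs_hz": trial_kwargs.get("fs", 2000.0),
        "muscles": list(MUSCLES),
        "groups": [{"name": g.name, "k_true": g.k_true,
                    "noise_sd": g.noise_sd} for g in groups],
        "n_subjects": n_subjects,
        "trials_per_subject": trials_per_subject,
        "trials": trials,
    }
    write_manifest(outdir / "manifest.json", manifest)
    return manifest


def default_groups() -> list[GroupSpec]:
    """Three-condition crossover defaults: squat (SG), resistance band
    (RBG), electrical stimulation (ESG), with a beta-band trunk-upper-limb
    drive planted in every condition."""
    plan = [(("BB", "LD"), "beta", 0.6)]
    return [
        GroupSpec("SG", k_true=3, coherence_plan=list(plan)),
        GroupSpec("RBG", k_true=5, coherence_plan=list(plan)),
        GroupSpec("ESG", k_true=2, coherence_plan=list(plan)),
    ]
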