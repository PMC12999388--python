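"""Surface-EMG conditioning chain.

The amplitude path follows the standard linear-envelope recipe: 20-400 Hz
fourth-order Butterworth bandpass, full-wave rectification, 20 Hz
fourth-order low-pass smoothing, amplitude normalization to a per-muscle
reference (MVC peak), segmentation of the stroke cycle by kinematic events,
and linear interpolation onto a 100-point normalized time axis.

The coherence path shares the bandpass/rectification front end but keeps the
full sampling rate, replacing the low-pass stage with a 10 ms moving-RMS
envelope so that band-limited (8-50 Hz) common drive survives.

All filtering is zero-phase (forward-backward second-order sections); the
stated order is the design order of the single pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .io import EMGRecording, PhaseEvents

N_POINTS = 100


@dataclass
class EnvelopeMatrix:
    """Normalized activation envelopes on the 100-point cycle axis.

    ``data`` is (channels x 100), non-negative; ``normalization`` records the
    per-channel reference each row was divided by; ``phase_marks`` maps each
    kinematic event to its index on the 100-point grid.  Values above 2.0
    after normalization are listed in ``flagged`` (supra-reference spikes).
    """

    channels: list[str]
    data: np.ndarray
    normalization: dict[str, float] = field(default_factory=dict)
    phase_marks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.channels), N_POINTS):
            raise ValueError(
                f"expected ({len(self.channels)}, {N_POINTS}), "
                f"got {self.data.shape}"
            )
        if (self.data < 0).any():
            raise ValueError("envelope values must be non-negative")

    @property
    def flagged(self) -> list[str]:
        return [c for c, row in zip(self.channels, self.data)
                if row.max() > 2.0]


def _sos_filtfilt(rec: EMGRecording, sos: np.ndarray) -> EMGRecording:
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def bandpass(rec: EMGRecording, low: float = 20.0, high: float = 400.0,
             order: int = 4) -> EMGRecording:
    """Zero-phase Butterworth bandpass; removes DC and motion artefact."""
    if not 0 < low < high < rec.fs / 2:
        raise ValueError(f"band ({low}, {high}) Hz invalid for fs={rec.fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                        output="sos")
    return _sos_filtfilt(rec, sos)


def rectify(rec: EMGRecording) -> EMGRecording:
    return rec.with_data(np.abs(rec.data))


def smooth_lowpass(rec: EMGRecording, cutoff: float = 20.0,
                   order: int = 4) -> EMGRecording:
    if not 0 < cutoff < rec.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz invalid for fs={rec.fs}")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=rec.fs,
                        output="sos")
    return _sos_filtfilt(rec, sos)


def normalize(rec: EMGRecording,
              reference: dict[str, float]) -> EMGRecording:
    """Divide each channel by its (positive) reference amplitude."""
    refs = []
    for code in rec.channels:
        r = reference[code]
        if not r > 0:
            raise ValueError(f"reference for {code} must be positive, got {r}")
        refs.append(r)
    out = rec.with_data(rec.data / np.asarray(refs)[:, None])
    out.meta["normalization"] = {c: float(reference[c]) for c in rec.channels}
    return out


def segment_cycle(rec: EMGRecording,
                  events: PhaseEvents) -> tuple[EMGRecording, PhaseEvents]:
    """Slice move_start..follow_through_end (inclusive both ends).

    Returns the segment plus the events re-expressed relative to its start.
    """
    events.validate_against(rec)
    a, e = events.move_start, events.follow_through_end
    seg = rec.with_data(rec.data[:, a:e + 1])
    shifted = PhaseEvents(*(v - a for v in events.as_tuple()))
    return seg, shifted


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def time_normalize(rec: EMGRecording,
                   events: PhaseEvents | None = None) -> EnvelopeMatrix:
    """Linear interpolation of each channel onto 100 equally spaced points.

    Phase boundaries are mapped proportionally onto the grid and rounded
    half-up.
    """
    n = rec.n_samples
    if n < 2:
        raise ValueError("segment too short to time-normalize")
    grid = np.linspace(0.0, n - 1, N_POINTS)
    data = np.vstack([np.interp(grid, np.arange(n), row)
                      for row in rec.data])
    marks: dict[str, int] = {}
    if events is not None:
        for name, idx in events.as_dict().items():
            marks[name] = _round_half_up(idx / (n - 1) * (N_POINTS - 1))
    norm = rec.meta.get("normalization", {})
    return EnvelopeMatrix(channels=list(rec.channels),
                          data=np.clip(data, 0.0, None),
                          normalization=dict(norm), phase_marks=marks)


def sliding_envelope(rec: EMGRecording, window_ms: float = 10.0) -> EMGRecording:
    """Centered moving-RMS envelope (reflective edges, same length)."""
    win = max(1, int(round(window_ms * 1e-3 * rec.fs)))
    if win > rec.n_samples:
        raise ValueError(
            f"{win}-sample window longer than {rec.n_samples}-sample signal"
        )
    ms = uniform_filter1d(rec.data ** 2, size=win, axis=1, mode="reflect")
    return rec.with_data(np.sqrt(np.clip(ms, 0.0, None)))


def mvc_reference(mvc_rec: EMGRecording, *, low: float = 20.0,
                  high: float = 400.0, order: int = 4,
                  cutoff: float = 20.0) -> dict[str, float]:
    """Per-muscle normalization reference: peak of the processed MVC envelope."""
    env = smooth_lowpass(rectify(bandpass(mvc_rec, low, high, order)),
                         cutoff, order)
    return {c: float(max(row.max(), np.finfo(float).tiny))
            for c, row in zip(env.channels, env.data)}


def process_trial(rec: EMGRecording, events: PhaseEvents,
                  reference: dict[str, float] | None = None,
                  config: dict[str, Any] | None = None) -> EnvelopeMatrix:
    """Full amplitude chain: bandpass -> rectify -> smooth -> normalize ->
    segment -> 100-point time normalization.

    ``reference`` is the per-muscle MVC peak; if None, falls back to each
    channel's within-trial maximum (``normalize.mode = trial_max``).
    """
    cfg = config or {}
    out = bandpass(rec, cfg.get("bandpass.low", 20.0),
                   cfg.get("bandpass.high", 400.0),
                   cfg.get("bandpass.order", 4))
    out = rectify(out)
    out = smooth_lowpass(out, cfg.get("smooth.cutoff", 20.0),
                         cfg.get("bandpass.order", 4))
    if reference is None:
        reference = {c: float(max(row.max(), np.finfo(float).tiny))
                     for c, row in zip(out.channels, out.data)}
    out = normalize(out, reference)
    seg, shifted = segment_cycle(out, events)
    return time_normalize(seg, shifted)


def coherence_input(rec: EMGRecording, events: PhaseEvents,
                    window_ms: float = 10.0,
                    config: dict[str, Any] | None = None) -> EMGRecording:
    """Coherence-path signal: bandpass -> rectify -> cycle segment -> 10 ms
    moving-RMS envelope, at the full sampling rate."""
    cfg = config or {}
    out = bandpass(rec, cfg.get("bandpass.low", 20.0),
                   cfg.get("bandpass.high", 400.0),
                   cfg.get("bandpass.order", 4))
    out = rectify(out)
    seg, _ = segment_cycle(out, events)
    return sliding_envelope(seg, cfg.get("envelope.window_ms", window_ms))
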