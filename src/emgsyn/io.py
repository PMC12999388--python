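"""Typed containers and on-disk formats for multi-channel surface EMG trials.

A trial is stored as a tab-separated matrix file (header row = muscle codes,
one row per sample) plus a JSON sidecar carrying the sampling rate and trial
metadata.  Kinematic phase events live in a separate JSON file of 0-based
sample indices.  A cohort manifest lists every trial with its provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

#: Canonical 14-muscle montage for the overhead-smash protocol: deltoid,
#: biceps/triceps brachii, brachioradialis, medial/lateral gastrocnemius,
#: vastus medialis/lateralis, biceps femoris, gluteus maximus, rectus
#: abdominis, latissimus dorsi, trapezius, pectoralis major.
MUSCLES = (
    "DEL", "BB", "TB", "BRD", "GM", "GL", "VM",
    "VL", "BF", "GLM", "ABS", "LD", "TRAP", "PM",
)

EVENT_NAMES = (
    "move_start", "takeoff", "backswing_start", "ball_contact",
    "follow_through_end",
)


class RaggedFileError(ValueError):
    """Matrix file whose rows do not all match the header width."""


@dataclass
class EMGRecording:
    """Multi-channel EMG: ``data`` is (channels x samples) at ``fs`` Hz."""

    channels: list[str]
    data: np.ndarray
    fs: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel codes must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, code: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(code)]
        except ValueError:
            raise KeyError(f"unknown channel code {code!r}") from None

    def with_data(self, data: np.ndarray) -> "EMGRecording":
        return replace(self, data=np.asarray(data, dtype=float),
                       channels=list(self.channels), meta=dict(self.meta))


@dataclass(frozen=True)
class PhaseEvents:
    """0-based sample indices delimiting the four stroke phases.

    movement: move_start..takeoff, take-off: takeoff..backswing_start,
    backswing: backswing_start..ball_contact,
    ball strike: ball_contact..follow_through_end.
    """

    move_start: int
    takeoff: int
    backswing_start: int
    ball_contact: int
    follow_through_end: int

    def __post_init__(self) -> None:
        seq = self.as_tuple()
        if any(int(v) != v or v < 0 for v in seq):
            raise ValueError("event indices must be non-negative integers")
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"events must be strictly increasing, got {seq}")

    def as_tuple(self) -> tuple[int, ...]:
        return (self.move_start, self.takeoff, self.backswing_start,
                self.ball_contact, self.follow_through_end)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(EVENT_NAMES, self.as_tuple()))

    def validate_against(self, rec: EMGRecording) -> None:
        if self.follow_through_end > rec.n_samples - 1:
            raise ValueError(
                f"event index {self.follow_through_end} outside recording "
                f"of {rec.n_samples} samples"
            )


def write_trial(path: str | Path, rec: EMGRecording) -> None:
    """Write the matrix file and its JSON sidecar (``<stem>.json``)."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channels)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    sidecar = {"fs_hz": rec.fs, **rec.meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trial(path: str | Path, *, strict_channels: bool = False) -> EMGRecording:
    """Read a tab-separated trial matrix and its JSON sidecar.

    Unknown muscle codes in the header produce a warning by default
    (``strict_channels=True`` raises instead).
    """
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    fs = meta.pop("fs_hz")

    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and line.rstrip("\n").count("\t") != len(header) - 1:
                raise RaggedFileError(
                    f"{path}:{lineno}: row width inconsistent with "
                    f"{len(header)}-column header")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise RaggedFileError(f"{path}: {exc}") from exc
    if df.shape[1] != len(header) or df.isna().any().any():
        raise RaggedFileError(
            f"{path}: rows inconsistent with {len(header)}-column header"
        )
    unknown = [c for c in header if c not in MUSCLES]
    if unknown:
        msg = f"{path}: unknown muscle codes {unknown}"
        if strict_channels:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return EMGRecording(channels=header, data=df.to_numpy().T, fs=fs, meta=meta)


def write_events(path: str | Path, events: PhaseEvents) -> None:
    Path(path).write_text(json.dumps(events.as_dict(), indent=1))


def read_events(path: str | Path) -> PhaseEvents:
    raw = json.loads(Path(path).read_text())
    missing = [k for k in EVENT_NAMES if k not in raw]
    if missing:
        raise ValueError(f"{path}: missing event keys {missing}")
    return PhaseEvents(**{k: int(raw[k]) for k in EVENT_NAMES})


def write_manifest(path: str | Path, manifest: dict[str, Any]) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1))


def read_manifest(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def validate_cohort(manifest_path: str | Path) -> dict[str, Any]:
    """Check that every manifest trial loads, with uniform fs and channels.

    Returns a report rather than raising; each failure names the offending
    path.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    root = manifest_path.parent
    failures: list[dict[str, str]] = []
    fs_seen: set[float] = set()
    channel_sets: set[tuple[str, ...]] = set()
    n_ok = 0
    for entry in manifest["trials"]:
        trial_path = root / entry["path"]
        try:
            rec = read_trial(trial_path)
            events = read_events(root / entry["events_path"])
            events.validate_against(rec)
        except Exception as exc:  # noqa: BLE001 - report, don't abort
            failures.append({"path": str(trial_path), "error": str(exc)})
            continue
        n_ok += 1
        fs_seen.add(rec.fs)
        channel_sets.add(tuple(rec.channels))
    return {
        "n_trials": len(manifest["trials"]),
        "n_ok": n_ok,
        "failures": failures,
        "fs_uniform": len(fs_seen) <= 1,
        "channels_uniform": len(channel_sets) <= 1,
    }
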