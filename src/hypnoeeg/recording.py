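"""Containers and I/O for single-channel EEG recordings.

A :class:`RawRecording` is one channel's sample series plus the metadata the
induction analysis needs: sampling rate, event marks (infusion start, loss of
consciousness, suppression onset) and artifact intervals.  Recordings are read
from EDF (via :mod:`mne`) or from plain two-column CSV files; events travel in
a sidecar CSV so that CSV recordings stay trivially inspectable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "Segment",
    "read_csv_recording",
    "read_edf_recording",
    "read_events",
    "write_csv_recording",
    "write_events",
]

#: canonical event labels
EVENT_LABELS = ("infusion_start", "loc", "suppression_onset")


@dataclass
class RawRecording:
    """One channel of EEG with sampling metadata, events and artifact marks.

    Parameters
    ----------
    channel_id : str
        Electrode label (the analysis uses Fp1).
    fs : float
        Sampling rate in Hz, strictly positive.
    samples : ndarray
        Amplitudes in microvolts.
    t0 : float
        Start time in seconds relative to infusion start.
    events : dict
        Label -> time in seconds (same clock as ``t0``).
    artifact_intervals : list of (start_s, end_s)
        Half-open intervals flagged as unusable.
    """

    channel_id: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0
    events: dict = field(default_factory=dict)
    artifact_intervals: list = field(default_factory=list)

    def __post_init__(self):
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        end = self.t0 + self.duration
        for label, t in self.events.items():
            if not (self.t0 - 1.0 / self.fs <= t <= end + 1.0 / self.fs):
                raise ValueError(
                    f"event {label!r} at {t} s outside recording "
                    f"[{self.t0}, {end}] s"
                )
        for a, b in self.artifact_intervals:
            if b < a:
                raise ValueError(f"artifact interval ({a}, {b}) has negative length")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def replace(self, **kw) -> "RawRecording":
        """Return a copy with fields replaced (samples are not copied)."""
        return dataclasses.replace(self, **kw)


@dataclass
class Segment:
    """A fixed-length 15 s analysis window aligned to the minute grid.

    ``minute_index`` is the integer minute relative to loss of consciousness
    (LOC): -2 and -1 before LOC, 0 the LOC minute itself, positive after.
    """

    subject_id: str
    start_s: float
    fs: float
    samples: np.ndarray
    minute_index: int
    segment_index: int
    clean: bool
    duration_s: float = 15.0

    def __post_init__(self):
        n_expected = self.duration_s * self.fs
        if abs(self.samples.size - n_expected) > 1:
            raise ValueError(
                f"segment has {self.samples.size} samples; expected "
                f"{n_expected:.1f} +- 1 for {self.duration_s} s at {self.fs} Hz"
            )


# ---------------------------------------------------------------------------
# readers / writers


def read_csv_recording(path, events_path=None, channel_id="Fp1") -> RawRecording:
    """Read a recording from a CSV with columns ``time_s`` and ``amplitude_uv``.

    The time column must be uniformly sampled; the sampling rate is inferred
    from the median step.  Events may be supplied in a sidecar CSV with
    columns ``label`` and ``time_s``.
    """
    df = pd.read_csv(path)
    if not {"time_s", "amplitude_uv"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, amplitude_uv")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or np.any(np.abs(steps - dt) > 0.01 * dt):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    fs = (t.size - 1) / (t[-1] - t[0])
    if abs(fs - round(fs)) < 0.01:  # snap to integer rates (89, 178, ...)
        fs = float(round(fs))
    events = read_events(events_path) if events_path is not None else {}
    return RawRecording(
        channel_id=channel_id,
        fs=fs,
        samples=df["amplitude_uv"].to_numpy(float),
        t0=float(t[0]),
        events=events,
    )


def read_edf_recording(path, channel="Fp1", events_path=None) -> RawRecording:
    """Read one channel from an EDF file (requires :mod:`mne`)."""
    import mne  # deferred: only needed for the EDF path

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = raw.ch_names
    matches = [c for c in names if channel.lower() in c.lower()]
    if not matches:
        raise ValueError(f"{path}: no channel matching {channel!r} in {names}")
    data = raw.get_data(picks=[matches[0]])[0] * 1e6  # volts -> microvolts
    events = read_events(events_path) if events_path is not None else {}
    return RawRecording(
        channel_id=matches[0], fs=float(raw.info["sfreq"]), samples=data, events=events
    )


def read_events(path) -> dict:
    df = pd.read_csv(path)
    if not {"label", "time_s"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns label, time_s")
    return {str(r.label): float(r.time_s) for r in df.itertuples()}


def write_csv_recording(rec: RawRecording, path) -> None:
    pd.DataFrame(
        {"time_s": np.round(rec.times, 6), "amplitude_uv": np.round(rec.samples, 4)}
    ).to_csv(path, index=False)


def write_events(events: dict, path) -> None:
    pd.DataFrame(
        {"label": list(events), "time_s": [events[k] for k in events]}
    ).to_csv(path, index=False)


def overlaps(a0: float, a1: float, intervals) -> bool:
    """True if [a0, a1) intersects any (start, end) interval."""
    return any(a0 < e and s < a1 for s, e in intervals)
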