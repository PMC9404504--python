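"""Preprocessing: sampling equalization, filtering, artifact marking, segmentation.

The recording dialects are 89 Hz (monitor-downsampled) and 178 Hz; all
recordings are brought to a common 89 Hz grid before analysis.  Filtering is
zero-phase (forward-backward second-order sections) so event timing is never
shifted.  The complexity/entropy measures are computed on a 25 Hz-lowpassed
copy, alpha power on an 8-12 Hz bandpassed copy, and spectral estimates on the
unfiltered (equalized) signal.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .recording import RawRecording, Segment, overlaps

__all__ = [
    "equalize_sampling",
    "lowpass_25",
    "bandpass_alpha",
    "detect_artifacts",
    "segment_15s",
    "minute_average",
]

TARGET_FS = 89.0
SEGMENT_S = 15.0
SEGMENTS_PER_MINUTE = 4


def equalize_sampling(rec: RawRecording, target_fs: float = TARGET_FS) -> RawRecording:
    """Resample a recording down to ``target_fs`` with anti-aliasing.

    The 178 -> 89 Hz path is an exact 2:1 polyphase decimation.  Upsampling is
    refused: the common grid must be the lowest rate in the cohort.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if rec.fs == target_fs:
        return rec
    if target_fs > rec.fs:
        raise ValueError(
            f"refusing to upsample {rec.fs} Hz -> {target_fs} Hz; equalization "
            "must decimate to the lowest cohort rate"
        )
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return rec.replace(fs=target_fs, samples=out)


def _sos_filtfilt(rec: RawRecording, sos) -> RawRecording:
    return rec.replace(samples=signal.sosfiltfilt(sos, rec.samples))


def lowpass_25(rec: RawRecording, cutoff_hz: float = 25.0, order: int = 4) -> RawRecording:
    """Fourth-order Butterworth lowpass (zero-phase) at 25 Hz."""
    if cutoff_hz >= rec.fs / 2:
        raise ValueError(
            f"lowpass cutoff {cutoff_hz} Hz >= Nyquist {rec.fs / 2} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.fs, output="sos")
    return _sos_filtfilt(rec, sos)


def bandpass_alpha(
    rec: RawRecording, lo_hz: float = 8.0, hi_hz: float = 12.0, order: int = 4
) -> RawRecording:
    """Fourth-order Butterworth 8-12 Hz bandpass (zero-phase)."""
    if hi_hz >= rec.fs / 2:
        raise ValueError(f"band edge {hi_hz} Hz >= Nyquist {rec.fs / 2} Hz")
    if not 0 < lo_hz < hi_hz:
        raise ValueError(f"invalid band ({lo_hz}, {hi_hz}) Hz")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="band", fs=rec.fs, output="sos")
    return _sos_filtfilt(rec, sos)


def detect_artifacts(
    rec: RawRecording,
    amp_thresh_uv: float = 250.0,
    grad_thresh_uv: float = 50.0,
    pad_s: float = 0.5,
) -> RawRecording:
    """Mark amplitude/gradient excursions as artifact intervals.

    A sample is suspect when its absolute amplitude exceeds ``amp_thresh_uv``
    or the absolute first difference exceeds ``grad_thresh_uv`` (per sample).
    Suspect runs are padded by ``pad_s`` on each side and merged.  This is an
    automated, conservative stand-in for per-segment visual inspection; the
    samples themselves are never modified.
    """
    if amp_thresh_uv <= 0 or grad_thresh_uv <= 0:
        raise ValueError("artifact thresholds must be positive")
    x = rec.samples
    bad = np.abs(x) > amp_thresh_uv
    if x.size > 1:
        grad_bad = np.abs(np.diff(x)) > grad_thresh_uv
        bad[:-1] |= grad_bad
        bad[1:] |= grad_bad
    intervals = []
    if bad.any():
        idx = np.flatnonzero(bad)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        end_t = rec.t0 + rec.duration
        for run in splits:
            a = max(rec.t0, rec.t0 + run[0] / rec.fs - pad_s)
            b = min(end_t, rec.t0 + (run[-1] + 1) / rec.fs + pad_s)
            if intervals and a <= intervals[-1][1]:
                intervals[-1] = (intervals[-1][0], max(intervals[-1][1], b))
            else:
                intervals.append((a, b))
    return rec.replace(artifact_intervals=intervals)


def segment_15s(
    rec: RawRecording,
    loc_time: float,
    end_minute: int,
    start_minute: int = -2,
    subject_id: str = "",
) -> list[Segment]:
    """Tile 15 s segments over minutes ``start_minute..end_minute`` around LOC.

    Each 1-min window relative to ``loc_time`` is split into 4 contiguous,
    non-overlapping 15 s segments.  Segments that overlap any artifact
    interval are flagged not clean; windows the recording cannot cover are
    omitted with a warning.
    """
    if not (rec.t0 <= loc_time <= rec.t0 + rec.duration):
        raise ValueError(f"LOC time {loc_time} s outside recording")
    if end_minute < start_minute:
        raise ValueError("end_minute before start_minute")
    nseg = int(round(SEGMENT_S * rec.fs))
    segments: list[Segment] = []
    missing = []
    for minute in range(start_minute, end_minute + 1):
        for k in range(SEGMENTS_PER_MINUTE):
            t_start = loc_time + 60.0 * minute + SEGMENT_S * k
            i0 = int(round((t_start - rec.t0) * rec.fs))
            i1 = i0 + nseg
            if i0 < 0 or i1 > rec.n:
                missing.append((minute, k))
                continue
            clean = not overlaps(t_start, t_start + SEGMENT_S, rec.artifact_intervals)
            segments.append(
                Segment(
                    subject_id=subject_id,
                    start_s=t_start,
                    fs=rec.fs,
                    samples=rec.samples[i0:i1],
                    minute_index=minute,
                    segment_index=k,
                    clean=clean,
                )
            )
    if missing:
        warnings.warn(
            f"recording covers only part of the requested window; "
            f"{len(missing)} segment(s) omitted (first: minute {missing[0][0]})",
            stacklevel=2,
        )
    return segments


def minute_average(values: pd.DataFrame) -> pd.DataFrame:
    """Average clean 15 s segment values within each minute.

    Parameters
    ----------
    values : DataFrame
        One row per segment with columns ``minute_index``, ``clean`` and one
        or more measure columns.

    Returns
    -------
    DataFrame indexed by ``minute_index`` covering the full observed minute
    range; minutes without any clean segment hold NaN.
    """
    required = {"minute_index", "clean"}
    if not required <= set(values.columns):
        raise ValueError(f"expected columns {required}")
    measures = [c for c in values.columns if c not in required]
    full_range = pd.RangeIndex(
        values["minute_index"].min(), values["minute_index"].max() + 1,
        name="minute_index",
    )
    clean = values[values["clean"].astype(bool)]
    out = clean.groupby("minute_index")[measures].mean()
    return out.reindex(full_range)
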