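"""End-to-end analysis: recordings -> segment measures -> stage table -> stats.

`analyze_subject` routes one recording through the measurement chain the way
the study describes: equalize to 89 Hz, mark artifacts, compute Lempel-Ziv
complexity and permutation entropy on the 25 Hz-lowpassed signal, alpha power
on the 8-12 Hz bandpassed signal, and Welch total power / SEF95 / band powers
on the unfiltered segments; average clean 15 s segments per minute; map the
five anesthesia stages.  `analyze_cohort` assembles the tidy stage table and
`cohort_statistics` runs the LOC t-tests and per-measure mixed ANOVAs.

`measures=` and `minutes="stages"` subset the work; replicated simulation
studies use them to compute only the quantity under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import measures as _m
from . import pk as _pk
from . import preprocess as _pp
from . import stages as _st
from . import stats as _stats
from .recording import RawRecording, read_csv_recording, read_events, \
    write_csv_recording, write_events

ALL_MEASURES = ("lzc", "pe", "alpha_power", "total_power", "sef95",
                "delta", "theta", "alpha", "beta")

#: measures the study's ANOVA layer analyses (surrogate BIS joins when present)
ANOVA_MEASURES = ("bis", "alpha_power", "lzc", "pe")


@dataclass
class PipelineConfig:
    """Knobs of the analysis chain (defaults = the study's settings)."""

    target_fs: float = 89.0
    lowpass_hz: float = 25.0
    alpha_band: tuple = (8.0, 12.0)
    amp_thresh_uv: float = 250.0
    grad_thresh_uv: float = 50.0
    measures: tuple = ALL_MEASURES
    pk_overrides: dict = field(default_factory=dict)
    pk_dt: float = 0.1
    sphericity_alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "target_fs": self.target_fs, "lowpass_hz": self.lowpass_hz,
            "alpha_band": list(self.alpha_band),
            "amp_thresh_uv": self.amp_thresh_uv,
            "grad_thresh_uv": self.grad_thresh_uv,
            "measures": list(self.measures),
            "pk_overrides": dict(self.pk_overrides), "pk_dt": self.pk_dt,
            "sphericity_alpha": self.sphericity_alpha,
        }


def segment_measure_table(
    rec: RawRecording,
    loc_time: float,
    end_minute: int,
    config: PipelineConfig = PipelineConfig(),
    minutes=None,
    subject_id: str = "",
) -> pd.DataFrame:
    """Per-15 s-segment measures for minutes -2..end_minute around LOC.

    ``minutes`` restricts computation to the given minute indices (e.g. the
    five stage minutes) without changing any value that is computed.
    """
    wanted = set(config.measures)
    rec_eq = _pp.equalize_sampling(rec, config.target_fs)
    rec_eq = _pp.detect_artifacts(rec_eq, config.amp_thresh_uv,
                                  config.grad_thresh_uv)
    need_lp = wanted & {"lzc", "pe"}
    need_alpha = "alpha_power" in wanted
    need_psd = wanted & {"total_power", "sef95", "delta", "theta", "alpha", "beta"}
    rec_lp = _pp.lowpass_25(rec_eq, config.lowpass_hz) if need_lp else None
    rec_al = _pp.bandpass_alpha(rec_eq, *config.alpha_band) if need_alpha else None

    segs_raw = _pp.segment_15s(rec_eq, loc_time, end_minute, subject_id=subject_id)
    rows = []
    for i, seg in enumerate(segs_raw):
        if minutes is not None and seg.minute_index not in minutes:
            continue
        i0 = int(round((seg.start_s - rec_eq.t0) * rec_eq.fs))
        i1 = i0 + seg.samples.size
        row = {"subject_id": subject_id, "minute_index": seg.minute_index,
               "segment_index": seg.segment_index, "clean": seg.clean}
        if need_lp:
            x = rec_lp.samples[i0:i1]
            if "lzc" in wanted:
                row["lzc"] = _m.lzc(x)
            if "pe" in wanted:
                row["pe"] = _m.permutation_entropy(_m.ordinal_patterns(x))
        if need_alpha:
            row["alpha_power"] = _m.alpha_power_hilbert(
                rec_al.samples[i0:i1], rec_eq.fs)
        if need_psd:
            psd = _m.welch_psd(seg.samples, seg.fs)
            if "total_power" in wanted:
                row["total_power"] = _m.total_power(psd)
            if "sef95" in wanted:
                row["sef95"] = _m.sef95(psd)
            for band in ("delta", "theta", "alpha", "beta"):
                if band in wanted:
                    row[band] = _m.band_power(psd, *_m.BANDS[band])
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_subject(
    rec: RawRecording,
    covariates: _pk.PatientCovariates,
    initial_rate: float,
    config: PipelineConfig = PipelineConfig(),
    stage_minutes_only: bool = False,
    subject_id: str = "",
    bis: pd.Series | None = None,
):
    """One subject: PK trajectory, stage windows, minute-averaged measures.

    Returns ``(per_minute_df, stage_windows)`` where the per-minute frame is
    indexed by minute relative to LOC.  Raises ``KeyError`` if the recording
    lacks a LOC event.
    """
    loc_time = rec.events["loc"]
    sr_onset = rec.events.get("suppression_onset")
    model = _pk.schnider_params(covariates, config.pk_overrides or None)
    schedule = _pk.protocol_schedule(covariates, sr_onset,
                                     initial_rate_young=initial_rate
                                     if not covariates.elderly else 22.5,
                                     elderly_rate=initial_rate)
    horizon = (sr_onset or rec.duration) + 900.0
    traj = _pk.simulate_pkpd(model, schedule, covariates.weight,
                             dt=config.pk_dt, horizon_s=horizon)
    cemax_minute, _ = _pk.find_cemax(traj, loc_time)
    # EEG can only support stages up to the last full recorded minute
    max_minute = int((rec.t0 + rec.duration - loc_time) // 60.0) - 1
    end_minute = min(cemax_minute, max(max_minute, 0))
    windows = _st.define_stages(0, end_minute)
    minutes = set(windows.minutes.values()) if stage_minutes_only else None
    seg_table = segment_measure_table(rec, loc_time, end_minute, config,
                                      minutes=minutes, subject_id=subject_id)
    per_minute = _pp.minute_average(
        seg_table.drop(columns=["subject_id", "segment_index"]))
    if bis is not None:
        per_minute = per_minute.join(bis.rename("bis"), how="left")
    return per_minute, windows


def analyze_cohort(
    subjects,
    config: PipelineConfig = PipelineConfig(),
    stage_minutes_only: bool = False,
    with_bis: bool = True,
    log=None,
    return_minutes: bool = False,
):
    """Tidy stage table for a cohort of :class:`SyntheticSubject`-like objects.

    Subjects whose recording lacks a LOC event are skipped with a logged
    reason.  With ``return_minutes=True`` also returns the long per-minute
    measure table.
    """
    minute_values, windows, ages = {}, {}, {}
    for subj in subjects:
        try:
            per_minute, sw = analyze_subject(
                subj.recording, subj.covariates, subj.initial_rate, config,
                stage_minutes_only=stage_minutes_only,
                subject_id=subj.subject_id,
                bis=subj.bis if with_bis and subj.bis is not None else None,
            )
        except KeyError as exc:
            if log is not None:
                log(f"skipping {subj.subject_id}: missing event {exc}")
            continue
        minute_values[subj.subject_id] = per_minute
        windows[subj.subject_id] = sw
        ages[subj.subject_id] = subj.covariates.age
    table = _st.build_stage_table(minute_values, windows, ages)
    if not return_minutes:
        return table
    minute_frames = [df.reset_index().assign(subject_id=sid)
                     for sid, df in minute_values.items()]
    minutes = (pd.concat(minute_frames, ignore_index=True)
               if minute_frames else pd.DataFrame())
    return table, minutes


def loc_ttest_table(stage_table: pd.DataFrame, variant: str = "student") -> pd.DataFrame:
    """Young-vs-elderly t-tests of every measure at the LOC stage."""
    loc = stage_table[stage_table["stage"] == "LOC"]
    rows = []
    for measure, sub in loc.groupby("measure"):
        young = sub.loc[sub["age_group"] == "young", "value"]
        old = sub.loc[sub["age_group"] == "elderly", "value"]
        res = _stats.ttest_independent(young, old, variant=variant)
        rows.append({
            "measure": measure,
            "young_mean": young.mean(), "young_sd": young.std(ddof=1),
            "elderly_mean": old.mean(), "elderly_sd": old.std(ddof=1),
            "t": res.t, "df": res.df, "p": res.p,
        })
    return pd.DataFrame(rows)


def cohort_statistics(
    stage_table: pd.DataFrame,
    measures=ANOVA_MEASURES,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Mixed ANOVA per measure plus the LOC comparison table."""
    present = [m for m in measures
               if m in set(stage_table["measure"])]
    anovas = {
        m: _stats.MixedAnova.from_stage_table(stage_table, m).fit(
            sphericity_alpha=config.sphericity_alpha)
        for m in present
    }
    return {"anova": anovas, "loc_ttest": loc_ttest_table(stage_table)}


# ---------------------------------------------------------------------------
# cohort file round-trip (CSV formats; EDF is read-only via mne)


def write_cohort(subjects, out_dir) -> None:
    """Write recordings, events, covariates and ground truth as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cov_rows, gt_rows, ev_rows, bis_rows = [], [], [], []
    for s in subjects:
        write_csv_recording(s.recording, out / f"{s.subject_id}_eeg.csv")
        s.trajectory.to_frame(step_s=1.0).round(5).to_csv(
            out / f"{s.subject_id}_trajectory.csv", index=False)
        for label, t in s.recording.events.items():
            ev_rows.append({"subject_id": s.subject_id, "label": label,
                            "time_s": t})
        cov_rows.append({
            "subject_id": s.subject_id, "age_years": s.covariates.age,
            "weight_kg": s.covariates.weight, "height_cm": s.covariates.height,
            "sex": s.covariates.sex, "age_group": s.group, "fs_hz": s.fs,
            "initial_rate_mg_kg_h": s.initial_rate,
        })
        gt_rows.append({"subject_id": s.subject_id,
                        "ce_loc_threshold": s.ce_loc_threshold,
                        "ce_sr_threshold": s.ce_sr_threshold,
                        "cemax_minute": s.cemax_minute, **s.ground_truth})
        for minute, value in s.bis.items():
            bis_rows.append({"subject_id": s.subject_id,
                             "minute_index": minute, "bis": value})
    pd.DataFrame(cov_rows).to_csv(out / "covariates.csv", index=False)
    pd.DataFrame(ev_rows).to_csv(out / "events.csv", index=False)
    pd.DataFrame(gt_rows).to_csv(out / "ground_truth.csv", index=False)
    pd.DataFrame(bis_rows).to_csv(out / "bis.csv", index=False)


@dataclass
class CohortSubject:
    """A subject reloaded from disk (ground truth not reattached)."""

    subject_id: str
    covariates: _pk.PatientCovariates
    initial_rate: float
    recording: RawRecording
    bis: pd.Series | None = None


def read_cohort(in_dir) -> list:
    """Reload a cohort written by :func:`write_cohort` (never the ground truth)."""
    root = Path(in_dir)
    cov = pd.read_csv(root / "covariates.csv")
    events = pd.read_csv(root / "events.csv")
    bis_path = root / "bis.csv"
    bis_all = pd.read_csv(bis_path) if bis_path.exists() else None
    subjects = []
    for row in cov.itertuples():
        rec = read_csv_recording(root / f"{row.subject_id}_eeg.csv")
        ev = events[events["subject_id"] == row.subject_id]
        rec.events.update({r.label: float(r.time_s) for r in ev.itertuples()})
        bis = None
        if bis_all is not None:
            sub = bis_all[bis_all["subject_id"] == row.subject_id]
            if not sub.empty:
                bis = pd.Series(sub["bis"].to_numpy(),
                                index=pd.Index(sub["minute_index"],
                                               name="minute_index"), name="bis")
        subjects.append(CohortSubject(
            subject_id=str(row.subject_id),
            covariates=_pk.PatientCovariates(
                age=row.age_years, weight=row.weight_kg,
                height=row.height_cm, sex=row.sex),
            initial_rate=float(row.initial_rate_mg_kg_h),
            recording=rec, bis=bis,
        ))
    return subjects
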