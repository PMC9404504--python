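"""Synthetic propofol-induction cohort: covariates, PK, events and EEG.

The generator emulates the features of the study data that the analysis
pipeline consumes, without claiming physiological realism:

* two age groups (young < 65, elderly >= 65) with group-specific infusion
  rates, Ce-at-LOC distributions, Ce-at-suppression distributions and total
  spectral power scales;
* EEG as 1/f-colored background noise plus a delta (0.5-4 Hz) component that
  rises monotonically with effect-site concentration, plus an alpha (8-12 Hz)
  component whose amplitude is a biphasic (Gaussian-bump) function of Ce;
* near-isoelectric suppression epochs once Ce exceeds the subject's
  suppression threshold, which is also what stops the infusion;
* the two sampling dialects (178 Hz, and 89 Hz with an extra built-in-monitor
  lowpass above 25 Hz);
* loss of consciousness at the first crossing of a subject-specific Ce
  threshold, quantized to the 30 s clinical assessment grid.

Group defaults follow the study's printed induction and spectral summaries
(young n=18 / elderly n=12; Ce at LOC 4.82+-1.39 vs 4.31+-0.48 ug/mL;
suppression near Ce 5.8 vs 8.0 ug/mL so the maximal Ce lands near 6.0 vs 8.3;
total power near 365 vs 59 uV^2).  One seed drives independent substreams for
covariates, thresholds and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _sig

from . import pk as _pk
from .recording import RawRecording

__all__ = ["GroupParams", "CohortSpec", "SyntheticSubject", "generate_cohort",
           "synth_eeg", "surrogate_bis"]


@dataclass
class GroupParams:
    """Generation parameters for one age group."""

    n: int
    age_range: tuple
    fs: float
    rate_range: tuple            # initial infusion rate draw, mg/kg/h
    ce_loc: tuple                # (mean, sd) ug/mL, truncated at ce_loc_min
    ce_sr: tuple                 # (mean, sd) ug/mL; suppression threshold
    total_power_uv2: float       # cohort-scale total power (< 30 Hz) at LOC
    total_power_log_sd: float    # lognormal spread of the per-subject target
    background_exponent: tuple   # (mean, sd) of the 1/f^chi exponent
    alpha_base: float            # baseline alpha amplitude (rel. to background sd)
    alpha_gain: float            # height of the biphasic alpha bump
    alpha_peak_ce: float         # Ce at which alpha power peaks, ug/mL
    alpha_width_ce: float        # bump width, ug/mL
    delta_base: float            # baseline delta amplitude
    delta_rise: float            # delta amplitude gain per ug/mL of Ce
    monitor_rolloff: bool        # extra >25 Hz lowpass (89 Hz dialect)
    bis_offset: float            # additive shift of the surrogate BIS series


def _young_defaults() -> GroupParams:
    return GroupParams(
        n=18, age_range=(19.0, 64.0), fs=178.0, rate_range=(20.0, 25.0),
        ce_loc=(4.82, 1.39), ce_sr=(5.8, 0.9),
        total_power_uv2=364.5, total_power_log_sd=0.55,
        background_exponent=(1.9, 0.12),
        alpha_base=0.02, alpha_gain=0.30, alpha_peak_ce=4.8, alpha_width_ce=1.8,
        delta_base=0.5, delta_rise=0.15,
        monitor_rolloff=False, bis_offset=0.0,
    )


def _elderly_defaults() -> GroupParams:
    return GroupParams(
        n=12, age_range=(65.0, 86.0), fs=89.0, rate_range=(15.0, 15.0),
        ce_loc=(4.31, 0.48), ce_sr=(8.0, 1.1),
        total_power_uv2=59.3, total_power_log_sd=0.27,
        background_exponent=(1.35, 0.12),
        alpha_base=0.03, alpha_gain=0.20, alpha_peak_ce=4.3, alpha_width_ce=1.8,
        delta_base=0.15, delta_rise=0.10,
        monitor_rolloff=True, bis_offset=15.0,
    )


@dataclass
class CohortSpec:
    """Full cohort specification; defaults are the study's group conditions."""

    young: GroupParams = field(default_factory=_young_defaults)
    elderly: GroupParams = field(default_factory=_elderly_defaults)
    seed: int = 0
    ce_loc_min: float = 2.5      # truncation so LOC leaves a 2-min pre-window
    ce_margin: float = 0.3       # enforced gap between LOC and SR thresholds
    pk_dt: float = 0.1           # trajectory grid step, s
    loc_grid_s: float = 30.0     # clinical LOC assessment cadence
    suppression_depth: float = 0.02   # amplitude factor inside suppression
    bis_noise_sd: float = 3.0

    def null(self, fs: float = 89.0) -> "CohortSpec":
        """A label-exchangeable variant: identical generation in both groups.

        Both groups share the young group's rates, thresholds, spectral
        parameters and the given sampling dialect; only the ages (hence the
        group label) differ.  Used for type-I-error calibration.
        """
        base = replace(self.young, fs=fs, monitor_rolloff=(fs == 89.0),
                       bis_offset=0.0)
        young = replace(base, n=self.young.n, age_range=self.young.age_range)
        elderly = replace(base, n=self.elderly.n, age_range=self.elderly.age_range)
        return replace(self, young=young, elderly=elderly)

    def with_lzc_effect(self, exponent_shift: float = -0.45) -> "CohortSpec":
        """Null variant plus a designed elderly complexity difference.

        Shifting the elderly background exponent down makes the elderly EEG
        relatively richer in high frequencies, raising its Lempel-Ziv
        complexity — the direction the study reports.
        """
        spec = self.null()
        mu, sd = spec.elderly.background_exponent
        return replace(
            spec,
            elderly=replace(spec.elderly,
                            background_exponent=(mu + exponent_shift, sd)),
        )


@dataclass
class SyntheticSubject:
    """Ground truth and generated data for one simulated patient."""

    subject_id: str
    covariates: _pk.PatientCovariates
    group: str
    fs: float
    initial_rate: float
    ce_loc_threshold: float
    ce_sr_threshold: float
    loc_time: float
    sr_onset_time: float
    cemax_minute: int            # relative to the LOC minute
    schedule: _pk.InfusionSchedule
    trajectory: _pk.ConcentrationTrajectory
    recording: RawRecording
    bis: pd.Series               # per-minute surrogate BIS, index = minute vs LOC
    ground_truth: dict


# ---------------------------------------------------------------------------
# signal building blocks


def _colored_noise(n, fs, exponent, rng, f_knee=1.0):
    """Unit-variance 1/f^exponent Gaussian noise via spectral shaping."""
    nf = n // 2 + 1
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.ones(nf)
    pos = freqs > 0
    amp[pos] = np.maximum(freqs[pos], f_knee) ** (-exponent / 2.0)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(nf) + 1j * rng.standard_normal(nf))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_noise(n, fs, lo, hi, rng):
    """Unit-variance Gaussian noise bandpassed to [lo, hi] Hz."""
    sos = _sig.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _suppression_mask(t, ce, threshold, rng, depth, cycle_s=6.0):
    """Amplitude mask with near-isoelectric epochs where Ce exceeds threshold.

    Above threshold the signal alternates bursts and suppressions; the
    suppressed fraction of each ~6 s cycle grows with the Ce overshoot, as a
    crude burst-suppression emulation.
    """
    mask = np.ones(t.size)
    above = np.flatnonzero(ce >= threshold)
    if above.size == 0:
        return mask
    fs = 1.0 / (t[1] - t[0])
    i = above[0]
    n = t.size
    while i < n:
        if ce[i] < threshold:
            i += int(round(cycle_s * fs))
            continue
        frac = float(np.clip(0.15 + 0.5 * (ce[i] - threshold), 0.05, 0.85))
        cyc = cycle_s * float(rng.uniform(0.7, 1.3))
        sup_n = int(round(frac * cyc * fs))
        cyc_n = max(int(round(cyc * fs)), sup_n + 1)
        mask[i : min(i + sup_n, n)] = depth
        i += cyc_n
    # soften edges so the gating itself does not look like a gradient artifact
    w = max(int(round(0.05 * fs)), 3)
    kernel = np.hanning(2 * w + 1)
    kernel /= kernel.sum()
    return np.convolve(mask, kernel, mode="same")


def synth_eeg(
    params: GroupParams,
    traj: _pk.ConcentrationTrajectory,
    duration_s: float,
    rng: np.random.Generator,
    exponent: float | None = None,
    total_power_target: float | None = None,
    ce_sr_threshold: float = np.inf,
    loc_time: float | None = None,
    suppression_depth: float = 0.02,
) -> RawRecording:
    """Generate one subject's EEG from their concentration trajectory.

    The signal is ``background + delta_env(Ce) * delta + alpha_env(Ce) * alpha``
    scaled so the LOC-minute total power (< 30 Hz) matches the subject's
    target, with suppression epochs above the suppression threshold and an
    optional monitor lowpass for the 89 Hz dialect.
    """
    fs = params.fs
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    ce = traj.ce_at(t)
    chi = params.background_exponent[0] if exponent is None else exponent

    background = _colored_noise(n, fs, chi, rng)
    delta = _band_noise(n, fs, 0.5, 4.0, rng)
    alpha = _band_noise(n, fs, 8.0, 12.0, rng)

    delta_env = params.delta_base + params.delta_rise * ce
    alpha_env = params.alpha_base + params.alpha_gain * np.exp(
        -((ce - params.alpha_peak_ce) ** 2) / (2.0 * params.alpha_width_ce**2)
    )
    x = background + delta_env * delta + alpha_env * alpha

    if params.monitor_rolloff:
        sos = _sig.butter(4, min(25.0, 0.45 * fs), btype="low", fs=fs, output="sos")
        x = _sig.sosfiltfilt(sos, x)

    # scale so total power (< 30 Hz) in the LOC minute hits the target
    if total_power_target is not None:
        anchor = loc_time if loc_time is not None else duration_s / 2.0
        i0 = int(np.clip(round(anchor * fs), 0, max(n - int(60 * fs), 0)))
        i1 = min(i0 + int(60 * fs), n)
        from .measures import total_power, welch_psd

        tp = total_power(welch_psd(x[i0:i1], fs))
        x = x * np.sqrt(total_power_target / tp)

    x = x * _suppression_mask(t, ce, ce_sr_threshold, rng, suppression_depth)
    events = {"infusion_start": 0.0}
    if loc_time is not None:
        events["loc"] = loc_time
    return RawRecording(channel_id="Fp1", fs=fs, samples=x, t0=0.0, events=events)


def surrogate_bis(
    traj: _pk.ConcentrationTrajectory,
    minutes: np.ndarray,
    loc_time: float,
    noise_sd: float = 3.0,
    rng: np.random.Generator | None = None,
    offset: float = 0.0,
    ceiling: float = 97.5,
    floor: float = 10.0,
    ec50: float = 6.0,
    gamma: float = 1.8,
) -> pd.Series:
    """Per-minute monotone sigmoid mapping of Ce to a 0-100 scale, plus noise.

    Pure plumbing: it exercises the table/statistics path the external
    monitor's index would travel, and the additive ``offset`` lets tests
    inject an age bias; it does not emulate the proprietary index itself.
    """
    values = []
    for m in minutes:
        sel = (traj.t >= loc_time + 60.0 * m) & (traj.t < loc_time + 60.0 * (m + 1))
        ce_m = traj.ce[sel].mean() if sel.any() else traj.ce[-1]
        bis = floor + (ceiling - floor) / (1.0 + (ce_m / ec50) ** gamma) + offset
        if rng is not None and noise_sd > 0:
            bis += rng.normal(0.0, noise_sd)
        values.append(float(np.clip(bis, 0.0, 100.0)))
    return pd.Series(values, index=pd.Index(minutes, name="minute_index"),
                     name="bis")


# ---------------------------------------------------------------------------
# cohort generation


def _draw_covariates(params: GroupParams, rng) -> tuple:
    age = float(rng.uniform(*params.age_range))
    sex = "male" if rng.random() < 0.733 else "female"
    height = float(rng.normal(172.0, 7.0) if sex == "male" else rng.normal(160.0, 7.0))
    height = float(np.clip(height, 145.0, 200.0))
    bmi = float(np.clip(rng.normal(26.5, 3.0), 18.5, 35.0))
    weight = round(bmi * (height / 100.0) ** 2, 1)
    return _pk.PatientCovariates(age=age, weight=weight, height=round(height, 1),
                                 sex=sex)


def _simulate_subject(sid, params: GroupParams, spec: CohortSpec, seedseq,
                      tp_target: float) -> SyntheticSubject:
    rng_param, rng_noise = (np.random.default_rng(s) for s in seedseq.spawn(2))
    cov = _draw_covariates(params, rng_param)
    ce_loc_thr = max(float(rng_param.normal(*params.ce_loc)), spec.ce_loc_min)
    ce_sr_thr = max(float(rng_param.normal(*params.ce_sr)),
                    ce_loc_thr + spec.ce_margin)
    rate0 = float(rng_param.uniform(*params.rate_range))
    chi = float(rng_param.normal(*params.background_exponent))

    model = _pk.schnider_params(cov)
    open_sched = _pk.protocol_schedule(cov, None, initial_rate_young=rate0,
                                       elderly_rate=rate0)
    # coarse probe to locate the suppression crossing (grid refined below)
    probe = _pk.simulate_pkpd(model, open_sched, cov.weight, dt=0.5,
                              horizon_s=3600.0)
    loc_probe = np.flatnonzero(probe.ce >= ce_loc_thr)
    if loc_probe.size == 0:
        raise RuntimeError(f"{sid}: Ce never reached the LOC threshold")
    loc_quant = float(np.ceil(probe.t[loc_probe[0]] / spec.loc_grid_s)
                      * spec.loc_grid_s)
    # suppression may not intrude into the LOC minute (the stop rule keeps
    # the analysis windows suppression-free); raise the threshold if needed
    min_sr_time = loc_quant + 90.0
    ce_floor = float(probe.ce_at(min_sr_time))
    ce_sr_thr = max(ce_sr_thr, ce_floor + 0.05)
    cross = np.flatnonzero(probe.ce >= ce_sr_thr)
    if cross.size == 0:
        raise RuntimeError(
            f"{sid}: Ce never reached the suppression threshold {ce_sr_thr:.2f}"
        )
    sr_onset = float(probe.t[cross[0]])
    schedule = _pk.protocol_schedule(cov, sr_onset, initial_rate_young=rate0,
                                     elderly_rate=rate0)
    traj = _pk.simulate_pkpd(model, schedule, cov.weight, dt=spec.pk_dt,
                             horizon_s=sr_onset + 900.0)

    loc_cross = np.flatnonzero(traj.ce >= ce_loc_thr)
    t_loc_raw = float(traj.t[loc_cross[0]])
    loc_time = float(np.ceil(t_loc_raw / spec.loc_grid_s) * spec.loc_grid_s)
    cemax_minute, ce_max = _pk.find_cemax(traj, loc_time)

    duration = min(
        max(sr_onset + 70.0, loc_time + 60.0 * (cemax_minute + 1) + 5.0),
        traj.t[-1],
    )
    rec = synth_eeg(
        params, traj, duration, rng_noise, exponent=chi,
        total_power_target=tp_target, ce_sr_threshold=ce_sr_thr,
        loc_time=loc_time, suppression_depth=spec.suppression_depth,
    )
    rec.events["suppression_onset"] = min(sr_onset, rec.duration)

    minutes = np.arange(-2, cemax_minute + 1)
    bis = surrogate_bis(traj, minutes, loc_time, noise_sd=spec.bis_noise_sd,
                        rng=rng_noise, offset=params.bis_offset)
    return SyntheticSubject(
        subject_id=sid, covariates=cov,
        group="elderly" if cov.elderly else "young",
        fs=params.fs, initial_rate=rate0,
        ce_loc_threshold=ce_loc_thr, ce_sr_threshold=ce_sr_thr,
        loc_time=loc_time, sr_onset_time=sr_onset, cemax_minute=cemax_minute,
        schedule=schedule, trajectory=traj, recording=rec, bis=bis,
        ground_truth={
            "background_exponent": chi,
            "total_power_target_uv2": tp_target,
            "ce_at_loc": float(traj.ce_at(loc_time)),
            "ce_max": ce_max,
        },
    )


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate the full synthetic cohort, reproducibly under ``spec.seed``."""
    if spec.young.n < 1 or spec.elderly.n < 1:
        raise ValueError("group sizes must be at least 1")
    root = np.random.SeedSequence(spec.seed)
    n_total = spec.young.n + spec.elderly.n
    seeds = root.spawn(n_total + 1)
    rng_tp = np.random.default_rng(seeds[n_total])

    def tp_targets(params):
        # lognormal spread anchored so the cohort mean hits the group scale
        mult = np.exp(rng_tp.normal(0.0, params.total_power_log_sd, params.n))
        return params.total_power_uv2 * mult / mult.mean()

    tp_young = tp_targets(spec.young)
    tp_elderly = tp_targets(spec.elderly)
    subjects = []
    for i in range(spec.young.n):
        subjects.append(_simulate_subject(f"Y{i + 1:02d}", spec.young, spec,
                                          seeds[i], tp_young[i]))
    for j in range(spec.elderly.n):
        subjects.append(
            _simulate_subject(f"E{j + 1:02d}", spec.elderly, spec,
                              seeds[spec.young.n + j], tp_elderly[j])
        )
    return subjects
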