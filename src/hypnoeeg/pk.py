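"""Propofol pharmacokinetics: Schnider covariate model and infusion simulation.

The Schnider model is a mammillary three-compartment model with an additional
first-order effect-site compartment, ``dCe/dt = ke0 * (Cp - Ce)``.  Covariate
equations (age on V2/Cl2; weight, height and James lean body mass on Cl1) use
the published constants; the clinically reported quantities are the effect-site
concentration at loss of consciousness and its post-infusion maximum (CeMax).

Default parameter set (overridable through :func:`schnider_params`)::

    V1 = 4.27 L                     Cl1 = 1.89 + 0.0456 (wt - 77)
    V2 = 18.9 - 0.391 (age - 53)          - 0.0681 (lbm - 59)
    V3 = 238 L                            + 0.0264 (ht - 177)  L/min
    Cl2 = 1.29 - 0.024 (age - 53)   Cl3 = 0.836 L/min
    ke0 = 0.456 / min

Simulation integrates the linear 4-state system exactly per piecewise-constant
infusion segment via eigendecomposition (matrix exponential); a fixed-step RK4
integrator is available as a cross-check (``method="rk4"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import RawRecording

__all__ = [
    "PatientCovariates",
    "PKModel",
    "InfusionSchedule",
    "ConcentrationTrajectory",
    "lbm_james",
    "schnider_params",
    "protocol_schedule",
    "simulate_pkpd",
    "find_cemax",
    "suppression_onset_surrogate",
]

#: default Schnider constants; keys may be overridden via ``schnider_params``
SCHNIDER_DEFAULTS = {
    "v1": 4.27,            # L
    "v2_ref": 18.9,        # L at age 53
    "v2_age_slope": -0.391,
    "v3": 238.0,           # L
    "cl1_ref": 1.89,       # L/min at wt 77, lbm 59, ht 177
    "cl1_wt_slope": 0.0456,
    "cl1_lbm_slope": -0.0681,
    "cl1_ht_slope": 0.0264,
    "cl2_ref": 1.29,       # L/min at age 53
    "cl2_age_slope": -0.024,
    "cl3": 0.836,          # L/min
    "ke0": 0.456,          # 1/min
}


def lbm_james(weight_kg: float, height_cm: float, sex: str) -> float:
    """James lean body mass (kg): the covariate the Schnider Cl1 equation uses."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    r = weight_kg / height_cm
    if sex == "male":
        lbm = 1.1 * weight_kg - 128.0 * r * r
    elif sex == "female":
        lbm = 1.07 * weight_kg - 148.0 * r * r
    else:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if lbm <= 0:
        raise ValueError(
            f"non-physiological covariates: James LBM <= 0 for "
            f"{weight_kg} kg / {height_cm} cm"
        )
    return lbm


@dataclass
class PatientCovariates:
    """Age (years), weight (kg), height (cm), sex; LBM derived via James."""

    age: float
    weight: float
    height: float
    sex: str
    lbm: float = field(init=False)

    def __post_init__(self):
        if not 18 <= self.age <= 110:
            raise ValueError(f"age {self.age} outside supported range [18, 110]")
        self.lbm = lbm_james(self.weight, self.height, self.sex)

    @property
    def elderly(self) -> bool:
        return self.age >= 65


@dataclass
class PKModel:
    """Compartment volumes (L), clearances (L/min), effect-site rate (1/min)."""

    v1: float
    v2: float
    v3: float
    cl1: float
    cl2: float
    cl3: float
    ke0: float

    def __post_init__(self):
        for name in ("v1", "v2", "v3", "cl1", "cl2", "cl3", "ke0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PK parameter {name} must be positive "
                                 f"(got {getattr(self, name)})")

    def system_matrix(self) -> np.ndarray:
        """State matrix (per second) for x = (a1, a2, a3 in mg; Ce in ug/mL)."""
        k10 = self.cl1 / self.v1
        k12 = self.cl2 / self.v1
        k21 = self.cl2 / self.v2
        k13 = self.cl3 / self.v1
        k31 = self.cl3 / self.v3
        a = np.array(
            [
                [-(k10 + k12 + k13), k21, k31, 0.0],
                [k12, -k21, 0.0, 0.0],
                [k13, 0.0, -k31, 0.0],
                [self.ke0 / self.v1, 0.0, 0.0, -self.ke0],
            ]
        )
        return a / 60.0  # per-minute rates -> per-second


def schnider_params(cov: PatientCovariates, overrides: dict | None = None) -> PKModel:
    """Schnider model parameters for one patient (config-overridable constants)."""
    c = dict(SCHNIDER_DEFAULTS)
    if overrides:
        unknown = set(overrides) - set(c)
        if unknown:
            raise ValueError(f"unknown Schnider overrides: {sorted(unknown)}")
        c.update(overrides)
    v2 = c["v2_ref"] + c["v2_age_slope"] * (cov.age - 53.0)
    cl1 = (
        c["cl1_ref"]
        + c["cl1_wt_slope"] * (cov.weight - 77.0)
        + c["cl1_lbm_slope"] * (cov.lbm - 59.0)
        + c["cl1_ht_slope"] * (cov.height - 177.0)
    )
    cl2 = c["cl2_ref"] + c["cl2_age_slope"] * (cov.age - 53.0)
    for name, val in (("V2", v2), ("Cl1", cl1), ("Cl2", cl2)):
        if val <= 0:
            raise ValueError(
                f"covariates drive {name} non-positive ({val:.3f}) for age "
                f"{cov.age}, weight {cov.weight}, height {cov.height}"
            )
    return PKModel(v1=c["v1"], v2=v2, v3=c["v3"], cl1=cl1, cl2=cl2, cl3=c["cl3"],
                   ke0=c["ke0"])


@dataclass
class InfusionSchedule:
    """Piecewise-constant infusion: [(start_s, rate_mg_kg_h), ...] + stop time."""

    segments: list
    stop_time: float | None = None

    def __post_init__(self):
        starts = [s for s, _ in self.segments]
        if starts != sorted(starts):
            raise ValueError("schedule segments must be ordered by start time")
        if any(r < 0 for _, r in self.segments):
            raise ValueError("infusion rates must be nonnegative")

    def rate_at(self, t: float) -> float:
        if self.stop_time is not None and t >= self.stop_time:
            return 0.0
        rate = 0.0
        for start, r in self.segments:
            if t >= start:
                rate = r
            else:
                break
        return rate

    def rates(self, t: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`rate_at` over a time grid."""
        starts = np.array([s for s, _ in self.segments])
        vals = np.array([r for _, r in self.segments])
        idx = np.searchsorted(starts, t, side="right") - 1
        out = np.where(idx >= 0, vals[np.clip(idx, 0, None)], 0.0)
        if self.stop_time is not None:
            out = np.where(t >= self.stop_time, 0.0, out)
        return out

    def breakpoints(self, horizon_s: float) -> list:
        bp = sorted({0.0, horizon_s}
                    | {s for s, _ in self.segments if 0.0 < s < horizon_s})
        if self.stop_time is not None and 0.0 < self.stop_time < horizon_s:
            bp = sorted(set(bp) | {self.stop_time})
        return bp


def protocol_schedule(
    cov: PatientCovariates,
    sr_onset_time: float | None = None,
    initial_rate_young: float = 22.5,
    elderly_rate: float = 15.0,
    escalation_mg_kg_h: float = 5.0,
    first_escalation_s: float = 600.0,
    escalation_interval_s: float = 300.0,
    horizon_s: float = 3600.0,
) -> InfusionSchedule:
    """The study's induction protocol as an infusion schedule.

    Initial rate 15 mg/kg/h for patients >= 65 years, otherwise a configured
    young-group rate in [20, 25]; while suppression has not appeared, the rate
    escalates by 5 mg/kg/h at 10 min and every 5 min thereafter; the infusion
    stops at suppression onset.
    """
    if cov.elderly:
        r0 = elderly_rate
    else:
        if not 20.0 <= initial_rate_young <= 25.0:
            raise ValueError("young-group initial rate must lie in [20, 25] mg/kg/h")
        r0 = initial_rate_young
    segments = [(0.0, r0)]
    t = first_escalation_s
    rate = r0
    while t < horizon_s and (sr_onset_time is None or t < sr_onset_time):
        rate += escalation_mg_kg_h
        segments.append((t, rate))
        t += escalation_interval_s
    return InfusionSchedule(segments=segments, stop_time=sr_onset_time)


@dataclass
class ConcentrationTrajectory:
    """Plasma and effect-site concentrations (ug/mL) on a uniform time grid (s)."""

    t: np.ndarray
    cp: np.ndarray
    ce: np.ndarray
    rate: np.ndarray  # infusion rate in mg/kg/h at each grid point

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def ce_at(self, times) -> np.ndarray:
        return np.interp(times, self.t, self.ce)

    def to_frame(self, step_s: float = 1.0):
        """Export as a DataFrame (t_s, cp_ug_ml, ce_ug_ml, rate_mg_kg_h)."""
        import pandas as pd

        stride = max(int(round(step_s / self.dt)), 1)
        sel = slice(None, None, stride)
        return pd.DataFrame({
            "t_s": self.t[sel], "cp_ug_ml": self.cp[sel],
            "ce_ug_ml": self.ce[sel], "rate_mg_kg_h": self.rate[sel],
        })


def _segment_states(a, x0, u, dts):
    """Exact states of dx/dt = A x + e1*u at offsets ``dts`` from the segment start."""
    lam, v = np.linalg.eig(a)
    vinv = np.linalg.inv(v)
    if u != 0.0:
        xss = -np.linalg.solve(a, np.array([u, 0.0, 0.0, 0.0]))
    else:
        xss = np.zeros(4)
    w = vinv @ (x0 - xss)
    e = np.exp(np.outer(lam, dts))
    return (v @ (e * w[:, None])).real + xss[:, None]


def simulate_pkpd(
    model: PKModel,
    schedule: InfusionSchedule,
    weight_kg: float,
    dt: float = 0.1,
    horizon_s: float = 3600.0,
    method: str = "analytic",
) -> ConcentrationTrajectory:
    """Simulate plasma and effect-site concentrations under an infusion schedule.

    ``method="analytic"`` (default) propagates the exact matrix-exponential
    solution segment by segment; ``method="rk4"`` is a classical fixed-step
    Runge-Kutta integrator for cross-validation.
    """
    if dt > 1.0 or dt <= 0:
        raise ValueError("dt must lie in (0, 1] s")
    a = model.system_matrix()
    n = int(round(horizon_s / dt)) + 1
    t = np.arange(n) * dt
    x = np.zeros((4, n))
    if method == "analytic":
        bp = schedule.breakpoints(horizon_s)
        state = np.zeros(4)
        for ts, te in zip(bp[:-1], bp[1:]):
            u = schedule.rate_at(ts) * weight_kg / 3600.0  # mg/s
            i0 = int(np.ceil(ts / dt - 1e-9))
            i1 = int(np.floor(te / dt + 1e-9))
            dts = t[i0 : i1 + 1] - ts
            if dts.size:
                x[:, i0 : i1 + 1] = _segment_states(a, state, u, dts)
            state = _segment_states(a, state, u, np.array([te - ts]))[:, 0]
    elif method == "rk4":
        state = np.zeros(4)
        for i in range(1, n):
            ti = t[i - 1]
            u = schedule.rate_at(ti + dt / 2) * weight_kg / 3600.0
            b = np.array([u, 0.0, 0.0, 0.0])
            k1 = a @ state + b
            k2 = a @ (state + dt / 2 * k1) + b
            k3 = a @ (state + dt / 2 * k2) + b
            k4 = a @ (state + dt * k3) + b
            state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            x[:, i] = state
    else:
        raise ValueError(f"unknown method {method!r}")
    cp = x[0] / model.v1
    ce = x[3]
    if cp.min() < -1e-6 or ce.min() < -1e-6:
        raise RuntimeError("integration instability: negative concentrations")
    rate = schedule.rates(t)
    return ConcentrationTrajectory(t=t, cp=np.maximum(cp, 0.0),
                                   ce=np.maximum(ce, 0.0), rate=rate)


def find_cemax(traj: ConcentrationTrajectory, loc_time: float | None = None):
    """Locate the 1-min window with maximal mean Ce and the instantaneous peak.

    Windows are anchored at ``loc_time`` (the LOC minute is index 0) when
    given, else at the trajectory start.  Ties break toward the earlier
    minute.  Returns ``(minute_index, ce_max)``.
    """
    if traj.t.size == 0:
        raise ValueError("empty trajectory")
    anchor = traj.t[0] if loc_time is None else loc_time
    t_end = traj.t[-1]
    n_minutes = int((t_end - anchor) // 60.0)
    ce_max = float(traj.ce.max())
    if n_minutes < 1:
        return 0, ce_max
    means = np.empty(n_minutes)
    for k in range(n_minutes):
        sel = (traj.t >= anchor + 60.0 * k) & (traj.t < anchor + 60.0 * (k + 1))
        means[k] = traj.ce[sel].mean()
    return int(np.argmax(means)), ce_max


def suppression_onset_surrogate(
    rec: RawRecording,
    thresh_uv: float = 5.0,
    window_s: float = 63.0,
    min_stretch_s: float = 0.5,
) -> float | None:
    """First time the envelope-based suppression ratio exceeds 1%.

    The suppression ratio at time t is the fraction of the trailing
    ``window_s`` spent in stretches of at least ``min_stretch_s`` where the
    amplitude envelope stays below ``thresh_uv``.  This is a documented
    surrogate for the monitor's proprietary suppression-rate output; it gates
    protocol simulation, never the hypnotic-depth measures.
    """
    if thresh_uv <= 0 or window_s <= 0 or min_stretch_s <= 0:
        raise ValueError("thresholds must be positive")
    from scipy.signal import hilbert

    env = np.abs(hilbert(rec.samples))
    below = env < thresh_uv
    min_run = int(round(min_stretch_s * rec.fs))
    suppressed = np.zeros(rec.n, dtype=bool)
    if below.any():
        idx = np.flatnonzero(below)
        for run in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1):
            if run.size >= min_run:
                suppressed[run[0] : run[-1] + 1] = True
    w = int(round(window_s * rec.fs))
    if rec.n < w:
        return None
    csum = np.concatenate([[0], np.cumsum(suppressed)])
    sr = (csum[w:] - csum[:-w]) / w  # sr[i] covers samples [i, i+w)
    hits = np.flatnonzero(sr > 0.01)
    if hits.size == 0:
        return None
    return float(rec.t0 + (hits[0] + w) / rec.fs)
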