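"""Hourly insulin-sensitivity identification from clinical-style records.

A "virtual patient" is an SI(t) profile identified from a patient's BG
measurements plus recorded insulin and carbohydrate inputs.  For each
inter-measurement interval a single constant SI is found by scalar
root-finding on the monotone map SI -> simulated BG at the interval end,
with the simulation state carried continuously across intervals.  When
measurements are 2- or 4-hourly one constant value spans the whole interval;
its provenance (interval length) is retained so downstream variability
analysis can restrict itself to 1-2 hourly data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import CoverageError, InsufficientDataError, InvalidInputError
from .model import (
    MU_MIN_PER_U_H,
    InputSchedule,
    MetabolicState,
    ModelParameters,
    PiecewiseConstant,
    integrate_model,
    steady_state_gut,
    steady_state_insulin,
)

logger = logging.getLogger(__name__)

#: default SI search bounds, L/(mU*min)
DEFAULT_SI_BOUNDS = (1e-8, 1e-2)

STATUS_IDENTIFIED = "identified"
STATUS_CLAMPED_LOW = "clamped-low"
STATUS_CLAMPED_HIGH = "clamped-high"


@dataclass
class PatientRecord:
    """Timestamped per-patient clinical-style record.

    BG in mmol/L at strictly increasing minute offsets; insulin as a
    piecewise-constant infusion in U/h; carbohydrate administration (all
    sources) as a piecewise-constant rate in mmol/min.  ``t_start``/``t_end``
    delimit the stay; both schedules must cover it.
    """

    patient_id: str
    bg_times: np.ndarray
    bg_values: np.ndarray
    insulin: PiecewiseConstant       # U/h
    carb: PiecewiseConstant          # mmol/min
    t_start: float
    t_end: float
    weight: float | None = None
    provenance: str = "clinical"

    def __post_init__(self) -> None:
        self.bg_times = np.asarray(self.bg_times, dtype=float)
        self.bg_values = np.asarray(self.bg_values, dtype=float)
        if self.bg_times.shape != self.bg_values.shape or self.bg_times.ndim != 1:
            raise InvalidInputError("bg_times/bg_values must be matching 1-D")
        if self.bg_times.size and np.any(np.diff(self.bg_times) <= 0):
            raise InvalidInputError("BG times must be strictly increasing")
        if np.any(self.bg_values <= 0):
            raise InvalidInputError("BG values must be positive")
        if self.t_end <= self.t_start:
            raise InvalidInputError("record span must have positive length")
        for name, sched in (("insulin", self.insulin), ("carb", self.carb)):
            if not sched.covers(self.t_start, self.t_end):
                raise CoverageError(
                    f"{name} schedule does not cover the record span "
                    f"[{self.t_start}, {self.t_end}] of {self.patient_id}")

    @property
    def span_min(self) -> float:
        return self.t_end - self.t_start

    def input_schedule(self) -> InputSchedule:
        """Model inputs: insulin converted U/h -> mU/min, carbs to the gut."""
        ins = PiecewiseConstant(self.insulin.times,
                               self.insulin.values * MU_MIN_PER_U_H,
                               self.insulin.end)
        return InputSchedule(insulin=ins, enteral=self.carb,
                             iv_dextrose=PiecewiseConstant.constant(
                                 0.0, self.t_start, self.t_end))


@dataclass
class SIProfile:
    """Piecewise-constant SI trajectory identified per measurement interval.

    ``breaks[i]`` starts interval i with value ``values[i]`` and status in
    {identified, clamped-low, clamped-high}; the last interval ends at
    ``end``.  ``interval_h`` records each interval's length in hours (its
    data-density provenance).
    """

    breaks: np.ndarray
    values: np.ndarray
    statuses: list
    end: float

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def interval_h(self) -> np.ndarray:
        edges = np.append(self.breaks, self.end)
        return np.diff(edges) / 60.0

    def as_piecewise(self) -> PiecewiseConstant:
        return PiecewiseConstant(self.breaks, self.values, self.end)

    def value_at(self, t: float) -> float:
        return self.as_piecewise().rate(t)

    def hourly(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Replicate onto the hourly grid: (hour starts, values, interval_h)."""
        sig = self.as_piecewise()
        hrs = np.arange(self.breaks[0], self.end - 1e-9, 60.0)
        vals = np.array([sig.rate(t) for t in hrs])
        prov = np.array([self.interval_h[
            np.searchsorted(self.breaks, t, side="right") - 1] for t in hrs])
        return hrs, vals, prov

    def transitions(self, max_interval_h: float = 2.0
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Consecutive-interval SI pairs where both intervals are short enough.

        2-hourly intervals contribute one transition; longer intervals are
        excluded entirely (sparse-data provenance).
        """
        lens = self.interval_h
        keep = [(self.values[i], self.values[i + 1])
                for i in range(len(self.values) - 1)
                if lens[i] <= max_interval_h + 1e-9
                and lens[i + 1] <= max_interval_h + 1e-9]
        if not keep:
            return np.empty(0), np.empty(0)
        arr = np.asarray(keep)
        return arr[:, 0], arr[:, 1]


@dataclass
class FitReport:
    """Per-patient fit and 1-hour forward prediction errors (percent)."""

    patient_id: str
    fit_errors_pct: np.ndarray = field(default_factory=lambda: np.empty(0))
    prediction_errors_pct: np.ndarray = field(
        default_factory=lambda: np.empty(0))
    skipped_predictions: int = 0

    @property
    def median_fit_pct(self) -> float:
        return float(np.median(self.fit_errors_pct)) if len(
            self.fit_errors_pct) else np.nan

    @property
    def median_prediction_pct(self) -> float:
        return float(np.median(self.prediction_errors_pct)) if len(
            self.prediction_errors_pct) else np.nan


def _initial_state(record: PatientRecord, params: ModelParameters
                   ) -> MetabolicState:
    """Start of identification: first BG, insulin/gut states at equilibrium
    for the first recorded input rates."""
    t0 = float(record.bg_times[0])
    uex0 = record.insulin.rate(t0) * MU_MIN_PER_U_H
    i0, q0 = steady_state_insulin(params, uex0)
    p1, p2 = steady_state_gut(params, record.carb.rate(t0))
    return MetabolicState(G=float(record.bg_values[0]), I=i0, Q=q0,
                          P1=p1, P2=p2, t=t0)


def identify_si_profile(record: PatientRecord, params: ModelParameters,
                        bounds: tuple[float, float] = DEFAULT_SI_BOUNDS,
                        rel_tol: float = 1e-6, rk4_dt: float = 0.5
                        ) -> SIProfile:
    """Identify one constant SI per inter-measurement interval.

    The map SI -> simulated interval-end BG is strictly decreasing, so each
    interval has a unique root, found with Brent's method.  Intervals whose
    target BG cannot be bracketed within ``bounds`` are clamped at the
    violated bound with a recorded status (never an exception); the forward
    simulation then continues from the clamped interval's end state so later
    intervals stay consistent.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise InvalidInputError(f"bounds must satisfy 0 < lo < hi, got {bounds}")
    if record.bg_times.size < 2:
        raise InsufficientDataError(
            f"{record.patient_id}: need >= 2 BG measurements, "
            f"have {record.bg_times.size}")

    schedule = record.input_schedule()
    state = _initial_state(record, params)
    p = params.as_tuple()
    breaks, values, statuses = [], [], []
    si_prev = None

    from .model import integrate_segment

    for i in range(record.bg_times.size - 1):
        ta, tb = float(record.bg_times[i]), float(record.bg_times[i + 1])
        target = float(record.bg_values[i + 1])
        # constant-input sub-segments inside [ta, tb]
        cuts = schedule.breakpoints_between(ta, tb)
        edges = np.concatenate([[ta], cuts, [tb]])
        seg_inputs = [schedule.rates_at(a) for a in edges[:-1]]
        y0 = (state.G, state.I, state.Q, state.P1, state.P2)

        def g_end(si: float, _edges=edges, _inputs=seg_inputs, _y0=y0):
            y = _y0
            for (a, b), (uex, ent, ivd) in zip(
                    zip(_edges[:-1], _edges[1:]), _inputs):
                y = integrate_segment(y, si, uex, ent, ivd, b - a, p, rk4_dt)
            return y

        f = lambda si: g_end(si)[0] - target  # noqa: E731
        f_lo = f(lo)
        if f_lo < 0:  # even minimal insulin action undershoots: BG rising fast
            si_hat, status = lo, STATUS_CLAMPED_LOW
        else:
            f_hi = f(hi)
            if f_hi > 0:
                si_hat, status = hi, STATUS_CLAMPED_HIGH
            else:
                a, b = lo, hi
                if si_prev is not None:  # warm bracket around the last value
                    wa, wb = max(lo, si_prev / 4.0), min(hi, si_prev * 4.0)
                    if wa < wb and f(wa) >= 0 >= f(wb):
                        a, b = wa, wb
                si_hat = brentq(f, a, b, xtol=1e-14, rtol=1e-12)
                status = STATUS_IDENTIFIED
        if status != STATUS_IDENTIFIED:
            logger.warning("%s: interval [%.0f, %.0f] min %s at SI=%.3g",
                           record.patient_id, ta, tb, status, si_hat)
        y_end = g_end(si_hat)
        if status == STATUS_IDENTIFIED:
            err = abs(y_end[0] - target) / target
            if err > rel_tol:
                logger.warning("%s: interval [%.0f, %.0f] residual %.2e "
                               "exceeds rel_tol %.1e", record.patient_id,
                               ta, tb, err, rel_tol)
        state = MetabolicState(G=y_end[0], I=y_end[1], Q=y_end[2],
                               P1=y_end[3], P2=y_end[4], t=tb)
        breaks.append(ta)
        values.append(si_hat)
        statuses.append(status)
        si_prev = si_hat

    return SIProfile(breaks=np.array(breaks), values=np.array(values),
                     statuses=statuses, end=float(record.bg_times[-1]))


def _fitted_trajectory(record: PatientRecord, profile: SIProfile,
                       params: ModelParameters, step: float = 60.0):
    t0 = float(profile.breaks[0])
    t1 = float(profile.end)
    if not (record.bg_times[0] <= t0 + 1e-9 and t1 <= record.bg_times[-1] + 1e-9
            and t1 > t0):
        raise CoverageError("profile span does not overlap the record span")
    state = _initial_state(record, params)
    schedule = record.input_schedule()
    # sample at every measurement time as well as the hourly grid
    traj = integrate_model(params, state, profile, schedule, t1 - t0, step=step)
    return traj


def fit_errors(record: PatientRecord, profile: SIProfile,
               params: ModelParameters) -> FitReport:
    """Percent BG error of the profile-driven simulation at each measurement."""
    traj = _fitted_trajectory(record, profile, params, step=60.0)
    errs = []
    for tm, bg in zip(record.bg_times, record.bg_values):
        if tm < profile.breaks[0] - 1e-9 or tm > profile.end + 1e-9:
            continue
        i = int(np.argmin(np.abs(traj.t - tm)))
        if abs(traj.t[i] - tm) > 1e-6:
            continue
        errs.append(abs(traj.G[i] - bg) / bg * 100.0)
    return FitReport(patient_id=record.patient_id,
                     fit_errors_pct=np.asarray(errs))


def forward_prediction_errors(record: PatientRecord, profile: SIProfile,
                              params: ModelParameters,
                              match_window_min: float = 1.0,
                              max_interp_gap_min: float = 125.0) -> FitReport:
    """1-hour-ahead BG prediction errors holding the last identified SI.

    From the fitted state at each hour boundary, BG is simulated one hour
    forward with the SI of the interval ending at (or covering) that boundary
    and the recorded inputs, then compared to the measurement at the horizon
    or to a linear estimate between 2-hourly measurements.  The first
    identified interval has no prior SI and is excluded; horizons with
    neither a measurement nor a bracketing pair are skipped and counted.
    """
    from .model import integrate_segment

    traj = _fitted_trajectory(record, profile, params, step=60.0)
    schedule = record.input_schedule()
    p = params.as_tuple()
    sig = profile.as_piecewise()
    t_first_pred = float(profile.breaks[0] + profile.interval_h[0] * 60.0)
    errs, skipped = [], 0
    t = t_first_pred
    while t + 60.0 <= profile.end + 1e-9:
        horizon_t = t + 60.0
        try:
            state = traj.state_at(t)
        except InvalidInputError:
            t += 60.0
            continue
        si_prev = sig.rate(t - 1e-6)
        cuts = schedule.breakpoints_between(t, horizon_t)
        edges = np.concatenate([[t], cuts, [horizon_t]])
        y = (state.G, state.I, state.Q, state.P1, state.P2)
        for a, b in zip(edges[:-1], edges[1:]):
            uex, ent, ivd = schedule.rates_at(a)
            y = integrate_segment(y, si_prev, uex, ent, ivd, b - a, p, 0.5)
        g_pred = y[0]

        bg_ref = _reference_bg(record, horizon_t, match_window_min,
                               max_interp_gap_min)
        if bg_ref is None:
            skipped += 1
        else:
            errs.append(abs(g_pred - bg_ref) / bg_ref * 100.0)
        t += 60.0
    return FitReport(patient_id=record.patient_id,
                     prediction_errors_pct=np.asarray(errs),
                     skipped_predictions=skipped)


def _reference_bg(record: PatientRecord, t: float, window: float,
                  max_gap: float) -> float | None:
    """Measured BG at t, else a linear estimate between near measurements."""
    d = np.abs(record.bg_times - t)
    i = int(np.argmin(d))
    if d[i] <= window:
        return float(record.bg_values[i])
    j = int(np.searchsorted(record.bg_times, t))
    if 0 < j < record.bg_times.size:
        ta, tb = record.bg_times[j - 1], record.bg_times[j]
        if tb - ta <= max_gap:
            w = (t - ta) / (tb - ta)
            return float((1 - w) * record.bg_values[j - 1]
                         + w * record.bg_values[j])
    return None


def fit_report(record: PatientRecord, profile: SIProfile,
               params: ModelParameters) -> FitReport:
    """Combined fit + prediction report for one patient."""
    fr = fit_errors(record, profile, params)
    pr = forward_prediction_errors(record, profile, params)
    return FitReport(patient_id=record.patient_id,
                     fit_errors_pct=fr.fit_errors_pct,
                     prediction_errors_pct=pr.prediction_errors_pct,
                     skipped_predictions=pr.skipped_predictions)


REASON_NO_INSULIN = "no insulin"
REASON_FEW_BG = "fewer than 5 BG measurements"
REASON_NO_CARB = "no carbohydrate > 48 h"

_NO_CARB_WINDOW_MIN = 48.0 * 60.0


def screen_cohort(records: list[PatientRecord]
                  ) -> tuple[list[PatientRecord], list[tuple[PatientRecord, str]]]:
    """Apply the cohort-selection rules; first matching rule wins.

    Excluded are patients who received no insulin for the entire stay, have
    fewer than 5 BG measurements, or have any window longer than 48 h with no
    recorded carbohydrate administration.
    """
    retained, excluded = [], []
    for rec in records:
        reason = None
        if np.all(rec.insulin.values == 0.0):
            reason = REASON_NO_INSULIN
        elif rec.bg_times.size < 5:
            reason = REASON_FEW_BG
        elif _longest_zero_run(rec.carb, rec.t_start, rec.t_end) \
                > _NO_CARB_WINDOW_MIN:
            reason = REASON_NO_CARB
        if reason is None:
            retained.append(rec)
        else:
            excluded.append((rec, reason))
    return retained, excluded


def _longest_zero_run(sig: PiecewiseConstant, t0: float, t1: float) -> float:
    edges = np.concatenate([[t0], sig.breakpoints_between(t0, t1), [t1]])
    longest = run = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        if sig.rate(a) == 0.0:
            run += b - a
            longest = max(longest, run)
        else:
            run = 0.0
    return longest
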