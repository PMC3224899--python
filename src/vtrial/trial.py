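"""Closed-loop virtual trials: a dosing protocol driving a virtual patient.

A virtual patient is an identified (or synthetic) SI(t) trajectory plus the
patient's own retained nutrition schedule, initial BG and stay length.  The
engine alternates protocol decisions at measurement times with forward model
integration between them, in either ``per_protocol`` timing (the protocol's
1/2/4-hourly rules schedule the next measurement) or ``replayed`` timing
(the source record's clinical timestamps are reused, so controller decisions
happen exactly when they did clinically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    SimulationFailure,
)
from .identify import PatientRecord, SIProfile, identify_si_profile
from .model import (
    GLUCOSE_G_PER_MMOL,
    MU_MIN_PER_U_H,
    InputSchedule,
    MetabolicState,
    ModelParameters,
    PiecewiseConstant,
    integrate_model,
    steady_state_gut,
    steady_state_insulin,
)
from .protocols import ControllerState, ProtocolDefinition, apply_decision

PER_PROTOCOL = "per_protocol"
REPLAYED = "replayed"
TIMING_MODES = (PER_PROTOCOL, REPLAYED)


@dataclass
class VirtualPatient:
    """Driver for one in-silico patient.

    ``si`` is an :class:`SIProfile`, a :class:`PiecewiseConstant`, or a
    stochastic process exposing ``step(t_from, t_to) -> float`` (constant SI
    per inter-measurement segment, advanced causally).
    """

    patient_id: str
    si: object
    carb: PiecewiseConstant          # mmol/min, retained from the source
    initial_bg: float                # mmol/L
    t_start: float
    t_end: float
    initial_rate_U_h: float = 0.0
    provenance: str = "clinical-derived"
    clinical_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.initial_bg <= 0:
            raise InvalidInputError("initial BG must be positive")
        if self.t_end < self.t_start:
            raise InvalidInputError("stay must have non-negative length")
        if not self.carb.covers(self.t_start, self.t_end):
            raise InvalidInputError(
                f"nutrition schedule does not cover the stay of "
                f"{self.patient_id}")

    @classmethod
    def from_record(cls, record: PatientRecord, params: ModelParameters,
                    **identify_kwargs) -> "VirtualPatient":
        profile = identify_si_profile(record, params, **identify_kwargs)
        return cls(
            patient_id=record.patient_id,
            si=profile,
            carb=record.carb,
            initial_bg=float(record.bg_values[0]),
            t_start=float(record.bg_times[0]),
            t_end=float(record.bg_times[-1]),
            initial_rate_U_h=record.insulin.rate(float(record.bg_times[0])),
            provenance="clinical-derived",
            clinical_times=record.bg_times.copy(),
        )


@dataclass(frozen=True)
class Intervention:
    t: float
    rate_U_h: float
    bolus_g: float = 0.0
    call_physician: bool = False
    interval_h: int = 1


@dataclass
class TrialResult:
    """Simulated BG trace plus measurement and intervention logs."""

    patient_id: str
    trace_t: np.ndarray
    trace_G: np.ndarray
    meas_t: np.ndarray
    meas_bg: np.ndarray
    interventions: list[Intervention]
    t_start: float
    t_end: float
    glucose_edges: np.ndarray        # min; nutrition segments over the stay
    glucose_values_g_h: np.ndarray

    def insulin_segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Commanded-rate segments (edges, U/h values) over the stay."""
        if not self.interventions:
            return (np.array([self.t_start, max(self.t_end, self.t_start)]),
                    np.array([0.0]))
        edges = [self.t_start] + [iv.t for iv in self.interventions[1:]] \
            + [self.t_end]
        vals = [iv.rate_U_h for iv in self.interventions]
        return np.asarray(edges, dtype=float), np.asarray(vals, dtype=float)

    def total_insulin_U(self) -> float:
        edges, vals = self.insulin_segments()
        return float(np.sum(np.diff(edges) / 60.0 * vals))

    def patient_stats(self):
        from .metrics import PatientStats
        edges, vals = self.insulin_segments()
        return PatientStats(
            patient_id=self.patient_id,
            bg=self.meas_bg.copy(),
            insulin_edges=edges, insulin_values=vals,
            glucose_edges=self.glucose_edges,
            glucose_values=self.glucose_values_g_h,
            stay_min=self.t_end - self.t_start,
        )


def _initial_trial_state(params: ModelParameters, patient: VirtualPatient
                         ) -> MetabolicState:
    uex0 = patient.initial_rate_U_h * MU_MIN_PER_U_H
    i0, q0 = steady_state_insulin(params, uex0)
    p1, p2 = steady_state_gut(params, patient.carb.rate(patient.t_start))
    return MetabolicState(G=patient.initial_bg, I=i0, Q=q0, P1=p1, P2=p2,
                          t=patient.t_start)


def run_virtual_trial(params: ModelParameters, patient: VirtualPatient,
                      protocol: ProtocolDefinition, mode: str = PER_PROTOCOL,
                      sensor_noise_cv: float | None = None,
                      rng: np.random.Generator | None = None,
                      rk4_dt: float = 0.5, trace_step: float = 60.0
                      ) -> TrialResult:
    """Simulate one virtual trial to the end of the patient's stay.

    At each measurement the model BG is read (optionally with multiplicative
    Gaussian sensor noise), the protocol decides a new rate (the starting
    table at the first measurement, the maintenance table thereafter), rescue
    boluses are applied as instantaneous G increments, and the model is
    integrated to the next measurement with the patient's SI and nutrition
    plus the commanded insulin.  The terminal interval is truncated at stay
    end, where a final sample is logged.
    """
    if mode not in TIMING_MODES:
        raise InvalidInputError(f"unknown timing mode {mode!r}; "
                                f"choose from {TIMING_MODES}")
    if mode == REPLAYED:
        if patient.clinical_times is None or patient.provenance == "synthetic":
            raise InvalidInputError(
                "replayed timing requires clinically recorded measurement "
                f"timestamps; patient {patient.patient_id} has none")
        replay = [float(t) for t in patient.clinical_times
                  if patient.t_start <= t <= patient.t_end]
    if sensor_noise_cv and rng is None:
        raise InvalidInputError("sensor noise requires an rng for reproducibility")

    dynamic_si = hasattr(patient.si, "step")
    state = _initial_trial_state(params, patient)
    cstate = ControllerState(rate=patient.initial_rate_U_h)
    meas_t: list[float] = []
    meas_bg: list[float] = []
    interventions: list[Intervention] = []
    trace_t = [patient.t_start]
    trace_G = [state.G]
    t = patient.t_start

    while True:
        bg = state.G
        if sensor_noise_cv:
            bg = max(bg * (1.0 + sensor_noise_cv / 100.0 * rng.standard_normal()),
                     0.1)
        meas_t.append(t)
        meas_bg.append(bg)
        if t >= patient.t_end - 1e-9:
            break
        action = apply_decision(protocol, cstate, bg, t)
        interventions.append(Intervention(
            t=t, rate_U_h=action.new_rate, bolus_g=action.bolus_g,
            call_physician=action.call_physician,
            interval_h=action.interval_h))
        if action.bolus_g > 0:
            state.G += action.bolus_g / GLUCOSE_G_PER_MMOL / params.VG
        if mode == PER_PROTOCOL:
            t_next = min(t + action.interval_h * 60.0, patient.t_end)
        else:
            later = [tt for tt in replay if tt > t + 1e-9]
            t_next = later[0] if later else patient.t_end
        si_seg = (patient.si.step(t, t_next) if dynamic_si else patient.si)
        seg_sched = InputSchedule(
            insulin=PiecewiseConstant.constant(
                action.new_rate * MU_MIN_PER_U_H, t, t_next),
            enteral=patient.carb,
            iv_dextrose=PiecewiseConstant.constant(0.0, t, t_next))
        try:
            traj = integrate_model(params, state, si_seg, seg_sched,
                                   t_next - t, step=trace_step, rk4_dt=rk4_dt)
        except SimulationFailure as exc:
            raise SimulationFailure(
                f"patient {patient.patient_id}: {exc}") from exc
        trace_t.extend(traj.t[1:].tolist())
        trace_G.extend(traj.G[1:].tolist())
        state = traj.final_state()
        t = t_next

    glucose_edges = np.concatenate([
        [patient.t_start],
        patient.carb.breakpoints_between(patient.t_start, patient.t_end),
        [max(patient.t_end, patient.t_start + 1e-9)]])
    glucose_vals = np.array([patient.carb.rate(a)
                             for a in glucose_edges[:-1]]) \
        * GLUCOSE_G_PER_MMOL * 60.0
    return TrialResult(
        patient_id=patient.patient_id,
        trace_t=np.asarray(trace_t), trace_G=np.asarray(trace_G),
        meas_t=np.asarray(meas_t), meas_bg=np.asarray(meas_bg),
        interventions=interventions,
        t_start=patient.t_start, t_end=patient.t_end,
        glucose_edges=glucose_edges, glucose_values_g_h=glucose_vals,
    )


def run_cohort_trial(params: ModelParameters,
                     patients: Sequence[VirtualPatient],
                     protocol: ProtocolDefinition, mode: str = PER_PROTOCOL,
                     sensor_noise_cv: float | None = None,
                     seed: int | None = None
                     ) -> tuple[list[TrialResult], list[tuple[str, str]]]:
    """Run a protocol over a cohort; failed patients are reported, not fatal."""
    if not patients:
        raise InsufficientDataError("empty cohort")
    results, failures = [], []
    root = np.random.default_rng(seed) if sensor_noise_cv else None
    for i, pat in enumerate(patients):
        rng = np.random.default_rng([seed or 0, i]) if sensor_noise_cv else None
        try:
            results.append(run_virtual_trial(
                params, pat, protocol, mode=mode,
                sensor_noise_cv=sensor_noise_cv, rng=rng))
        except SimulationFailure as exc:
            failures.append((pat.patient_id, str(exc)))
    if not results:
        raise SimulationFailure("all patients in the cohort failed simulation")
    return results, failures


def patients_from_records(records: Sequence[PatientRecord],
                          params: ModelParameters, **identify_kwargs
                          ) -> list[VirtualPatient]:
    return [VirtualPatient.from_record(r, params, **identify_kwargs)
            for r in records]


@dataclass
class ValidationArms:
    """Aligned result sets for the validation analytics."""

    records: list
    patients: list
    per_protocol: list
    replayed: list
    failures: list = field(default_factory=list)


def self_validation(records: Sequence[PatientRecord],
                    protocol: ProtocolDefinition, params: ModelParameters,
                    **identify_kwargs) -> ValidationArms:
    """Re-simulate a cohort's own protocol in both timing modes.

    Residual differences from the clinical records reflect model error plus
    (in the per-protocol arm) clinical compliance to measurement timing.
    """
    if not records:
        raise InsufficientDataError("empty record list")
    patients = patients_from_records(records, params, **identify_kwargs)
    pp, fail_pp = run_cohort_trial(params, patients, protocol,
                                   mode=PER_PROTOCOL)
    rp, fail_rp = run_cohort_trial(params, patients, protocol, mode=REPLAYED)
    return ValidationArms(records=list(records), patients=patients,
                          per_protocol=pp, replayed=rp,
                          failures=fail_pp + fail_rp)


def cross_validation(records: Sequence[PatientRecord],
                     protocol_other: ProtocolDefinition,
                     params: ModelParameters, **identify_kwargs
                     ) -> list[TrialResult]:
    """Simulate a *different* protocol on patients derived from these records.

    Nutrition schedules are retained per patient (they were clinician-driven,
    not protocol-driven).  Agreement with the other group's clinical results
    tests the independence of SI(t) from the inputs used to identify it.
    """
    if not records:
        raise InsufficientDataError("empty record list")
    patients = patients_from_records(records, params, **identify_kwargs)
    results, _ = run_cohort_trial(params, patients, protocol_other,
                                  mode=PER_PROTOCOL)
    return results
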