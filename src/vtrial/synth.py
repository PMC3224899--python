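"""Synthetic cohort generation: virtual patients plus pseudo-clinical records.

The generator emulates the statistical structure a TGC dataset is assumed to
have: lognormal initial BG (median/IQR targets around 6.6 [5.6-8.6] mmol/L),
lognormal initial insulin sensitivity centred in the clinically dense SI
range, multiplicative hour-to-hour SI variability, clinician-chosen constant
nutrition rates, and measurement cadence produced by actually running a
dosing protocol in closed loop.  Each generated record is schema-identical
to clinical input, and the generating truth (SI trajectory, nutrition, seed)
is retained for recovery testing.

The true SI trajectory is piecewise-constant on the measurement grid: a
k-hour inter-measurement interval receives one multiplicative step with
variance scaled by k, preserving hourly-scale variability while keeping the
truth exactly representable by per-interval identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError, SimulationFailure
from .identify import PatientRecord, SIProfile
from .model import ModelParameters, PiecewiseConstant
from .protocols import ProtocolDefinition, load_protocol, starting_rate
from .stochastic import StochasticSIModel, sample_next_si
from .trial import VirtualPatient, run_virtual_trial


@dataclass(frozen=True)
class CohortConfig:
    """Generating distributions for one synthetic cohort."""

    n_patients: int
    seed: int
    protocol: str = "glucontrol_a"
    initial_bg_median: float = 6.6           # mmol/L
    initial_bg_iqr: tuple[float, float] = (5.6, 8.6)
    initial_si_median: float = 3.0e-4        # L/(mU*min)
    initial_si_sigma: float = 0.55           # lognormal sd (log scale)
    si_hourly_cv: float = 0.10               # multiplicative step sd per hour
    si_clip: tuple[float, float] = (2.0e-5, 2.0e-3)
    si_model: StochasticSIModel | None = None  # overrides the random walk
    nutrition_range: tuple[float, float] = (0.1, 1.0)  # mmol/min, uniform
    stay_h: float = 72.0
    sensor_noise_cv: float | None = None     # % multiplicative, off by default
    nurse_delay_max_min: float = 0.0         # record-timestamp perturbation

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidInputError("n_patients must be >= 1")
        if self.seed is None:
            raise InvalidInputError("seed is mandatory")
        for name, v in (("initial_bg_median", self.initial_bg_median),
                        ("initial_si_median", self.initial_si_median),
                        ("initial_si_sigma", self.initial_si_sigma),
                        ("si_hourly_cv", self.si_hourly_cv),
                        ("stay_h", self.stay_h)):
            if v <= 0:
                raise InvalidInputError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Per-patient generating truth stored alongside the records."""

    si_profiles: dict = field(default_factory=dict)   # id -> SIProfile
    nutrition: dict = field(default_factory=dict)     # id -> PiecewiseConstant
    seeds: dict = field(default_factory=dict)         # id -> seed sequence


class RandomWalkSI:
    """Multiplicative lognormal SI walk stepped per inter-measurement interval.

    The step applied when entering a new interval scales its log-variance
    with the length of the *previous* interval (hours elapsed), so hourly
    variability statistics are independent of measurement cadence.  Values
    are clipped to a physiological range; the realized trajectory is
    recorded for the truth manifest.
    """

    def __init__(self, si0: float, hourly_cv: float,
                 clip: tuple[float, float], rng: np.random.Generator) -> None:
        self.si = float(np.clip(si0, *clip))
        self.hourly_cv = hourly_cv
        self.clip = clip
        self.rng = rng
        self.breaks: list[float] = []
        self.values: list[float] = []

    def step(self, t_from: float, t_to: float) -> float:
        if self.breaks:
            k = (t_from - self.breaks[-1]) / 60.0
            sigma = self.hourly_cv * math.sqrt(max(k, 1e-9))
            self.si = float(np.clip(
                self.si * math.exp(sigma * self.rng.standard_normal()
                                   - 0.5 * sigma * sigma),
                *self.clip))
        self.breaks.append(t_from)
        self.values.append(self.si)
        return self.si

    def profile(self, end: float) -> SIProfile:
        return SIProfile(breaks=np.array(self.breaks),
                         values=np.array(self.values),
                         statuses=["truth"] * len(self.values), end=end)


class FittedModelSI(RandomWalkSI):
    """SI transitions drawn from a fitted stochastic model (one draw/hour)."""

    def __init__(self, si0: float, model: StochasticSIModel,
                 clip: tuple[float, float], rng: np.random.Generator) -> None:
        super().__init__(si0, hourly_cv=0.0, clip=clip, rng=rng)
        self.model = model

    def step(self, t_from: float, t_to: float) -> float:
        if self.breaks:
            k = max(1, int(round((t_from - self.breaks[-1]) / 60.0)))
            si = self.si
            for _ in range(k):
                si = sample_next_si(self.model, si, self.rng)
            self.si = float(np.clip(si, *self.clip))
        self.breaks.append(t_from)
        self.values.append(self.si)
        return self.si


def _lognormal_from_median_iqr(median: float, iqr: tuple[float, float],
                               rng: np.random.Generator) -> float:
    sigma = (math.log(iqr[1]) - math.log(iqr[0])) / (2.0 * 0.6744897501960817)
    return float(median * math.exp(sigma * rng.standard_normal()))


def _generate_patient(config: CohortConfig, params: ModelParameters,
                      protocol: ProtocolDefinition, pid: str, seed_seq
                      ) -> tuple[PatientRecord, SIProfile, VirtualPatient]:
    rng = np.random.default_rng(seed_seq)
    bg0 = float(np.clip(_lognormal_from_median_iqr(
        config.initial_bg_median, config.initial_bg_iqr, rng), 2.5, 30.0))
    si0 = float(np.clip(
        config.initial_si_median
        * math.exp(config.initial_si_sigma * rng.standard_normal()),
        *config.si_clip))
    carb_rate = float(rng.uniform(*config.nutrition_range))
    stay_min = config.stay_h * 60.0
    carb = PiecewiseConstant.constant(carb_rate, 0.0, stay_min)
    if config.si_model is not None:
        walk = FittedModelSI(si0, config.si_model, config.si_clip, rng)
    else:
        walk = RandomWalkSI(si0, config.si_hourly_cv, config.si_clip, rng)
    # start at insulin equilibrium for the rate the protocol will command at
    # t=0, matching identification's initial-state convention (which reads
    # the first *recorded* rate) so the generating truth stays recoverable
    rate0 = starting_rate(protocol, bg0)
    vp = VirtualPatient(patient_id=pid, si=walk, carb=carb, initial_bg=bg0,
                        t_start=0.0, t_end=stay_min, initial_rate_U_h=rate0,
                        provenance="synthetic")
    result = run_virtual_trial(params, vp, protocol,
                               sensor_noise_cv=config.sensor_noise_cv,
                               rng=rng if config.sensor_noise_cv else None)
    truth_profile = walk.profile(end=stay_min)

    iv_times = [iv.t for iv in result.interventions]
    iv_rates = [iv.rate_U_h for iv in result.interventions]
    if not iv_times or iv_times[0] > 0.0:
        iv_times, iv_rates = [0.0] + iv_times, [0.0] + iv_rates
    insulin = PiecewiseConstant(iv_times, iv_rates, stay_min)

    bg_times = result.meas_t.copy()
    if config.nurse_delay_max_min > 0:
        delays = rng.uniform(0, config.nurse_delay_max_min,
                             size=bg_times.size - 2)
        bg_times[1:-1] = bg_times[1:-1] + delays
        order = np.argsort(bg_times, kind="stable")
        bg_times = bg_times[order]
        bg_vals = result.meas_bg[order]
    else:
        bg_vals = result.meas_bg.copy()

    record = PatientRecord(patient_id=pid, bg_times=bg_times,
                           bg_values=bg_vals, insulin=insulin, carb=carb,
                           t_start=0.0, t_end=stay_min,
                           provenance="synthetic")
    truth_patient = VirtualPatient(
        patient_id=pid, si=truth_profile, carb=carb, initial_bg=bg0,
        t_start=0.0, t_end=stay_min, initial_rate_U_h=0.0,
        provenance="synthetic", clinical_times=result.meas_t.copy())
    return record, truth_profile, truth_patient


def generate_cohort(config: CohortConfig, params: ModelParameters | None = None,
                    max_retries: int = 5
                    ) -> tuple[list[PatientRecord], SyntheticTruth,
                               list[VirtualPatient]]:
    """Generate records, truth manifest and truth-driven virtual patients.

    Each patient draws initial BG, SI and nutrition, evolves SI through the
    configured transition source, and is treated in closed loop by the
    generating protocol, producing a record indistinguishable in schema from
    clinical input.  Fully reproducible from the config seed; patients whose
    simulation fails (nonphysical state) are resampled with bounded retries.
    """
    if params is None:
        params = ModelParameters.default()
    protocol = load_protocol(config.protocol)
    records, patients = [], []
    truth = SyntheticTruth()
    for i in range(config.n_patients):
        pid = f"synth-{config.seed}-{i:04d}"
        last_err: Exception | None = None
        for attempt in range(max_retries):
            seed_seq = [int(config.seed) % (2 ** 31), i, attempt]
            try:
                rec, prof, vp = _generate_patient(config, params, protocol,
                                                  pid, seed_seq)
            except SimulationFailure as exc:
                last_err = exc
                continue
            records.append(rec)
            patients.append(vp)
            truth.si_profiles[pid] = prof
            truth.nutrition[pid] = rec.carb
            truth.seeds[pid] = seed_seq
            break
        else:
            raise SimulationFailure(
                f"patient {pid} failed {max_retries} generation attempts: "
                f"{last_err}")
    return records, truth, patients


def generate_matched_pair(config: CohortConfig, protocol_a: str = "glucontrol_a",
                          protocol_b: str = "glucontrol_b",
                          params: ModelParameters | None = None):
    """Two cohorts from one generating distribution, treated differently.

    Independent draws (disjoint seed streams), identical distributions; the
    synthetic analogue of two clinically matched trial arms.
    """
    cfg_a = replace(config, protocol=protocol_a,
                    seed=int(config.seed) % (2 ** 31))
    cfg_b = replace(config, protocol=protocol_b,
                    seed=(int(config.seed) + 104729) % (2 ** 31))
    return (generate_cohort(cfg_a, params=params),
            generate_cohort(cfg_b, params=params))


def thin_measurements(record: PatientRecord, keep_fraction: float,
                      rng: np.random.Generator) -> PatientRecord:
    """Randomly drop interior measurements (compliance-gap emulation).

    The first and last measurements are always kept so the record span is
    preserved.
    """
    if not 0 < keep_fraction <= 1:
        raise InvalidInputError("keep_fraction must be in (0, 1]")
    n = record.bg_times.size
    keep = rng.uniform(size=n) < keep_fraction
    keep[0] = keep[-1] = True
    return PatientRecord(
        patient_id=record.patient_id,
        bg_times=record.bg_times[keep], bg_values=record.bg_values[keep],
        insulin=record.insulin, carb=record.carb,
        t_start=record.t_start, t_end=record.t_end,
        provenance=record.provenance)
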