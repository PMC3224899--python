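"""Glucose-insulin system model for critically ill patients.

The model tracks total plasma glucose G (mmol/L), plasma insulin I (mU/L) and
the interstitial insulin effect Q (mU/L), driven by endogenous glucose
production (suppressed with rising glucose through the clearance term pG),
constant central-nervous-system uptake, saturable insulin-mediated glucose
removal with patient-specific insulin sensitivity SI, and exogenous inputs:
IV insulin infusion and glucose appearance P(t) from enteral nutrition (a
two-compartment gut model) plus IV dextrose.

All population constants live in a config file (``data/default_params.yaml``);
the single patient-specific parameter is SI, identified hourly elsewhere.
Internal time unit is minutes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    CoverageError,
    InvalidInputError,
    NumericalError,
    SimulationFailure,
)

logger = logging.getLogger(__name__)

#: 1 U/h of insulin = 1000/60 mU/min
MU_MIN_PER_U_H = 1000.0 / 60.0
#: molar mass of glucose, g/mmol
GLUCOSE_G_PER_MMOL = 0.18016
#: mg/dL per mmol/L for blood glucose
MGDL_PER_MMOL = 18.016


@dataclass(frozen=True)
class ModelParameters:
    """Population constants of the glucose-insulin model.

    Parameters
    ----------
    pG : float
        Non-insulin-mediated glucose clearance (1/min).
    alphaG : float
        Saturation of insulin-mediated glucose removal (L/mU).
    alphaI : float
        Saturation of plasma insulin clearance (L/mU).
    n : float
        Plasma insulin decay rate (1/min).
    k : float
        Plasma-to-interstitial insulin transport rate (1/min).
    EGPmax : float
        Maximum endogenous glucose production (mmol/min).
    CNS : float
        Insulin-independent central-nervous-system glucose uptake (mmol/min).
    VG, VI : float
        Glucose and insulin distribution volumes (L).
    IB : float
        Basal endogenous insulin appearance (mU/L/min).
    kI : float
        Suppression constant of endogenous insulin per unit exogenous
        infusion (min/mU); the endogenous term is ``exp(-kI*uex)*IB``.
    d1, d2 : float
        Enteral glucose transport/absorption rates (1/min).
    """

    pG: float
    alphaG: float
    alphaI: float
    n: float
    k: float
    EGPmax: float
    CNS: float
    VG: float
    VI: float
    IB: float
    kI: float
    d1: float
    d2: float

    def __post_init__(self) -> None:
        for name in ("pG", "n", "k", "EGPmax", "CNS", "VG", "VI", "IB", "kI",
                     "d1", "d2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"parameter {name}={v!r} must be "
                                         "finite and strictly positive")
        for name in ("alphaG", "alphaI"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ConfigurationError(f"parameter {name}={v!r} must be "
                                         "finite and non-negative")
        if self.CNS > self.EGPmax:
            raise ConfigurationError(
                f"CNS uptake ({self.CNS}) exceeds EGPmax ({self.EGPmax}); "
                "basal glucose balance would be negative")

    def as_tuple(self) -> tuple:
        """Flat tuple for the scalar integration hot path."""
        return (self.pG, self.alphaG, self.alphaI, self.n, self.k,
                self.EGPmax, self.CNS, self.VG, self.VI, self.IB, self.kI,
                self.d1, self.d2)

    @property
    def basal_glucose(self) -> float:
        """Insulin-free fasting equilibrium (EGPmax - CNS)/(pG*VG), mmol/L."""
        return (self.EGPmax - self.CNS) / (self.pG * self.VG)

    @classmethod
    def from_mapping(cls, m: dict) -> "ModelParameters":
        m = dict(m)
        ib_units = m.pop("ib_units", "per_volume")
        if ib_units not in ("per_volume", "total"):
            raise ConfigurationError(f"unknown ib_units {ib_units!r}")
        known = {f for f in cls.__dataclass_fields__}
        extra = set(m) - known
        if extra:
            raise ConfigurationError(f"unknown parameter keys: {sorted(extra)}")
        missing = known - set(m)
        if missing:
            raise ConfigurationError(f"missing parameter keys: {sorted(missing)}")
        if ib_units == "total":
            m["IB"] = m["IB"] / m["VI"]
        return cls(**{k: float(v) for k, v in m.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ModelParameters":
        """Packaged literature-typical defaults (see data/default_params.yaml)."""
        ref = resources.files("vtrial.data").joinpath("default_params.yaml")
        return cls.from_mapping(yaml.safe_load(ref.read_text()))


@dataclass
class MetabolicState:
    """Instantaneous model state.

    G: plasma glucose (mmol/L); I: plasma insulin (mU/L); Q: interstitial
    insulin effect (mU/L); P1, P2: gut glucose compartment masses (mmol);
    t: time (min).
    """

    G: float
    I: float
    Q: float
    P1: float = 0.0
    P2: float = 0.0
    t: float = 0.0

    def validate(self) -> None:
        vals = (self.G, self.I, self.Q, self.P1, self.P2, self.t)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidInputError(f"non-finite state: {self}")
        if self.G <= 0:
            raise InvalidInputError(f"plasma glucose must be positive: G={self.G}")
        if min(self.I, self.Q, self.P1, self.P2) < 0:
            raise InvalidInputError(f"negative insulin/gut state: {self}")


class PiecewiseConstant:
    """Right-open piecewise-constant signal on [start, end).

    ``values[i]`` holds on ``[times[i], times[i+1])``; the last value holds to
    ``end``.  Evaluation at ``end`` returns the last value.
    """

    def __init__(self, times: Sequence[float], values: Sequence[float],
                 end: float) -> None:
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.size == 0 or t.size != v.size:
            raise InvalidInputError("times and values must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("breakpoints must be strictly increasing")
        if end < t[-1]:
            raise InvalidInputError("end precedes the last breakpoint")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("non-finite values in schedule")
        self.times = t
        self.values = v
        self.end = float(end)

    @classmethod
    def constant(cls, value: float, start: float, end: float) -> "PiecewiseConstant":
        return cls([start], [value], end)

    @property
    def start(self) -> float:
        return float(self.times[0])

    def covers(self, t0: float, t1: float) -> bool:
        return self.start <= t0 + 1e-9 and t1 <= self.end + 1e-9

    def rate(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.values[max(i, 0)])

    def breakpoints_between(self, t0: float, t1: float) -> np.ndarray:
        m = (self.times > t0) & (self.times < t1)
        return self.times[m]

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, PiecewiseConstant)
                and self.end == other.end
                and np.array_equal(self.times, other.times)
                and np.array_equal(self.values, other.values))


def _as_signal(x, start: float, end: float) -> PiecewiseConstant:
    if isinstance(x, PiecewiseConstant):
        return x
    if hasattr(x, "as_piecewise"):  # SIProfile duck type
        return x.as_piecewise()
    return PiecewiseConstant.constant(float(x), start, end)


@dataclass
class InputSchedule:
    """Exogenous inputs: IV insulin, enteral carbohydrate, IV dextrose, boluses.

    Rates are piecewise constant (insulin in mU/min, glucose channels in
    mmol/min); boluses are instantaneous IV glucose amounts in mmol applied at
    their timestamp as a state increment of ``mmol/VG`` on G.
    """

    insulin: PiecewiseConstant
    enteral: PiecewiseConstant
    iv_dextrose: PiecewiseConstant
    boluses: list = field(default_factory=list)  # [(t_min, mmol), ...]

    @classmethod
    def constant(cls, start: float, end: float, insulin_mU_min: float = 0.0,
                 enteral_mmol_min: float = 0.0,
                 iv_dextrose_mmol_min: float = 0.0) -> "InputSchedule":
        return cls(
            insulin=PiecewiseConstant.constant(insulin_mU_min, start, end),
            enteral=PiecewiseConstant.constant(enteral_mmol_min, start, end),
            iv_dextrose=PiecewiseConstant.constant(iv_dextrose_mmol_min, start, end),
        )

    def covers(self, t0: float, t1: float) -> bool:
        return (self.insulin.covers(t0, t1) and self.enteral.covers(t0, t1)
                and self.iv_dextrose.covers(t0, t1))

    def rates_at(self, t: float) -> tuple[float, float, float]:
        return (self.insulin.rate(t), self.enteral.rate(t),
                self.iv_dextrose.rate(t))

    def breakpoints_between(self, t0: float, t1: float) -> np.ndarray:
        pts = [self.insulin.breakpoints_between(t0, t1),
               self.enteral.breakpoints_between(t0, t1),
               self.iv_dextrose.breakpoints_between(t0, t1),
               np.array([t for t, _ in self.boluses if t0 < t < t1])]
        return np.unique(np.concatenate(pts)) if pts else np.array([])


def derivatives(state: MetabolicState, params: ModelParameters, si: float,
                uex: float = 0.0, enteral_rate: float = 0.0,
                iv_dextrose_rate: float = 0.0) -> MetabolicState:
    """Time derivative of the model state (returned in state layout, t=dt/dt=1).

    dG/dt = -pG*G - si*G*Q/(1+alphaG*Q) + (P(t) + EGPmax - CNS)/VG
    dQ/dt = -k*Q + k*I
    dI/dt = -n*I/(1+alphaI*I) + uex/VI + exp(-kI*uex)*IB
    dP1/dt = -d1*P1 + enteral_rate ;  dP2/dt = -d2*P2 + d1*P1
    with plasma glucose appearance P(t) = d2*P2 + iv_dextrose_rate.
    """
    state.validate()
    if not np.isfinite(si) or si < 0:
        raise InvalidInputError(f"insulin sensitivity must be >= 0, got {si}")
    for name, v in (("uex", uex), ("enteral_rate", enteral_rate),
                    ("iv_dextrose_rate", iv_dextrose_rate)):
        if not np.isfinite(v) or v < 0:
            raise InvalidInputError(f"{name} must be finite and >= 0, got {v}")
    p = params
    P = p.d2 * state.P2 + iv_dextrose_rate
    dG = (-p.pG * state.G
          - si * state.G * state.Q / (1.0 + p.alphaG * state.Q)
          + (P + p.EGPmax - p.CNS) / p.VG)
    dQ = -p.k * state.Q + p.k * state.I
    dI = (-p.n * state.I / (1.0 + p.alphaI * state.I)
          + uex / p.VI + math.exp(-p.kI * uex) * p.IB)
    dP1 = -p.d1 * state.P1 + enteral_rate
    dP2 = -p.d2 * state.P2 + p.d1 * state.P1
    return MetabolicState(G=dG, I=dI, Q=dQ, P1=dP1, P2=dP2, t=1.0)


def _rhs(y, si, uex, ent, ivd, p):
    """Scalar RHS on a 5-tuple (G, I, Q, P1, P2); p is params.as_tuple()."""
    pG, aG, aI, n, k, EGP, CNS, VG, VI, IB, kI, d1, d2 = p
    G, I, Q, P1, P2 = y
    dG = -pG * G - si * G * Q / (1.0 + aG * Q) + (d2 * P2 + ivd + EGP - CNS) / VG
    dI = -n * I / (1.0 + aI * I) + uex / VI + math.exp(-kI * uex) * IB
    dQ = -k * Q + k * I
    dP1 = -d1 * P1 + ent
    dP2 = -d2 * P2 + d1 * P1
    return dG, dI, dQ, dP1, dP2


def _rk4_core(G, I, Q, P1, P2, si, en_in, ent, app, pG, aG, aI, n, k, VG,
              d1, d2, nsteps, h):
    """Numeric RK4 loop over one constant-input segment (numba-friendly)."""
    h2 = h * 0.5
    h6 = h / 6.0
    for _ in range(nsteps):
        # stage 1
        aG1 = -pG * G - si * G * Q / (1.0 + aG * Q) + (d2 * P2 + app) / VG
        aI1 = -n * I / (1.0 + aI * I) + en_in
        aQ1 = k * (I - Q)
        aP11 = -d1 * P1 + ent
        aP21 = -d2 * P2 + d1 * P1
        # stage 2
        Gm = G + h2 * aG1; Im = I + h2 * aI1; Qm = Q + h2 * aQ1
        P1m = P1 + h2 * aP11; P2m = P2 + h2 * aP21
        aG2 = -pG * Gm - si * Gm * Qm / (1.0 + aG * Qm) + (d2 * P2m + app) / VG
        aI2 = -n * Im / (1.0 + aI * Im) + en_in
        aQ2 = k * (Im - Qm)
        aP12 = -d1 * P1m + ent
        aP22 = -d2 * P2m + d1 * P1m
        # stage 3
        Gm = G + h2 * aG2; Im = I + h2 * aI2; Qm = Q + h2 * aQ2
        P1m = P1 + h2 * aP12; P2m = P2 + h2 * aP22
        aG3 = -pG * Gm - si * Gm * Qm / (1.0 + aG * Qm) + (d2 * P2m + app) / VG
        aI3 = -n * Im / (1.0 + aI * Im) + en_in
        aQ3 = k * (Im - Qm)
        aP13 = -d1 * P1m + ent
        aP23 = -d2 * P2m + d1 * P1m
        # stage 4
        Gm = G + h * aG3; Im = I + h * aI3; Qm = Q + h * aQ3
        P1m = P1 + h * aP13; P2m = P2 + h * aP23
        aG4 = -pG * Gm - si * Gm * Qm / (1.0 + aG * Qm) + (d2 * P2m + app) / VG
        aI4 = -n * Im / (1.0 + aI * Im) + en_in
        aQ4 = k * (Im - Qm)
        aP14 = -d1 * P1m + ent
        aP24 = -d2 * P2m + d1 * P1m
        G += h6 * (aG1 + 2.0 * (aG2 + aG3) + aG4)
        I += h6 * (aI1 + 2.0 * (aI2 + aI3) + aI4)
        Q += h6 * (aQ1 + 2.0 * (aQ2 + aQ3) + aQ4)
        P1 += h6 * (aP11 + 2.0 * (aP12 + aP13) + aP14)
        P2 += h6 * (aP21 + 2.0 * (aP22 + aP23) + aP24)
        if I < 0.0: I = 0.0
        if Q < 0.0: Q = 0.0
        if P1 < 0.0: P1 = 0.0
        if P2 < 0.0: P2 = 0.0
    return G, I, Q, P1, P2


try:  # optional JIT of the inner loop; semantics identical either way
    from numba import njit as _njit

    _rk4_core = _njit(cache=False, fastmath=False)(_rk4_core)
except Exception:  # pragma: no cover - numba is normally present
    pass


def integrate_segment(y: tuple, si: float, uex: float, ent: float, ivd: float,
                      duration: float, p: tuple, dt: float = 0.25) -> tuple:
    """Advance the state over one constant-input segment with fixed-step RK4.

    This is the hot path shared by identification and the trial engine; inputs
    are constant over the segment by construction, so no event handling is
    needed.  Negative I/Q/P1/P2 excursions (integration noise near zero) are
    clipped at 0.
    """
    if duration <= 0:
        return y
    nsteps = max(1, int(math.ceil(duration / dt - 1e-12)))
    h = duration / nsteps
    pG, aG, aI, n, k, EGP, CNS, VG, VI, IB, kI, d1, d2 = p
    en_in = uex / VI + math.exp(-kI * uex) * IB  # constant over the segment
    app = ivd + EGP - CNS
    G, I, Q, P1, P2 = _rk4_core(y[0], y[1], y[2], y[3], y[4], si, en_in, ent,
                                app, pG, aG, aI, n, k, VG, d1, d2, nsteps, h)
    if G <= 0.0:
        raise SimulationFailure(
            f"plasma glucose became nonphysical (G={G:.4g} mmol/L)")
    if not (math.isfinite(G) and math.isfinite(I) and math.isfinite(Q)):
        raise NumericalError("non-finite state after segment integration")
    return (G, I, Q, P1, P2)


def _lsoda_segment(y, si, uex, ent, ivd, duration, p, rtol=1e-9, atol=1e-10):
    from scipy.integrate import solve_ivp

    def f(t, yy):
        return _rhs(tuple(yy), si, uex, ent, ivd, p)

    sol = solve_ivp(f, (0.0, duration), list(y), method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise NumericalError(f"LSODA failed over a {duration:.3g}-min segment: "
                             f"{sol.message}")
    out = [max(v, 0.0) for v in sol.y[:, -1]]
    out[0] = sol.y[0, -1]
    if out[0] <= 0:
        raise SimulationFailure(
            f"plasma glucose became nonphysical (G={out[0]:.4g} mmol/L)")
    return tuple(out)


@dataclass
class Trajectory:
    """Sampled model trajectory; P is plasma glucose appearance (mmol/min)."""

    t: np.ndarray
    G: np.ndarray
    I: np.ndarray
    Q: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    P: np.ndarray

    def final_state(self) -> MetabolicState:
        return MetabolicState(G=float(self.G[-1]), I=float(self.I[-1]),
                              Q=float(self.Q[-1]), P1=float(self.P1[-1]),
                              P2=float(self.P2[-1]), t=float(self.t[-1]))

    def state_at(self, t: float) -> MetabolicState:
        i = int(np.argmin(np.abs(self.t - t)))
        if abs(self.t[i] - t) > 1e-6:
            raise InvalidInputError(f"time {t} is not a sampled trajectory point")
        return MetabolicState(G=float(self.G[i]), I=float(self.I[i]),
                              Q=float(self.Q[i]), P1=float(self.P1[i]),
                              P2=float(self.P2[i]), t=float(self.t[i]))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_min": self.t, "G_mmol_L": self.G, "I_mU_L": self.I,
            "Q_mU_L": self.Q, "P_mmol_min": self.P,
        })


def integrate(initial: MetabolicState, si_profile, schedule: InputSchedule,
              horizon: float, step: float = 15.0, method: str = "rk4",
              rk4_dt: float = 0.25,
              params: ModelParameters | None = None) -> Trajectory:
    """Integrate the model over ``[initial.t, initial.t + horizon]``.

    ``si_profile`` may be a float (constant SI), a :class:`PiecewiseConstant`
    or any object with ``as_piecewise()``.  Integration restarts at every
    breakpoint of SI and of the input schedule so piecewise-constant inputs
    are never averaged across their discontinuities; boluses are applied as
    instantaneous increments of ``mmol/VG`` on G.  ``step`` controls output
    sampling only; ``method`` selects the fixed-step RK4 hot path (default)
    or scipy's adaptive LSODA (``"lsoda"``).  ``params`` defaults to the
    packaged population constants.
    """
    if params is None:
        params = ModelParameters.default()
    return integrate_model(params, initial, si_profile, schedule, horizon,
                           step=step, method=method, rk4_dt=rk4_dt)


def integrate_model(params: ModelParameters, initial: MetabolicState,
                    si_profile, schedule: InputSchedule, horizon: float,
                    step: float = 15.0, method: str = "rk4",
                    rk4_dt: float = 0.25) -> Trajectory:
    """See :func:`integrate`; explicit-parameter form used throughout."""
    initial.validate()
    if horizon < 0 or step <= 0:
        raise InvalidInputError("horizon must be >= 0 and step > 0")
    t0, t1 = initial.t, initial.t + horizon
    si = _as_signal(si_profile, t0, t1)
    if not si.covers(t0, t1):
        raise CoverageError(
            f"SI profile covers [{si.start}, {si.end}], need [{t0}, {t1}]")
    if not schedule.covers(t0, t1):
        raise CoverageError(f"input schedule does not cover [{t0}, {t1}]")

    p = params.as_tuple()
    y = (initial.G, initial.I, initial.Q, initial.P1, initial.P2)
    if horizon == 0:
        return _finish([t0], [y], [schedule.rates_at(t0)], params)

    pts = np.unique(np.concatenate([
        np.arange(t0, t1, step), [t1],
        si.breakpoints_between(t0, t1),
        schedule.breakpoints_between(t0, t1),
    ]))
    bolus_map: dict[float, float] = {}
    for tb, mmol in schedule.boluses:
        if t0 <= tb <= t1:
            bolus_map[tb] = bolus_map.get(tb, 0.0) + mmol

    times = [float(pts[0])]
    states = [y]
    rates = [schedule.rates_at(pts[0])]
    if pts[0] in bolus_map:
        y = (y[0] + bolus_map[pts[0]] / params.VG,) + y[1:]
        states[-1] = y
    for a, b in zip(pts[:-1], pts[1:]):
        svalue = si.rate(a)
        if svalue < 0:
            raise InvalidInputError(f"negative SI {svalue} at t={a}")
        uex, ent, ivd = schedule.rates_at(a)
        try:
            if method == "rk4":
                y = integrate_segment(y, svalue, uex, ent, ivd, b - a, p, rk4_dt)
            elif method == "lsoda":
                y = _lsoda_segment(y, svalue, uex, ent, ivd, b - a, p)
            else:
                raise InvalidInputError(f"unknown method {method!r}")
        except (SimulationFailure, NumericalError) as exc:
            raise type(exc)(f"{exc} (interval [{a:.1f}, {b:.1f}] min)") from exc
        if b in bolus_map:
            y = (y[0] + bolus_map[b] / params.VG,) + y[1:]
        times.append(float(b))
        states.append(y)
        rates.append(schedule.rates_at(b))
    return _finish(times, states, rates, params)


def _finish(times, states, rates, params) -> Trajectory:
    arr = np.asarray(states, dtype=float)
    ivd = np.asarray([r[2] for r in rates], dtype=float)
    return Trajectory(
        t=np.asarray(times, dtype=float),
        G=arr[:, 0], I=arr[:, 1], Q=arr[:, 2], P1=arr[:, 3], P2=arr[:, 4],
        P=params.d2 * arr[:, 4] + ivd,
    )


def steady_state_insulin(params: ModelParameters, uex: float = 0.0
                         ) -> tuple[float, float]:
    """Equilibrium (I*, Q*) of the insulin subsystem at constant infusion.

    Solves ``n*I/(1 + alphaI*I) = uex/VI + exp(-kI*uex)*IB`` in closed form
    (the saturable clearance makes it linear after cross-multiplying) and
    returns Q* = I*.  Raises :class:`ConfigurationError` when clearance cannot
    balance the appearance rate (no positive root: nonphysical parameters or
    an enormous infusion).
    """
    if not np.isfinite(uex) or uex < 0:
        raise InvalidInputError(f"uex must be finite and >= 0, got {uex}")
    b = uex / params.VI + math.exp(-params.kI * uex) * params.IB
    denom = params.n - b * params.alphaI
    if denom <= 0:
        raise ConfigurationError(
            "insulin clearance saturates below the appearance rate "
            f"(n={params.n}, appearance={b:.4g}, alphaI={params.alphaI}); "
            "no positive equilibrium exists")
    i_star = b / denom
    return i_star, i_star


def steady_state_gut(params: ModelParameters, enteral_rate: float
                     ) -> tuple[float, float]:
    """Equilibrium gut compartment masses (P1*, P2*) at a constant feed rate."""
    if enteral_rate < 0:
        raise InvalidInputError("enteral rate must be >= 0")
    p1 = enteral_rate / params.d1
    return p1, params.d1 * p1 / params.d2
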