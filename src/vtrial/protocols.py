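"""Declarative table-driven insulin dosing protocols.

A protocol is a set of ordered BG bands with actions: an absolute starting
rate used at the first measurement, and maintenance actions (rate increments,
no-change in the target band, halving, stop, stop-with-rescue-bolus) used
thereafter, plus measurement-timing rules.  Bands are lower-inclusive,
upper-exclusive ``[lo, hi)`` since the published tables reuse endpoints.

The two Glucontrol arms ship as packaged configs: ``glucontrol_a`` (intensive,
target 4.4-6.1 mmol/L) and ``glucontrol_b`` (conventional, target
7.8-10.0 mmol/L).  Custom protocols load from the same YAML layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import InvalidInputError, ProtocolDefinitionError
from .model import MGDL_PER_MMOL

BUILTIN_PROTOCOLS = ("glucontrol_a", "glucontrol_b")

_STARTING_ACTIONS = {"hold", "rate"}
_MAINTENANCE_ACTIONS = {"increment", "target", "halve", "stop", "stop_bolus"}
#: actions that stop the infusion and force hourly measurements (hypoglycemia)
_HYPO_ACTIONS = {"stop", "stop_bolus"}


@dataclass(frozen=True)
class Band:
    lo: float
    hi: float  # math.inf allowed
    action: str
    value: float = 0.0

    def contains(self, bg: float) -> bool:
        return self.lo <= bg < self.hi


@dataclass(frozen=True)
class TimingRules:
    relative_change_threshold: float = 0.5
    four_hour_rule: str = "literal"  # or "sustained"
    lookback_h: float = 4.0


@dataclass(frozen=True)
class ProtocolDefinition:
    name: str
    target: tuple[float, float]
    starting: tuple[Band, ...]
    maintenance: tuple[Band, ...]
    bolus_g: float = 10.0
    resume_threshold: float = 80.0 / MGDL_PER_MMOL  # mmol/L
    timing: TimingRules = field(default_factory=TimingRules)

    def in_target(self, bg: float) -> bool:
        return self.target[0] <= bg < self.target[1]


@dataclass
class ControllerState:
    """Mutable controller memory carried between measurements."""

    rate: float = 0.0                    # commanded infusion, U/h
    history: list = field(default_factory=list)  # [(t_min, bg_mmol_L), ...]
    started: bool = False
    insulin_stopped: bool = False
    hypo_lock: bool = False              # hourly measurements until resume
    next_due: float = 0.0                # min


@dataclass(frozen=True)
class ControlAction:
    """Outcome of one protocol decision."""

    new_rate: float                      # U/h
    bolus_g: float = 0.0                 # instantaneous IV glucose
    call_physician: bool = False
    interval_h: int = 1                  # next measurement in {1, 2, 4} h


def _lookup(bands: tuple[Band, ...], bg: float) -> Band:
    if not (bg > 0 and math.isfinite(bg)):
        raise InvalidInputError(f"BG must be finite and positive, got {bg}")
    for b in bands:
        if b.contains(bg):
            return b
    raise ProtocolDefinitionError(f"no band contains BG={bg}")  # pragma: no cover


def starting_rate(protocol: ProtocolDefinition, bg: float) -> float:
    """Absolute infusion rate (U/h) from the starting table; hold bands -> 0."""
    band = _lookup(protocol.starting, bg)
    return 0.0 if band.action == "hold" else band.value


def maintenance_action(protocol: ProtocolDefinition, state: ControllerState,
                       bg: float) -> ControlAction:
    """Apply the maintenance table to the current commanded rate.

    Increments add to the current rate (floored at 0), ``halve`` multiplies by
    0.5, ``stop`` zeroes the rate, ``stop_bolus`` also emits the rescue IV
    glucose bolus and a call-physician flag.  The target band leaves the rate
    unchanged.  The returned measurement interval already accounts for the
    hypoglycemia lock (hourly until BG exceeds the resume threshold).
    """
    band = _lookup(protocol.maintenance, bg)
    rate = state.rate
    bolus = 0.0
    physician = False
    if band.action == "increment":
        rate = max(rate + band.value, 0.0)
    elif band.action == "target":
        pass
    elif band.action == "halve":
        rate *= 0.5
    elif band.action == "stop":
        rate = 0.0
    elif band.action == "stop_bolus":
        rate = 0.0
        bolus = protocol.bolus_g
        physician = True
    hypo_now = band.action in _HYPO_ACTIONS
    lock = (state.hypo_lock or hypo_now) and bg <= protocol.resume_threshold
    interval = next_measurement_interval(protocol, state, bg,
                                         hypo_lock=lock or hypo_now)
    return ControlAction(new_rate=rate, bolus_g=bolus, call_physician=physician,
                         interval_h=interval)


def next_measurement_interval(protocol: ProtocolDefinition,
                              state: ControllerState, bg: float,
                              hypo_lock: bool | None = None) -> int:
    """Hours until the next BG measurement: 1, 2 or 4.

    Hourly whenever BG is outside the target band or a hypoglycemia lock is
    active.  In target, 2-hourly under limited variation (relative change from
    the previous measurement below the configured 50% threshold).  The
    4-hourly escalation follows the configured interpretation: ``literal``
    (BG below half the highest BG of the lookback window) or ``sustained``
    (in target throughout the lookback window with limited variation).
    """
    if not state.history:
        raise InvalidInputError("measurement history is empty")
    if hypo_lock is None:
        hypo_lock = state.hypo_lock and bg <= protocol.resume_threshold
    if hypo_lock or not protocol.in_target(bg):
        return 1
    t_now = state.history[-1][0]
    rules = protocol.timing
    prev = state.history[-2] if len(state.history) >= 2 else None
    small_change = (prev is not None and prev[1] > 0 and
                    abs(bg - prev[1]) / prev[1] < rules.relative_change_threshold)
    window = [(t, v) for t, v in state.history
              if t_now - rules.lookback_h * 60.0 <= t <= t_now]
    if rules.four_hour_rule == "sustained":
        covered = window and window[0][0] <= t_now - rules.lookback_h * 60.0 + 1e-9
        if (covered and small_change
                and all(protocol.in_target(v) for _, v in window)):
            return 4
        return 2 if small_change else 1
    # literal rule: BG under half the highest glycemia of the last 4 hours
    if small_change:
        return 2
    hmax = max(v for _, v in window)
    if bg < 0.5 * hmax:
        return 4
    return 1


def apply_decision(protocol: ProtocolDefinition, state: ControllerState,
                   bg: float, t: float) -> ControlAction:
    """Record a measurement, decide, and update the controller state.

    At the first measurement the starting table sets an absolute rate; the
    maintenance table governs thereafter.  This is the single entry point the
    trial engine uses, so replaying a measurement log through it reproduces
    the commanded insulin trace exactly.
    """
    state.history.append((t, bg))
    if not state.started:
        rate = starting_rate(protocol, bg)
        state.started = True
        # hypoglycemic on admission: hourly watch per the maintenance table
        hypo = _lookup(protocol.maintenance, bg).action in _HYPO_ACTIONS
        lock = hypo and bg <= protocol.resume_threshold
        interval = 1 if (lock or not protocol.in_target(bg)) else \
            next_measurement_interval(protocol, state, bg, hypo_lock=False)
        action = ControlAction(new_rate=rate, interval_h=interval)
        state.hypo_lock = lock
    else:
        action = maintenance_action(protocol, state, bg)
        band = _lookup(protocol.maintenance, bg)
        hypo_now = band.action in _HYPO_ACTIONS
        state.hypo_lock = ((state.hypo_lock or hypo_now)
                           and bg <= protocol.resume_threshold)
    state.rate = action.new_rate
    state.insulin_stopped = action.new_rate == 0.0
    state.next_due = t + action.interval_h * 60.0
    return action


def _parse_band(row, allowed, where: str) -> Band:
    if not isinstance(row, (list, tuple)) or len(row) not in (3, 4):
        raise ProtocolDefinitionError(f"{where}: band row {row!r} must be "
                                      "[lo, hi, action] or [lo, hi, action, value]")
    lo, hi, action = row[0], row[1], row[2]
    hi = math.inf if hi in ("inf", ".inf", None) else float(hi)
    band = Band(lo=float(lo), hi=hi, action=str(action),
                value=float(row[3]) if len(row) == 4 else 0.0)
    if band.action not in allowed:
        raise ProtocolDefinitionError(f"{where}: unknown action {band.action!r}")
    if band.action in ("rate", "increment") and len(row) != 4:
        raise ProtocolDefinitionError(f"{where}: action {band.action!r} needs a value")
    return band


def _validate_partition(bands: tuple[Band, ...], where: str) -> tuple[Band, ...]:
    bands = tuple(sorted(bands, key=lambda b: b.lo))
    if not bands or bands[0].lo != 0.0:
        raise ProtocolDefinitionError(f"{where}: bands must start at 0")
    for a, b in zip(bands[:-1], bands[1:]):
        if a.hi < b.lo:
            raise ProtocolDefinitionError(
                f"{where}: gap between [{a.lo}, {a.hi}) and [{b.lo}, {b.hi})")
        if a.hi > b.lo:
            raise ProtocolDefinitionError(
                f"{where}: overlap between [{a.lo}, {a.hi}) and [{b.lo}, {b.hi})")
    if bands[-1].hi != math.inf:
        raise ProtocolDefinitionError(f"{where}: last band must be unbounded")
    return bands


def load_protocol(source) -> ProtocolDefinition:
    """Load a protocol from a builtin name, a YAML path, or a mapping.

    The band partition of each table is validated at load time (no gaps,
    overlaps, or bounded final band), so runtime lookups cannot fail.
    """
    if isinstance(source, str) and source in BUILTIN_PROTOCOLS:
        ref = resources.files("vtrial.data").joinpath(f"{source}.yaml")
        cfg = yaml.safe_load(ref.read_text())
    elif isinstance(source, dict):
        cfg = source
    else:
        path = Path(source)
        if not path.exists():
            raise ProtocolDefinitionError(
                f"unknown protocol {source!r}; built-ins: "
                f"{', '.join(BUILTIN_PROTOCOLS)}")
        cfg = yaml.safe_load(path.read_text())

    try:
        name = cfg["name"]
        target = (float(cfg["target"][0]), float(cfg["target"][1]))
        starting = tuple(_parse_band(r, _STARTING_ACTIONS, f"{name}.starting")
                         for r in cfg["starting"])
        maintenance = tuple(_parse_band(r, _MAINTENANCE_ACTIONS,
                                        f"{name}.maintenance")
                            for r in cfg["maintenance"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ProtocolDefinitionError(f"malformed protocol config: {exc}") from exc
    starting = _validate_partition(starting, f"{name}.starting")
    maintenance = _validate_partition(maintenance, f"{name}.maintenance")
    hypo = cfg.get("hypoglycemia", {})
    timing_cfg = cfg.get("timing", {})
    timing = TimingRules(
        relative_change_threshold=float(
            timing_cfg.get("relative_change_threshold", 0.5)),
        four_hour_rule=str(timing_cfg.get("four_hour_rule", "literal")),
        lookback_h=float(timing_cfg.get("lookback_h", 4.0)),
    )
    if timing.four_hour_rule not in ("literal", "sustained"):
        raise ProtocolDefinitionError(
            f"four_hour_rule must be 'literal' or 'sustained', "
            f"got {timing.four_hour_rule!r}")
    target_bands = [b for b in maintenance if b.action == "target"]
    if len(target_bands) != 1 or (target_bands[0].lo, target_bands[0].hi) != target:
        raise ProtocolDefinitionError(
            f"{name}: exactly one maintenance band must be the target band "
            f"{target}")
    return ProtocolDefinition(
        name=name, target=target, starting=starting, maintenance=maintenance,
        bolus_g=float(hypo.get("bolus_g", 10.0)),
        resume_threshold=float(hypo.get("resume_threshold_mg_dl", 80.0))
        / MGDL_PER_MMOL,
        timing=timing,
    )
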