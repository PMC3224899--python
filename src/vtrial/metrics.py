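"""Comparison analytics for clinical records versus virtual-trial results.

Everything here reduces to three primitives: pooled and per-patient empirical
BG CDFs, median [IQR] cohort summary tables (insulin rate, glucose rate, BG,
measurement frequency), and the compliance fraction (actual measurements as a
percentage of protocol-specified measurement opportunities).

Conventions: quantiles use linear interpolation between order statistics;
per-patient rate medians are time-weighted over their piecewise-constant
segments (dosing segments have unequal lengths); patient-days are counted
fractionally (stay minutes / 1440).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError
from .model import GLUCOSE_G_PER_MMOL


@dataclass(frozen=True)
class EmpiricalCDF:
    """Right-continuous empirical CDF: P(X <= x)."""

    values: np.ndarray
    probs: np.ndarray

    @classmethod
    def from_values(cls, values) -> "EmpiricalCDF":
        v = np.sort(np.asarray(values, dtype=float))
        if v.size == 0:
            raise InsufficientDataError("cannot build a CDF from no values")
        return cls(values=v, probs=np.arange(1, v.size + 1) / v.size)

    def evaluate(self, x: float) -> float:
        return float(np.searchsorted(self.values, x, side="right") / self.values.size)

    def quantile(self, p: float) -> float:
        return float(np.quantile(self.values, p))  # linear interpolation

    @property
    def median(self) -> float:
        return self.quantile(0.5)


def time_weighted_median(edges, values) -> float:
    """Median of a piecewise-constant signal weighted by segment duration.

    ``edges`` has one more entry than ``values``.  The weighted median is the
    value at which cumulative duration crosses half the total; at an exact
    tie the two straddling values are averaged.
    """
    edges = np.asarray(edges, dtype=float)
    vals = np.asarray(values, dtype=float)
    if edges.size != vals.size + 1:
        raise InvalidInputError("edges must have len(values)+1 entries")
    w = np.diff(edges)
    if np.any(w < 0) or w.sum() <= 0:
        raise InvalidInputError("edges must be non-decreasing with span > 0")
    order = np.argsort(vals, kind="stable")
    v, w = vals[order], w[order]
    cw = np.cumsum(w)
    half = 0.5 * cw[-1]
    i = int(np.searchsorted(cw, half))
    if np.isclose(cw[i], half) and i + 1 < v.size:
        return float(0.5 * (v[i] + v[i + 1]))
    return float(v[i])


@dataclass(frozen=True)
class PatientStats:
    """Flattened per-patient quantities shared by records and trial results."""

    patient_id: str
    bg: np.ndarray                  # measured BG, mmol/L
    insulin_edges: np.ndarray       # min
    insulin_values: np.ndarray      # U/h
    glucose_edges: np.ndarray       # min
    glucose_values: np.ndarray      # g/h
    stay_min: float

    @property
    def median_bg(self) -> float:
        return float(np.median(self.bg))

    @property
    def median_insulin_rate(self) -> float:
        return time_weighted_median(self.insulin_edges, self.insulin_values)

    @property
    def median_glucose_rate(self) -> float:
        return time_weighted_median(self.glucose_edges, self.glucose_values)

    @property
    def n_measurements(self) -> int:
        return int(self.bg.size)

    @property
    def stay_days(self) -> float:
        return self.stay_min / 1440.0


def as_patient_stats(x) -> PatientStats:
    """Adapt a PatientRecord or TrialResult to :class:`PatientStats`."""
    if isinstance(x, PatientStats):
        return x
    if hasattr(x, "patient_stats"):        # TrialResult
        return x.patient_stats()
    if hasattr(x, "bg_values"):            # PatientRecord
        ins_edges = np.append(
            np.clip(x.insulin.times, x.t_start, None), x.t_end)
        glu_edges = np.append(np.clip(x.carb.times, x.t_start, None), x.t_end)
        return PatientStats(
            patient_id=x.patient_id,
            bg=np.asarray(x.bg_values, dtype=float),
            insulin_edges=ins_edges,
            insulin_values=np.asarray(x.insulin.values, dtype=float),
            glucose_edges=glu_edges,
            glucose_values=np.asarray(x.carb.values, dtype=float)
            * GLUCOSE_G_PER_MMOL * 60.0,   # mmol/min -> g/h
            stay_min=float(x.t_end - x.t_start),
        )
    raise InvalidInputError(f"cannot extract patient statistics from {type(x)}")


def cohort_bg_cdf(items) -> EmpiricalCDF:
    """Pooled empirical CDF over every measured BG value in the cohort."""
    stats = [as_patient_stats(x) for x in items]
    pooled = np.concatenate([s.bg for s in stats]) if stats else np.empty(0)
    return EmpiricalCDF.from_values(pooled)


def per_patient_median_cdf(items) -> EmpiricalCDF:
    """Empirical CDF of per-patient median BG values."""
    stats = [as_patient_stats(x) for x in items]
    if not stats:
        raise InsufficientDataError("no patients")
    return EmpiricalCDF.from_values([s.median_bg for s in stats])


def _median_iqr(values) -> tuple[float, float, float]:
    v = np.asarray(values, dtype=float)
    return (float(np.quantile(v, 0.5)), float(np.quantile(v, 0.25)),
            float(np.quantile(v, 0.75)))


@dataclass(frozen=True)
class CohortSummary:
    """Median [IQR] across per-patient statistics, plus measurement load."""

    n_patients: int
    insulin_rate_median: float
    insulin_rate_iqr: tuple[float, float]
    glucose_rate_median: float
    glucose_rate_iqr: tuple[float, float]
    bg_median: float
    bg_iqr: tuple[float, float]
    total_bg_measures: int
    measurements_per_patient_day: float

    def as_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "insulin_rate_U_h": [self.insulin_rate_median,
                                 *self.insulin_rate_iqr],
            "glucose_rate_g_h": [self.glucose_rate_median,
                                 *self.glucose_rate_iqr],
            "bg_mmol_L": [self.bg_median, *self.bg_iqr],
            "total_bg_measures": self.total_bg_measures,
            "measurements_per_patient_day": self.measurements_per_patient_day,
        }


def cohort_summary(items) -> CohortSummary:
    """Per-patient statistics first, then cohort median [IQR] across patients."""
    stats = [as_patient_stats(x) for x in items]
    if not stats:
        raise InsufficientDataError("no patients")
    ins = _median_iqr([s.median_insulin_rate for s in stats])
    glu = _median_iqr([s.median_glucose_rate for s in stats])
    bg = _median_iqr([s.median_bg for s in stats])
    total = sum(s.n_measurements for s in stats)
    days = sum(s.stay_days for s in stats)
    return CohortSummary(
        n_patients=len(stats),
        insulin_rate_median=ins[0], insulin_rate_iqr=(ins[1], ins[2]),
        glucose_rate_median=glu[0], glucose_rate_iqr=(glu[1], glu[2]),
        bg_median=bg[0], bg_iqr=(bg[1], bg[2]),
        total_bg_measures=total,
        measurements_per_patient_day=total / days if days > 0 else float("nan"),
    )


def compliance_fraction(actual_counts, per_protocol_results) -> dict:
    """Actual measurements as a percentage of per-protocol opportunities.

    ``actual_counts`` maps patient id -> number of clinically recorded
    measurements (or is an iterable of records); ``per_protocol_results`` are
    the matching per-protocol trial results.  Returns per-patient fractions
    and the cohort-pooled fraction (total actual / total specified x 100).
    """
    if not isinstance(actual_counts, dict):
        actual_counts = {r.patient_id: as_patient_stats(r).n_measurements
                         for r in actual_counts}
    per_patient = {}
    tot_actual = tot_spec = 0
    for res in per_protocol_results:
        s = as_patient_stats(res)
        if s.patient_id not in actual_counts:
            raise InvalidInputError(
                f"no actual measurements for patient {s.patient_id}")
        a = actual_counts[s.patient_id]
        per_patient[s.patient_id] = 100.0 * a / s.n_measurements
        tot_actual += a
        tot_spec += s.n_measurements
    if tot_spec == 0:
        raise InsufficientDataError("per-protocol results have no measurements")
    return {"per_patient_pct": per_patient,
            "pooled_pct": 100.0 * tot_actual / tot_spec}


def validation_report(clinical_records, self_per_protocol, self_replayed,
                      cross) -> dict:
    """Bundle the four validation arms into CDFs, summaries and differences.

    The self-vs-clinical median-BG gap reflects model plus compliance error;
    the cross-vs-clinical gap additionally tests the independence of the
    identified SI profiles from the treatment that produced them.
    """
    arms = {
        "clinical": clinical_records,
        "self_per_protocol": self_per_protocol,
        "self_replayed": self_replayed,
        "cross_per_protocol": cross,
    }
    report: dict = {"arms": {}, "pairwise_median_bg_diff_pct": {}}
    medians = {}
    for name, items in arms.items():
        cdf = cohort_bg_cdf(items)
        report["arms"][name] = {
            "cohort_bg_cdf": cdf,
            "per_patient_median_cdf": per_patient_median_cdf(items),
            "summary": cohort_summary(items),
        }
        medians[name] = cdf.median
    for name in ("self_per_protocol", "self_replayed", "cross_per_protocol"):
        ref = medians["clinical"]
        report["pairwise_median_bg_diff_pct"][f"{name}_vs_clinical"] = (
            100.0 * (medians[name] - ref) / ref)
    report["compliance"] = compliance_fraction(clinical_records,
                                               self_per_protocol)
    return report
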