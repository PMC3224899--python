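"""SI identification: round-trip recovery, fit/prediction errors, screening."""

import numpy as np
import pytest

from vtrial.errors import CoverageError, InsufficientDataError
from vtrial.identify import (
    DEFAULT_SI_BOUNDS,
    PatientRecord,
    SIProfile,
    STATUS_CLAMPED_LOW,
    STATUS_IDENTIFIED,
    fit_errors,
    forward_prediction_errors,
    identify_si_profile,
    screen_cohort,
)
from vtrial.model import (
    MU_MIN_PER_U_H,
    InputSchedule,
    MetabolicState,
    PiecewiseConstant,
    integrate_model,
    integrate_segment,
    steady_state_gut,
    steady_state_insulin,
)


def simulate_record(params, si_signal, span_min, bg_every_min=60.0,
                    insulin_U_h=2.0, carb_mmol_min=0.5, g0=8.0,
                    patient_id="sim") -> PatientRecord:
    """Forward-simulate the model and package the samples as a record."""
    uex = insulin_U_h * MU_MIN_PER_U_H
    i0, q0 = steady_state_insulin(params, uex)
    p1, p2 = steady_state_gut(params, carb_mmol_min)
    s0 = MetabolicState(G=g0, I=i0, Q=q0, P1=p1, P2=p2, t=0.0)
    sched = InputSchedule.constant(0.0, span_min, insulin_mU_min=uex,
                                   enteral_mmol_min=carb_mmol_min)
    traj = integrate_model(params, s0, si_signal, sched, span_min,
                           step=bg_every_min)
    times = np.arange(0.0, span_min + 1e-9, bg_every_min)
    bg = np.array([traj.G[np.argmin(np.abs(traj.t - t))] for t in times])
    return PatientRecord(
        patient_id=patient_id, bg_times=times, bg_values=bg,
        insulin=PiecewiseConstant.constant(insulin_U_h, 0.0, span_min),
        carb=PiecewiseConstant.constant(carb_mmol_min, 0.0, span_min),
        t_start=0.0, t_end=span_min)


class TestRoundTrip:
    def test_constant_si_recovered_within_a_tenth_percent(self, params):
        rec = simulate_record(params, 5.0e-4, span_min=12 * 60.0)
        prof = identify_si_profile(rec, params)
        assert np.all(np.abs(prof.values - 5.0e-4) / 5.0e-4 < 1e-3)
        assert all(s == STATUS_IDENTIFIED for s in prof.statuses)

    def test_step_profile_recovered(self, params):
        si = PiecewiseConstant([0.0, 6 * 60.0], [3.0e-4, 8.0e-4], 12 * 60.0)
        rec = simulate_record(params, si, span_min=12 * 60.0)
        prof = identify_si_profile(rec, params)
        truth = np.array([si.rate(t) for t in prof.breaks])
        rel = np.abs(prof.values - truth) / truth
        away_from_step = np.abs(prof.breaks - 6 * 60.0) > 1.0
        assert np.all(rel[away_from_step] < 5e-3)

    def test_unreachable_rise_clamps_low(self, params):
        rec = simulate_record(params, 3.0e-4, span_min=3 * 60.0)
        bg = rec.bg_values.copy()
        bg[1] = 30.0  # faster rise than the model can produce at SI_min
        rec = PatientRecord(patient_id="clamp", bg_times=rec.bg_times,
                            bg_values=bg, insulin=rec.insulin, carb=rec.carb,
                            t_start=rec.t_start, t_end=rec.t_end)
        prof = identify_si_profile(rec, params)
        assert prof.statuses[0] == STATUS_CLAMPED_LOW
        assert prof.values[0] == DEFAULT_SI_BOUNDS[0]

    def test_two_measurements_required(self, params):
        rec = simulate_record(params, 3e-4, span_min=60.0)
        rec = PatientRecord(patient_id="one", bg_times=rec.bg_times[:1],
                            bg_values=rec.bg_values[:1], insulin=rec.insulin,
                            carb=rec.carb, t_start=0.0, t_end=60.0)
        with pytest.raises(InsufficientDataError):
            identify_si_profile(rec, params)

    def test_si_to_bg_map_is_strictly_decreasing(self, params):
        rng = np.random.default_rng(5)
        p = params.as_tuple()
        for _ in range(10):
            g = rng.uniform(4, 15)
            i = q = rng.uniform(5, 80)
            uex = rng.uniform(0, 80)
            ent = rng.uniform(0, 1.2)
            y0 = (g, i, q, ent / params.d1, ent / params.d2)
            ends = [integrate_segment(y0, si, uex, ent, 0.0, 60.0, p)[0]
                    for si in np.geomspace(1e-6, 5e-3, 12)]
            assert np.all(np.diff(ends) < 0)


class TestFitErrors:
    def test_identified_profile_fits_to_numerical_noise(self, params):
        rec = simulate_record(params, 4.0e-4, span_min=10 * 60.0)
        prof = identify_si_profile(rec, params)
        assert fit_errors(rec, prof, params).median_fit_pct < 1e-4

    def test_perturbed_profile_has_positive_error(self, params):
        rec = simulate_record(params, 4.0e-4, span_min=10 * 60.0)
        prof = identify_si_profile(rec, params)
        worse = SIProfile(breaks=prof.breaks, values=prof.values * 1.1,
                          statuses=prof.statuses, end=prof.end)
        assert fit_errors(rec, worse, params).median_fit_pct > 0.0

    def test_disjoint_profile_span_raises(self, params):
        rec = simulate_record(params, 4.0e-4, span_min=6 * 60.0)
        prof = SIProfile(breaks=np.array([1e5]), values=np.array([3e-4]),
                         statuses=[STATUS_IDENTIFIED], end=1e5 + 60.0)
        with pytest.raises(CoverageError):
            fit_errors(rec, prof, params)

    def test_piecewise_fit_dominates_any_constant_profile(self, params):
        si = PiecewiseConstant([0.0, 3 * 60.0], [2.5e-4, 6.0e-4], 6 * 60.0)
        rec = simulate_record(params, si, span_min=6 * 60.0)
        prof = identify_si_profile(rec, params)
        best = fit_errors(rec, prof, params).median_fit_pct
        for c in np.geomspace(1e-4, 1e-3, 15):  # grid-search oracle
            const = SIProfile(breaks=prof.breaks,
                              values=np.full_like(prof.values, c),
                              statuses=prof.statuses, end=prof.end)
            assert best <= fit_errors(rec, const, params).median_fit_pct + 1e-12


class TestPrediction:
    def test_constant_si_predicts_exactly(self, params):
        rec = simulate_record(params, 4.0e-4, span_min=10 * 60.0)
        prof = identify_si_profile(rec, params)
        rep = forward_prediction_errors(rec, prof, params)
        assert rep.prediction_errors_pct.size > 0
        assert np.all(rep.prediction_errors_pct < 1e-4)

    def test_variable_si_predicts_worse_than_it_fits(self, params):
        rng = np.random.default_rng(11)
        hours = np.arange(0.0, 12 * 60.0, 60.0)
        vals = 4.0e-4 * (1.0 + 0.2 * rng.choice([-1.0, 1.0], hours.size))
        si = PiecewiseConstant(hours, vals, 12 * 60.0)
        rec = simulate_record(params, si, span_min=12 * 60.0)
        prof = identify_si_profile(rec, params)
        fit = fit_errors(rec, prof, params).median_fit_pct
        pred = forward_prediction_errors(rec, prof, params
                                         ).median_prediction_pct
        assert pred > fit

    def test_two_hourly_sampling_uses_midpoint_interpolation(self, params):
        rng = np.random.default_rng(3)
        hours = np.arange(0.0, 8 * 60.0, 60.0)
        vals = 4.0e-4 * np.exp(0.15 * rng.standard_normal(hours.size))
        si = PiecewiseConstant(hours, vals, 8 * 60.0)
        rec2 = simulate_record(params, si, span_min=8 * 60.0,
                               bg_every_min=120.0)
        prof = identify_si_profile(rec2, params)
        rep = forward_prediction_errors(rec2, prof, params)
        # hand-computed oracle for the first interpolated horizon (t=180 min):
        # the fitted trajectory from t=120 with the [0,120) interval's SI
        t_h = 180.0
        sig = prof.as_piecewise()
        traj = integrate_model(
            params,
            _state_at(rec2, prof, params, 120.0),
            sig.rate(120.0 - 1e-6),
            rec2.input_schedule(), 60.0, step=60.0)
        bg_ref = 0.5 * (rec2.bg_values[1] + rec2.bg_values[2])
        expected = abs(traj.G[-1] - bg_ref) / bg_ref * 100.0
        assert rep.prediction_errors_pct[0] == pytest.approx(expected,
                                                             rel=1e-6)

    def test_first_interval_excluded_from_prediction(self, params):
        rec = simulate_record(params, 4.0e-4, span_min=5 * 60.0)
        prof = identify_si_profile(rec, params)
        rep = forward_prediction_errors(rec, prof, params)
        # horizons start one interval in: at most span/60 - 1 predictions
        assert rep.prediction_errors_pct.size <= 4


def _state_at(record, profile, params, t):
    from vtrial.identify import _fitted_trajectory
    return _fitted_trajectory(record, profile, params).state_at(t)


class TestScreening:
    def _base(self, params, **kw):
        return simulate_record(params, 3e-4, span_min=72 * 60.0, **kw)

    def test_rules_and_reasons(self, params):
        ok = self._base(params)
        no_insulin = self._base(params, insulin_U_h=0.0, patient_id="ni")
        few = self._base(params, bg_every_min=24 * 60.0, patient_id="few")
        starved = PatientRecord(
            patient_id="starve", bg_times=ok.bg_times, bg_values=ok.bg_values,
            insulin=ok.insulin,
            carb=PiecewiseConstant([0.0, 49 * 60.0], [0.0, 0.5], 72 * 60.0),
            t_start=0.0, t_end=72 * 60.0)
        retained, excluded = screen_cohort([ok, no_insulin, few, starved])
        assert [r.patient_id for r in retained] == ["sim"]
        reasons = {r.patient_id: why for r, why in excluded}
        assert reasons["ni"] == "no insulin"
        assert reasons["few"] == "fewer than 5 BG measurements"
        assert reasons["starve"] == "no carbohydrate > 48 h"

    def test_exactly_48h_gap_is_retained(self, params):
        ok = self._base(params)
        borderline = PatientRecord(
            patient_id="border", bg_times=ok.bg_times, bg_values=ok.bg_values,
            insulin=ok.insulin,
            carb=PiecewiseConstant([0.0, 48 * 60.0], [0.0, 0.5], 72 * 60.0),
            t_start=0.0, t_end=72 * 60.0)
        retained, _ = screen_cohort([borderline])
        assert retained
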