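"""Glucose-insulin model: derivatives, equilibria, integration accuracy."""

import math

import numpy as np
import pytest
from scipy.optimize import bisect

from vtrial.errors import ConfigurationError, CoverageError, InvalidInputError
from vtrial.model import (
    InputSchedule,
    MetabolicState,
    ModelParameters,
    PiecewiseConstant,
    derivatives,
    integrate_model,
    steady_state_gut,
    steady_state_insulin,
)


def euler_oracle(params, state, si, uex, ent, ivd, duration, dt=0.01):
    """Independent explicit-Euler integration written directly from the ODEs."""
    p = params
    G, I, Q, P1, P2 = state.G, state.I, state.Q, state.P1, state.P2
    n = int(round(duration / dt))
    for _ in range(n):
        P = p.d2 * P2 + ivd
        dG = -p.pG * G - si * G * Q / (1 + p.alphaG * Q) \
            + (P + p.EGPmax - p.CNS) / p.VG
        dI = -p.n * I / (1 + p.alphaI * I) + uex / p.VI \
            + math.exp(-p.kI * uex) * p.IB
        dQ = -p.k * Q + p.k * I
        dP1 = -p.d1 * P1 + ent
        dP2 = -p.d2 * P2 + p.d1 * P1
        G, I, Q = G + dt * dG, I + dt * dI, Q + dt * dQ
        P1, P2 = P1 + dt * dP1, P2 + dt * dP2
    return G


class TestDerivatives:
    def test_insulin_free_glucose_equilibrium(self, params):
        g_star = (params.EGPmax - params.CNS) / (params.pG * params.VG)
        d = derivatives(MetabolicState(G=g_star, I=0, Q=0), params, si=0.0)
        assert d.G == pytest.approx(0.0, abs=1e-12)

    def test_interstitial_fixed_point_when_I_equals_Q(self, params):
        d = derivatives(MetabolicState(G=6.0, I=17.3, Q=17.3), params,
                        si=3e-4)
        assert d.Q == pytest.approx(0.0, abs=1e-12)

    def test_basal_secretion_unsuppressed_without_infusion(self, params):
        d = derivatives(MetabolicState(G=6.0, I=0.0, Q=0.0), params, si=0.0)
        assert d.I == pytest.approx(params.IB)

    def test_saturation_caps_insulin_mediated_uptake(self, params):
        # as Q -> inf the uptake term approaches si*G/alphaG from below
        g, si = 8.0, 4e-4
        d_inf = derivatives(MetabolicState(G=g, I=0, Q=1e12), params, si=si)
        d_zero = derivatives(MetabolicState(G=g, I=0, Q=0), params, si=si)
        assert d_zero.G - d_inf.G == pytest.approx(si * g / params.alphaG,
                                                   rel=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(state=MetabolicState(G=float("nan"), I=0, Q=0), si=1e-4),
        dict(state=MetabolicState(G=6.0, I=0, Q=0), si=-1e-5),
        dict(state=MetabolicState(G=-2.0, I=0, Q=0), si=1e-4),
    ])
    def test_invalid_inputs_rejected(self, params, bad):
        with pytest.raises(InvalidInputError):
            derivatives(bad["state"], params, si=bad["si"])


class TestIntegration:
    def test_zero_horizon_returns_initial_state_only(self, params):
        s0 = MetabolicState(G=7.0, I=10.0, Q=10.0)
        sched = InputSchedule.constant(0.0, 0.0)
        traj = integrate_model(params, s0, 3e-4, sched, horizon=0.0)
        assert traj.t.size == 1 and traj.G[0] == 7.0

    def test_agrees_with_euler_oracle_within_a_tenth_percent(self, params):
        s0 = MetabolicState(G=9.0, I=15.0, Q=15.0, P1=5.0, P2=5.0)
        si, uex, ent = 4e-4, 33.3, 0.5
        sched = InputSchedule.constant(0.0, 480.0, insulin_mU_min=uex,
                                       enteral_mmol_min=ent)
        traj = integrate_model(params, s0, si, sched, horizon=480.0)
        g_ref = euler_oracle(params, s0, si, uex, ent, 0.0, 480.0, dt=0.01)
        assert traj.G[-1] == pytest.approx(g_ref, rel=1e-3)

    def test_lsoda_and_rk4_agree(self, params):
        s0 = MetabolicState(G=9.0, I=15.0, Q=15.0)
        sched = InputSchedule.constant(0.0, 240.0, insulin_mU_min=20.0,
                                       enteral_mmol_min=0.4)
        kw = dict(horizon=240.0, step=60.0)
        g_rk4 = integrate_model(params, s0, 3e-4, sched, **kw).G[-1]
        g_lsoda = integrate_model(params, s0, 3e-4, sched, method="lsoda",
                                  **kw).G[-1]
        assert g_rk4 == pytest.approx(g_lsoda, rel=1e-7)

    def test_more_insulin_lowers_final_glucose(self, params):
        s0 = MetabolicState(G=9.0, I=12.0, Q=12.0)
        finals = []
        for uex in (10.0, 50.0):
            sched = InputSchedule.constant(0.0, 480.0, insulin_mU_min=uex)
            finals.append(
                integrate_model(params, s0, 3e-4, sched, horizon=480.0).G[-1])
        assert finals[1] < finals[0]

    def test_higher_si_never_raises_glucose_anywhere(self, params):
        s0 = MetabolicState(G=10.0, I=20.0, Q=20.0)
        sched = InputSchedule.constant(0.0, 600.0, insulin_mU_min=25.0,
                                       enteral_mmol_min=0.6)
        lo = integrate_model(params, s0, 2e-4, sched, horizon=600.0, step=30.0)
        hi = integrate_model(params, s0, 6e-4, sched, horizon=600.0, step=30.0)
        assert np.all(hi.G <= lo.G + 1e-9)

    def test_insulin_free_relaxation_to_basal_glucose_is_monotone(self, params):
        sched = InputSchedule.constant(0.0, 1440.0)
        for g0 in (3.0, 25.0):
            s0 = MetabolicState(G=g0, I=0.0, Q=0.0)
            traj = integrate_model(params, s0, 0.0, sched, horizon=1440.0,
                                   step=30.0)
            gaps = np.abs(traj.G - params.basal_glucose)
            assert np.all(np.diff(gaps) <= 1e-9)
            assert gaps[-1] < 0.05 * abs(g0 - params.basal_glucose) + 1e-6

    def test_step_refinement_invariance(self, params):
        s0 = MetabolicState(G=8.0, I=14.0, Q=14.0)
        sched = InputSchedule.constant(0.0, 480.0, insulin_mU_min=30.0,
                                       enteral_mmol_min=0.3)
        g1 = integrate_model(params, s0, 3e-4, sched, horizon=480.0,
                             rk4_dt=0.5).G[-1]
        g2 = integrate_model(params, s0, 3e-4, sched, horizon=480.0,
                             rk4_dt=0.25).G[-1]
        assert abs(g1 - g2) / g2 < 1e-6

    def test_breakpoints_are_honored_not_averaged(self, params):
        # insulin switched on at t=120; trajectory must sample the breakpoint
        ins = PiecewiseConstant([0.0, 120.0], [0.0, 50.0], 480.0)
        sched = InputSchedule(insulin=ins,
                              enteral=PiecewiseConstant.constant(0, 0, 480),
                              iv_dextrose=PiecewiseConstant.constant(0, 0, 480))
        s0 = MetabolicState(G=9.0, I=12.0, Q=12.0)
        traj = integrate_model(params, s0, 3e-4, sched, horizon=480.0,
                               step=480.0)
        assert 120.0 in traj.t
        g_ref = euler_oracle(params, s0, 3e-4, 0.0, 0.0, 0.0, 120.0, 0.01)
        i_mid = np.flatnonzero(traj.t == 120.0)[0]
        assert traj.G[i_mid] == pytest.approx(g_ref, rel=1e-3)

    def test_bolus_raises_glucose_by_mmol_over_vg(self, params):
        sched = InputSchedule.constant(0.0, 120.0)
        sched.boluses.append((60.0, 55.5))
        s0 = MetabolicState(G=params.basal_glucose, I=0.0, Q=0.0)
        traj = integrate_model(params, s0, 0.0, sched, horizon=120.0,
                               step=60.0)
        i = np.flatnonzero(traj.t == 60.0)[0]
        # at basal equilibrium with no insulin, G just before the bolus ~ basal
        assert traj.G[i] == pytest.approx(
            params.basal_glucose + 55.5 / params.VG, rel=1e-6)

    def test_coverage_gap_raises(self, params):
        s0 = MetabolicState(G=7.0, I=10.0, Q=10.0)
        sched = InputSchedule.constant(0.0, 100.0)
        with pytest.raises(CoverageError):
            integrate_model(params, s0, 3e-4, sched, horizon=200.0)
        short_si = PiecewiseConstant.constant(3e-4, 0.0, 50.0)
        with pytest.raises(CoverageError):
            integrate_model(params, s0, short_si,
                            InputSchedule.constant(0.0, 200.0), horizon=200.0)


class TestSteadyState:
    def test_linear_closed_form_when_clearance_unsaturated(self, params):
        p = ModelParameters.from_mapping({**_as_dict(params), "alphaI": 0.0})
        i_star, q_star = steady_state_insulin(p, 0.0)
        assert i_star == pytest.approx(p.IB / p.n, rel=1e-12)
        assert q_star == i_star

    def test_matches_bisection_oracle_with_saturation(self, params):
        for uex in (0.0, 16.7, 66.7):
            i_star, _ = steady_state_insulin(params, uex)
            b = uex / params.VI + math.exp(-params.kI * uex) * params.IB
            f = lambda i: params.n * i / (1 + params.alphaI * i) - b  # noqa
            i_ref = bisect(f, 1e-9, 1e6, xtol=1e-12)
            assert i_star == pytest.approx(i_ref, abs=1e-9 * max(1, i_ref))

    def test_derivatives_vanish_at_equilibrium(self, params):
        uex = 33.3
        i_star, q_star = steady_state_insulin(params, uex)
        d = derivatives(MetabolicState(G=6.0, I=i_star, Q=q_star), params,
                        si=3e-4, uex=uex)
        assert abs(d.I) < 1e-9 and abs(d.Q) < 1e-9

    def test_nonphysical_parameters_detected(self, params):
        p = ModelParameters.from_mapping({**_as_dict(params), "alphaI": 10.0})
        with pytest.raises(ConfigurationError):
            steady_state_insulin(p, 1000.0)

    def test_gut_equilibrium_absorbs_feed_rate(self, params):
        p1, p2 = steady_state_gut(params, 0.6)
        # at equilibrium the appearance rate equals the feed rate
        assert params.d2 * p2 == pytest.approx(0.6, rel=1e-12)
        assert params.d1 * p1 == pytest.approx(0.6, rel=1e-12)


class TestParameters:
    def test_cns_cannot_exceed_egp(self, params):
        with pytest.raises(ConfigurationError):
            ModelParameters.from_mapping(
                {**_as_dict(params), "CNS": params.EGPmax * 2})

    def test_total_ib_convention_scales_by_volume(self, params):
        d = _as_dict(params)
        p2 = ModelParameters.from_mapping(
            {**d, "IB": params.IB * params.VI, "ib_units": "total"})
        assert p2.IB == pytest.approx(params.IB)

    def test_missing_key_rejected(self, params):
        d = _as_dict(params)
        d.pop("pG")
        with pytest.raises(ConfigurationError):
            ModelParameters.from_mapping(d)


def _as_dict(p: ModelParameters) -> dict:
    return {k: getattr(p, k) for k in p.__dataclass_fields__}
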