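"""Ionic-model unit tests: rate functions, currents, identity equivalence."""

import numpy as np
import pytest

import atrialab.courtemanche as cm
from atrialab.cell import ModelSpec, StimulusPulse, integrate_cell, pace_cell
from atrialab.clamp import gate_curves
from atrialab.params import (MUTATIONS, InvalidParameterError,
                             MutationParameterSet, get_mutation, get_region)

from oracle_courtemanche import derivatives as oracle_derivs


class TestGateRates:
    def test_xr_alpha_analytic_limit_at_singularity(self):
        alpha, _ = cm.gate_rates("xr", -14.1)
        assert alpha == pytest.approx(0.0015, rel=1e-9)

    def test_xr_beta_analytic_limit_at_singularity(self):
        _, beta = cm.gate_rates("xr", 3.3328)
        assert beta == pytest.approx(7.3898e-5 * 5.1237, rel=1e-9)

    def test_xr_alpha_at_zero_mv(self):
        # direct hand evaluation: 0.0003*14.1 / (1 - exp(-14.1/5))
        alpha, _ = cm.gate_rates("xr", 0.0)
        expected = 0.0003 * 14.1 / (1.0 - np.exp(-14.1 / 5.0))
        assert alpha == pytest.approx(expected, rel=1e-12)
        assert alpha == pytest.approx(4.498e-3, rel=1e-3)

    def test_p0t_scales_oi_alpha_exactly(self):
        p = MutationParameterSet(p0t=2.0, label="custom")
        for v in (-90.0, -40.0, 0.0, 35.0):
            a_id, b_id = cm.gate_rates("oi", v)
            a_mut, b_mut = cm.gate_rates("oi", v, p)
            assert a_mut == pytest.approx(2.0 * a_id, rel=1e-14)
            assert b_mut == b_id

    @pytest.mark.parametrize("preset", list(MUTATIONS))
    def test_removable_singularities_continuous(self, preset):
        p = MUTATIONS[preset]
        for v_sing in (-14.1 - p.p1r, 3.3328 - p.p4r):
            centre = cm.gate_rates("xr", v_sing, p)
            for dv in (-1e-6, 1e-6):
                side = cm.gate_rates("xr", v_sing + dv, p)
                assert abs(side[0] - centre[0]) < 1e-9
                assert abs(side[1] - centre[1]) < 1e-9

    def test_rates_positive_finite_over_physiological_range(self):
        for preset in MUTATIONS.values():
            for gate in ("xr", "oi"):
                for v in np.linspace(-120, 60, 37):
                    a, b = cm.gate_rates(gate, float(v), preset)
                    assert np.isfinite(a) and np.isfinite(b)
                    assert a > 0 and b > 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            MutationParameterSet(p6r=-1.0)
        with pytest.raises(InvalidParameterError):
            MutationParameterSet(p2t=0.0)
        with pytest.raises(InvalidParameterError):
            MutationParameterSet(p4r=np.inf)

    def test_non_finite_voltage_rejected(self):
        with pytest.raises(ValueError):
            cm.gate_rates("xr", np.nan)


class TestCurrents:
    def test_ikr_zero_at_reversal(self):
        consts = cm.CellConstants()
        ek = consts.e_k(139.0)
        assert cm.i_kr(ek, 0.5, consts, ki=139.0) == pytest.approx(0.0, abs=1e-12)

    def test_ikr_scales_with_p6r(self):
        p = get_mutation("V17M").replace(p3r=1.0, p8r=1.0, label="custom")
        base = cm.i_kr(-20.0, 0.3)
        assert cm.i_kr(-20.0, 0.3, params=p) == pytest.approx(6.18 * base, rel=1e-12)

    def test_ikr_region_ratio_pv_vs_ra(self):
        ra = cm.i_kr(-20.0, 0.3, region=get_region("RA"))
        pv = cm.i_kr(-20.0, 0.3, region=get_region("PV"))
        assert pv / ra == pytest.approx(2.5, rel=1e-12)

    def test_ito_zero_at_reversal_and_scalings(self):
        consts = cm.CellConstants()
        ek = consts.e_k(139.0)
        assert cm.i_to(ek, 0.5, 0.5, consts, ki=139.0) == pytest.approx(0.0, abs=1e-12)
        p = MutationParameterSet(p6t=12.56, label="custom")
        assert cm.i_to(0.0, 0.4, 0.8, params=p) == pytest.approx(
            12.56 * cm.i_to(0.0, 0.4, 0.8), rel=1e-12)
        ra = cm.i_to(0.0, 0.4, 0.8, region=get_region("RA"))
        pv = cm.i_to(0.0, 0.4, 0.8, region=get_region("PV"))
        assert pv / ra == pytest.approx(0.9, rel=1e-12)

    def test_ito_cubic_in_activation_gate(self):
        base = cm.i_to(0.0, 0.2, 0.9)
        assert cm.i_to(0.0, 0.4, 0.9) == pytest.approx(8.0 * base, rel=1e-12)

    def test_ikach_dose_dependence(self):
        assert cm.i_kach(-70.0, cm.CellConstants(ach=0.0)) == 0.0
        consts = cm.CellConstants(ach=0.005)
        ek = consts.e_k(139.0)
        assert cm.i_kach(ek, consts) == pytest.approx(0.0, abs=1e-12)
        lo = abs(cm.i_kach(-70.0, cm.CellConstants(ach=0.005)))
        hi = abs(cm.i_kach(-70.0, cm.CellConstants(ach=0.01)))
        assert hi > lo > 0

    def test_negative_ach_rejected(self):
        with pytest.raises(ValueError):
            cm.CellConstants(ach=-0.1)


class TestDerivatives:
    def _random_states(self, n=25, seed=7):
        rng = np.random.default_rng(seed)
        states = []
        for _ in range(n):
            y = cm.initial_state()
            y[0] = rng.uniform(-90, 30)
            y[1:16] = rng.uniform(0.01, 0.99, 15)
            y[16] = rng.uniform(8, 15)
            y[17] = rng.uniform(130, 145)
            y[18] = rng.uniform(5e-5, 1e-3)
            y[19] = rng.uniform(0.5, 3.0)
            y[20] = rng.uniform(0.5, 3.0)
            states.append(y)
        return states

    def test_identity_params_match_independent_oracle(self):
        """WT parameters reduce exactly to the published baseline model."""
        for y in self._random_states():
            got = cm.cell_derivatives(0.0, y, stim=1.5)
            want = oracle_derivs(y, stim=1.5, ach=0.005)
            denom = np.maximum(np.abs(want), 1e-6)
            assert np.max(np.abs(got - want) / denom) < 1e-10

    def test_region_scaling_matches_oracle(self):
        y = self._random_states(1)[0]
        got = cm.cell_derivatives(0.0, y, region=get_region("PV"))
        want = oracle_derivs(y, ach=0.005, region=(0.8, 2.5, 1.0, 0.9, 0.9, 1.9))
        denom = np.maximum(np.abs(want), 1e-6)
        assert np.max(np.abs(got - want) / denom) < 1e-10

    def test_nan_state_raises_with_diagnostic(self):
        y = cm.initial_state()
        y[5] = np.nan
        with pytest.raises(cm.IntegrationError):
            cm.cell_derivatives(3.0, y)

    def test_v17m_repolarises_faster_at_matched_state(self):
        """Larger outward K currents make dV/dt more negative in repolarisation."""
        run = pace_cell(ModelSpec("WT", "RA"), nbeats=3)
        idx = np.argmin(np.abs(run.beat_states[:, 0] - (-30.0)))
        y = run.beat_states[idx]
        dv_wt = cm.cell_derivatives(0.0, y)[0]
        dv_mut = cm.cell_derivatives(0.0, y, params=get_mutation("V17M"))[0]
        assert dv_mut < dv_wt

    def test_resting_state_is_near_equilibrium(self):
        res = integrate_cell(cm.initial_state(), [], t_end=30000.0,
                             spec=ModelSpec("WT", "RA"), out_dt=10.0)
        dy = cm.cell_derivatives(0.0, res.final_state)
        assert abs(dy[0]) < 1e-3
        assert abs(res.v[-1] - res.v[0]) < 1.0  # < 1 mV drift


class TestIntegration:
    def test_single_pulse_produces_overshooting_ap(self):
        res = integrate_cell(cm.initial_state(),
                             [StimulusPulse(t_on=10.0)], t_end=400.0)
        assert res.v.max() > 0.0
        assert res.v[0] < -75.0

    def test_gates_stay_boxed_during_pacing(self):
        run = pace_cell(ModelSpec("KCNE3-V17M", "PV"), nbeats=3)
        gates = run.beat_states[:, 1:16]
        assert gates.min() >= -1e-9
        assert gates.max() <= 1.0 + 1e-9

    def test_time_step_halving_changes_apd90_below_half_ms(self):
        from atrialab.protocols import apd90
        apds = []
        for dt in (0.01, 0.005):
            run = pace_cell(ModelSpec("WT", "RA"), bcl=600.0, nbeats=4, dt=dt)
            apds.append(apd90(run.t_beat, run.analysis_v))
        assert abs(apds[0] - apds[1]) < 0.5

    def test_unsorted_schedule_rejected(self):
        with pytest.raises(ValueError):
            integrate_cell(cm.initial_state(),
                           [StimulusPulse(5.0), StimulusPulse(-3.0, duration=-1)],
                           t_end=10.0)


class TestSteadyStateConsistency:
    @pytest.mark.parametrize("preset", list(MUTATIONS))
    @pytest.mark.parametrize("gate", ["xr", "oi"])
    def test_inf_in_unit_interval_tau_positive(self, preset, gate):
        v = np.linspace(-120, 60, 61)
        inf, tau = gate_curves(gate, MUTATIONS[preset], v)
        assert np.all((inf > 0) & (inf < 1))
        assert np.all(tau > 0)
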