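"""Atrial myocyte model: remodeling, integration, AP features."""

import numpy as np
import pytest

from vablate import (
    AF_REMODELING_FACTORS,
    CellParams,
    CellState,
    apply_af_remodeling,
    measure_apd90,
    pace_cell,
    step_cell,
)
from vablate import ionic


class TestRemodeling:
    def test_factors_applied_exactly(self, remodeled_params):
        f = remodeled_params.remodeling_factors
        assert f["g_to"] == pytest.approx(0.2)
        assert f["g_CaL"] == pytest.approx(0.6)
        assert f["g_Kur"] == pytest.approx(0.5)
        assert f["g_K1"] == pytest.approx(1.5)

    def test_unlisted_currents_unchanged(self, baseline_params, remodeled_params):
        base = baseline_params.scaled()
        rem = remodeled_params.scaled()
        names = list(ionic._CURRENT_NAMES)
        changed = {"g_to", "g_CaL", "g_Kur", "g_K1"}
        for i, name in enumerate(names):
            if name in changed:
                assert rem[i] != base[i]
            else:
                assert rem[i] == base[i]

    def test_remodeling_composes(self):
        once = apply_af_remodeling(CellParams())
        twice = apply_af_remodeling(once)
        assert twice.remodeling_factors["g_to"] == pytest.approx(0.04)

    def test_factors_match_stated_constants(self):
        assert AF_REMODELING_FACTORS == {
            "g_to": 0.2, "g_CaL": 0.6, "g_Kur": 0.5, "g_K1": 1.5
        }

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            CellParams(g_Na=-1.0)


class TestRestingState:
    def test_is_fixed_point(self, remodeled_params, resting_remodeled):
        _, vm, _ = ionic.simulate_unstimulated(
            resting_remodeled, remodeled_params, 1000.0
        )
        assert abs(vm[-1] - resting_remodeled.Vm) < 0.01

    def test_equilibrium_single_step(self, remodeled_params, resting_remodeled):
        after = step_cell(resting_remodeled, remodeled_params, i_stim=0.0)
        assert abs(after.Vm - resting_remodeled.Vm) < 1e-6

    def test_remodeled_close_to_baseline(self, resting_remodeled, resting_baseline):
        assert abs(resting_remodeled.Vm - resting_baseline.Vm) < 3.0

    def test_physiological_range(self, resting_remodeled):
        assert -90.0 < resting_remodeled.Vm < -75.0


class TestIntegration:
    def test_suprathreshold_pulse_fires_within_5ms(
        self, remodeled_params, resting_remodeled, stim_amplitude
    ):
        s = resting_remodeled.values.copy()
        t, vm = ionic._integrate_single(
            s, remodeled_params.scaled(), 0.02, int(10 / 0.02),
            0.0, 2.0, stim_amplitude, 5,
        )
        crossing = t[np.flatnonzero(vm > 0.0)]
        assert len(crossing) and crossing[0] < 5.0

    def test_dt_halving_convergence(
        self, remodeled_params, resting_remodeled, stim_amplitude
    ):
        # first-order convergence: at dt = 0.02 ms the AP peak (the most
        # dt-sensitive feature) moves ~0.6 mV per halving and APD90 < 0.5 ms
        feats = {}
        for dt in (0.02, 0.01):
            t, vm = pace_cell(
                remodeled_params, 500.0, 2, stim_amplitude, dt=dt,
                initial=resting_remodeled,
            )
            from vablate import measure_apd90

            feats[dt] = (vm[len(vm) // 2:].max(), measure_apd90(vm, t))
        assert abs(feats[0.02][0] - feats[0.01][0]) < 1.0
        assert abs(feats[0.02][1] - feats[0.01][1]) < 1.0

    def test_gates_bounded_concentrations_positive_under_fast_pacing(
        self, remodeled_params, resting_remodeled, stim_amplitude
    ):
        # sustained rapid pacing at CL 180 ms (the fastest induction rate)
        t, vm = pace_cell(
            remodeled_params, 180.0, 60, stim_amplitude, initial=resting_remodeled,
        )
        s = resting_remodeled.values.copy()
        p = remodeled_params.scaled()
        steps_per_beat = int(round(180.0 / 0.02))
        for beat in range(60):
            for step in range(steps_per_beat):
                ionic._cell_kernel(s, p, 0.02, stim_amplitude if step < 100 else 0.0)
        state = CellState(s)
        state.validate()  # gates in [0,1], concentrations > 0, finite

    def test_lut_path_matches_analytic_path(
        self, remodeled_params, resting_remodeled, stim_amplitude
    ):
        p = remodeled_params.scaled()
        a = np.tile(resting_remodeled.values, (1, 1))
        b = a.copy()
        idx = np.array([0])
        diffs = []
        for step in range(int(400 / 0.02)):
            ist = np.array([stim_amplitude if step * 0.02 < 2.0 else 0.0])
            ionic.step_states(a, p, 0.02, ist)
            ionic.step_states_subset(b, idx, p, 0.02, ist)
            if step % 500 == 0:
                diffs.append(abs(a[0, 0] - b[0, 0]))
        assert max(diffs) < 0.1

    def test_nonfinite_state_reported_by_name(self, remodeled_params, resting_remodeled):
        bad = resting_remodeled.copy()
        bad.values[18] = np.nan
        with pytest.raises(FloatingPointError, match="Ca_i"):
            step_cell(bad, remodeled_params)

    def test_invalid_dt_rejected(self, remodeled_params, resting_remodeled):
        with pytest.raises(ValueError):
            step_cell(resting_remodeled, remodeled_params, dt=0.5)


class TestAPD90:
    def test_triangular_pulse_analytic(self):
        # instant rise -80 -> +20, then linear 300 ms fall back to -80:
        # the 90% level (-70 mV) is reached 270 ms after the upstroke
        t = np.arange(0.0, 400.0, 1.0)
        vm = np.full_like(t, -80.0)
        vm[(t >= 50) & (t < 350)] = 20.0 - (t[(t >= 50) & (t < 350)] - 50.0) / 3.0
        assert measure_apd90(vm, t) == pytest.approx(270.0, abs=1.5)

    def test_flat_trace_raises(self):
        t = np.arange(0.0, 500.0, 1.0)
        with pytest.raises(ValueError):
            measure_apd90(np.full_like(t, -81.0), t)

    def test_uses_last_complete_ap(self):
        # two APs with different durations; the second (shorter) is measured
        t = np.arange(0.0, 1000.0, 1.0)
        vm = np.full_like(t, -80.0)
        m1 = (t >= 100) & (t < 400)
        vm[m1] = 20.0 - (t[m1] - 100.0) / 3.0
        m2 = (t >= 600) & (t < 750)
        vm[m2] = 20.0 - (t[m2] - 600.0) / 1.5
        assert measure_apd90(vm, t) == pytest.approx(135.0, abs=1.5)

    def test_rate_dependence_monotone(
        self, remodeled_params, resting_remodeled, stim_amplitude
    ):
        apds = {}
        for cl in (300.0, 1000.0):
            t, vm = pace_cell(
                remodeled_params, cl, 12, stim_amplitude, initial=resting_remodeled
            )
            apds[cl] = measure_apd90(vm, t)
        assert apds[300.0] <= apds[1000.0]

    def test_remodeling_shortens_apd(
        self, baseline_params, remodeled_params, resting_baseline, resting_remodeled
    ):
        t_b, vm_b = pace_cell(baseline_params, 1000.0, 10, initial=resting_baseline)
        t_r, vm_r = pace_cell(remodeled_params, 1000.0, 10, initial=resting_remodeled)
        assert measure_apd90(vm_r, t_r) < measure_apd90(vm_b, t_b)
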