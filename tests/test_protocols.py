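"""Pacing protocol, termination detection and lesion-set ranking."""

import math

import numpy as np
import pytest

from vablate import (
    PacingProtocol,
    RunConfig,
    SimulationResult,
    SolverParams,
    Stimulus,
    TissueSimulator,
    detect_termination,
    rank_lesion_sets,
    rectangular_strip,
)
from vablate.propagation import Recording, activation_times
from vablate.protocols import NOT_TERMINATED, best_protocol


class TestPacingProtocol:
    def test_default_train_is_24_stimuli(self):
        p = PacingProtocol()
        assert p.n_stimuli == 24
        assert len(p.stimulus_times()) == 24

    def test_default_spacing_8x_200_190_180(self):
        times = PacingProtocol().stimulus_times()
        gaps = np.diff(times)
        assert np.array_equal(gaps[:7], [200.0] * 7)
        # the gap between blocks equals the previous block's cycle length
        assert np.array_equal(gaps[7:15], [200.0] + [190.0] * 7)
        assert np.array_equal(gaps[15:], [190.0] + [180.0] * 7)
        assert PacingProtocol().train_duration_ms == 8 * (200 + 190 + 180)

    def test_empty_cycle_list_is_noop(self):
        p = PacingProtocol(cycle_lengths_ms=())
        assert p.n_stimuli == 0
        assert len(p.stimulus_times()) == 0
        assert p.train_duration_ms == 0.0

    def test_stimulus_count_additivity(self):
        p = PacingProtocol(cycle_lengths_ms=(250.0, 240.0), beats_per_cycle_length=5)
        assert p.n_stimuli == 10 == len(p.stimulus_times())


def _summary(times, vmax, ndep=None):
    vmax = np.asarray(vmax, dtype=float)
    if ndep is None:
        ndep = (vmax > -40.0).astype(np.int64)
    return Recording(np.asarray(times, dtype=float), vmax, np.asarray(ndep))


class TestDetectTermination:
    REST = -83.0

    def test_resting_recording_terminates_immediately(self):
        rec = _summary(np.arange(10.0), np.full(10, self.REST))
        term, t = detect_termination(rec, self.REST)
        assert term and t == 0.0

    def test_activity_at_horizon_not_terminated(self):
        vmax = np.full(100, self.REST)
        vmax[::3] = 10.0  # fibrillatory activity through the end
        term, t = detect_termination(_summary(np.arange(100.0), vmax), self.REST)
        assert not term and t == NOT_TERMINATED

    def test_termination_time_is_first_quiet_sample(self):
        vmax = np.full(50, self.REST)
        vmax[:20] = 15.0
        term, t = detect_termination(_summary(np.arange(50.0), vmax), self.REST)
        assert term and t == 20.0

    def test_matches_exhaustive_scan_on_single_beat(
        self, remodeled_params, resting_remodeled
    ):
        # one paced beat on a small sheet: compare against a brute-force
        # per-sample scan of the full voltage recording
        sheet = rectangular_strip(15.0, 6.0, 1.0)
        sim = TissueSimulator(
            sheet, remodeled_params, SolverParams(diffusivity=0.5),
            resting=resting_remodeled,
        )
        x = sheet.surface.vertices[:, 0]
        rec = sim.run(450.0, [Stimulus(np.flatnonzero(x < 1.0), start=0.0)],
                      record_full=True)
        term, t = detect_termination(rec, resting_remodeled.Vm)
        assert term
        # oracle: earliest sample from which every node stays repolarized
        peak = rec.vm.max()
        thr = resting_remodeled.Vm + 0.1 * (peak - resting_remodeled.Vm)
        quiet = (rec.vm <= thr).all(axis=1)
        idx = len(quiet) - 1
        while idx > 0 and quiet[idx - 1]:
            idx -= 1
        assert t == pytest.approx(rec.times[idx], abs=1.0)
        # and the wave did traverse the sheet first
        assert np.isfinite(activation_times(rec)).all()
        # termination time is robust to sampling cadence: subsampling the
        # recording to 5 ms moves the time by at most one coarse sample
        coarse = Recording(rec.times[::5], rec.vmax[::5], rec.n_depolarized[::5])
        term5, t5 = detect_termination(coarse, resting_remodeled.Vm)
        assert term5 and abs(t5 - t) <= 5.0 + 1e-6


def _result(name, terminated, t, n=10):
    return SimulationResult(
        protocol=name, induced=True, terminated=terminated,
        time_to_termination_ms=t if terminated else NOT_TERMINATED,
        n_ablated_nodes=n,
    )


class TestRanking:
    def test_terminated_dominates_nonterminated(self):
        r = rank_lesion_sets([_result("A", False, 0), _result("B", True, 12000.0)])
        assert r[0].protocol == "B"
        assert best_protocol(r).protocol == "B"

    def test_all_nonterminated_reports_none(self):
        rs = [_result(p, False, 0) for p in ("CPVI", "CPVI+POBI")]
        ranked = rank_lesion_sets(rs)
        assert len(ranked) == 2
        assert best_protocol(ranked) is None

    def test_tie_breaks_by_fewer_ablated_nodes_then_order(self):
        a = _result("CPVI+POBI", True, 500.0, n=200)
        b = _result("CPVI", True, 500.0, n=100)
        assert rank_lesion_sets([a, b])[0].protocol == "CPVI"
        c = _result("CPVI+POBI+AL", True, 500.0, n=100)
        ranked = rank_lesion_sets([a, c])
        assert ranked[0].protocol == "CPVI+POBI+AL"  # fewer nodes wins first
        d = _result("CPVI+RL+LLI", True, 500.0, n=100)
        ranked = rank_lesion_sets([c, d])
        assert ranked[0].protocol == "CPVI+POBI+AL"  # canonical order last

    def test_matches_bruteforce_sort_oracle(self, rng):
        protos = ["CPVI", "CPVI+POBI", "CPVI+POBI+AL", "CPVI+RL+LLI", "CPVI+CFAE"]
        for _ in range(50):
            results = []
            for p in protos:
                term = bool(rng.integers(0, 2))
                t = float(rng.choice([250.0, 500.0, 500.0, 1200.0]))
                results.append(_result(p, term, t, n=int(rng.choice([50, 100, 100]))))
            ranked = rank_lesion_sets(results)
            key = lambda r: (
                not r.terminated,
                r.time_to_termination_ms if r.terminated else math.inf,
                r.n_ablated_nodes,
                protos.index(r.protocol),
            )
            assert [r.protocol for r in ranked] == [
                r.protocol for r in sorted(results, key=key)
            ]

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            rank_lesion_sets([])


class TestRunConfigDefaults:
    def test_paper_timing_defaults(self):
        cfg = RunConfig()
        assert cfg.wait_after_pacing_ms == 4000.0
        assert cfg.horizon_ms == 25000.0
        assert cfg.repol_fraction == 0.9
        assert cfg.cfae_cl_threshold_ms == 120.0
        assert cfg.cfae_area_cap == 0.05
        assert cfg.pacing.n_stimuli == 24
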