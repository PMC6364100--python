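"""The synthetic instrument model: response linearity, extraction
arithmetic, calibration series, spiked batches, reproducibility."""

import numpy as np
import pytest

import phenoscreen as ps
from phenoscreen.simulate import (UnknownCompoundError, extract_concentration,
                                  simulate_calibration_series,
                                  simulate_spiked_batch)


def conc_of(content, recovery=1.0, mass=0.5, volume=10.0):
    return extract_concentration(content, recovery, mass, volume)


class TestExtractionArithmetic:
    def test_erianin_content_425_gives_21_25_ug_ml(self):
        # 425 mg/kg * 0.5 g / 10 mL, hand-checked
        assert conc_of(425.0) == pytest.approx(21.25)

    def test_recovery_scales_concentration(self):
        assert conc_of(100.0, recovery=0.5) == pytest.approx(conc_of(50.0))


class TestSimulateRun:
    def test_noise_free_area_equals_response_times_concentration(self, library):
        # conc 10 ug/mL at response 1000 -> integrated SIM area 10000 +- 1%
        rf = {r.code: 1000.0 for r in library}
        sc = ps.ScenarioConfig(compounds={"ER": 200.0}, response_factor=rf)
        run, truth = ps.simulate_run(sc, library)
        assert truth.concentration("ER") == pytest.approx(10.0)
        trace = run.sim_trace(341, "positive")
        raw_area = np.trapezoid(trace.intensity, trace.rt)  # independent integral
        assert raw_area == pytest.approx(10000.0, rel=0.01)

    def test_zero_content_gives_identically_zero_traces(self, library):
        sc = ps.ScenarioConfig(compounds={c.code: 0.0 for c in library})
        run, _ = ps.simulate_run(sc, library)
        for trace in run.sim_traces.values():
            assert not np.any(trace.intensity)

    def test_doubling_content_doubles_noise_free_trace_exactly(self, library):
        runs = []
        for content in (100.0, 200.0):
            sc = ps.ScenarioConfig(compounds={"TR": content})
            run, _ = ps.simulate_run(sc, library)
            runs.append(run.sim_trace(283, "positive").intensity)
        np.testing.assert_allclose(runs[1], 2 * runs[0], rtol=1e-12)

    def test_unknown_compound_raises(self, library):
        sc = ps.ScenarioConfig(compounds={"NOPE": 10.0})
        with pytest.raises(UnknownCompoundError):
            ps.simulate_run(sc, library)

    def test_same_seed_reproduces_noisy_run(self, library):
        sc = ps.ScenarioConfig(compounds={"TR": 50.0}, noise_level=200.0, seed=7)
        t1 = ps.simulate_run(sc, library)[0].sim_trace(283, "positive")
        t2 = ps.simulate_run(sc, library)[0].sim_trace(283, "positive")
        np.testing.assert_array_equal(t1.intensity, t2.intensity)

    def test_run_invariants(self, library):
        sc = ps.ScenarioConfig(compounds={"GI": 100.0}, noise_level=50.0, seed=3)
        run, _ = ps.simulate_run(sc, library)
        rts = run.rts
        assert np.all(np.diff(rts) > 0)
        for cycle in run.cycles:
            for spec in (cycle.positive, cycle.negative):
                assert np.all(spec.intensity >= 0)
                assert spec.mz.min(initial=400) >= 50
                assert spec.mz.max(initial=50) <= 400


class TestCalibrationSeries:
    LEVELS = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0)

    def test_six_levels_triplicate_gives_18_runs(self, library):
        sc = ps.ScenarioConfig(compounds={})
        series = simulate_calibration_series("ER", self.LEVELS, sc,
                                             n_replicates=3, library=library)
        assert len(series) == 18

    def test_single_level_single_replicate(self, library):
        sc = ps.ScenarioConfig(compounds={})
        series = simulate_calibration_series("ER", (10.0,), sc,
                                             n_replicates=1, library=library)
        assert len(series) == 1

    def test_true_areas_refit_to_generating_line(self, library):
        # generating line: area = 14667 x + 3462 (erianin), zero noise
        sc = ps.ScenarioConfig(compounds={},
                               response_factor={"ER": 14667.0},
                               area_intercept=3462.0)
        series = simulate_calibration_series("ER", self.LEVELS, sc,
                                             n_replicates=1, library=library)
        model = ps.fit_calibration([c.level for c in series],
                                   [c.true_area for c in series])
        assert model.slope == pytest.approx(14667.0, rel=1e-12)
        assert model.intercept == pytest.approx(3462.0, rel=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("levels", [(), (5.0, 2.0), (-1.0, 2.0)])
    def test_bad_levels_rejected(self, library, levels):
        sc = ps.ScenarioConfig(compounds={})
        with pytest.raises(ValueError):
            simulate_calibration_series("ER", levels, sc, library=library)


class TestSpikedBatch:
    def test_noise_free_contents_are_exact(self, library):
        batch = simulate_spiked_batch({"TR": 0.0}, 50.0, n_replicates=5,
                                      recovery_true=1.0, noise=0.0, seed=1,
                                      library=library)
        for _, truth in batch.spiked:
            assert truth.content("TR") == pytest.approx(50.0)

    def test_gigantol_arithmetic(self, library):
        # endogenous 12.7 + 0.958 * 50 = 60.6 mg/kg, hand-checked
        batch = simulate_spiked_batch({"GI": 12.7}, 50.0, n_replicates=2,
                                      recovery_true=0.958, noise=0.0,
                                      library=library)
        for _, truth in batch.spiked:
            assert truth.content("GI") == pytest.approx(60.6)
        for _, truth in batch.blanks:
            assert truth.content("GI") == pytest.approx(12.7)

    def test_replicate_counts(self, library):
        batch = simulate_spiked_batch({"TR": 0.0}, 50.0, n_replicates=5,
                                      library=library)
        assert len(batch.spiked) == 5 and len(batch.blanks) == 5

    def test_invalid_inputs_rejected(self, library):
        with pytest.raises(ValueError):
            simulate_spiked_batch({"TR": 0.0}, 0.0, library=library)
        with pytest.raises(ValueError):
            simulate_spiked_batch({"TR": 0.0}, 50.0, n_replicates=1,
                                  library=library)


class TestScenarioValidation:
    @pytest.mark.parametrize("kw", [
        {"sample_mass": 0.0}, {"elution_volume": -1.0},
        {"noise_level": -5.0}, {"recovery_factor": 1.5},
        {"response_factor": {"ER": 0.0}}, {"compounds": {"ER": -1.0}},
    ])
    def test_invariants_enforced(self, kw):
        base = dict(compounds={"ER": 10.0})
        base.update(kw if "compounds" not in kw else {})
        if "compounds" in kw:
            base["compounds"] = kw["compounds"]
        with pytest.raises(ValueError):
            ps.ScenarioConfig(**base)
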