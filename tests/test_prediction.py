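import numpy as np
import pandas as pd
import pytest

from mctmm.cohort import CohortDesign, generate_design
from mctmm.data import PatientRecord
from mctmm.model_core import EtaPair, PopulationParams
from mctmm.prediction import (
    map_eta,
    ppv_npv,
    ppv_npv_by_cycle,
    predict_next_cycle,
    prediction_table,
)
from mctmm.simulate import simulate_dataset

SEED = 12345


class TestMapEta:
    def test_no_observations_gives_prior_mode(self, reference_params,
                                              final_spec):
        rec = PatientRecord("p", [], [], [3000])
        eta = map_eta(rec, reference_params, final_spec)
        assert eta == EtaPair(0.0, 0.0)

    def test_degenerate_prior_pins_eta_to_zero(self, final_spec):
        params = PopulationParams(alpha1=1.81, b2=-1.8, b3=-2.08, met=1.09,
                                  theta_dose=8.33e-4)
        rec = PatientRecord("p", [1, 2], [2, 3], [3000, 3000])
        eta = map_eta(rec, params, final_spec)
        assert eta == EtaPair(0.0, 0.0)

    def test_high_grades_pull_intercept_up(self, reference_params,
                                           final_spec):
        hot = PatientRecord("p", [1, 2, 3], [2, 3, 3], [3000] * 3)
        cold = PatientRecord("p", [1, 2, 3], [0, 0, 0], [3000] * 3)
        assert (map_eta(hot, reference_params, final_spec).eta_alpha
                > map_eta(cold, reference_params, final_spec).eta_alpha)

    def test_recovery_correlates_with_truth(self, reference_params,
                                            final_spec):
        # shrinkage-aware check: MAP estimates of simulated subjects
        # correlate positively with the generating random effects
        rng = np.random.default_rng(SEED)
        templates = generate_design(CohortDesign.scaled(150), rng)
        true_eta = np.column_stack([
            rng.normal(0, reference_params.omega_alpha, len(templates)),
            rng.normal(0, reference_params.omega_met, len(templates))])
        sims = simulate_dataset(templates, reference_params, final_spec, rng,
                                eta=true_eta)
        maps = np.array([
            [map_eta(r, reference_params, final_spec).eta_alpha,
             map_eta(r, reference_params, final_spec).eta_met]
            for r in sims])
        keep = np.array([r.n_observations >= 4 for r in sims])
        corr = np.corrcoef(true_eta[keep, 0], maps[keep, 0])[0, 1]
        assert corr > 0.3


class TestPredictNextCycle:
    def test_frozen_dynamics_repeat_last_grade(self, final_spec):
        slow = PopulationParams(alpha1=1.81, b2=-1.8, b3=-2.08, met=1e9)
        rec = PatientRecord("p", [1, 2], [1, 2], [3000] * 3)
        dist, modal = predict_next_cycle(rec, slow, final_spec, EtaPair(),
                                         at_cycle=3)
        assert modal == 2
        assert dist.p[2] > 0.999

    def test_matches_monte_carlo_frequencies(self, reference_params,
                                             final_spec):
        from mctmm.simulate import _simulate_grades
        params = reference_params.replace(omega_alpha=0.0, omega_met=0.0)
        rec = PatientRecord("p", [1], [1], [3000, 3000])
        dist, _ = predict_next_cycle(rec, params, final_spec, EtaPair(),
                                     at_cycle=2)
        # simulate many second-cycle outcomes conditional on grade 1 at
        # cycle 1 by restarting the chain there
        n = 100_000
        restart = PatientRecord("p", [1], [0], [3000])
        g = _simulate_grades([restart], params, final_spec,
                             np.random.default_rng(5), n_replicates=n)
        # the chain is homogeneous at constant dose: transitions out of
        # grade 1 over one cycle have the same law from any cycle start
        from mctmm.markov import transition_matrix
        row = transition_matrix(params, EtaPair(), 3000.0, 1.0,
                                final_spec).t_mat[1]
        np.testing.assert_allclose(dist.p, row, atol=1e-12)

    def test_recovery_after_discontinuation(self, reference_params,
                                            final_spec):
        # dose 0 shifts the stationary law toward low grades, so the
        # equilibrium modal grade cannot exceed the last observed one
        rec = PatientRecord("p", [1, 2], [2, 2], [4000, 4000, 0],
                            discontinuation_cycle=2)
        slow_equil = reference_params.replace(met=1e-3)
        _, modal = predict_next_cycle(rec, slow_equil, final_spec, EtaPair(),
                                      at_cycle=3)
        assert modal <= 2

    def test_missing_dose_rejected(self, reference_params, final_spec):
        rec = PatientRecord("p", [1], [1], [3000])
        with pytest.raises(ValueError, match="no dose"):
            predict_next_cycle(rec, reference_params, final_spec,
                               at_cycle=2)


class TestPpvNpv:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["patient_id", "cycle",
                                         "predicted", "observed"])
        return df

    def test_direct_counts(self):
        rows = ([("a", 2, 2, 2), ("b", 2, 2, 2)]          # 2 correct >=2
                + [(f"c{i}", 2, 3, 1) for i in range(6)]  # 6 wrong >=2
                + [("d", 2, 0, 0), ("e", 2, 1, 3)])
        ppv, npv = ppv_npv(self._table(rows))
        assert ppv == pytest.approx(2 / 8)
        assert npv == pytest.approx(1 / 2)

    def test_perfect_predictions(self):
        rows = [("a", 2, g, g) for g in range(4)]
        ppv, npv = ppv_npv(self._table(rows))
        assert ppv == 1.0 and npv == 1.0

    def test_empty_denominator_is_missing(self):
        rows = [("a", 2, 0, 0), ("b", 2, 1, 1)]
        ppv, npv = ppv_npv(self._table(rows))
        assert np.isnan(ppv) and npv == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ppv_npv(self._table([]))


class TestPredictionTable:
    def test_baseline_and_first_cycle_excluded(self, small_cohort,
                                               reference_params, final_spec):
        table = prediction_table(small_cohort, reference_params, final_spec)
        assert table.cycle.min() >= 2
        assert set(table.predicted).issubset({0, 1, 2, 3})
        assert set(table.observed).issubset({0, 1, 2, 3})

    def test_per_cycle_summary_shapes(self, small_cohort, reference_params,
                                      final_spec):
        table = prediction_table(small_cohort, reference_params, final_spec)
        summary = ppv_npv_by_cycle(table)
        assert "pooled" in set(summary.cycle)
        per_cycle = summary[summary.cycle != "pooled"]
        assert per_cycle.n.sum() == len(table)

    def test_deterministic_limit_is_exact(self, final_spec):
        # frozen dynamics + all-zero data: every prediction is correct
        frozen = PopulationParams(alpha1=1.81, b2=-1.8, b3=-2.08, met=1e9)
        records = [PatientRecord(f"p{i}", [1, 2, 3, 4], [0] * 4, [3000] * 4)
                   for i in range(5)]
        table = prediction_table(records, frozen, final_spec)
        ppv, npv = ppv_npv(table)
        assert np.isnan(ppv)  # no clinically relevant predictions occur
        assert npv == 1.0
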