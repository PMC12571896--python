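import numpy as np
import pandas as pd
import pytest

from clpr.fitting import (
    ConfidenceModel,
    aic,
    compare_models,
    fit_model,
    predict_cells,
    sse_cost,
    summarize_cells,
)
from clpr.model import ModelParams, simulate_dataset
from clpr.oracles import confidence_pmf_oracle
from clpr.stimuli import Stimulus, StimulusDesign, generate_design_set


def _toy_trials(choices, categories, confidences, mean_level=1, var_level=1):
    n = len(choices)
    data = {f"hue_{i}": np.zeros(n) + 0.05 for i in range(1, 9)}
    data.update(
        choice=choices, category=categories, confidence=confidences,
        mean_level=mean_level, var_level=var_level,
    )
    return pd.DataFrame(data)


class TestSummarizeCells:
    def test_all_correct_max_confidence(self):
        tabs = []
        for k in (1, 2):
            for j in (1, 2):
                t = _toy_trials([1] * 100, [1] * 100, [6] * 100, k, j)
                tabs.append(t)
        cells = summarize_cells(pd.concat(tabs, ignore_index=True))
        assert len(cells) == 4
        assert (cells["oACC"] == 1.0).all()
        assert (cells["oCJ"] == 6.0).all()

    def test_half_correct(self):
        cells = summarize_cells(_toy_trials([1, -1], [1, 1], [4, 4]))
        assert cells["oACC"].iloc[0] == pytest.approx(0.5)

    def test_missing_cell_named_in_error(self):
        a = _toy_trials([1] * 5, [1] * 5, [4] * 5, mean_level=1, var_level=1)
        b = _toy_trials([1] * 5, [1] * 5, [4] * 5, mean_level=2, var_level=2)
        with pytest.raises(ValueError, match="mean_level=1, var_level=2"):
            summarize_cells(pd.concat([a, b], ignore_index=True))

    def test_csv_roundtrip_preserves_summaries(self, tmp_path, v4_dataset_2k):
        path = tmp_path / "trials.csv"
        v4_dataset_2k.to_csv(path, index=False)
        reread = pd.read_csv(path)
        pd.testing.assert_frame_equal(
            summarize_cells(v4_dataset_2k), summarize_cells(reread)
        )


class TestSseCost:
    @staticmethod
    def _cells(acc, cj, pred=False):
        prefix = "p" if pred else "o"
        return pd.DataFrame(
            {
                "mean_level": np.arange(len(acc)) + 1,
                "var_level": 1,
                f"{prefix}ACC": acc,
                f"{prefix}CJ": cj,
            }
        )

    def test_identity_gives_zero(self):
        obs = self._cells([0.8, 0.9], [4.0, 4.5])
        pred = self._cells([0.8, 0.9], [4.0, 4.5], pred=True)
        assert sse_cost(obs, pred) == 0.0

    def test_single_cell_arithmetic(self):
        obs = self._cells([0.8], [4.5])
        pred = self._cells([0.7], [4.0], pred=True)
        assert sse_cost(obs, pred) == pytest.approx(0.26)

    def test_order_invariance(self):
        obs = self._cells([0.8, 0.6], [4.5, 3.0])
        pred = self._cells([0.7, 0.65], [4.0, 3.3], pred=True)
        assert sse_cost(obs, pred) == pytest.approx(
            sse_cost(obs.iloc[::-1], pred)
        )

    def test_mismatched_cells_rejected(self):
        obs = self._cells([0.8], [4.5])
        pred = self._cells([0.7, 0.6], [4.0, 3.9], pred=True)
        with pytest.raises(ValueError):
            sse_cost(obs, pred)

    def test_normalized_confidence_option_downweights_cj(self):
        obs = self._cells([0.8], [6.0])
        pred = self._cells([0.8], [1.0], pred=True)
        assert sse_cost(obs, pred) == pytest.approx(25.0)
        assert sse_cost(obs, pred, normalize_confidence=True) == pytest.approx(1.0)


class TestAic:
    def test_printed_arithmetic(self):
        assert aic(8.0, 2, 8) == pytest.approx(4.0)
        assert aic(0.5, 3, 20) == pytest.approx(6 + 20 * np.log(0.025), abs=1e-6)
        assert aic(0.5, 3, 20) == pytest.approx(-67.78, abs=0.01)

    def test_each_free_parameter_costs_two(self):
        assert aic(0.3, 3, 10) - aic(0.3, 2, 10) == pytest.approx(2.0)

    def test_zero_sse_rejected_with_sentinel_guidance(self):
        with pytest.raises(ValueError, match="-inf"):
            aic(0.0, 2, 8)


class TestPredictCells:
    def test_noiseless_strong_evidence_is_perfect(self):
        stim = generate_design_set(
            StimulusDesign(mean_levels=(0.2,), variance_levels=(0.02,), n_per_cell=50),
            np.random.default_rng(0),
        )
        p = ModelParams(variant=4, d=0.02, decnoise=1e-9)
        pred = predict_cells(p, stim)
        assert pred["pACC"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_oracle_agrees_with_simulation_path(self):
        stim = generate_design_set(StimulusDesign(n_per_cell=25), np.random.default_rng(1))
        p = ModelParams(variant=4, d=0.05, decnoise=0.15)
        oracle = predict_cells(p, stim, method="oracle")
        sim = predict_cells(p, stim, method="simulation", n_sim=60_000, seed=3)
        n = 60_000
        for (_, o), (_, s) in zip(oracle.iterrows(), sim.iterrows()):
            se_acc = np.sqrt(o.pACC * (1 - o.pACC) / n) + 1e-4
            assert s.pACC == pytest.approx(o.pACC, abs=3.5 * se_acc)
            assert s.pCJ == pytest.approx(o.pCJ, abs=3.5 * 1.5 / np.sqrt(n) + 1e-3)

    def test_simulation_path_deterministic_per_seed(self):
        stim = generate_design_set(StimulusDesign(n_per_cell=10), np.random.default_rng(1))
        p = ModelParams(variant=7, d=0.05, decnoise=0.1)
        a = predict_cells(p, stim, n_sim=500, seed=11)
        b = predict_cells(p, stim, n_sim=500, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestNestedVariants:
    def test_variant1_gamma_zero_equals_variant2(self):
        stim = Stimulus(hues=np.linspace(-0.1, 0.2, 8), category=1, sigma=0.15)
        p1 = ModelParams(variant=1, d=0.05, decnoise=0.15, metanoise=0.1, scalemetanoise=0.0)
        p2 = ModelParams(variant=2, d=0.05, decnoise=0.15, metanoise=0.1)
        np.testing.assert_allclose(
            confidence_pmf_oracle(stim, p1, 0.15, 0.05),
            confidence_pmf_oracle(stim, p2, 0.15, 0.05),
        )

    def test_variant1_collapses_to_variant4(self):
        stim = Stimulus(hues=np.linspace(-0.1, 0.2, 8), category=1, sigma=0.15)
        p1 = ModelParams(variant=1, d=0.05, decnoise=0.15, metanoise=0.15, scalemetanoise=0.0)
        p4 = ModelParams(variant=4, d=0.05, decnoise=0.15)
        np.testing.assert_allclose(
            confidence_pmf_oracle(stim, p1, 0.15, 0.05),
            confidence_pmf_oracle(stim, p4, 0.15, 0.05),
        )


@pytest.fixture(scope="module")
def small_sim():
    rng = np.random.default_rng(100)
    stim = generate_design_set(StimulusDesign(n_per_cell=150), rng)
    return simulate_dataset(stim, ModelParams(variant=4, d=0.05, decnoise=0.15), rng)


class TestFitting:

    def test_fit_is_deterministic_under_seed(self, small_sim):
        a = fit_model(small_sim, 4, budget=8, seed=3)
        b = fit_model(small_sim, 4, budget=8, seed=3)
        assert a.params == b.params
        assert a.sse == b.sse

    def test_fit_beats_generative_parameters(self, small_sim):
        res = fit_model(small_sim, 4, budget=10, seed=2)
        model = ConfidenceModel(small_sim, 4)
        sse_true = model.objective([0.05, 0.15])
        assert res.sse <= sse_true + 1e-12

    def test_aic_invariant_recomputed_on_results(self, small_sim):
        res = fit_model(small_sim, 4, budget=5, seed=1)
        assert res.aic == pytest.approx(aic(res.sse, res.k_free, res.n_points))
        assert res.n_points == 8  # 4 cells x (accuracy + confidence)

    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(11)
        stim = generate_design_set(StimulusDesign(n_per_cell=1000), rng)
        sim = simulate_dataset(stim, ModelParams(variant=4, d=0.05, decnoise=0.15), rng)
        res = fit_model(sim, 4, budget=20, seed=5, max_pred_stimuli=250)
        assert res.params.d == pytest.approx(0.05, rel=0.2)
        assert res.params.decnoise == pytest.approx(0.15, rel=0.2)

    def test_budget_must_be_positive(self, small_sim):
        with pytest.raises(ValueError):
            fit_model(small_sim, 4, budget=0, seed=0)

    def test_summary_mentions_parameters(self, small_sim):
        res = fit_model(small_sim, 4, budget=5, seed=1)
        text = str(res.summary())
        assert "AIC" in text and "decnoise" in text


class TestCompareModels:
    def test_single_variant_wins_trivially(self, v4_dataset_2k):
        comp = compare_models(v4_dataset_2k, variants=[4], budget=5, seed=0,
                              max_pred_stimuli=100)
        assert comp.winner == 4

    def test_mean_aic_is_sum_over_agents(self, v4_dataset_2k):
        two_agents = pd.concat(
            [v4_dataset_2k.assign(agent_id=0), v4_dataset_2k.assign(agent_id=1)],
            ignore_index=True,
        )
        comp = compare_models(two_agents, variants=[4], budget=5, seed=0,
                              max_pred_stimuli=100)
        s = comp.summary_table.iloc[0]
        assert s.mean_aic == pytest.approx(s.sum_aic / 2)

    def test_generative_variant_preferred_over_linear(self):
        rng = np.random.default_rng(21)
        stim = generate_design_set(StimulusDesign(n_per_cell=500), rng)
        sim = simulate_dataset(stim, ModelParams(variant=4, d=0.05, decnoise=0.15), rng)
        comp = compare_models(sim, variants=[4, 6], budget=15, seed=1,
                              max_pred_stimuli=250)
        assert comp.winner == 4
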