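import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clpr.model import (
    ConfidenceCriteria,
    ModelParams,
    choose,
    compute_dv1,
    compute_dv2,
    linear_transfer,
    map_confidence,
    sigmoid_transfer,
    simulate_dataset,
    simulate_trial,
)
from clpr.stimuli import Stimulus, StimulusDesign, generate_design_set


class TestTransfers:
    def test_sigmoid_is_tanh_of_half_argument(self):
        assert sigmoid_transfer(0.05, 0.05) == pytest.approx(np.tanh(0.5))
        assert sigmoid_transfer(0.05, 0.05) == pytest.approx(0.462117, abs=1e-6)
        # the printed logistic form agrees with the tanh identity
        C, d = 0.13, 0.04
        assert sigmoid_transfer(C, d) == pytest.approx(-1 + 2 / (1 + np.exp(-C / d)))

    def test_sigmoid_zero_at_boundary(self):
        assert sigmoid_transfer(0.0, 0.123) == 0.0

    @given(C=st.floats(-0.5, 0.5), d=st.floats(1e-4, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_sigmoid_antisymmetric(self, C, d):
        assert sigmoid_transfer(-C, d) == pytest.approx(-sigmoid_transfer(C, d))

    def test_sigmoid_limits(self):
        # weak compression: linear regime with slope 1/(2d)
        assert sigmoid_transfer(0.1, 50.0) == pytest.approx(0.1 / 100.0, rel=1e-3)
        # strong compression: sign function
        assert sigmoid_transfer(0.01, 1e-5) == pytest.approx(1.0)
        assert sigmoid_transfer(-0.01, 1e-5) == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "C,d,expected", [(0.0, 0.3, 0.0), (0.5, 0.5, 1.0), (0.1, 0.5, 0.2), (-0.9, 0.5, -1.0)]
    )
    def test_linear_transfer_values(self, C, d, expected):
        assert linear_transfer(C, d) == pytest.approx(expected)

    @pytest.mark.parametrize("fn", [sigmoid_transfer, linear_transfer])
    def test_nonpositive_compression_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.1, 0.0)


class TestChoiceRule:
    def test_tie_at_zero_goes_blue(self):
        assert choose(0.0) == -1

    def test_strict_inequality(self):
        assert choose(0.2) == 1
        assert choose(-1e-12) == -1


class TestDecisionVariables:
    def test_noiseless_mean(self):
        rng = np.random.default_rng(0)
        assert compute_dv1(np.full(8, 0.5), 0.0, rng) == pytest.approx(0.5)
        E = np.array([-1, -1, -1, -1, 1, 1, 1, 1], float)
        assert compute_dv1(E, 0.0, rng) == pytest.approx(0.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            compute_dv1(np.zeros(7), 0.1, np.random.default_rng(0))

    def test_dv1_moments(self):
        rng = np.random.default_rng(1)
        E = np.full(8, 0.1)
        draws = np.array([compute_dv1(E, 0.2, rng) for _ in range(10_000)])
        assert draws.mean() == pytest.approx(0.1, abs=3 * 0.2 / 100)
        assert draws.std() == pytest.approx(0.2, rel=0.05)

    def test_dv2_noiseless_identity(self):
        p = ModelParams(variant=2, d=0.05, decnoise=0.1, metanoise=0.0)
        assert compute_dv2(0.3, p, 0.15, 0.05, np.random.default_rng(0)) == pytest.approx(0.3)

    def test_dv2_lowest_variance_adds_baseline_metanoise_only(self):
        # with the gamma term read as *additional* noise, the lowest
        # variance level gets exactly the baseline metanoise SD
        p = ModelParams(variant=1, d=0.05, decnoise=0.1, metanoise=0.1, scalemetanoise=5.0)
        assert p.metanoise_sd(0.05, 0.05) == pytest.approx(0.1)

    def test_dv2_variance_scaling(self):
        p = ModelParams(variant=1, d=0.05, decnoise=0.1, metanoise=0.1, scalemetanoise=2.0)
        assert p.metanoise_sd(0.15, 0.05) == pytest.approx(0.12)
        rng = np.random.default_rng(2)
        draws = np.array([compute_dv2(0.0, p, 0.15, 0.05, rng) for _ in range(10_000)])
        se_of_sd = 0.12 / np.sqrt(2 * len(draws))
        assert draws.std() == pytest.approx(0.12, abs=3 * se_of_sd)

    def test_dv2_literal_form_zeroes_noise_at_lowest_variance(self):
        p = ModelParams(
            variant=1, d=0.05, decnoise=0.1, metanoise=0.1, scalemetanoise=2.0,
            eq4_literal=True,
        )
        assert p.metanoise_sd(0.05, 0.05) == 0.0
        assert p.metanoise_sd(0.15, 0.05) == pytest.approx(0.02)

    def test_dv2_rejects_variance_below_floor(self):
        p = ModelParams(variant=4, d=0.05, decnoise=0.1)
        with pytest.raises(ValueError):
            p.metanoise_sd(0.01, 0.05)


class TestConfidenceCriteria:
    @pytest.mark.parametrize(
        "dv2,x,expected",
        [
            (0.7, 1, 6),
            (0.7, -1, 1),
            (0.0, 1, 3),
            (0.60, 1, 5),   # ties sit in the lower bin
            (0.601, 1, 6),
            (-0.40, 1, 1),
            (-0.39, 1, 2),
            (-0.7, -1, 6),  # mirrored criteria for blue choices
            (-0.12, -1, 4),  # oriented 0.12 lies in (0.10, 0.35]
        ],
    )
    def test_binning_table(self, dv2, x, expected):
        assert map_confidence(dv2, x, ConfidenceCriteria()) == expected

    def test_criteria_must_descend(self):
        with pytest.raises(ValueError):
            ConfidenceCriteria(thresholds=(0.1, 0.2, 0.3, 0.4, 0.5))

    def test_invalid_choice_rejected(self):
        with pytest.raises(ValueError):
            map_confidence(0.0, 0)


class TestModelParams:
    def test_variant_fixings_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(variant=4, d=0.05, decnoise=0.1, metanoise=0.2)
        with pytest.raises(ValueError):
            ModelParams(variant=4, d=0.05, decnoise=0.1, scalemetanoise=1.0)
        with pytest.raises(ValueError):
            ModelParams(variant=1, d=0.05, decnoise=0.1)  # metanoise required
        with pytest.raises(ValueError):
            ModelParams(variant=8, d=0.05, decnoise=0.1)

    def test_transfer_kind_by_variant(self):
        assert ModelParams(variant=4, d=0.1, decnoise=0.1).transfer == "sigmoidal"
        assert ModelParams(variant=6, d=0.1, decnoise=0.1).transfer == "linear"

    def test_free_parameter_counts_match_model_table(self):
        dfs = {1: 4, 2: 3, 3: 3, 4: 2, 5: 3, 6: 2, 7: 2}
        for variant, k in dfs.items():
            names = ModelParams.from_free(variant, [0.1] * k).free_names
            assert len(names) == k

    def test_metanoise_fixed_to_decnoise_for_variants_4_to_7(self):
        for variant in (4, 6, 7):
            p = ModelParams(variant=variant, d=0.05, decnoise=0.17)
            assert p.metanoise_effective == pytest.approx(0.17)


class TestSimulateTrial:
    def test_noise_free_variant4_chain(self):
        stim = Stimulus(hues=np.full(8, 0.05), category=1, sigma=0.0)
        p = ModelParams(variant=4, d=0.05, decnoise=0.0)
        out = simulate_trial(stim, p, np.random.default_rng(0))
        assert out.x == 1
        assert out.dv1 == pytest.approx(np.tanh(0.5))
        assert out.confidence == 5  # DV2 = 0.4621 in (0.35, 0.60]

    def test_variant7_congruent_sum_boundary_case(self):
        hues = np.array([-0.1, -0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        stim = Stimulus(hues=hues, category=1, sigma=0.0)
        p = ModelParams(variant=7, d=0.05, decnoise=0.0)
        out = simulate_trial(stim, p, np.random.default_rng(0))
        assert out.x == 1
        assert out.congruent_sum == pytest.approx(0.6)
        # 0.6 is not strictly above the 0.60 criterion, so it stays in bin 5
        assert out.confidence == 5

    def test_variant7_congruence_follows_choice_sign(self):
        hues = np.array([-0.1] * 6 + [0.1] * 2)
        stim = Stimulus(hues=hues, category=-1, sigma=0.0)
        p = ModelParams(variant=7, d=0.05, decnoise=0.0)
        out = simulate_trial(stim, p, np.random.default_rng(0))
        assert out.x == -1
        assert out.congruent_sum == pytest.approx(-0.6)
        assert out.confidence == 5

    def test_color_symmetry_of_simulated_distributions(self):
        # negating all hues mirrors the joint (choice, confidence) distribution
        rng = np.random.default_rng(9)
        stim = generate_design_set(StimulusDesign(n_per_cell=40), rng)
        stim = stim[stim["category"] == 1].reset_index(drop=True)
        big = stim.loc[np.repeat(stim.index, 40)].reset_index(drop=True)
        mirrored = big.copy()
        hue_cols = [f"hue_{i}" for i in range(1, 9)]
        mirrored[hue_cols] = -mirrored[hue_cols]
        mirrored["category"] = -1
        p = ModelParams(variant=4, d=0.05, decnoise=0.15)
        a = simulate_dataset(big, p, np.random.default_rng(1))
        b = simulate_dataset(mirrored, p, np.random.default_rng(1))
        assert a["choice"].mean() == pytest.approx(-b["choice"].mean(), abs=0.03)
        assert a["confidence"].mean() == pytest.approx(b["confidence"].mean(), abs=0.03)
        assert a["accuracy"].mean() == pytest.approx(b["accuracy"].mean(), abs=0.03)

    def test_simulated_dataset_deterministic_under_seed(self, v4_params):
        stim = generate_design_set(StimulusDesign(n_per_cell=20), np.random.default_rng(0))
        a = simulate_dataset(stim, v4_params, np.random.default_rng(5))
        b = simulate_dataset(stim, v4_params, np.random.default_rng(5))
        assert a.equals(b)
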