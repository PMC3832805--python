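import math

import numpy as np
import pytest

from pitnet import (
    EvaluationConfig,
    McmcConfig,
    ParadigmConfig,
    ParameterSpace,
    PosteriorSampleSet,
    PriorSpec,
    TestCondition,
    Trial,
    UtilityVector,
    WeightConfiguration,
    context_overlap_sweep,
    devaluation_experiment,
    efficacy,
    infer_latent_posterior,
    pit_effects,
    predict_food_probability,
    response_score,
    run_pit_battery,
    schedule_sweep,
    utility,
)
from pitnet.paradigm import test_evidence as make_test_evidence
from pitnet.evaluation import battery_to_frame, frame_to_battery

from .oracles import (
    brute_force_food_prediction,
    brute_force_latent_posterior,
    sigmoid,
)
from .test_model import random_weights


def samples_from_configs(configs, spec):
    space = ParameterSpace(spec)
    draws = np.stack([space.to_vector(w) for w in configs])
    return PosteriorSampleSet(
        draws=draws,
        chain_ids=np.zeros(len(configs), dtype=int),
        parameter_names=space.names,
        acceptance_rates=np.ones((1, space.size)),
        config=McmcConfig(n_iterations=len(configs) + 1, n_burn_in=0, thinning=1, n_chains=1),
        spec=spec,
    )


def zero_weight_samples(spec, bias=0.0):
    weights = WeightConfiguration.zeros(spec)
    for n in weights.biases:
        weights.biases[n] = bias
    return samples_from_configs([weights], spec)


class TestLatentPosterior:
    def test_zero_weights_give_prior_over_configurations(self, spec):
        weights = WeightConfiguration.zeros(spec)
        weights.biases.update({h: -1.0 for h in spec.latent_nodes})
        evidence = make_test_evidence(TestCondition.for_lever("baseline", "L1", spec), spec)
        post = infer_latent_posterior(weights, spec, evidence)
        p_on = sigmoid(-1.0)
        for config, prob in post.items():
            expected = math.prod(p_on if h else 1 - p_on for h in config)
            assert prob == pytest.approx(expected, abs=1e-12)

    def test_cue_evidence_raises_cause_probability(self, spec):
        weights = WeightConfiguration.zeros(spec)
        weights.biases["H1"] = -2.0
        weights.biases["S1"] = -3.0
        weights.edge_weights[("H1", "S1")] = 6.0
        evidence = Trial(states={"S1": 1})
        post = infer_latent_posterior(weights, spec, evidence)
        h1_marginal = sum(p for cfg, p in post.items() if cfg[0] == 1)
        assert h1_marginal > sigmoid(-2.0)

    @pytest.mark.parametrize("case", range(10))
    def test_matches_brute_force_bayes(self, spec, case):
        rng = np.random.default_rng(2000 + case)
        weights = random_weights(spec, rng)
        observed = rng.choice(
            spec.observable_nodes, size=rng.integers(1, 6), replace=False
        )
        evidence = Trial(states={n: int(rng.integers(0, 2)) for n in observed})
        action = int(rng.integers(0, 2))
        expected = brute_force_latent_posterior(weights, spec, evidence, action)
        got = infer_latent_posterior(weights, spec, evidence, action_state=action)
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-10)
        assert got.sum() == pytest.approx(1.0, abs=1e-10)

    def test_latent_in_evidence_rejected(self, spec):
        weights = WeightConfiguration.zeros(spec)
        with pytest.raises(ValueError):
            infer_latent_posterior(weights, spec, Trial(states={"H1": 1}))


class TestFoodPrediction:
    def test_zero_weights_reduce_to_background(self, spec):
        samples = zero_weight_samples(spec, bias=-1.5)
        evidence = make_test_evidence(TestCondition.for_lever("same", "L1", spec), spec)
        for action in (0, 1):
            p = predict_food_probability(samples, spec, evidence, action, "F1")
            assert p == pytest.approx(sigmoid(-1.5), abs=1e-12)

    def test_positive_action_weight_increases_prediction(self, spec):
        weights = WeightConfiguration.zeros(spec)
        weights.edge_weights[("A", "F1")] = 2.0
        samples = samples_from_configs([weights], spec)
        evidence = make_test_evidence(TestCondition.for_lever("baseline", "L1", spec), spec)
        on = predict_food_probability(samples, spec, evidence, 1, "F1")
        off = predict_food_probability(samples, spec, evidence, 0, "F1")
        assert on > off

    def test_matches_brute_force_double_sum(self, spec, rng):
        configs = [random_weights(spec, rng), random_weights(spec, rng)]
        samples = samples_from_configs(configs, spec)
        evidence = make_test_evidence(TestCondition.for_lever("different", "L1", spec), spec)
        for food in spec.food_nodes:
            expected = brute_force_food_prediction(configs, spec, evidence, 1, food)
            got = predict_food_probability(samples, spec, evidence, 1, food)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_observed_food_rejected(self, spec, tiny_fit):
        evidence = Trial(states={"L1": 1, "F1": 1})
        with pytest.raises(ValueError):
            predict_food_probability(tiny_fit, spec, evidence, 1, "F1")


class TestEfficacyUtilityResponse:
    def test_efficacy_is_action_clamped_target_prediction(self, spec, tiny_fit):
        cfg = EvaluationConfig()
        evidence = make_test_evidence(TestCondition.for_lever("same", "L1", spec), spec)
        assert efficacy(tiny_fit, spec, evidence, cfg) == pytest.approx(
            predict_food_probability(tiny_fit, spec, evidence, 1, "F1")
        )

    def test_efficacy_ignores_utilities(self, spec, tiny_fit):
        """E reads no utilities: identical bit for bit across states."""
        cfg = EvaluationConfig()
        evidence = make_test_evidence(TestCondition.for_lever("same", "L1", spec), spec)
        e = efficacy(tiny_fit, spec, evidence, cfg)
        hungry = run_pit_battery(tiny_fit, spec, UtilityVector.hungry(spec), cfg)
        sated = run_pit_battery(tiny_fit, spec, UtilityVector.sated(spec), cfg)
        assert [r.efficacy for r in hungry] == [r.efficacy for r in sated]
        assert next(r.efficacy for r in hungry if r.condition == "same") == e

    def test_zero_utilities_zero_utility(self, spec, tiny_fit):
        cfg = EvaluationConfig()
        evidence = make_test_evidence(TestCondition.for_lever("general", "L1", spec), spec)
        assert utility(tiny_fit, spec, evidence, UtilityVector.sated(spec), cfg) == 0.0

    def test_utility_excludes_target_and_scales_linearly(self, spec, tiny_fit):
        cfg = EvaluationConfig(target_food="F1")
        evidence = make_test_evidence(TestCondition.for_lever("general", "L1", spec), spec)
        base = utility(tiny_fit, spec, evidence, UtilityVector.hungry(spec), cfg)
        doubled = utility(
            tiny_fit, spec, evidence, UtilityVector({"F1": 5.0, "F2": 2.0, "F3": 2.0}), cfg
        )
        assert doubled == pytest.approx(2 * base, rel=1e-12)  # F1's value never enters

    def test_response_reduces_to_efficacy(self, spec, tiny_fit):
        evidence = make_test_evidence(TestCondition.for_lever("same", "L1", spec), spec)
        cfg = EvaluationConfig(alpha=1.0, beta=0.0)
        u = UtilityVector.hungry(spec)
        assert response_score(tiny_fit, spec, evidence, u, cfg) == pytest.approx(
            efficacy(tiny_fit, spec, evidence, cfg)
        )
        cfg2 = EvaluationConfig(alpha=2.0, beta=1.0)
        assert response_score(
            tiny_fit, spec, evidence, UtilityVector.sated(spec), cfg2
        ) == pytest.approx(2.0 * efficacy(tiny_fit, spec, evidence, cfg2))

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            EvaluationConfig(alpha=-1.0)

    def test_negative_utility_rejected(self):
        with pytest.raises(ValueError):
            UtilityVector({"F1": -0.5})


class TestBattery:
    def test_untrained_model_shows_no_transfer(self, spec):
        """With uninformative (all-zero) weights the evidence cannot move
        any prediction: all four conditions score identically."""
        samples = zero_weight_samples(spec)
        battery = run_pit_battery(samples, spec)
        responses = {r.response for r in battery}
        assert len(battery) == 4
        assert max(responses) - min(responses) < 1e-12

    def test_latent_posterior_normalized(self, spec, tiny_fit):
        for result in run_pit_battery(tiny_fit, spec):
            assert result.latent_posterior.sum() == pytest.approx(1.0, abs=1e-10)
            assert 0.0 <= result.efficacy <= 1.0
            assert result.utility >= 0.0

    def test_csv_round_trip(self, spec, tiny_fit, tmp_path):
        battery = run_pit_battery(tiny_fit, spec)
        frame = battery_to_frame(battery)
        path = tmp_path / "battery.csv"
        frame.to_csv(path, index=False)
        import pandas as pd

        again = frame_to_battery(pd.read_csv(path))
        for a, b in zip(again, battery):
            assert a.condition == b.condition
            assert a.response == pytest.approx(b.response, rel=1e-12)
            assert a.food_probs_action == pytest.approx(b.food_probs_action, rel=1e-12)


class TestDevaluation:
    def test_general_effect_vanishes_exactly_when_sated(self, spec, tiny_fit):
        out = devaluation_experiment(tiny_fit, spec)
        sated = out["effects"].set_index("condition")["sated_effect"]
        assert sated["general"] == 0.0

    def test_specific_effect_survives_devaluation_bitwise(self, spec, tiny_fit):
        out = devaluation_experiment(tiny_fit, spec)
        hungry_e = {r.condition: r.efficacy for r in out["hungry"]}
        sated_e = {r.condition: r.efficacy for r in out["sated"]}
        assert hungry_e == sated_e  # exact float equality

    def test_hungry_table_matches_unit_utility_battery(self, spec, tiny_fit):
        out = devaluation_experiment(tiny_fit, spec)
        direct = run_pit_battery(tiny_fit, spec, UtilityVector.hungry(spec))
        for a, b in zip(out["hungry"], direct):
            assert a.response == b.response


@pytest.fixture(scope="module")
def fast_setup():
    paradigm = ParadigmConfig(
        n_pavlovian_per_cs=30, n_instrumental_per_lever=120, n_blank=50
    )
    mcmc = McmcConfig(n_iterations=600, n_burn_in=200, thinning=2, seed=0)
    return paradigm, mcmc


class TestSweeps:
    def test_schedule_sweep_schema_and_reproducibility(self, spec, fast_setup):
        paradigm, mcmc = fast_setup
        kwargs = dict(
            paradigm=paradigm, spec=spec, mcmc=mcmc, reinforce_probs=(0.05,), seed=9
        )
        a = schedule_sweep(**kwargs)
        b = schedule_sweep(**kwargs)
        assert list(a.columns) == [
            "reinforce_prob", "e_baseline", "e_same", "specific_effect", "general_effect",
        ]
        assert a.equals(b)

    def test_context_sweep_schema(self, spec, fast_setup):
        paradigm, mcmc = fast_setup
        table = context_overlap_sweep(
            paradigm=paradigm, spec=spec, mcmc=mcmc, leaks=(0.0,), seed=9
        )
        assert list(table.columns) == ["cross_food_leak", "different_effect", "w_H4_F2_mean"]
        assert len(table) == 1
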