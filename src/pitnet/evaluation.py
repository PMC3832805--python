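"""Test-phase evaluation: context, efficacy and utility.

Given a fitted posterior over weights, a test-condition evidence
pattern (which lever, which sound) drives exact inference over latent
causes; foods are then predicted under the *intervention* do(A=1) —
pressing is the option being evaluated, so the action is clamped and
never used as evidence about the latents.

Efficacy E is the predicted probability of the action's own food.
Utility U is the value of the *additional* rewards the scene predicts
(all foods except the action's target, weighted by their utilities).
The response score combines them linearly, R = alpha*E + beta*U, and
PIT effects are reported as R(condition) - R(baseline):

* specific PIT: the same-condition sound raises E (higher chance of
  the action's goal);
* general PIT: the general-condition sound adds a new predicted
  reward, raising U — and vanishing when utilities are zeroed
  (devaluation);
* PIT inhibition: the different-condition sound's food is suppressed
  by the negative link from the active instrumental context, leaving
  R near baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .inference import McmcConfig, PosteriorSampleSet, fit_posterior
from .model import ParameterSpace, PriorSpec, Trial, WeightConfiguration
from .network import NetworkSpec, default_network_spec
from .paradigm import TEST_LABELS, ParadigmConfig, TestCondition, generate_paradigm, test_evidence

__all__ = [
    "UtilityVector",
    "EvaluationConfig",
    "EvaluationResult",
    "infer_latent_posterior",
    "predict_food_probability",
    "efficacy",
    "utility",
    "response_score",
    "run_pit_battery",
    "pit_effects",
    "devaluation_experiment",
    "schedule_sweep",
    "context_overlap_sweep",
    "battery_to_frame",
    "frame_to_battery",
]


@dataclass(frozen=True)
class UtilityVector:
    """Non-negative value of each food to the animal (its motivational
    state).  Hungry: all ones.  Sated (devaluation): all zeros."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise ValueError("utilities must be non-negative")

    def __getitem__(self, food: str) -> float:
        return self.values[food]

    @classmethod
    def uniform(cls, spec: NetworkSpec, value: float = 1.0) -> "UtilityVector":
        return cls({f: value for f in spec.food_nodes})

    @classmethod
    def hungry(cls, spec: NetworkSpec) -> "UtilityVector":
        return cls.uniform(spec, 1.0)

    @classmethod
    def sated(cls, spec: NetworkSpec) -> "UtilityVector":
        return cls.uniform(spec, 0.0)


@dataclass(frozen=True)
class EvaluationConfig:
    """Gains of the response rule R = alpha*E + beta*U and the food the
    evaluated action is directed at."""

    alpha: float = 1.0
    beta: float = 1.0
    target_food: str = "F1"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("gains must be non-negative")


@dataclass
class EvaluationResult:
    condition: str
    efficacy: float
    utility: float
    response: float
    food_probs_action: dict[str, float]
    food_probs_no_action: dict[str, float]
    latent_posterior: np.ndarray  # mean over draws, one entry per latent configuration


# -- exact inference over latent configurations --------------------------


def _latent_configs(spec: NetworkSpec) -> np.ndarray:
    return np.array(list(itertools.product((0.0, 1.0), repeat=len(spec.latent_nodes))))


def _split_evidence(spec: NetworkSpec, evidence: Trial) -> dict[str, int]:
    for node in evidence.states:
        if node in spec.latent_nodes:
            raise ValueError(f"evidence must not contain latent node {node!r}")
    return {n: v for n, v in evidence.states.items() if n != spec.action_node}


def _config_log_posterior(
    draws: np.ndarray,
    space: ParameterSpace,
    spec: NetworkSpec,
    observed: dict[str, int],
    action_state: int,
) -> np.ndarray:
    """Unnormalized log P(latent config | evidence), shape (D, R)."""
    configs = _latent_configs(spec)  # (R, L)
    bias_pos = {n: space.n_weights + i for i, n in enumerate(space.bias_nodes)}
    edge_pos = {e: i for i, e in enumerate(space.edges)}
    latents = spec.latent_nodes

    b_lat = draws[:, [bias_pos[h] for h in latents]]  # (D, L)
    log_p = _logsig(b_lat) @ configs.T + _logsig(-b_lat) @ (1.0 - configs).T  # (D, R)

    for child, value in observed.items():
        eta = _child_logit(draws, space, spec, configs, child, action_state, bias_pos, edge_pos)
        log_p = log_p + (_logsig(eta) if value == 1 else _logsig(-eta))
    return log_p


def _logsig(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _child_logit(draws, space, spec, configs, child, action_state, bias_pos, edge_pos) -> np.ndarray:
    """Activation input of a child node per draw per latent config, (D, R)."""
    eta = np.repeat(draws[:, [bias_pos[child]]], configs.shape[0], axis=1)
    for parent in spec.parents_of(child):
        if parent == spec.action_node:
            eta = eta + action_state * draws[:, [edge_pos[(parent, child)]]]
        else:
            h = spec.latent_nodes.index(parent)
            eta = eta + np.outer(draws[:, edge_pos[(parent, child)]], configs[:, h])
    return eta


def infer_latent_posterior(
    weights: WeightConfiguration,
    spec: NetworkSpec,
    evidence: Trial,
    action_state: int = 0,
) -> pd.Series:
    """Exact posterior over latent configurations given evidence.

    Returns a Series indexed by latent on/off tuples, normalized to
    one.  The action state is clamped (it is a decision, not data);
    if the action node appears in the evidence its value is used.
    """
    weights.validate(spec)
    if spec.action_node and spec.action_node in evidence.states:
        action_state = evidence.states[spec.action_node]
    observed = _split_evidence(spec, evidence)
    space = ParameterSpace(spec)
    theta = space.to_vector(weights)[None, :]
    log_p = _config_log_posterior(theta, space, spec, observed, action_state)[0]
    log_p = log_p - log_p.max()
    p = np.exp(log_p)
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        raise RuntimeError("latent posterior normalizer vanished")
    configs = _latent_configs(spec)
    index = pd.MultiIndex.from_tuples(
        [tuple(int(v) for v in row) for row in configs], names=list(spec.latent_nodes)
    )
    return pd.Series(p / total, index=index, name="posterior")


def _draws_and_space(samples: PosteriorSampleSet, spec: NetworkSpec):
    space = ParameterSpace(spec)
    if tuple(samples.parameter_names) != space.names:
        raise ValueError("sample set parameters do not match the NetworkSpec")
    return samples.draws, space


def _food_probabilities(
    samples: PosteriorSampleSet,
    spec: NetworkSpec,
    evidence: Trial,
    action_state: int,
) -> tuple[dict[str, float], np.ndarray]:
    """Posterior-predictive P(food | evidence, do(A=action_state)) per
    food, plus the draw-averaged latent-configuration posterior."""
    if action_state not in (0, 1):
        raise ValueError("action_state must be 0 or 1")
    draws, space = _draws_and_space(samples, spec)
    observed = _split_evidence(spec, evidence)
    configs = _latent_configs(spec)
    bias_pos = {n: space.n_weights + i for i, n in enumerate(space.bias_nodes)}
    edge_pos = {e: i for i, e in enumerate(space.edges)}

    log_p = _config_log_posterior(draws, space, spec, observed, action_state)
    log_p = log_p - log_p.max(axis=1, keepdims=True)
    post = np.exp(log_p)
    post /= post.sum(axis=1, keepdims=True)  # (D, R)

    probs: dict[str, float] = {}
    for food in spec.food_nodes:
        if food in evidence.states:
            raise ValueError(f"food {food!r} is observed in the evidence")
        eta = _child_logit(draws, space, spec, configs, food, action_state, bias_pos, edge_pos)
        probs[food] = float(np.mean(np.sum(post * _sigmoid(eta), axis=1)))
    return probs, post.mean(axis=0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return np.exp(_logsig(x))


def predict_food_probability(
    samples: PosteriorSampleSet,
    spec: NetworkSpec,
    evidence: Trial,
    action_state: int,
    food: str,
) -> float:
    """Posterior-draw average of sum_config P(config|evidence) *
    sigma(food activation with A clamped to action_state)."""
    if food not in spec.food_nodes:
        raise ValueError(f"unknown food {food!r}")
    probs, _ = _food_probabilities(samples, spec, evidence, action_state)
    return probs[food]


def efficacy(
    samples: PosteriorSampleSet,
    spec: NetworkSpec,
    evidence: Trial,
    config: EvaluationConfig,
) -> float:
    """Probability of reaching the action's goal: P(target food | do(A=1))."""
    return predict_food_probability(samples, spec, evidence, 1, config.target_food)


def utility(
    samples: PosteriorSampleSet,
    spec: NetworkSpec,
    evidence: Trial,
    utilities: UtilityVector,
    config: EvaluationConfig,
) -> float:
    """Value of the additional predicted rewards: sum over non-target
    foods of u_j * P(F_j | do(A=1))."""
    total = 0.0
    for food in spec.food_nodes:
        if food == config.target_food:
            continue
        total += utilities[food] * predict_food_probability(samples, spec, evidence, 1, food)
    return total


def response_score(
    samples: PosteriorSampleSet,
    spec: NetworkSpec,
    evidence: Trial,
    utilities: UtilityVector,
    config: EvaluationConfig,
) -> float:
    """R = alpha*E + beta*U; PIT effects are differences from baseline."""
    e = efficacy(samples, spec, evidence, config)
    u = utility(samples, spec, evidence, utilities, config)
    return config.alpha * e + config.beta * u


def _evaluate_condition(
    samples: PosteriorSampleSet,
    spec: NetworkSpec,
    condition: TestCondition,
    utilities: UtilityVector,
    config: EvaluationConfig,
) -> EvaluationResult:
    evidence = test_evidence(condition, spec)
    probs_on, latent_post = _food_probabilities(samples, spec, evidence, 1)
    probs_off, _ = _food_probabilities(samples, spec, evidence, 0)
    e = probs_on[config.target_food]
    u = sum(
        utilities[f] * probs_on[f] for f in spec.food_nodes if f != config.target_food
    )
    return EvaluationResult(
        condition=condition.label,
        efficacy=e,
        utility=u,
        response=config.alpha * e + config.beta * u,
        food_probs_action=probs_on,
        food_probs_no_action=probs_off,
        latent_posterior=latent_post,
    )


def run_pit_battery(
    samples: PosteriorSampleSet,
    spec: NetworkSpec | None = None,
    utilities: UtilityVector | None = None,
    config: EvaluationConfig | None = None,
    lever: str = "L1",
) -> list[EvaluationResult]:
    """Evaluate the four test conditions (baseline, same, different,
    general) on one lever.  Deterministic given the sample set."""
    spec = spec or default_network_spec()
    utilities = utilities or UtilityVector.hungry(spec)
    config = config or EvaluationConfig()
    return [
        _evaluate_condition(samples, spec, TestCondition.for_lever(label, lever, spec), utilities, config)
        for label in TEST_LABELS
    ]


def pit_effects(battery: list[EvaluationResult]) -> dict[str, float]:
    """Response-score difference of each condition from baseline."""
    base = next(r.response for r in battery if r.condition == "baseline")
    return {r.condition: r.response - base for r in battery if r.condition != "baseline"}


def battery_to_frame(battery: list[EvaluationResult]) -> pd.DataFrame:
    base = next(r.response for r in battery if r.condition == "baseline")
    rows = []
    for r in battery:
        row = {
            "condition": r.condition,
            "efficacy": r.efficacy,
            "utility": r.utility,
            "response": r.response,
            "effect": r.response - base,
        }
        for food, p in r.food_probs_action.items():
            row[f"p_{food}_press"] = p
        for food, p in r.food_probs_no_action.items():
            row[f"p_{food}_nopress"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_battery(frame: pd.DataFrame) -> list[EvaluationResult]:
    """Rebuild battery rows from their CSV form (latent posteriors are
    not serialized and come back empty)."""
    results = []
    for _, row in frame.iterrows():
        on = {c[2:-6]: row[c] for c in frame.columns if c.startswith("p_") and c.endswith("_press")}
        off = {c[2:-8]: row[c] for c in frame.columns if c.startswith("p_") and c.endswith("_nopress")}
        results.append(
            EvaluationResult(
                condition=row["condition"],
                efficacy=float(row["efficacy"]),
                utility=float(row["utility"]),
                response=float(row["response"]),
                food_probs_action=on,
                food_probs_no_action=off,
                latent_posterior=np.array([]),
            )
        )
    return results


def devaluation_experiment(
    samples: PosteriorSampleSet,
    spec: NetworkSpec | None = None,
    config: EvaluationConfig | None = None,
    lever: str = "L1",
) -> dict:
    """PIT battery under hunger (u=1) and satiety (u=0).

    Efficacy never reads utilities, so the specific-PIT effect is
    bit-identical across states; the general-PIT effect collapses to
    zero when utilities vanish — only the utility route is devalued.
    """
    spec = spec or default_network_spec()
    config = config or EvaluationConfig()
    hungry = run_pit_battery(samples, spec, UtilityVector.hungry(spec), config, lever)
    sated = run_pit_battery(samples, spec, UtilityVector.sated(spec), config, lever)
    effects = pd.DataFrame(
        {
            "condition": [c for c in TEST_LABELS if c != "baseline"],
            "hungry_effect": [pit_effects(hungry)[c] for c in TEST_LABELS if c != "baseline"],
            "sated_effect": [pit_effects(sated)[c] for c in TEST_LABELS if c != "baseline"],
        }
    )
    return {"hungry": hungry, "sated": sated, "effects": effects}


# -- end-to-end prediction experiments -----------------------------------


def _derived_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def run_pipeline(
    paradigm: ParadigmConfig,
    spec: NetworkSpec | None = None,
    prior: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorSampleSet:
    """generate -> fit, the shared backbone of the sweep experiments."""
    spec = spec or default_network_spec()
    trials = generate_paradigm(paradigm, spec)
    return fit_posterior(trials, spec, prior or PriorSpec(), mcmc or McmcConfig())


def schedule_sweep(
    paradigm: ParadigmConfig | None = None,
    spec: NetworkSpec | None = None,
    prior: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    reinforce_probs=(0.05, 0.25, 0.5, 1.0),
    seed: int = 0,
    config: EvaluationConfig | None = None,
) -> pd.DataFrame:
    """Specific-PIT effect as a function of the reinforcement schedule.

    Each schedule gets a full generate->fit->evaluate run.  Under
    continuous reinforcement the action already succeeds with
    certainty, so the same-condition sound can no longer raise
    efficacy and specific PIT should vanish; general PIT, carried by
    utility, should persist.
    """
    spec = spec or default_network_spec()
    paradigm = paradigm or ParadigmConfig()
    config = config or EvaluationConfig()
    rows = []
    for i, p in enumerate(reinforce_probs):
        run_paradigm = replace(paradigm, reinforce_prob=p, seed=_derived_seed(seed, i))
        run_mcmc = replace(mcmc or McmcConfig(), seed=_derived_seed(seed, 1000 + i))
        samples = run_pipeline(run_paradigm, spec, prior, run_mcmc)
        battery = run_pit_battery(samples, spec, UtilityVector.hungry(spec), config)
        by_cond = {r.condition: r for r in battery}
        rows.append(
            {
                "reinforce_prob": p,
                "e_baseline": by_cond["baseline"].efficacy,
                "e_same": by_cond["same"].efficacy,
                "specific_effect": by_cond["same"].efficacy - by_cond["baseline"].efficacy,
                "general_effect": pit_effects(battery)["general"],
            }
        )
    return pd.DataFrame(rows)


def context_overlap_sweep(
    paradigm: ParadigmConfig | None = None,
    spec: NetworkSpec | None = None,
    prior: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    leaks=(0.0, 0.1, 0.3),
    seed: int = 0,
    config: EvaluationConfig | None = None,
) -> pd.DataFrame:
    """Different-condition PIT effect as the two lever contexts overlap.

    cross_food_leak lets the other instrumental food appear during a
    lever's sessions; the inhibitory link from the instrumental
    context to that food then weakens (becomes less negative) and PIT
    inhibition should fade, leaving a partial transfer effect in the
    different condition.
    """
    spec = spec or default_network_spec()
    paradigm = paradigm or ParadigmConfig()
    config = config or EvaluationConfig()
    rows = []
    for i, eps in enumerate(leaks):
        run_paradigm = replace(paradigm, cross_food_leak=eps, seed=_derived_seed(seed, 2000 + i))
        run_mcmc = replace(mcmc or McmcConfig(), seed=_derived_seed(seed, 3000 + i))
        samples = run_pipeline(run_paradigm, spec, prior, run_mcmc)
        battery = run_pit_battery(samples, spec, UtilityVector.hungry(spec), config)
        rows.append(
            {
                "cross_food_leak": eps,
                "different_effect": pit_effects(battery)["different"],
                "w_H4_F2_mean": float(np.mean(samples.parameter("w(H4->F2)"))),
            }
        )
    return pd.DataFrame(rows)
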