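"""Likelihood, priors and parameters of the sigmoid belief network.

Every node is binary and fires with probability sigma(bias + sum of
active-parent weights).  Latent causes are independent Bernoulli per
trial with prior probability sigma(latent bias); the marginal
likelihood of a trial sums over all 2^n_latent latent configurations
exactly (32 for the default network), which keeps the likelihood
deterministic and lets tests check it against brute-force enumeration.

The action node, when present, is an exogenous root: observed states
contribute a Bernoulli(sigma(bias)) factor and feed the foods it is
linked to; if it is ever unobserved it is marginalized like a latent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .network import Edge, NetworkSpec

__all__ = [
    "Trial",
    "WeightConfiguration",
    "PriorSpec",
    "ParameterSpace",
    "LikelihoodEvaluator",
    "activation_probability",
    "trial_log_likelihood",
    "log_prior",
    "compress_trials",
]


def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def activation_probability(bias: float, active_parent_weights=()) -> float:
    """sigma(bias + sum of active-parent weights), in (0, 1).

    Strictly increasing in the bias and in each weight; raises on
    non-finite input.
    """
    weights = np.asarray(list(active_parent_weights), dtype=float)
    if not np.isfinite(bias) or not np.all(np.isfinite(weights)):
        raise ValueError("bias and weights must be finite")
    z = float(bias + weights.sum())
    return float(np.exp(_log_sigmoid(z)))


@dataclass(frozen=True)
class Trial:
    """One time bin of observed binary states.

    ``states`` holds only the *observed* visible nodes (value 0 or 1);
    anything absent from the map is unobserved and marginalized.
    Latent nodes never appear.  ``multiplicity`` counts identical bins
    compressed into this record.
    """

    states: dict[str, int]
    phase: str = "test"
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        for node, value in self.states.items():
            if value not in (0, 1):
                raise ValueError(f"state of {node} must be 0 or 1, got {value!r}")
        if self.phase != "blank" and not self.states:
            raise ValueError("non-blank trial must observe at least one node")

    def key(self) -> tuple:
        return (self.phase, tuple(sorted(self.states.items())))


def compress_trials(trials) -> list[Trial]:
    """Aggregate identical trials into multiplicity counts.

    Bit-identical to evaluating the uncompressed list, orders of
    magnitude cheaper for long training runs.
    """
    counts: dict[tuple, int] = {}
    order: dict[tuple, Trial] = {}
    for t in trials:
        k = t.key()
        counts[k] = counts.get(k, 0) + t.multiplicity
        order.setdefault(k, t)
    return [
        Trial(states=dict(order[k].states), phase=order[k].phase, multiplicity=n)
        for k, n in counts.items()
    ]


@dataclass
class WeightConfiguration:
    """Per-edge weights and per-node biases, all in log-odds units."""

    edge_weights: dict[Edge, float]
    biases: dict[str, float]

    def validate(self, spec: NetworkSpec) -> None:
        if set(self.edge_weights) != set(spec.edges):
            raise ValueError("edge_weights must cover exactly the edges of the NetworkSpec")
        expected = set(spec.all_nodes)
        if set(self.biases) != expected:
            raise ValueError("biases must cover every latent and visible node")
        values = list(self.edge_weights.values()) + list(self.biases.values())
        if not np.all(np.isfinite(values)):
            raise ValueError("all weights and biases must be finite")

    @classmethod
    def zeros(cls, spec: NetworkSpec) -> "WeightConfiguration":
        return cls(
            edge_weights={e: 0.0 for e in spec.edges},
            biases={n: 0.0 for n in spec.all_nodes},
        )


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors, zero-centered on the link weights.

    Weights and biases get separately configurable means and scales.
    The weight scale (2.0) leaves room for the strong excitatory and
    inhibitory links the paradigm demands; the tighter observable-bias
    scale (0.75) keeps background rates anchored near zero so that
    absent outcomes must be explained by inhibitory links rather than
    by a collapsed background.  Latent biases get their own prior,
    centered below zero: a latent cause is a *context*, rare a priori.
    A zero-centered latent-bias prior would leave the likelihood's
    complement symmetry (relabel a cause as its own absence, negating
    its weights) unbroken and chains would land in mirrored modes.
    See docs/methods.md.
    """

    weight_mean: float = 0.0
    weight_scale: float = 5.0
    bias_mean: float = -4.0
    bias_scale: float = 0.5
    latent_bias_mean: float = -2.0
    latent_bias_scale: float = 0.4

    def __post_init__(self) -> None:
        if self.weight_scale <= 0 or self.bias_scale <= 0 or self.latent_bias_scale <= 0:
            raise ValueError("prior scales must be positive")


def log_prior(
    weights: WeightConfiguration, prior: PriorSpec, spec: NetworkSpec | None = None
) -> float:
    """Sum of Gaussian log-densities over all edge weights and biases.

    Pass the NetworkSpec so latent-node biases get the latent prior
    family; without it every bias uses the observable-bias family.
    """

    def _normal_logpdf(x: np.ndarray, mean: float, scale: float) -> float:
        z = (np.asarray(x, dtype=float) - mean) / scale
        return float(np.sum(-0.5 * z * z - math.log(scale) - 0.5 * math.log(2.0 * math.pi)))

    latents = set(spec.latent_nodes) if spec is not None else set()
    w = list(weights.edge_weights.values())
    b_lat = [v for n, v in weights.biases.items() if n in latents]
    b_obs = [v for n, v in weights.biases.items() if n not in latents]
    return (
        _normal_logpdf(w, prior.weight_mean, prior.weight_scale)
        + _normal_logpdf(b_obs, prior.bias_mean, prior.bias_scale)
        + _normal_logpdf(b_lat, prior.latent_bias_mean, prior.latent_bias_scale)
    )


class ParameterSpace:
    """Canonical flat-vector layout of a WeightConfiguration.

    Edge weights first (edges sorted lexicographically), then biases
    (nodes sorted); the fixed ordering makes samplers and CSV output
    reproducible.
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.edges: tuple[Edge, ...] = spec.sorted_edges()
        self.bias_nodes: tuple[str, ...] = tuple(sorted(spec.all_nodes))
        self.names: tuple[str, ...] = tuple(
            [f"w({p}->{c})" for p, c in self.edges] + [f"b({n})" for n in self.bias_nodes]
        )
        self.n_weights = len(self.edges)
        self.size = len(self.names)

    def to_vector(self, weights: WeightConfiguration) -> np.ndarray:
        weights.validate(self.spec)
        return np.array(
            [weights.edge_weights[e] for e in self.edges]
            + [weights.biases[n] for n in self.bias_nodes],
            dtype=float,
        )

    def to_configuration(self, theta: np.ndarray) -> WeightConfiguration:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.size,):
            raise ValueError(f"expected vector of length {self.size}")
        return WeightConfiguration(
            edge_weights={e: float(theta[i]) for i, e in enumerate(self.edges)},
            biases={
                n: float(theta[self.n_weights + i]) for i, n in enumerate(self.bias_nodes)
            },
        )

    def prior_mean_and_scale(self, prior: PriorSpec) -> tuple[np.ndarray, np.ndarray]:
        mean = np.full(self.size, prior.bias_mean)
        scale = np.full(self.size, prior.bias_scale)
        mean[: self.n_weights] = prior.weight_mean
        scale[: self.n_weights] = prior.weight_scale
        latents = set(self.spec.latent_nodes)
        for i, node in enumerate(self.bias_nodes):
            if node in latents:
                mean[self.n_weights + i] = prior.latent_bias_mean
                scale[self.n_weights + i] = prior.latent_bias_scale
        return mean, scale


@dataclass
class _CompiledTrials:
    x_one: np.ndarray  # (P, C) indicator: child observed present
    x_zero: np.ndarray  # (P, C) indicator: child observed absent
    action_state: np.ndarray  # (P,) 0/1 observed, -1 unobserved/no action
    multiplicity: np.ndarray  # (P,)


class LikelihoodEvaluator:
    """Vectorized marginal log-likelihood of a fixed trial collection.

    Compiles the (compressed) trials into index arrays once, then each
    call with a parameter vector sums over every latent configuration
    (and over the action state where it is unobserved) in a handful of
    dense operations on arrays of size 2^n_latent x n_children.
    """

    def __init__(self, spec: NetworkSpec, trials):
        self.spec = spec
        self.space = ParameterSpace(spec)
        self.children = spec.observable_nodes
        self._child_index = {c: i for i, c in enumerate(self.children)}
        self._latents = spec.latent_nodes
        n_lat = len(self._latents)

        # enumeration rows: latent configs x action states (if any action
        # node); roots = latents plus the action node treated uniformly
        configs = np.array(list(itertools.product((0.0, 1.0), repeat=n_lat)))
        if spec.action_node is not None:
            self._root_rows = np.column_stack(
                [np.repeat(configs, 2, axis=0), np.tile(np.array([0.0, 1.0]), len(configs))]
            )
            self._a_rows = self._root_rows[:, -1]
            roots = list(self._latents) + [spec.action_node]
        else:
            self._root_rows = configs
            self._a_rows = None
            roots = list(self._latents)
        self._root_rows_c = 1.0 - self._root_rows

        # index maps from the flat parameter vector; -1 points at a
        # padding zero appended to theta at evaluation time
        n_children = len(self.children)
        pad = self.space.size
        self._w_index = np.full((len(roots), n_children), pad, dtype=int)
        for i, (parent, child) in enumerate(self.space.edges):
            self._w_index[roots.index(parent), self._child_index[child]] = i
        bias_offset = self.space.n_weights
        bias_pos = {n: bias_offset + i for i, n in enumerate(self.space.bias_nodes)}
        self._b_child_index = np.array([bias_pos[c] for c in self.children])
        self._b_root_index = np.array([bias_pos[r] for r in roots])

        self._compiled = self._compile(compress_trials(trials))
        ct = self._compiled
        # observation masks, transposed once for the matmuls
        self._xt_obs = (ct.x_one + ct.x_zero).T  # (C, P)
        self._xt_zero = ct.x_zero.T
        # additive row-validity mask for observed action states
        if self._a_rows is not None:
            mismatch = (ct.action_state >= 0)[None, :] & (
                self._a_rows[:, None] != ct.action_state[None, :]
            )
            self._row_mask = np.where(mismatch, -np.inf, 0.0)
        else:
            self._row_mask = None

    def _compile(self, trials: list[Trial]) -> _CompiledTrials:
        n_children = len(self.children)
        x_one = np.zeros((len(trials), n_children))
        x_zero = np.zeros((len(trials), n_children))
        action_state = np.full(len(trials), -1, dtype=int)
        mult = np.zeros(len(trials))
        for p, t in enumerate(trials):
            mult[p] = t.multiplicity
            for node, value in t.states.items():
                if node == self.spec.action_node:
                    action_state[p] = value
                elif node in self._child_index:
                    (x_one if value else x_zero)[p, self._child_index[node]] = 1.0
                else:
                    raise ValueError(f"unknown or latent node {node!r} in trial states")
        return _CompiledTrials(x_one, x_zero, action_state, mult)

    def log_likelihood(self, theta: np.ndarray) -> float:
        ct = self._compiled
        if ct.multiplicity.size == 0:
            return 0.0
        theta = np.append(np.asarray(theta, dtype=float), 0.0)  # pad for absent edges

        # log-prior of each enumeration row (latent roots, plus the
        # action root whose factor covers observed action states)
        b_root = theta[self._b_root_index]
        row_lp = self._root_rows @ _log_sigmoid(b_root) + self._root_rows_c @ _log_sigmoid(-b_root)

        eta = theta[self._b_child_index] + self._root_rows @ theta[self._w_index]  # (R, C)
        log_on = _log_sigmoid(eta)
        # logsig(-x) = logsig(x) - x, so one transcendental pass suffices
        ll_rows = log_on @ self._xt_obs - eta @ self._xt_zero  # (R, P)
        ll_rows += row_lp[:, None]
        if self._row_mask is not None:
            ll_rows += self._row_mask

        m = ll_rows.max(axis=0)
        per_trial = m + np.log(np.einsum("rp->p", np.exp(ll_rows - m)))
        return float(per_trial @ ct.multiplicity)


def trial_log_likelihood(
    weights: WeightConfiguration, spec: NetworkSpec, trial: Trial
) -> float:
    """Marginal log-likelihood of one trial, scaled by its multiplicity.

    Sums over all latent configurations exactly; unobserved children
    contribute a factor of one.
    """
    weights.validate(spec)
    evaluator = LikelihoodEvaluator(spec, [trial])
    return evaluator.log_likelihood(evaluator.space.to_vector(weights))
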