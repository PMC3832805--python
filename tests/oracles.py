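"""Independent brute-force references used by several test modules.

These deliberately re-derive every quantity from first principles
(plain Python loops over explicit enumerations) and share no code with
the package internals they check.
"""

import itertools
import math


def sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def brute_force_trial_log_likelihood(weights, spec, trial) -> float:
    """Enumerate every root configuration (latents, plus the action node
    when unobserved) and sum the exact joint probabilities."""
    w = weights.edge_weights
    b = weights.biases
    action = spec.action_node
    roots = list(spec.latent_nodes)
    if action is not None and action not in trial.states:
        roots.append(action)
    total = 0.0
    for values in itertools.product((0, 1), repeat=len(roots)):
        assign = dict(zip(roots, values))
        if action is not None and action in trial.states:
            assign[action] = trial.states[action]
        p = 1.0
        for root in list(spec.latent_nodes) + ([action] if action else []):
            prior = sigmoid(b[root])
            p *= prior if assign[root] == 1 else 1.0 - prior
        for child in spec.observable_nodes:
            if child not in trial.states:
                continue
            eta = b[child] + sum(
                w[(parent, child)] * assign[parent] for parent in spec.parents_of(child)
            )
            pc = sigmoid(eta)
            p *= pc if trial.states[child] == 1 else 1.0 - pc
        total += p
    return math.log(total) * trial.multiplicity


def brute_force_latent_posterior(weights, spec, evidence, action_state=0):
    """Exact Bayes over every latent configuration, as plain loops."""
    w = weights.edge_weights
    b = weights.biases
    latents = list(spec.latent_nodes)
    unnorm = []
    for values in itertools.product((0, 1), repeat=len(latents)):
        assign = dict(zip(latents, values))
        if spec.action_node is not None:
            assign[spec.action_node] = action_state
        p = 1.0
        for h in latents:
            prior = sigmoid(b[h])
            p *= prior if assign[h] == 1 else 1.0 - prior
        for child, value in evidence.states.items():
            if child == spec.action_node:
                continue
            eta = b[child] + sum(
                w[(parent, child)] * assign.get(parent, 0) for parent in spec.parents_of(child)
            )
            pc = sigmoid(eta)
            p *= pc if value == 1 else 1.0 - pc
        unnorm.append(p)
    z = sum(unnorm)
    return [p / z for p in unnorm]


def brute_force_food_prediction(draws_config_list, spec, evidence, action_state, food):
    """Double sum over draws and latent configurations."""
    acc = 0.0
    for weights in draws_config_list:
        post = brute_force_latent_posterior(weights, spec, evidence, action_state)
        w = weights.edge_weights
        b = weights.biases
        for p_cfg, values in zip(
            post, itertools.product((0, 1), repeat=len(spec.latent_nodes))
        ):
            assign = dict(zip(spec.latent_nodes, values))
            if spec.action_node is not None:
                assign[spec.action_node] = action_state
            eta = b[food] + sum(
                w[(parent, food)] * assign[parent] for parent in spec.parents_of(food)
            )
            acc += p_cfg * sigmoid(eta)
    return acc / len(draws_config_list)
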