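"""Synthetic conditioning trials for the three-phase PIT paradigm.

Time is discretized into trial bins.  The Pavlovian phase pairs each
sound with its food; the instrumental phase presents one lever at a
time and rewards pressing under a random-ratio schedule (RR-k modeled
as per-press reward probability 1/k, so RR20 -> 0.05); blank
inter-trial bins with nothing present anchor the background rates.
Test-phase evidence patterns present a lever with or without a sound,
with foods and action left unobserved, and are never added to the
training set (the test runs in extinction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Trial
from .network import NetworkSpec, default_network_spec

__all__ = [
    "ParadigmConfig",
    "TestCondition",
    "generate_pavlovian_phase",
    "generate_instrumental_phase",
    "generate_paradigm",
    "test_evidence",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials_csv",
    "read_trials_csv",
]

TEST_LABELS = ("baseline", "same", "different", "general")


@dataclass(frozen=True)
class ParadigmConfig:
    """Trial counts and contingency probabilities of the paradigm.

    Defaults emulate extended training: intermittent food delivery
    during each CS (pavlovian_pairing_prob, the per-bin chance that
    the food arrives while the sound plays), continuous engagement
    with the lever whenever it is available (press_prob), and an RR20
    reward schedule (reinforce_prob 0.05).  cross_food_leak is the
    probability that the *other* instrumental food turns up in a lever
    session bin; at 0 the two instrumental contexts exclude each
    other, which is what makes PIT inhibition learnable.
    """

    n_pavlovian_per_cs: int = 200
    pavlovian_pairing_prob: float = 0.45
    n_instrumental_per_lever: int = 1600
    press_prob: float = 0.9
    reinforce_prob: float = 0.05
    n_blank: int = 400
    cross_food_leak: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pavlovian_pairing_prob", "press_prob", "reinforce_prob", "cross_food_leak"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("n_pavlovian_per_cs", "n_instrumental_per_lever", "n_blank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TestCondition:
    """A test-phase condition: which lever is available, which sound plays.

    For lever L1 the canonical mapping is same -> S1 (CS of the lever's
    own food), different -> S2 (CS of the other lever's food),
    general -> S3 (CS of the food never used instrumentally).
    """

    __test__ = False  # keep pytest from collecting the imported class

    label: str
    lever: str
    sound: str | None

    def __post_init__(self) -> None:
        if self.label not in TEST_LABELS:
            raise ValueError(f"unknown test condition label {self.label!r}")
        if self.label == "baseline" and self.sound is not None:
            raise ValueError("baseline condition has no sound")
        if self.label != "baseline" and self.sound is None:
            raise ValueError(f"{self.label} condition requires a sound")

    @classmethod
    def for_lever(cls, label: str, lever: str = "L1", spec: NetworkSpec | None = None) -> "TestCondition":
        spec = spec or default_network_spec()
        if lever not in spec.lever_nodes:
            raise ValueError(f"unknown lever {lever!r}")
        j = spec.lever_nodes.index(lever)
        other = 1 - j
        mapping = {
            "baseline": None,
            "same": spec.stimulus_nodes[j],
            "different": spec.stimulus_nodes[other],
            "general": spec.stimulus_nodes[2],
        }
        if label not in mapping:
            raise ValueError(f"unknown test condition label {label!r}")
        return cls(label=label, lever=lever, sound=mapping[label])


def _blank_trials(spec: NetworkSpec, n: int) -> list[Trial]:
    states = {node: 0 for node in spec.visible_nodes}
    return [Trial(states=dict(states), phase="blank") for _ in range(n)]


def generate_pavlovian_phase(config: ParadigmConfig, spec: NetworkSpec | None = None) -> list[Trial]:
    """Sound->food pairings: for each CS i, bins with S_i present and
    F_i delivered with the pairing probability; everything else absent.
    Includes the phase's blank bins.  Deterministic given the seed.
    """
    spec = spec or default_network_spec()
    rng = np.random.default_rng([config.seed, 1])
    trials: list[Trial] = []
    for i, sound in enumerate(spec.stimulus_nodes):
        food = spec.food_nodes[i]
        delivered = rng.random(config.n_pavlovian_per_cs) < config.pavlovian_pairing_prob
        for got_food in delivered:
            states = {node: 0 for node in spec.visible_nodes}
            states[sound] = 1
            states[food] = int(got_food)
            trials.append(Trial(states=states, phase="pavlovian"))
    trials.extend(_blank_trials(spec, config.n_blank))
    return trials


def generate_instrumental_phase(config: ParadigmConfig, spec: NetworkSpec | None = None) -> list[Trial]:
    """Lever-press training: one lever present per bin, pressing with
    press_prob, its food delivered per press with reinforce_prob (the
    random-ratio schedule), and the other instrumental food leaking in
    with cross_food_leak.  F3 never appears.  Includes blank bins.
    """
    spec = spec or default_network_spec()
    rng = np.random.default_rng([config.seed, 2])
    trials: list[Trial] = []
    for j, lever in enumerate(spec.lever_nodes):
        own_food = spec.food_nodes[j]
        other_food = spec.food_nodes[1 - j]
        n = config.n_instrumental_per_lever
        pressed = rng.random(n) < config.press_prob
        rewarded = pressed & (rng.random(n) < config.reinforce_prob)
        leaked = rng.random(n) < config.cross_food_leak
        for k in range(n):
            states = {node: 0 for node in spec.visible_nodes}
            states[lever] = 1
            if spec.action_node:
                states[spec.action_node] = int(pressed[k])
            states[own_food] = int(rewarded[k])
            states[other_food] = int(leaked[k])
            trials.append(Trial(states=states, phase="instrumental"))
    trials.extend(_blank_trials(spec, config.n_blank))
    return trials


def generate_paradigm(config: ParadigmConfig, spec: NetworkSpec | None = None) -> list[Trial]:
    """Full training set: Pavlovian phase then instrumental phase."""
    spec = spec or default_network_spec()
    return generate_pavlovian_phase(config, spec) + generate_instrumental_phase(config, spec)


def test_evidence(condition: TestCondition, spec: NetworkSpec | None = None) -> Trial:
    """Evidence pattern for a test bin: the shown lever present, other
    levers absent, the condition's sound present (others absent), all
    foods and the action unobserved.  Test trials are never used for
    learning.
    """
    spec = spec or default_network_spec()
    if condition.lever not in spec.lever_nodes:
        raise ValueError(f"unknown lever {condition.lever!r}")
    if condition.sound is not None and condition.sound not in spec.stimulus_nodes:
        raise ValueError(f"unknown sound {condition.sound!r}")
    states: dict[str, int] = {}
    for lever in spec.lever_nodes:
        states[lever] = int(lever == condition.lever)
    for sound in spec.stimulus_nodes:
        states[sound] = int(sound == condition.sound)
    return Trial(states=states, phase="test")


# -- CSV interchange -----------------------------------------------------


def trials_to_frame(trials, spec: NetworkSpec | None = None) -> pd.DataFrame:
    """One row per trial record: phase, multiplicity, then one column
    per visible node with values 0/1/NA (NA = unobserved)."""
    spec = spec or default_network_spec()
    rows = []
    for t in trials:
        row: dict = {"phase": t.phase, "multiplicity": t.multiplicity}
        for node in spec.visible_nodes:
            row[node] = t.states.get(node, pd.NA)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["phase", "multiplicity", *spec.visible_nodes])
    for node in spec.visible_nodes:
        frame[node] = frame[node].astype("Int64")
    return frame


def frame_to_trials(frame: pd.DataFrame, spec: NetworkSpec | None = None) -> list[Trial]:
    spec = spec or default_network_spec()
    trials = []
    for _, row in frame.iterrows():
        states = {
            node: int(row[node])
            for node in spec.visible_nodes
            if node in frame.columns and pd.notna(row[node])
        }
        trials.append(Trial(states=states, phase=str(row["phase"]), multiplicity=int(row["multiplicity"])))
    return trials


def write_trials_csv(path, trials, spec: NetworkSpec | None = None) -> None:
    trials_to_frame(trials, spec).to_csv(path, index=False)


def read_trials_csv(path, spec: NetworkSpec | None = None) -> list[Trial]:
    frame = pd.read_csv(path, dtype={"phase": str})
    return frame_to_trials(frame, spec)
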