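"""Network structure for the latent-cause belief network.

The model is a two-layer sigmoid belief network: binary latent causes
(contexts) sit above binary observables (sounds, levers, foods), and a
single exogenous action node feeds the foods it can produce.  The
structure is fixed; only weights and biases are learned.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
import yaml

Edge = tuple[str, str]


@dataclass(frozen=True)
class NetworkSpec:
    """Node roles and fixed parent→child adjacency.

    Edges may run only latent→{stimulus, lever, food} or action→food;
    nothing feeds into latent or action nodes, so the graph is a
    bipartite DAG and the latent posterior is computable by enumeration.
    """

    latent_nodes: tuple[str, ...] = ("H1", "H2", "H3", "H4", "H5")
    stimulus_nodes: tuple[str, ...] = ("S1", "S2", "S3")
    lever_nodes: tuple[str, ...] = ("L1", "L2")
    food_nodes: tuple[str, ...] = ("F1", "F2", "F3")
    action_node: str | None = "A"
    edges: frozenset[Edge] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        names = (
            list(self.latent_nodes)
            + list(self.stimulus_nodes)
            + list(self.lever_nodes)
            + list(self.food_nodes)
            + ([self.action_node] if self.action_node else [])
        )
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique across roles")
        observables = set(self.stimulus_nodes) | set(self.lever_nodes) | set(self.food_nodes)
        for parent, child in self.edges:
            if parent in self.latent_nodes:
                if child not in observables:
                    raise ValueError(f"latent edge {parent}->{child} must point at an observable")
            elif self.action_node is not None and parent == self.action_node:
                if child not in self.food_nodes:
                    raise ValueError(f"action edge {parent}->{child} must point at a food")
            else:
                raise ValueError(f"edge {parent}->{child}: parent must be a latent or the action node")

    # -- derived views ---------------------------------------------------

    @property
    def observable_nodes(self) -> tuple[str, ...]:
        """Stimuli, levers and foods, in canonical order (no action node)."""
        return self.stimulus_nodes + self.lever_nodes + self.food_nodes

    @property
    def visible_nodes(self) -> tuple[str, ...]:
        """Every node that can appear in a trial record."""
        extra = (self.action_node,) if self.action_node else ()
        return self.observable_nodes + extra

    @property
    def all_nodes(self) -> tuple[str, ...]:
        return self.latent_nodes + self.visible_nodes

    def parents_of(self, child: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, c in self.edges if c == child))

    def children_of(self, parent: str) -> tuple[str, ...]:
        return tuple(sorted(c for p, c in self.edges if p == parent))

    def sorted_edges(self) -> tuple[Edge, ...]:
        return tuple(sorted(self.edges))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "latent_nodes": list(self.latent_nodes),
            "stimulus_nodes": list(self.stimulus_nodes),
            "lever_nodes": list(self.lever_nodes),
            "food_nodes": list(self.food_nodes),
            "action_node": self.action_node,
            "edges": [list(e) for e in self.sorted_edges()],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkSpec":
        return cls(
            latent_nodes=tuple(data["latent_nodes"]),
            stimulus_nodes=tuple(data["stimulus_nodes"]),
            lever_nodes=tuple(data["lever_nodes"]),
            food_nodes=tuple(data["food_nodes"]),
            action_node=data.get("action_node"),
            edges=frozenset(tuple(e) for e in data["edges"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        return cls.from_dict(yaml.safe_load(text))

    def edges_to_csv(self) -> str:
        """Edge list as two-column CSV (parent, child)."""
        frame = pd.DataFrame(self.sorted_edges(), columns=["parent", "child"])
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        return buf.getvalue()


def default_network_spec() -> NetworkSpec:
    """The PIT network: three Pavlovian contexts H1–H3, each generating
    its sound and food; two instrumental contexts H4/H5 generating a
    lever and gating both instrumental foods; pressing (A) linked only
    to the foods it can produce, F1 and F2 — never to F3, sounds or
    levers.
    """
    edges: set[Edge] = set()
    for i in (1, 2, 3):
        edges.add((f"H{i}", f"S{i}"))
        edges.add((f"H{i}", f"F{i}"))
    edges.update({("H4", "L1"), ("H4", "F1"), ("H4", "F2")})
    edges.update({("H5", "L2"), ("H5", "F1"), ("H5", "F2")})
    edges.update({("A", "F1"), ("A", "F2")})
    return NetworkSpec(edges=frozenset(edges))
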