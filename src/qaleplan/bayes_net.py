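"""Discrete Bayesian networks with exact inference.

The outcome models in this package are small discrete networks (well under a
dozen nodes), so exact inference by variable elimination is both fast and
auditable.  CPT rows follow a fixed convention: parents vary in their declared
order with the *last* parent cycling fastest, and the same convention is used
in the JSON serialization so files are unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np

__all__ = [
    "NodeSpec",
    "Network",
    "InconsistentEvidenceError",
    "validate",
    "joint",
    "query",
    "or_node",
    "network_to_json",
    "network_from_json",
]

_ROW_TOL = 1e-9


class InconsistentEvidenceError(ValueError):
    """Evidence assignment has probability zero under the model."""


@dataclass(frozen=True)
class NodeSpec:
    """One discrete node: states, parents, and its conditional table.

    ``cpt`` has shape (n_parent_combinations, n_states); rows are indexed by
    the parent-state combination with the last parent fastest.
    """

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()
    cpt: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(self, "cpt", np.asarray(self.cpt, dtype=float))

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"{state!r} is not a state of node {self.name!r}") from None


@dataclass
class Network:
    """A set of nodes; edges are implied by each node's parent list."""

    nodes: dict[str, NodeSpec] = field(default_factory=dict)

    def add(self, node: NodeSpec) -> None:
        self.nodes[node.name] = node

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for node in self.nodes.values():
            for p in node.parents:
                g.add_edge(p, node.name)
        return g


def cpt_row_index(network: Network, node: NodeSpec,
                  parent_states: dict[str, str]) -> int:
    """Row index for a parent assignment (last parent fastest)."""
    idx = 0
    for p in node.parents:
        pnode = network.nodes[p]
        idx = idx * len(pnode.states) + pnode.state_index(parent_states[p])
    return idx


def validate(network: Network) -> list[str]:
    """Structural checks; returns a list of human-readable errors (empty = ok)."""
    errors: list[str] = []
    for node in network.nodes.values():
        if len(node.states) < 2:
            errors.append(f"node {node.name}: needs at least 2 states")
        missing = [p for p in node.parents if p not in network.nodes]
        for p in missing:
            errors.append(f"node {node.name}: dangling parent {p!r}")
        if missing:
            continue
        n_rows = int(np.prod([len(network.nodes[p].states) for p in node.parents])) \
            if node.parents else 1
        if node.cpt.shape != (n_rows, len(node.states)):
            errors.append(
                f"node {node.name}: CPT shape {node.cpt.shape} != ({n_rows}, {len(node.states)})")
            continue
        sums = node.cpt.sum(axis=1)
        for r in np.nonzero(np.abs(sums - 1.0) > _ROW_TOL)[0]:
            errors.append(f"node {node.name}: CPT row {r} sums to {sums[r]:.6g}, not 1")
        if np.any(node.cpt < -_ROW_TOL):
            errors.append(f"node {node.name}: CPT has negative entries")
    g = Network(nodes=dict(network.nodes)).graph()
    try:
        cycle = nx.find_cycle(g)
        errors.append("cycle detected: " + " -> ".join(e[0] for e in cycle))
    except nx.NetworkXNoCycle:
        pass
    return errors


def _require_valid(network: Network) -> None:
    errors = validate(network)
    if errors:
        raise ValueError("invalid network: " + "; ".join(errors))


def joint(network: Network, assignment: dict[str, str]) -> float:
    """Probability of a full assignment: product of node conditionals."""
    missing = set(network.nodes) - set(assignment)
    if missing:
        raise KeyError(f"assignment missing nodes: {sorted(missing)}")
    p = 1.0
    for node in network.nodes.values():
        row = cpt_row_index(network, node, assignment)
        p *= node.cpt[row, node.state_index(assignment[node.name])]
    return float(p)


# --- variable elimination ----------------------------------------------------

@dataclass
class _Factor:
    vars: tuple[str, ...]
    card: tuple[int, ...]
    table: np.ndarray  # shape == card

    def marginalize(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            vars=self.vars[:axis] + self.vars[axis + 1:],
            card=self.card[:axis] + self.card[axis + 1:],
            table=self.table.sum(axis=axis),
        )


def _broadcast(f: _Factor, all_vars: list[str]) -> np.ndarray:
    """Reshape a factor table so its axes align with ``all_vars`` (size-1 elsewhere)."""
    missing = [v for v in all_vars if v not in f.vars]
    t = f.table.reshape(f.table.shape + (1,) * len(missing))
    cur = list(f.vars) + missing
    return t.transpose([cur.index(v) for v in all_vars])


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    all_vars = list(a.vars) + [v for v in b.vars if v not in a.vars]
    card = {**dict(zip(a.vars, a.card)), **dict(zip(b.vars, b.card))}
    table = _broadcast(a, all_vars) * _broadcast(b, all_vars)
    return _Factor(vars=tuple(all_vars),
                   card=tuple(card[v] for v in all_vars), table=table)


def _node_factor(network: Network, node: NodeSpec,
                 evidence: dict[str, str]) -> _Factor:
    parent_cards = [len(network.nodes[p].states) for p in node.parents]
    shape = tuple(parent_cards) + (len(node.states),)
    table = node.cpt.reshape(shape)
    vars_ = node.parents + (node.name,)
    # slice out evidence
    keep_vars, keep_card = [], []
    index: list = []
    for v, c in zip(vars_, table.shape):
        if v in evidence:
            index.append(network.nodes[v].state_index(evidence[v]))
        else:
            index.append(slice(None))
            keep_vars.append(v)
            keep_card.append(c)
    return _Factor(vars=tuple(keep_vars), card=tuple(keep_card),
                   table=np.asarray(table[tuple(index)], dtype=float))


def query(network: Network, target: str,
          evidence: dict[str, str] | None = None) -> dict[str, float]:
    """Exact posterior P(target | evidence) by variable elimination.

    Elimination order is the min-degree heuristic on the moralized interaction
    graph.  Inconsistent evidence (zero probability) raises
    :class:`InconsistentEvidenceError`.
    """
    evidence = dict(evidence or {})
    if target not in network.nodes:
        raise KeyError(f"unknown target node {target!r}")
    for v, s in evidence.items():
        network.nodes[v].state_index(s)  # validates
    _require_valid(network)

    tnode = network.nodes[target]
    if target in evidence:
        dist = {s: 0.0 for s in tnode.states}
        dist[evidence[target]] = 1.0
        return dist

    factors = [_node_factor(network, n, evidence) for n in network.nodes.values()]
    to_eliminate = set(network.nodes) - set(evidence) - {target}

    while to_eliminate:
        # min-degree: variable appearing with the fewest distinct neighbours
        def degree(v: str) -> int:
            nbrs: set[str] = set()
            for f in factors:
                if v in f.vars:
                    nbrs.update(f.vars)
            nbrs.discard(v)
            return len(nbrs)

        var = min(sorted(to_eliminate), key=degree)
        to_eliminate.discard(var)
        related = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        if not related:
            continue
        prod = related[0]
        for f in related[1:]:
            prod = _multiply(prod, f)
        factors.append(prod.marginalize(var))

    result = _Factor(vars=(), card=(), table=np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    if result.vars != (target,):
        # scalar factors may precede/follow; ensure target axis present
        if target not in result.vars:
            raise RuntimeError("target eliminated unexpectedly")
        axis = result.vars.index(target)
        table = np.moveaxis(result.table, axis, 0).reshape(len(tnode.states), -1).sum(axis=1)
    else:
        table = result.table
    total = float(table.sum())
    if total <= 0.0:
        raise InconsistentEvidenceError(
            f"evidence {evidence} has probability zero")
    return {s: float(p) for s, p in zip(tnode.states, table / total)}


def or_node(name: str, parents: list[str], network: Network,
            positive: str = "yes", negative: str = "no") -> NodeSpec:
    """Deterministic OR: positive iff any parent is in its positive state.

    All parents must be binary with states (positive, negative) resolvable.
    """
    for p in parents:
        pnode = network.nodes[p]
        if len(pnode.states) != 2:
            raise ValueError(f"or_node parent {p!r} is not binary")
    parent_states = [network.nodes[p].states for p in parents]
    rows = []
    for combo in product(*parent_states):
        any_pos = any(s == positive for s in combo)
        rows.append([1.0, 0.0] if any_pos else [0.0, 1.0])
    return NodeSpec(name=name, states=(positive, negative),
                    parents=tuple(parents), cpt=np.array(rows))


# --- JSON round trip ---------------------------------------------------------

def network_to_json(network: Network) -> str:
    payload = {
        "nodes": [
            {
                "name": n.name,
                "states": list(n.states),
                "parents": list(n.parents),
                "cpt": n.cpt.reshape(-1).tolist(),
                "row_convention": "last_parent_fastest",
            }
            for n in network.nodes.values()
        ]
    }
    return json.dumps(payload, indent=2)


def network_from_json(text: str) -> Network:
    payload = json.loads(text)
    net = Network()
    for item in payload["nodes"]:
        n_states = len(item["states"])
        cpt = np.asarray(item["cpt"], dtype=float).reshape(-1, n_states)
        net.add(NodeSpec(name=item["name"], states=tuple(item["states"]),
                         parents=tuple(item["parents"]), cpt=cpt))
    return net
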