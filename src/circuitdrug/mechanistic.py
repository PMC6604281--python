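"""Signal-propagation model of signaling-circuit activity.

Gene expression on the unit interval is taken as a proxy for protein
presence.  Node values summarize gene memberships (complexes need all
subunits, so take the minimum; families need any member, so take the mean).
Signal then propagates from receptor nodes to the effector of each circuit
with the multiplicative recurrence

    S_n = v_n * (1 - prod_{a in A(n)} (1 - S_a)) * prod_{i in I(n)} (1 - S_i)

where v_n is the node's own value, A(n)/I(n) its activating/inhibiting
inputs, and receptor nodes start at S = v.  Activation saturates (any strong
activator suffices), inhibition annihilates (a saturated inhibitor silences
the node), and the signal stays inside [0, 1].  Each effector's signal is the
activity of its circuit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .knowledge_base import PathwayGraph
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

COMPLEX_RULES = ("min", "mean")


class PropagationError(RuntimeError):
    """Fixed-point iteration failed to converge on a cyclic circuit."""


@dataclass
class NodeValueMatrix:
    """Nodes x samples values in [0, 1], plus a record of imputed genes."""

    values: pd.DataFrame
    missing_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("node values must lie in [0, 1]")


@dataclass(frozen=True)
class Circuit:
    """The receptor-to-effector subgraph named after its effector node."""

    circuit_id: str
    effector: str
    receptors: frozenset[str]
    node_ids: frozenset[str]


@dataclass
class CircuitActivityMatrix:
    """Circuits x samples activities in [0, 1]."""

    activities: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.activities.to_numpy()
        if ((arr < -1e-12) | (arr > 1 + 1e-12)).any():
            raise ValueError("circuit activities must lie in [0, 1]")

    @property
    def circuit_ids(self) -> list[str]:
        return list(self.activities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.activities.columns)


def summarize_nodes(
    expr: ExpressionMatrix,
    graph: PathwayGraph,
    complex_rule: str = "min",
) -> NodeValueMatrix:
    """Collapse gene values to node values.

    Simple nodes copy their gene's value; family nodes average members;
    complex nodes take the member minimum (all subunits required) unless
    ``complex_rule='mean'``.  A gene absent from ``expr`` is dropped from its
    node; a node with *no* measured gene is imputed with the per-sample
    median of the computed node values and reported in ``missing_genes``.
    """
    if expr.scale != "unit":
        raise ValueError("summarize_nodes expects unit-scale expression")
    if complex_rule not in COMPLEX_RULES:
        raise ValueError(f"unknown complex rule {complex_rule!r}")
    available = set(expr.gene_ids)
    rows: dict[str, np.ndarray | None] = {}
    missing: dict[str, list[str]] = {}
    for node in graph.nodes.values():
        present = [g for g in node.genes if g in available]
        absent = [g for g in node.genes if g not in available]
        if absent:
            missing[node.node_id] = absent
        if not present:
            rows[node.node_id] = None  # imputed below
            continue
        sub = expr.values.loc[present].to_numpy(dtype=float)
        if node.node_class == "simple":
            rows[node.node_id] = sub[0]
        elif node.node_class == "family":
            rows[node.node_id] = sub.mean(axis=0)
        else:  # complex
            rows[node.node_id] = sub.min(axis=0) if complex_rule == "min" else sub.mean(axis=0)
    observed = np.array([v for v in rows.values() if v is not None])
    if observed.size == 0:
        raise ValueError("no graph gene is present in the expression matrix")
    medians = np.median(observed, axis=0)
    for node_id, v in rows.items():
        if v is None:
            logger.warning(
                "node %s: all member genes missing; imputed per-sample median",
                node_id,
            )
            rows[node_id] = medians
    df = pd.DataFrame(
        {nid: rows[nid] for nid in graph.nodes}, index=expr.sample_ids
    ).T
    df.columns = expr.sample_ids
    return NodeValueMatrix(values=df, missing_genes=missing)


def extract_circuits(graph: PathwayGraph) -> list[Circuit]:
    """One circuit per effector: all nodes lying on a receptor->effector path.

    A node belongs to the circuit iff it is reachable from some receptor and
    the effector is reachable from it.
    """
    g = graph.to_networkx()
    circuits = []
    for effector in sorted(graph.effectors):
        upstream = nx.ancestors(g, effector) | {effector}
        reachable_from_receptors = set()
        for r in sorted(graph.receptors):
            if r == effector or nx.has_path(g, r, effector):
                reachable_from_receptors |= nx.descendants(g, r) | {r}
        members = upstream & (reachable_from_receptors | {effector})
        receptors = frozenset(r for r in graph.receptors if r in members)
        if not receptors and effector not in graph.receptors:
            raise ValueError(f"effector {effector!r} unreachable from every receptor")
        circuits.append(
            Circuit(
                circuit_id=effector,
                effector=effector,
                receptors=receptors,
                node_ids=frozenset(members),
            )
        )
    return circuits


def _node_inputs(g: nx.DiGraph, circuit: Circuit) -> dict[str, tuple[list[str], list[str]]]:
    """activating / inhibiting predecessors of each circuit node, inside the circuit."""
    inputs = {}
    for n in circuit.node_ids:
        acts, inhs = [], []
        for pred in g.predecessors(n):
            if pred not in circuit.node_ids:
                continue
            (acts if g.edges[pred, n]["sign"] == "activation" else inhs).append(pred)
        inputs[n] = (sorted(acts), sorted(inhs))
    return inputs


def propagate(
    circuit: Circuit,
    node_values: pd.Series | dict[str, float],
    graph: PathwayGraph,
    tol: float = 1e-6,
    max_sweeps: int = 100,
    method: str = "auto",
) -> float:
    """Effector signal of one circuit for one sample's node values.

    Acyclic circuits are evaluated once in topological order; cyclic ones are
    iterated from S = v until the largest update falls below ``tol``.
    ``method`` forces ``'topological'`` (acyclic only) or ``'iterative'``
    evaluation; ``'auto'`` picks by cyclicity.
    """
    g = graph.to_networkx()
    v = {n: float(node_values[n]) for n in circuit.node_ids}
    for n, val in v.items():
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"node value out of [0,1] at {n!r}: {val}")
    inputs = _node_inputs(g, circuit)
    sub = g.subgraph(circuit.node_ids)

    def update(n: str, s: dict[str, float]) -> float:
        acts, inhs = inputs[n]
        if not acts and not inhs:  # receptor (no inputs inside the circuit)
            return v[n]
        signal = v[n]
        if acts:
            act_term = 1.0
            for a in acts:
                act_term *= 1.0 - s[a]
            signal *= 1.0 - act_term
        for i in inhs:
            signal *= 1.0 - s[i]
        return signal

    acyclic = nx.is_directed_acyclic_graph(sub)
    if method not in ("auto", "topological", "iterative"):
        raise ValueError(f"unknown method {method!r}")
    if method == "topological" and not acyclic:
        raise ValueError("topological evaluation requires an acyclic circuit")
    if acyclic and method != "iterative":
        s: dict[str, float] = {}
        for n in nx.topological_sort(sub):
            s[n] = update(n, s)
        return s[circuit.effector]
    s = dict(v)
    order = sorted(circuit.node_ids)
    for _ in range(max_sweeps):
        delta = 0.0
        for n in order:
            new = update(n, s)
            delta = max(delta, abs(new - s[n]))
            s[n] = new
        if delta < tol:
            return s[circuit.effector]
    cycle = [n for c in nx.simple_cycles(sub) for n in c]
    raise PropagationError(
        f"no fixed point after {max_sweeps} sweeps; cycle nodes: {sorted(set(cycle))}"
    )


def circuit_activities(
    expr: ExpressionMatrix,
    graph: PathwayGraph,
    complex_rule: str = "min",
) -> CircuitActivityMatrix:
    """Full model: summarize nodes, then propagate every circuit x sample."""
    node_values = summarize_nodes(expr, graph, complex_rule=complex_rule)
    circuits = extract_circuits(graph)
    out = np.empty((len(circuits), len(expr.sample_ids)))
    for j, sample in enumerate(expr.sample_ids):
        column = node_values.values[sample]
        for i, circuit in enumerate(circuits):
            out[i, j] = propagate(circuit, column, graph)
    df = pd.DataFrame(
        np.clip(out, 0.0, 1.0),
        index=[c.circuit_id for c in circuits],
        columns=expr.sample_ids,
    )
    return CircuitActivityMatrix(activities=df)


def write_activities_tsv(cam: CircuitActivityMatrix, path) -> None:
    cam.activities.to_csv(path, sep="\t")


def circuits_to_json_dict(circuits: list[Circuit]) -> list[dict]:
    return [
        {
            "circuit_id": c.circuit_id,
            "effector": c.effector,
            "receptors": sorted(c.receptors),
            "nodes": sorted(c.node_ids),
        }
        for c in circuits
    ]
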