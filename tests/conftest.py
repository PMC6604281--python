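"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from circuitdrug.knowledge_base import PathwayEdge, PathwayGraph, PathwayNode


@pytest.fixture(scope="session")
def fa_graph():
    from circuitdrug.knowledge_base import load_pathway

    return load_pathway()


def make_graph(edges, node_genes=None, signs=None):
    """Build a simple-node pathway from an edge list like [('A','B'), ...].

    ``signs`` maps (source, target) -> 'activation'/'inhibition' (activation
    by default); ``node_genes`` maps node -> gene tuple for multi-gene nodes.
    """
    node_genes = node_genes or {}
    signs = signs or {}
    node_ids = sorted({n for e in edges for n in e})
    nodes = {}
    for nid in node_ids:
        genes = tuple(node_genes.get(nid, (nid,)))
        cls = "simple" if len(genes) == 1 else "complex"
        nodes[nid] = PathwayNode(node_id=nid, genes=genes, node_class=cls)
    edge_objs = [
        PathwayEdge(
            source=s,
            target=t,
            sign=signs.get((s, t), "activation"),
            provenance="curated",
        )
        for s, t in edges
    ]
    return PathwayGraph(nodes=nodes, edges=edge_objs)


def oracle_effector_signal(edges, signs, values, effector):
    """Independent recursive evaluation of the propagation recurrence on a DAG.

    Written as plain memoized recursion over predecessors — deliberately a
    different code path from the package's topological-sweep implementation.
    """
    preds: dict[str, list[tuple[str, str]]] = {}
    nodes = {n for e in edges for n in e} | {effector}
    for n in nodes:
        preds[n] = []
    for s, t in edges:
        preds[t].append((s, signs.get((s, t), "activation")))
    memo: dict[str, float] = {}

    def signal(n: str) -> float:
        if n in memo:
            return memo[n]
        acts = [p for p, sign in preds[n] if sign == "activation"]
        inhs = [p for p, sign in preds[n] if sign == "inhibition"]
        if not acts and not inhs:
            out = values[n]
        else:
            out = values[n]
            if acts:
                miss = 1.0
                for a in acts:
                    miss *= 1.0 - signal(a)
                out *= 1.0 - miss
            for i in inhs:
                out *= 1.0 - signal(i)
        memo[n] = out
        return out

    return signal(effector)


def random_toy_dag(rng: np.random.Generator, max_nodes: int = 6):
    """A random acyclic signed single-receptor-compatible toy graph.

    Nodes are labelled in topological order; each non-first node gets >= 1
    incoming edge from earlier nodes with a random sign.  The last node is
    the (unique) effector only if nothing leaves it, which holds by
    construction.
    """
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"N{i}" for i in range(n)]
    edges, signs = [], {}
    for j in range(1, n):
        n_in = int(rng.integers(1, j + 1))
        sources = rng.choice(j, size=n_in, replace=False)
        for i in sources:
            if j < n - 1 and rng.random() < 0.3:
                continue  # leave some sparse structure
            edges.append((names[i], names[j]))
            signs[(names[i], names[j])] = (
                "inhibition" if rng.random() < 0.3 else "activation"
            )
    # guarantee connectivity of the effector
    if not any(t == names[-1] for _, t in edges):
        edges.append((names[0], names[-1]))
        signs[(names[0], names[-1])] = "activation"
    # drop dead-end intermediates (nodes with no outgoing edge other than the
    # effector would become extra effectors); wire them to the last node
    for j in range(1, n - 1):
        if not any(s == names[j] for s, _ in edges):
            edges.append((names[j], names[-1]))
            signs[(names[j], names[-1])] = "activation"
    edges = sorted(set(edges))
    values = {name: float(rng.uniform(0, 1)) for name in names}
    return edges, signs, values, names[-1]
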