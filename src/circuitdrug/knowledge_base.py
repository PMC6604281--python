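"""Curated pathway knowledge: the expanded Fanconi-anemia (FA) map and drug-target tables.

The FA signaling map is packaged as a pair of plain-text tables (nodes and
signed directed edges).  Nodes are either single genes, gene families, or
protein complexes (e.g. the four-subunit RPA complex); edges carry an
activation/inhibition sign and a provenance tag distinguishing the KEGG-derived
backbone (``kegg``) from manually curated literature additions (``curated``).
Terminal *effector* nodes name the signaling circuits whose activity the
mechanistic model estimates; source nodes with no incoming signal are
*receptors*.

Also housed here: the Orphanet FA gene list, the KEGG hsa03460 membership
list, the known-drug-target (KDT) table, and the packaged table of
high-relevance genes with their DrugBank annotations.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

NODE_CLASSES = ("simple", "family", "complex")
EDGE_SIGNS = ("activation", "inhibition")
EDGE_PROVENANCES = ("kegg", "curated")

#: Symbol aliases for tokens used in the packaged tables that are not current
#: HGNC symbols (the curation literature predates some renames).
SYMBOL_ALIASES = {
    "STRA13": "CENPX",
    "COX1": "MT-CO1",
    "FAAP24": "C19orf40",
    "FAAP100": "C17orf70",
}


class PathwayFormatError(ValueError):
    """A pathway table failed to parse (bad token, wrong columns...)."""


class PathwayStructureError(ValueError):
    """A parsed pathway violates a structural invariant."""


def canonical_symbol(symbol: str) -> str:
    """Case-insensitive canonical form of a gene symbol, via the alias map."""
    s = symbol.strip().upper()
    return SYMBOL_ALIASES.get(s, s)


@dataclass(frozen=True)
class GeneId:
    """A gene identified by HGNC-style symbol, optionally with an Entrez id."""

    symbol: str
    entrez: int | None = None

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise ValueError("gene symbol must be non-empty")
        if self.entrez is not None and self.entrez <= 0:
            raise ValueError(f"entrez id must be positive, got {self.entrez}")


@dataclass(frozen=True)
class PathwayNode:
    node_id: str
    genes: tuple[str, ...]
    node_class: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.node_class not in NODE_CLASSES:
            raise PathwayFormatError(
                f"node {self.node_id!r}: unknown class {self.node_class!r}"
            )
        if len(self.genes) == 0:
            raise PathwayStructureError(f"node {self.node_id!r} has no genes")
        if self.node_class == "simple" and len(self.genes) != 1:
            raise PathwayStructureError(
                f"simple node {self.node_id!r} must hold exactly one gene"
            )
        if self.node_class in ("family", "complex") and len(self.genes) < 2:
            raise PathwayStructureError(
                f"{self.node_class} node {self.node_id!r} needs >= 2 genes"
            )


@dataclass(frozen=True)
class PathwayEdge:
    source: str
    target: str
    sign: str
    provenance: str
    reference: str = ""
    self_loop: bool = False

    def __post_init__(self) -> None:
        if self.sign not in EDGE_SIGNS:
            raise PathwayFormatError(
                f"edge {self.source}->{self.target}: invalid sign {self.sign!r}"
            )
        if self.provenance not in EDGE_PROVENANCES:
            raise PathwayFormatError(
                f"edge {self.source}->{self.target}: invalid provenance "
                f"{self.provenance!r}"
            )
        if self.source == self.target and not self.self_loop:
            raise PathwayStructureError(
                f"self-loop {self.source}->{self.target} not flagged"
            )


@dataclass
class PathwayGraph:
    """A validated signed directed pathway with receptor/effector designations.

    Receptors are the nodes with no incoming edge; effectors the nodes with no
    outgoing edge.  Each effector names one signaling circuit.
    """

    nodes: dict[str, PathwayNode]
    edges: list[PathwayEdge]
    receptors: set[str] = field(default_factory=set)
    effectors: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise PathwayStructureError(
                        f"edge row {e.source}\t{e.target}\t{e.sign}: "
                        f"unknown node {endpoint!r}"
                    )
            key = (e.source, e.target, e.sign)
            if key in seen:
                raise PathwayStructureError(f"duplicate edge {key}")
            seen.add(key)
        g = self.to_networkx()
        if not self.receptors:
            self.receptors = {n for n in g.nodes if g.in_degree(n) == 0}
        if not self.effectors:
            self.effectors = {n for n in g.nodes if g.out_degree(n) == 0}
        for r in self.receptors:
            if g.in_degree(r) != 0:
                raise PathwayStructureError(f"receptor {r!r} has incoming edges")
        for eff in self.effectors:
            if g.out_degree(eff) != 0:
                raise PathwayStructureError(f"effector {eff!r} has outgoing edges")
            if not any(
                r == eff or nx.has_path(g, r, eff) for r in self.receptors
            ):
                raise PathwayStructureError(
                    f"effector {eff!r} unreachable from every receptor"
                )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node_id, node in self.nodes.items():
            g.add_node(node_id, node=node)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, provenance=e.provenance,
                       reference=e.reference)
        return g

    @property
    def gene_symbols(self) -> set[str]:
        return {g for n in self.nodes.values() for g in n.genes}

    def curated_edges(self) -> list[PathwayEdge]:
        return [e for e in self.edges if e.provenance == "curated"]


@dataclass(frozen=True)
class KDTRecord:
    """One known-drug-target gene with the drugs that target it."""

    gene: GeneId
    drug_ids: tuple[str, ...]
    approved_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not set(self.approved_ids) <= set(self.drug_ids):
            raise ValueError(
                f"{self.gene.symbol}: approved ids not a subset of drug ids"
            )


@dataclass(frozen=True)
class RelevanceFixtureRow:
    gene: GeneId
    relevance: float
    drug_ids: tuple[str, ...]
    approved_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.relevance < 0:
            raise ValueError("relevance must be >= 0")
        if not set(self.approved_ids) <= set(self.drug_ids):
            raise ValueError("approved ids must be a subset of drug ids")


# ---------------------------------------------------------------------------
# readers / writers

def _str_or_empty(value) -> str:
    return value if isinstance(value, str) else ""


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("circuitdrug") / "data" / name))


def load_pathway(
    node_path: str | Path | None = None,
    edge_path: str | Path | None = None,
) -> PathwayGraph:
    """Load a pathway from its node and edge TSV tables.

    With no arguments, loads the packaged curated expanded FA pathway.
    Node table columns: ``node_id  class  genes  label`` (genes ';'-separated);
    edge table columns: ``source  target  sign  provenance  reference``.
    """
    node_path = _data_path("fa_pathway_nodes.tsv") if node_path is None else Path(node_path)
    edge_path = _data_path("fa_pathway_edges.tsv") if edge_path is None else Path(edge_path)
    nodes_df = pd.read_csv(node_path, sep="\t", dtype=str, comment="#")
    edges_df = pd.read_csv(edge_path, sep="\t", dtype=str, comment="#")
    for col in ("node_id", "class", "genes"):
        if col not in nodes_df.columns:
            raise PathwayFormatError(f"node table missing column {col!r}")
    for col in ("source", "target", "sign", "provenance"):
        if col not in edges_df.columns:
            raise PathwayFormatError(f"edge table missing column {col!r}")
    nodes: dict[str, PathwayNode] = {}
    for row in nodes_df.to_dict("records"):
        node_id = row["node_id"]
        if node_id in nodes:
            raise PathwayStructureError(f"duplicate node id {node_id!r}")
        nodes[node_id] = PathwayNode(
            node_id=node_id,
            genes=tuple(g.strip() for g in row["genes"].split(";") if g.strip()),
            node_class=row["class"],
            label=_str_or_empty(row.get("label")),
        )
    edges = []
    for row in edges_df.to_dict("records"):
        src, tgt = row["source"], row["target"]
        if src not in nodes or tgt not in nodes:
            missing = src if src not in nodes else tgt
            raise PathwayStructureError(
                f"edge row '{src}\t{tgt}': unknown node {missing!r}"
            )
        edges.append(
            PathwayEdge(
                source=src,
                target=tgt,
                sign=row["sign"],
                provenance=row["provenance"],
                reference=_str_or_empty(row.get("reference")),
            )
        )
    return PathwayGraph(nodes=nodes, edges=edges)


def write_pathway(graph: PathwayGraph, node_path: str | Path,
                  edge_path: str | Path) -> None:
    """Write a pathway back to the TSV dialect read by :func:`load_pathway`."""
    nrows = [
        {
            "node_id": n.node_id,
            "class": n.node_class,
            "genes": ";".join(n.genes),
            "label": n.label,
        }
        for n in graph.nodes.values()
    ]
    erows = [
        {
            "source": e.source,
            "target": e.target,
            "sign": e.sign,
            "provenance": e.provenance,
            "reference": e.reference,
        }
        for e in graph.edges
    ]
    pd.DataFrame(nrows).to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(erows).to_csv(edge_path, sep="\t", index=False)


def load_gene_list(path: str | Path) -> set[GeneId]:
    """Read a one-symbol-per-line gene list ('#' comments allowed)."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return {GeneId(symbol=s) for s in symbols}


def load_orphanet_fa_genes() -> set[GeneId]:
    """The Orphanet (ORPHA:84) FA gene list, with Entrez ids (22 genes)."""
    df = pd.read_csv(_data_path("orphanet_fa_genes.tsv"), sep="\t")
    return {GeneId(symbol=r.symbol, entrez=int(r.entrez)) for r in df.itertuples()}


def load_kegg_fa_genes() -> set[GeneId]:
    """Gene membership of the KEGG FA pathway hsa03460 (54 genes)."""
    return load_gene_list(_data_path("kegg_hsa03460_genes.txt"))


def load_relevance_fixture(path: str | Path | None = None) -> list[RelevanceFixtureRow]:
    """The packaged high-relevance gene table with DrugBank annotations.

    Rows are sorted by descending relevance (an invariant that is checked).
    """
    path = _data_path("relevant_genes_drugs.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t")
    rows = []
    for r in df.itertuples(index=False):
        drugs = tuple(str(r.drug_ids).split(";")) if pd.notna(r.drug_ids) else ()
        approved = (
            tuple(str(r.approved_ids).split(";")) if pd.notna(r.approved_ids) else ()
        )
        rows.append(
            RelevanceFixtureRow(
                gene=GeneId(symbol=r.symbol, entrez=int(r.entrez)),
                relevance=float(r.relevance),
                drug_ids=drugs,
                approved_ids=approved,
            )
        )
    rel = [r.relevance for r in rows]
    if rel != sorted(rel, reverse=True):
        raise ValueError("relevance fixture rows must be sorted by descending relevance")
    return rows


def fixture_to_kdt_records(rows: Iterable[RelevanceFixtureRow]) -> list[KDTRecord]:
    return [
        KDTRecord(gene=r.gene, drug_ids=r.drug_ids, approved_ids=r.approved_ids)
        for r in rows
    ]


def load_kdt_table(path: str | Path) -> list[KDTRecord]:
    """Read a KDT TSV: ``symbol  entrez  drug_ids  approved_ids`` (';'-separated)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for r in df.itertuples(index=False):
        entrez = int(r.entrez) if "entrez" in df.columns and pd.notna(r.entrez) else None
        drugs = tuple(str(r.drug_ids).split(";")) if pd.notna(r.drug_ids) else ()
        approved = (
            tuple(str(r.approved_ids).split(";"))
            if "approved_ids" in df.columns and pd.notna(r.approved_ids)
            else ()
        )
        records.append(
            KDTRecord(GeneId(symbol=r.symbol, entrez=entrez), drugs, approved)
        )
    return records


def write_kdt_table(records: Sequence[KDTRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "symbol": [r.gene.symbol for r in records],
            "entrez": [r.gene.entrez for r in records],
            "drug_ids": [";".join(r.drug_ids) for r in records],
            "approved_ids": [";".join(r.approved_ids) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations

def gene_list_diff(list_a: Iterable[GeneId], list_b: Iterable[GeneId]) -> set[GeneId]:
    """Genes of ``list_a`` absent from ``list_b`` (symbol match, case-insensitive,
    through the alias map)."""
    b_symbols = {canonical_symbol(g.symbol) for g in list_b}
    return {g for g in list_a if canonical_symbol(g.symbol) not in b_symbols}


def count_drug_targets(table: Sequence[KDTRecord]) -> tuple[int, int, int]:
    """(distinct genes, distinct drugs, distinct approved drugs) of a KDT table."""
    symbols = [canonical_symbol(r.gene.symbol) for r in table]
    if len(symbols) != len(set(symbols)):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValueError(f"duplicate gene rows in KDT table: {dupes}")
    drugs = {d for r in table for d in r.drug_ids}
    approved = {d for r in table for d in r.approved_ids}
    return len(set(symbols)), len(drugs), len(approved)


def synthetic_kdt_table(
    n_genes: int = 965,
    n_drugs: int = 7122,
    approved_fraction: float = 0.35,
) -> list[KDTRecord]:
    """A deterministic *synthetic* stand-in for a genome-wide known-drug-target
    catalogue of the defaults' size (965 genes targeted by 7122 distinct drugs).

    The 17 packaged high-relevance genes keep their real DrugBank annotations;
    the remaining genes receive synthetic symbols (``KDT0018``...) and synthetic
    drug accessions (``SD00001``...) laid out deterministically so that the
    distinct-drug total is exact.  Useful wherever the pipeline needs a KDT
    table of realistic size without redistributing the licensed catalogue.
    """
    fixture = load_relevance_fixture()
    records = fixture_to_kdt_records(fixture)
    used_drugs = {d for r in records for d in r.drug_ids}
    n_extra_genes = n_genes - len(records)
    n_extra_drugs = n_drugs - len(used_drugs)
    if n_extra_genes < 0 or n_extra_drugs < 0:
        raise ValueError("requested table smaller than the packaged fixture")
    extra_ids = [f"SD{i:05d}" for i in range(1, n_extra_drugs + 1)]
    # Deal the synthetic drugs round-robin so every synthetic gene gets >= 1
    # and the distinct total is exact; a deterministic 'approved' prefix per
    # hand mimics the approved/experimental split.
    hands: list[list[str]] = [[] for _ in range(n_extra_genes)]
    for i, drug in enumerate(extra_ids):
        hands[i % n_extra_genes].append(drug)
    for gi, hand in enumerate(hands):
        n_app = int(len(hand) * approved_fraction)
        records.append(
            KDTRecord(
                gene=GeneId(symbol=f"KDT{gi + len(fixture) + 1:04d}"),
                drug_ids=tuple(hand),
                approved_ids=tuple(hand[:n_app]),
            )
        )
    return records
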