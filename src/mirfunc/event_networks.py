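"""Stage-specific somatic-event networks and interaction-network composition.

Somatic events in colorectal cancer are consumed as an exported table (gene,
evolutionary stage, variant type, optional antecedent->subsequent links) and
assembled into a directed temporal-order graph; interaction networks arrive as
an undirected typed edge list whose composition is summarized as percentage of
total weight per interaction kind. Live database queries are out of scope;
the tables are the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import pandas as pd

STAGES = frozenset(
    {"early", "late", "relapse", "metastatic", "drug-induced", "drug-resistance"}
)
VARIANT_TYPES = frozenset(
    {"mutation", "methylation", "LOH", "CNV-loss", "CNV-gain", "alteration"}
)
INTERACTION_KINDS = frozenset(
    {"co-expression", "genetic", "physical", "shared-domain", "pathway", "predicted"}
)


@dataclass
class EventNode:
    """A gene with its stage-specific somatic events.

    ``stages`` may be empty for genes that appear only through temporal links.
    """

    gene: str
    stages: set = field(default_factory=set)
    variant_types: set = field(default_factory=set)
    is_target: bool = False


@dataclass(frozen=True)
class TemporalEdge:
    """Directed antecedent -> subsequent temporal-order link."""

    antecedent: str
    subsequent: str
    mechanism: str = "antecedent_of"

    def __post_init__(self) -> None:
        if self.antecedent == self.subsequent:
            raise ValueError(f"self-loop on {self.antecedent}")


@dataclass(frozen=True)
class InteractionEdge:
    """Undirected typed interaction with a non-negative weight."""

    gene_a: str
    gene_b: str
    kind: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_KINDS:
            raise ValueError(
                f"unknown interaction kind {self.kind!r}; valid: "
                f"{sorted(INTERACTION_KINDS)}"
            )
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


def load_event_table(
    path: str | Path, target_genes: Iterable[str] = ()
) -> tuple[list[EventNode], list[TemporalEdge]]:
    """Read a somatic-event TSV (gene, stage, variant_type[, antecedent_of]).

    Duplicate gene rows merge into one node with unioned stage/variant sets;
    the optional antecedent_of column adds a temporal edge from the row's gene.
    Unknown stage or variant tokens are errors naming the valid vocabulary.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene", "stage", "variant_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"event table must have columns {sorted(required)}")
    targets = set(target_genes)
    nodes: dict[str, EventNode] = {}
    edges: list[TemporalEdge] = []
    seen_edges: set[tuple[str, str]] = set()

    def node(gene: str) -> EventNode:
        if gene not in nodes:
            nodes[gene] = EventNode(gene=gene, is_target=gene in targets)
        return nodes[gene]

    for row in df.itertuples(index=False):
        gene = row.gene.strip()
        if not gene:
            raise ValueError("empty gene name in event table")
        n = node(gene)
        if row.stage:
            if row.stage not in STAGES:
                raise ValueError(
                    f"unknown stage {row.stage!r} for {gene}; valid: {sorted(STAGES)}"
                )
            n.stages.add(row.stage)
        if row.variant_type:
            if row.variant_type not in VARIANT_TYPES:
                raise ValueError(
                    f"unknown variant type {row.variant_type!r} for {gene}; "
                    f"valid: {sorted(VARIANT_TYPES)}"
                )
            n.variant_types.add(row.variant_type)
        subsequent = getattr(row, "antecedent_of", "").strip()
        if subsequent:
            node(subsequent)
            if (gene, subsequent) not in seen_edges:
                seen_edges.add((gene, subsequent))
                edges.append(TemporalEdge(antecedent=gene, subsequent=subsequent))
    return list(nodes.values()), edges


def stage_of(gene: str, nodes: Sequence[EventNode]) -> set:
    """Stage set of a gene's somatic events; unknown genes are errors."""
    for n in nodes:
        if n.gene == gene:
            return set(n.stages)
    raise KeyError(f"gene {gene!r} not in event network")


def temporal_graph(edges: Sequence[TemporalEdge]) -> nx.DiGraph:
    g = nx.DiGraph()
    for e in edges:
        g.add_edge(e.antecedent, e.subsequent, mechanism=e.mechanism)
    return g


def temporal_path(
    a: str, b: str, edges: Sequence[TemporalEdge]
) -> list[str] | None:
    """Shortest directed antecedent chain a -> ... -> b, or None.

    Breadth-first; equal-length alternatives resolve by lexicographic
    neighbor order.
    """
    g = temporal_graph(edges)
    if a == b:
        return [a]
    if a not in g or b not in g:
        return None
    # BFS with sorted adjacency for a deterministic tie-break
    prev: dict[str, str] = {}
    frontier = [a]
    visited = {a}
    while frontier:
        nxt: list[str] = []
        for u in frontier:
            for v in sorted(g.successors(u)):
                if v not in visited:
                    visited.add(v)
                    prev[v] = u
                    if v == b:
                        path = [b]
                        while path[-1] != a:
                            path.append(prev[path[-1]])
                        return path[::-1]
                    nxt.append(v)
        frontier = nxt
    return None


def load_edge_list(path: str | Path) -> list[InteractionEdge]:
    """Read an interaction TSV (gene_a, gene_b, kind[, weight])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "kind": str})
    edges = []
    for row in df.itertuples(index=False):
        weight = float(getattr(row, "weight", 1.0))
        edges.append(
            InteractionEdge(
                gene_a=row.gene_a, gene_b=row.gene_b, kind=row.kind, weight=weight
            )
        )
    return edges


def edge_composition(edges: Sequence[InteractionEdge]) -> dict:
    """Percentage of total interaction weight per kind (sums to 100)."""
    if not edges:
        raise ValueError("at least one interaction edge required")
    total = sum(e.weight for e in edges)
    if total == 0:
        raise ValueError("total interaction weight is zero")
    out: dict[str, float] = {}
    for e in edges:
        out[e.kind] = out.get(e.kind, 0.0) + e.weight
    return {k: 100.0 * v / total for k, v in sorted(out.items())}


def export_network(
    nodes: Sequence[EventNode],
    edges: Sequence[TemporalEdge],
    path: str | Path,
    fmt: Literal["SIF", "GraphML"] = "SIF",
) -> None:
    """Write the temporal event network for Cytoscape import.

    SIF lines are "antecedent<TAB>mechanism<TAB>subsequent" with isolated
    genes on their own line; GraphML carries stage/variant/is_target node
    attributes and round-trips through :func:`import_graphml`.
    """
    if not nodes:
        raise ValueError("cannot export an empty network")
    path = Path(path)
    if fmt == "SIF":
        linked = {e.antecedent for e in edges} | {e.subsequent for e in edges}
        with open(path, "w") as fh:
            for e in edges:
                fh.write(f"{e.antecedent}\t{e.mechanism}\t{e.subsequent}\n")
            for n in nodes:
                if n.gene not in linked:
                    fh.write(f"{n.gene}\n")
        return
    g = nx.DiGraph()
    for n in nodes:
        g.add_node(
            n.gene,
            stages=",".join(sorted(n.stages)),
            variant_types=",".join(sorted(n.variant_types)),
            is_target=int(n.is_target),
        )
    for e in edges:
        g.add_edge(e.antecedent, e.subsequent, mechanism=e.mechanism)
    nx.write_graphml(g, path)


def import_graphml(path: str | Path) -> tuple[list[EventNode], list[TemporalEdge]]:
    """Inverse of GraphML export (set-valued attributes decoded)."""
    g = nx.read_graphml(path)
    nodes = [
        EventNode(
            gene=v,
            stages=set(filter(None, d.get("stages", "").split(","))),
            variant_types=set(filter(None, d.get("variant_types", "").split(","))),
            is_target=bool(int(d.get("is_target", 0))),
        )
        for v, d in g.nodes(data=True)
    ]
    edges = [
        TemporalEdge(antecedent=u, subsequent=v, mechanism=d.get("mechanism", "antecedent_of"))
        for u, v, d in g.edges(data=True)
    ]
    return nodes, edges


def write_composition_table(composition: dict, path: str | Path) -> None:
    """TSV of interaction-kind percentages, 2 decimals, descending."""
    with open(path, "w") as fh:
        fh.write("kind\tpercent\n")
        for kind, pct in sorted(composition.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{kind}\t{pct:.2f}\n")
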