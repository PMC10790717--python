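"""Gene Ontology graph handling: loading, annotation, pruning, subtree extraction.

The ontology is a DAG of terms in up to three namespaces (biological_process,
molecular_function, cellular_component). Edges point child -> parent, i.e.
from the more specific to the more general term. A term's *direct* genes are
the genes annotated to it; its *propagated* genes are the union of direct
genes over the term and all of its descendants (all more-specific terms that
reach it). Visible-network scaffolds are *subtrees*: a leaf term together
with every ancestor reachable from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: ontology relations that define the term hierarchy; all others are ignored
HIERARCHY_RELATIONS = ("is_a", "part_of")

NAMESPACE_ALIASES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
    "biological_process": "biological_process",
    "molecular_function": "molecular_function",
    "cellular_component": "cellular_component",
}


class OntologyError(ValueError):
    """Raised for unreadable sources, empty annotation sets or empty graphs."""


@dataclass
class OntologyGraph:
    """Annotated ontology DAG.

    Parameters
    ----------
    graph
        Directed graph with child -> parent edges restricted to hierarchy
        relations.
    namespace
        Term id -> namespace string.
    direct_genes
        Term id -> frozenset of directly annotated gene symbols.
    names
        Optional term id -> human-readable name.
    """

    graph: nx.DiGraph
    namespace: dict[str, str]
    direct_genes: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    # -- basic structure ---------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from *term* along child->parent edges."""
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """All more-specific terms from which *term* is reachable."""
        return nx.ancestors(self.graph, term)

    def leaves(self) -> list[str]:
        return sorted(t for t in self.graph.nodes if self.graph.in_degree(t) == 0)

    def roots(self) -> list[str]:
        return sorted(t for t in self.graph.nodes if self.graph.out_degree(t) == 0)

    # -- gene sets ---------------------------------------------------------

    def propagated_genes(self, term: str) -> frozenset[str]:
        genes = set(self.direct_genes.get(term, ()))
        for d in self.descendants(term):
            genes |= self.direct_genes.get(d, frozenset())
        return frozenset(genes)

    def all_propagated_genes(self) -> dict[str, frozenset[str]]:
        """Propagated gene sets for every term in one reverse-topological sweep."""
        out: dict[str, set[str]] = {}
        for term in nx.topological_sort(self.graph):
            genes = set(self.direct_genes.get(term, ()))
            for child in self.graph.predecessors(term):
                genes |= out[child]
            out[term] = genes
        return {t: frozenset(g) for t, g in out.items()}

    @property
    def gene_universe(self) -> frozenset[str]:
        universe: set[str] = set()
        for genes in self.direct_genes.values():
            universe |= genes
        return frozenset(universe)

    def gene_term_pairs(self) -> list[tuple[str, str]]:
        """All direct (gene, term) annotation pairs, sorted."""
        return sorted(
            (g, t) for t, gs in self.direct_genes.items() for g in gs
        )

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise OntologyError("ontology graph contains a directed cycle")
        unknown = set(self.direct_genes) - set(self.graph.nodes)
        if unknown:
            raise OntologyError(f"annotations reference unknown terms: {sorted(unknown)[:5]}")

    # -- export ------------------------------------------------------------

    def to_edge_list(self, path) -> None:
        """Write child->parent edges as TSV for inspection."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("child\tparent\n")
            for child, parent in sorted(self.graph.edges):
                fh.write(f"{child}\t{parent}\n")


@dataclass
class Subtree:
    """A leaf term plus all of its ancestors: the scaffold for one VNN.

    ``members`` always contains the leaf; edges are the parent-child edges of
    the pruned graph restricted to the members; ``direct_genes`` are the
    member terms' direct annotations.
    """

    leaf: str
    members: set[str]
    edges: list[tuple[str, str]]
    direct_genes: dict[str, frozenset[str]]
    root: str

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        g.add_edges_from(self.edges)
        return g

    def gene_term_pairs(self) -> list[tuple[str, str]]:
        return sorted(
            (g, t) for t, gs in self.direct_genes.items() for g in gs
        )


# ---------------------------------------------------------------------------
# loading


def _read_gaf(path) -> list[tuple[str, str]]:
    """(gene symbol, term id) pairs from a GAF 2.x file (columns 3 and 5)."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                continue
            pairs.append((cols[2], cols[4]))
    return pairs


def _read_tsv(path) -> list[tuple[str, str]]:
    """(gene, term) pairs from a two-column term<TAB>gene table."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                continue
            term, gene = cols[0].strip(), cols[1].strip()
            if term.lower() in ("term", "term_id") and gene.lower() in ("gene", "symbol"):
                continue  # header
            pairs.append((gene, term))
    return pairs


def read_annotations(path, dialect: str | None = None) -> list[tuple[str, str]]:
    """Read gene-term annotations as (gene, term) pairs.

    ``dialect`` is ``"gaf"`` or ``"tsv"``; by default it is sniffed from the
    file name (``.gaf`` -> GAF, anything else -> two-column TSV).
    """
    if dialect is None:
        dialect = "gaf" if str(path).endswith((".gaf", ".gaf.gz")) else "tsv"
    if dialect == "gaf":
        return _read_gaf(path)
    if dialect == "tsv":
        return _read_tsv(path)
    raise OntologyError(f"unknown annotation dialect: {dialect!r}")


def load_ontology(
    obo_source,
    annotation_source,
    namespaces: tuple[str, ...] | None = ("biological_process",),
    annotation_dialect: str | None = None,
) -> OntologyGraph:
    """Load an OBO ontology, attach gene annotations, restrict namespaces.

    Only ``is_a`` and ``part_of`` edges are retained. Annotations to unknown
    or obsolete terms are dropped (a count is logged). Duplicate annotations
    are deduplicated; gene symbols are case-sensitive.

    Raises
    ------
    OntologyError
        If the OBO source is unreadable or no annotation survives filtering.
    """
    try:
        multi = obonet.read_obo(obo_source, ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - passthrough wrapper
        raise OntologyError(f"cannot read OBO source {obo_source!r}: {exc}") from exc

    wanted = None
    if namespaces is not None:
        wanted = {NAMESPACE_ALIASES.get(ns, ns) for ns in namespaces}

    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    for term, data in multi.nodes(data=True):
        ns = data.get("namespace", "biological_process")
        if wanted is not None and ns not in wanted:
            continue
        graph.add_node(term)
        namespace[term] = ns

    # obonet edges run child -> parent with the relation as the edge key
    for child, parent, rel in multi.edges(keys=True):
        if rel not in HIERARCHY_RELATIONS:
            continue
        if child in graph and parent in graph:
            graph.add_edge(child, parent)

    pairs = read_annotations(annotation_source, annotation_dialect)
    direct: dict[str, set[str]] = {}
    dropped = 0
    for gene, term in pairs:
        if term in graph:
            direct.setdefault(term, set()).add(gene)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d annotations to unknown/obsolete/out-of-namespace terms", dropped)
    if not direct:
        raise OntologyError("no annotations match any retained ontology term")

    og = OntologyGraph(
        graph=graph,
        namespace=namespace,
        direct_genes={t: frozenset(g) for t, g in direct.items()},
        names={t: d.get("name", t) for t, d in multi.nodes(data=True) if t in graph},
    )
    og.validate()
    return og


# ---------------------------------------------------------------------------
# pruning


def _nearest_retained_ancestors(graph: nx.DiGraph, node: str, retained: set[str]) -> set[str]:
    """BFS along parent edges, stopping at the first retained term on each path."""
    found: set[str] = set()
    stack = list(graph.successors(node))
    seen: set[str] = set()
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        if cur in retained:
            found.add(cur)
        else:
            stack.extend(graph.successors(cur))
    return found


def contract_terms(ontology: OntologyGraph, retained: set[str]) -> OntologyGraph:
    """Restrict the graph to ``retained`` terms, rewiring each survivor's
    parents to its nearest retained ancestors (paths through removed terms
    are contracted to single edges). The result is still a DAG."""
    graph = ontology.graph
    missing = retained - set(graph.nodes)
    if missing:
        raise OntologyError(f"cannot retain unknown terms: {sorted(missing)[:5]}")
    if not retained:
        raise OntologyError("cannot contract to an empty term set")
    new_edges = []
    for t in retained:
        for anc in _nearest_retained_ancestors(graph, t, retained):
            new_edges.append((t, anc))
    out = nx.DiGraph()
    out.add_nodes_from(retained)
    out.add_edges_from(new_edges)
    return OntologyGraph(
        graph=out,
        namespace={t: ontology.namespace.get(t, "biological_process") for t in retained},
        direct_genes={
            t: g for t, g in ontology.direct_genes.items() if t in retained and g
        },
        names={t: n for t, n in ontology.names.items() if t in retained},
    )


def prune_graph(ontology: OntologyGraph, min_genes: int = 5) -> OntologyGraph:
    """Drop terms whose propagated gene set is smaller than ``min_genes``.

    Removal and propagated-set recomputation are iterated to a fixed point
    (losing a descendant's direct genes can push an ancestor below the
    threshold), which makes pruning idempotent. Survivors are then rewired so
    each term's parents are its nearest surviving ancestors; the result is
    still a DAG. Namespaces are handled independently by construction since
    hierarchy edges never cross namespaces.

    Raises
    ------
    OntologyError
        If no term survives.
    """
    current = ontology
    while True:
        prop = current.all_propagated_genes()
        drop = {t for t in current.terms if len(prop[t]) < min_genes}
        if not drop:
            break
        retained = current.terms - drop
        if not retained:
            raise OntologyError(f"pruning at min_genes={min_genes} removed every term")
        current = contract_terms(current, retained)

    current.validate()
    return current


# ---------------------------------------------------------------------------
# subtrees


def extract_subtrees(ontology: OntologyGraph) -> list[Subtree]:
    """One subtree per leaf term: the leaf plus its full ancestor closure."""
    subtrees = []
    for leaf in ontology.leaves():
        members = {leaf} | ontology.ancestors(leaf)
        edges = [(c, p) for c, p in ontology.graph.edges if c in members and p in members]
        sub_graph = nx.DiGraph()
        sub_graph.add_nodes_from(members)
        sub_graph.add_edges_from(edges)
        roots = [t for t in members if sub_graph.out_degree(t) == 0]
        subtrees.append(
            Subtree(
                leaf=leaf,
                members=members,
                edges=sorted(edges),
                direct_genes={
                    t: ontology.direct_genes.get(t, frozenset()) for t in members
                },
                root=roots[0] if len(roots) == 1 else "",
            )
        )
    return subtrees
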