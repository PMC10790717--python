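"""Synthetic ontologies and expression data with planted cell-type signals.

The generator builds a small single-rooted annotated DAG and simulates cells
from C classes whose identity is carried by *planted modules*: for each
class, the direct genes of one (or more) designated driver terms are shifted
upward by a fixed effect size in that class's cells, on top of shared
per-gene baselines and Gaussian log-scale noise. This reproduces the
statistical structure the visible network assumes — class-coherent,
term-aligned gene modules — without attempting realistic scRNA-seq noise
(no dropout, batch effects or doublets). A negative-binomial count layer is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .ontology import OntologyGraph
from .vnn import ExpressionDataset

#: default study conditions for the planted-signal fixture
DEFAULT_N_TERMS = 12
DEFAULT_N_GENES = 150
DEFAULT_N_CLASSES = 3
DEFAULT_CELLS_PER_CLASS = 100
DEFAULT_EFFECT_SIZE = 2.0
DEFAULT_NOISE_SD = 1.0


class GenerationError(ValueError):
    """Infeasible generator parameters."""


@dataclass
class SyntheticTruth:
    """Ground truth of a planted simulation: which genes drive which class."""

    planted: dict[str, dict[str, list[str]]]  # class -> driver term -> genes
    effect_size: float
    noise_sd: float
    seed: int
    cells_per_class: int

    def driver_genes(self, cls: str) -> list[str]:
        genes: list[str] = []
        for gs in self.planted.get(cls, {}).values():
            genes.extend(g for g in gs if g not in genes)
        return genes

    def driver_terms(self, cls: str) -> list[str]:
        return sorted(self.planted.get(cls, {}))


def _term_id(i: int) -> str:
    return f"GO:{7_000_000 + i:07d}"


def _gene_id(i: int) -> str:
    return f"g{i:04d}"


def make_toy_ontology(
    n_terms: int = DEFAULT_N_TERMS,
    n_genes: int = DEFAULT_N_GENES,
    max_parents: int = 2,
    seed: int = 0,
    min_genes: int = 5,
    namespace: str = "biological_process",
) -> OntologyGraph:
    """Random single-rooted annotated DAG with at least two leaf terms.

    Term i > 0 picks 1..max_parents parents among earlier terms (the last
    term's parents avoid the second-to-last, guaranteeing >= 2 leaves).
    Genes are dealt out so that every term receives at least ``min_genes``
    direct genes, hence every propagated set meets the pruning threshold;
    a fifth of the genes get a second annotation. Deterministic per seed.
    """
    if n_terms < 3:
        raise GenerationError("need at least 3 terms")
    if n_genes < n_terms * min_genes:
        raise GenerationError(
            f"need at least {n_terms * min_genes} genes for {n_terms} terms at min_genes={min_genes}"
        )
    rng = np.random.default_rng(seed)
    terms = [_term_id(i) for i in range(n_terms)]
    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for i in range(1, n_terms):
        pool = terms[: i if i < n_terms - 1 else n_terms - 2]
        k = int(rng.integers(1, min(max_parents, len(pool)) + 1))
        parents = rng.choice(len(pool), size=k, replace=False)
        for p in parents:
            graph.add_edge(terms[i], pool[int(p)])

    genes = [_gene_id(i) for i in range(n_genes)]
    order = rng.permutation(n_genes)
    direct: dict[str, set[str]] = {t: set() for t in terms}
    for j, gi in enumerate(order):
        direct[terms[j % n_terms]].add(genes[int(gi)])
    second = rng.random(n_genes) < 0.2
    for gi in np.flatnonzero(second):
        t = terms[int(rng.integers(0, n_terms))]
        direct[t].add(genes[int(gi)])

    og = OntologyGraph(
        graph=graph,
        namespace={t: namespace for t in terms},
        direct_genes={t: frozenset(g) for t, g in direct.items()},
        names={t: f"toy process {i}" for i, t in enumerate(terms)},
    )
    og.validate()
    if len(og.leaves()) < 2:
        raise GenerationError("construction failed to produce two leaves")
    return og


def plant_default_truth(
    graph: OntologyGraph,
    n_classes: int = DEFAULT_N_CLASSES,
    genes_per_class: int = 10,
    seed: int = 0,
    effect_size: float = DEFAULT_EFFECT_SIZE,
    noise_sd: float = DEFAULT_NOISE_SD,
    cells_per_class: int = DEFAULT_CELLS_PER_CLASS,
) -> SyntheticTruth:
    """Assign one driver leaf term (and its direct genes) per class.

    Classes are named ``ct0..ct{C-1}``. Leaves are assigned in rotation when
    there are fewer leaves than classes.
    """
    rng = np.random.default_rng(seed)
    leaves = graph.leaves()
    if not leaves:
        raise GenerationError("graph has no leaves")
    if n_classes > len(leaves):
        raise GenerationError(
            f"{n_classes} classes need {n_classes} distinct driver leaves, graph has {len(leaves)}"
        )
    chosen = rng.permutation(len(leaves))
    planted: dict[str, dict[str, list[str]]] = {}
    for c in range(n_classes):
        leaf = leaves[int(chosen[c % len(leaves)])]
        pool = sorted(graph.direct_genes.get(leaf, frozenset()))
        if not pool:
            raise GenerationError(f"driver leaf {leaf} has no direct genes")
        take = min(genes_per_class, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        planted[f"ct{c}"] = {leaf: sorted(pool[int(i)] for i in idx)}
    return SyntheticTruth(
        planted=planted,
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed,
        cells_per_class=cells_per_class,
    )


def simulate_expression(
    graph: OntologyGraph,
    truth: SyntheticTruth,
    n_cells_per_class: int | None = None,
    seed: int | None = None,
    counts: bool = False,
) -> ExpressionDataset:
    """Simulate a cells x genes matrix with the truth's planted modules.

    Per-gene baselines are drawn once (Normal(1, 0.5) on the log scale);
    each cell adds Gaussian noise of scale ``truth.noise_sd``; driver genes
    gain ``truth.effect_size`` in their own class only. With
    ``counts=True`` the log-scale intensities are pushed through a
    negative-binomial layer and returned as log1p counts.
    """
    seed = truth.seed if seed is None else seed
    n_per = truth.cells_per_class if n_cells_per_class is None else n_cells_per_class
    rng = np.random.default_rng(seed)
    genes = sorted(graph.gene_universe)
    gene_pos = {g: i for i, g in enumerate(genes)}
    classes = sorted(truth.planted)
    for cls in classes:
        for term, gs in truth.planted[cls].items():
            if term not in graph.terms:
                raise GenerationError(f"driver term {term} not in graph")
            for g in gs:
                if g not in gene_pos:
                    raise GenerationError(f"driver gene {g} not in gene universe")

    n_cells = n_per * len(classes)
    baseline = rng.normal(1.0, 0.5, size=len(genes))
    X = baseline[None, :] + rng.normal(0.0, truth.noise_sd, size=(n_cells, len(genes)))
    y = np.repeat(np.arange(len(classes)), n_per)
    for c, cls in enumerate(classes):
        rows = np.flatnonzero(y == c)
        for g in truth.driver_genes(cls):
            X[rows, gene_pos[g]] += truth.effect_size
    if counts:
        lam = np.exp(X)
        r = 10.0  # NB dispersion: var = lam + lam^2 / r
        p = r / (r + lam)
        X = np.log1p(rng.negative_binomial(r, p).astype(np.float64))
    return ExpressionDataset(X=X, y=y, gene_names=genes, class_names=classes)


def planted_fixture(
    seed: int = 0,
    n_terms: int = DEFAULT_N_TERMS,
    n_genes: int = DEFAULT_N_GENES,
    n_classes: int = DEFAULT_N_CLASSES,
    cells_per_class: int = DEFAULT_CELLS_PER_CLASS,
    effect_size: float = DEFAULT_EFFECT_SIZE,
    noise_sd: float = DEFAULT_NOISE_SD,
    genes_per_class: int = 10,
) -> tuple[OntologyGraph, ExpressionDataset, SyntheticTruth]:
    """One-call study fixture: toy ontology, planted expression, ground truth.

    The ontology draw is retried on derived sub-seeds until it offers one
    distinct driver leaf per class (still deterministic per seed).
    """
    graph = None
    for attempt in range(32):
        candidate = make_toy_ontology(
            n_terms=n_terms, n_genes=n_genes, seed=(seed * 1009 + attempt) % (2**31)
        )
        if len(candidate.leaves()) >= n_classes:
            graph = candidate
            break
    if graph is None:
        raise GenerationError("could not draw an ontology with enough driver leaves")
    truth = plant_default_truth(
        graph,
        n_classes=n_classes,
        genes_per_class=genes_per_class,
        seed=seed,
        effect_size=effect_size,
        noise_sd=noise_sd,
        cells_per_class=cells_per_class,
    )
    dataset = simulate_expression(graph, truth)
    return graph, dataset, truth
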