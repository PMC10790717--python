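"""Analysis phase: pathway activity, cell-type enrichment, communities.

Takes the gene-term score table produced by the modeling phase plus a query
gene or gene set and computes, per cell type:

* GPPAS — a gene's mean gene-term score over a pathway and its descendant
  terms directly annotated with the gene;
* ctPAS — the sum of GPPASs over query genes annotated under a pathway,
  with an empirical P-value from size-matched random gene sets and a
  z-score against the permutation distribution;
* a one-sided two-sample Kolmogorov-Smirnov comparison of query-gene scores
  against all remaining gene-term scores (small P = query scores
  stochastically larger);
* random-walk-with-restart expansion of the active-pathway set on the term
  graph, modularity community partition, and a capped mean -log10 P
  significance per community;
* the most active gene (MAG, largest GPPAS) per pathway, and a classical
  Fisher over-representation P-value as a baseline.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats

from .ontology import OntologyGraph
from .scoring import GeneTermScoreTable


class QueryError(ValueError):
    """Query gene absent from the annotation universe / score table."""


# ---------------------------------------------------------------------------
# per-gene / per-pathway scores


def compute_gppas(
    table: GeneTermScoreTable,
    graph: OntologyGraph,
    gene: str,
    pathway: str,
    cell_type: str,
) -> float:
    """Mean gene-term score of *gene* over *pathway* and its descendants.

    Only terms directly annotated with the gene (i.e. rows present in the
    score table) contribute; a gene directly annotated to the pathway alone
    gets that single score back.
    """
    if pathway not in graph.terms:
        raise QueryError(f"unknown pathway {pathway!r}")
    prop = graph.propagated_genes(pathway)
    if gene not in prop:
        raise QueryError(f"gene {gene!r} is not annotated under pathway {pathway!r}")
    members = {pathway} | graph.descendants(pathway)
    df = table.data
    sub = df[(df["gene"] == gene) & (df["cell_type"] == cell_type) & df["term"].isin(members)]
    if sub.empty:
        return float("nan")
    return float(sub["score"].mean())


def compute_ctpas(gppas_by_gene: dict[str, float]) -> float:
    """Sum of GPPASs over the query genes annotated under the pathway."""
    vals = [v for v in gppas_by_gene.values() if np.isfinite(v)]
    return float(np.sum(vals)) if vals else 0.0


def select_mag(gppas_by_gene: dict[str, float]) -> str | None:
    """Most active gene: the largest GPPAS, ties broken lexicographically."""
    finite = {g: v for g, v in gppas_by_gene.items() if np.isfinite(v)}
    if not finite:
        return None
    return min(finite, key=lambda g: (-finite[g], g))


def fisher_ora_counts(overlap: int, n_query: int, n_pathway: int, n_universe: int) -> float:
    """One-sided Fisher's exact test from ORA contingency counts."""
    if n_universe <= 0:
        raise ValueError("empty gene universe")
    table = [
        [overlap, n_query - overlap],
        [n_pathway - overlap, n_universe - n_query - n_pathway + overlap],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def fisher_ora(query: set[str], pathway_genes: set[str], universe: set[str]) -> float:
    """One-sided Fisher's exact test for query/pathway over-representation.

    Standard ORA contingency table on the gene universe:
    ``[[overlap, query-only], [pathway-only, neither]]``, alternative
    'greater'.
    """
    q = query & universe
    p = pathway_genes & universe
    return fisher_ora_counts(len(q & p), len(q), len(p), len(universe))


# ---------------------------------------------------------------------------
# RWR + communities


def rwr_expand(
    graph: OntologyGraph | "ig.Graph",
    seed_terms: list[str],
    restart_prob: float = 0.5,
    expansion_factor: int = 5,
    namespace: str | None = None,
) -> tuple[list[str], dict[str, float]]:
    """Random walk with restart from the seed pathways on the term graph.

    The term graph is the undirected, unweighted parent-child graph.
    Solves ``(I - (1 - r) W) a = r e`` with column-stochastic W and uniform
    restart vector e over the seeds; the affinity vector sums to 1
    (isolated nodes get a self-loop). Returns the union of the seeds with
    the ``expansion_factor * len(seeds)`` highest-affinity nodes, plus the
    full affinity map.
    """
    if isinstance(graph, OntologyGraph):
        if namespace is not None:
            nodes = sorted(t for t in graph.terms if graph.namespace.get(t) == namespace)
        else:
            nodes = sorted(graph.terms)
        node_set = set(nodes)
        edges = [(c, p) for c, p in graph.graph.edges if c in node_set and p in node_set]
    else:  # pragma: no cover - igraph passthrough used by tests
        nodes = sorted(v["name"] for v in graph.vs)
        edges = [(graph.vs[e.source]["name"], graph.vs[e.target]["name"]) for e in graph.es]

    missing = [s for s in seed_terms if s not in set(nodes)]
    if missing or not seed_terms:
        raise KeyError(f"seed terms not in graph: {missing or seed_terms}")
    if not 0.0 < restart_prob <= 1.0:
        raise ValueError("restart probability must be in (0, 1]")

    idx = {t: i for i, t in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for c, p in edges:
        A[idx[c], idx[p]] = 1.0
        A[idx[p], idx[c]] = 1.0
    deg = A.sum(axis=0)
    A[np.arange(n), np.arange(n)] = np.where(deg == 0, 1.0, A.diagonal())
    W = A / A.sum(axis=0, keepdims=True)

    e = np.zeros(n)
    for s in seed_terms:
        e[idx[s]] = 1.0 / len(seed_terms)
    a = np.linalg.solve(np.eye(n) - (1.0 - restart_prob) * W, restart_prob * e)

    affinity = {t: float(a[idx[t]]) for t in nodes}
    k = expansion_factor * len(seed_terms)
    ranked = sorted(nodes, key=lambda t: (-affinity[t], t))
    selected = set(ranked[:k]) | set(seed_terms)
    return sorted(selected, key=lambda t: (-affinity[t], t)), affinity


def partition_communities(
    nodes: list[str],
    edges: list[tuple[str, str]],
    seed: int = 0,
) -> list[set[str]]:
    """Seeded modularity partition of the expanded pathway network.

    Communities are disjoint, cover every node, and are deterministic for a
    fixed seed. Returned largest-first, ties by smallest member id.
    """
    if not nodes:
        raise ValueError("empty subgraph")
    g = ig.Graph()
    g.add_vertices(sorted(nodes))
    name_idx = {v["name"]: v.index for v in g.vs}
    uniq = {tuple(sorted((a, b))) for a, b in edges if a != b and a in name_idx and b in name_idx}
    g.add_edges([(name_idx[a], name_idx[b]) for a, b in sorted(uniq)])
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition, seed=int(seed), n_iterations=2
    )
    communities = [set(g.vs[i]["name"] for i in comm) for comm in part]
    return sorted(communities, key=lambda c: (-len(c), min(c)))


@dataclass
class Community:
    index: int
    terms: list[str]
    significance: float
    active: bool
    reported: bool
    label_terms: list[str] = field(default_factory=list)


@dataclass
class CommunityReport:
    seeds: list[str]
    expanded: list[str]
    affinities: dict[str, float]
    communities: list[Community]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.communities:
            rows.append(
                {
                    "community": c.index,
                    "n_pathways": len(c.terms),
                    "significance": c.significance,
                    "active": c.active,
                    "reported": c.reported,
                    "pathways": ";".join(sorted(c.terms)),
                    "label": ";".join(c.label_terms),
                }
            )
        return pd.DataFrame(rows)


def community_significance(
    partition: list[set[str]],
    pathway_pvalues: dict[str, float],
    active_p: float = 0.01,
) -> list[Community]:
    """Score each community as the mean of min(4, -log10 P) over its pathways.

    A community is *active* when its significance exceeds -log10(active_p);
    among active communities, those with fewer pathways than the mean active
    community size are dropped from the report (``reported=False``).
    Pathways without a P-value enter with P = 1.
    """
    comms: list[Community] = []
    for i, terms in enumerate(partition):
        logs = []
        for t in sorted(terms):
            p = pathway_pvalues.get(t, 1.0)
            p = min(max(p, 1e-300), 1.0)
            logs.append(min(4.0, -np.log10(p)))
        sig = float(np.mean(logs)) if logs else 0.0
        active = bool(sig > -np.log10(active_p))
        member_ps = sorted(
            (t for t in terms), key=lambda t: (pathway_pvalues.get(t, 1.0), t)
        )
        comms.append(
            Community(
                index=i,
                terms=sorted(terms),
                significance=sig,
                active=active,
                reported=active,
                label_terms=member_ps[:3],
            )
        )
    active_sizes = [len(c.terms) for c in comms if c.active]
    if active_sizes:
        mean_size = float(np.mean(active_sizes))
        for c in comms:
            c.reported = c.active and len(c.terms) >= mean_size
    return comms


# ---------------------------------------------------------------------------
# gene-set analysis object


@dataclass
class CellTypeEnrichment:
    cell_type: str
    statistic: float
    p_value: float
    n_active_pathways: int


@dataclass
class GeneSetResult:
    """Everything the gene-set mode reports."""

    query: list[str]
    unmatched: list[str]
    pathways: pd.DataFrame
    cell_types: pd.DataFrame
    community_reports: dict[str, CommunityReport] = field(default_factory=dict)

    def active_counts(self) -> pd.Series:
        counts = {}
        for ct, sub in self.pathways.groupby("cell_type"):
            counts[ct] = int((sub["p_value"] <= sub["active_p"]).sum())
        return pd.Series(counts, name="n_active_pathways").sort_index()


class GeneSetAnalysis:
    """Gene-set (and single-gene) analysis over a gene-term score table.

    Parameters
    ----------
    table
        Modeling-phase score table.
    graph
        The pruned annotated ontology used for modeling; supplies the
        descendant structure, the propagated gene sets and the background
        gene universe (all annotated genes).
    n_perm, active_p, restart_prob, expansion_factor, namespace, seed
        Analysis knobs; defaults are 10 000 permutations, active-pathway
        cutoff P <= 0.01, restart probability 0.5, 5-fold expansion and the
        biological_process namespace.
    """

    def __init__(
        self,
        table: GeneTermScoreTable,
        graph: OntologyGraph,
        n_perm: int = 10_000,
        active_p: float = 0.01,
        restart_prob: float = 0.5,
        expansion_factor: int = 5,
        namespace: str = "biological_process",
        seed: int = 0,
    ):
        if n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        self.table = table
        self.graph = graph
        self.n_perm = int(n_perm)
        self.active_p = float(active_p)
        self.restart_prob = float(restart_prob)
        self.expansion_factor = int(expansion_factor)
        self.namespace = namespace
        self.seed = int(seed)
        self.universe: list[str] = sorted(graph.gene_universe)
        self._prop = graph.all_propagated_genes()
        self._desc = {t: graph.descendants(t) for t in graph.terms}

    # -- query handling ----------------------------------------------------

    def match_query(self, genes) -> tuple[list[str], list[str]]:
        uni = set(self.universe)
        seen: set[str] = set()
        matched, unmatched = [], []
        for g in genes:
            if g in seen:
                continue
            seen.add(g)
            (matched if g in uni else unmatched).append(g)
        return matched, unmatched

    # -- GPPAS matrices ----------------------------------------------------

    def _gppas_matrix(self, pathway: str) -> pd.DataFrame:
        """genes x cell_types GPPAS for one pathway (NaN where undefined)."""
        members = {pathway} | self._desc[pathway]
        df = self.table.data
        sub = df[df["term"].isin(members)]
        if sub.empty:
            return pd.DataFrame(columns=self.table.cell_types)
        return sub.pivot_table(index="gene", columns="cell_type", values="score", aggfunc="mean")

    def testable_pathways(self, query: list[str]) -> list[str]:
        qset = set(query)
        return sorted(
            t
            for t in self.graph.terms
            if (self.namespace is None or self.graph.namespace.get(t) == self.namespace)
            and qset & self._prop[t]
        )

    # -- core statistics ---------------------------------------------------

    def pathway_scores(self, query: list[str]) -> pd.DataFrame:
        """ctPAS, permutation P, z-score, MAG and Fisher ORA per pathway/cell type."""
        matched, _ = self.match_query(query)
        if not matched:
            raise QueryError("no query gene matches the annotation universe")
        pathways = self.testable_pathways(matched)
        cell_types = self.table.cell_types
        rng = np.random.default_rng(self.seed)

        n_uni = len(self.universe)
        gene_pos = {g: i for i, g in enumerate(self.universe)}
        q_idx = np.array([gene_pos[g] for g in matched], dtype=np.int64)

        # GPPAS matrix per pathway stacked over (pathway, cell type) columns
        mats = {}
        cols = []
        M = np.zeros((n_uni, len(pathways) * len(cell_types)))
        for j, p in enumerate(pathways):
            gm = self._gppas_matrix(p)
            mats[p] = gm
            for k, ct in enumerate(cell_types):
                col = j * len(cell_types) + k
                cols.append((p, ct))
                if ct in gm.columns:
                    vals = gm[ct].reindex(self.universe).to_numpy()
                    M[:, col] = np.nan_to_num(vals, nan=0.0)

        observed = M[q_idx].sum(axis=0)
        perm_idx = np.stack(
            [rng.choice(n_uni, size=len(q_idx), replace=False) for _ in range(self.n_perm)]
        )
        perm = M[perm_idx].sum(axis=1)  # n_perm x columns
        count_ge = (perm >= observed[None, :]).sum(axis=0)
        pvals = (1.0 + count_ge) / (1.0 + self.n_perm)
        mean = perm.mean(axis=0)
        sd = perm.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (observed - mean) / sd, np.nan)

        uni_set = set(self.universe)
        rows = []
        for col, (p, ct) in enumerate(cols):
            gm = mats[p]
            in_path = [g for g in matched if g in self._prop[p]]
            gppas = {}
            if ct in gm.columns:
                series = gm[ct]
                gppas = {g: float(series[g]) for g in in_path if g in series.index}
            mag = select_mag(gppas)
            rows.append(
                {
                    "term": p,
                    "name": self.graph.names.get(p, p),
                    "cell_type": ct,
                    "ctpas": observed[col],
                    "z": z[col],
                    "p_value": pvals[col],
                    "mag": mag,
                    "n_query_genes": len(in_path),
                    "ora_p": fisher_ora(set(matched), set(self._prop[p]), uni_set),
                    "active_p": self.active_p,
                }
            )
        return pd.DataFrame(rows).sort_values(["cell_type", "p_value", "term"], kind="mergesort").reset_index(drop=True)

    def cell_type_enrichment(self, query: list[str]) -> pd.DataFrame:
        """One-sided two-sample K-S of query-gene scores vs the background,
        per cell type (small P = query scores stochastically larger)."""
        matched, _ = self.match_query(query)
        if not matched:
            raise QueryError("no query gene matches the annotation universe")
        qset = set(matched)
        df = self.table.data
        rows = []
        for ct, sub in df.groupby("cell_type"):
            fg = sub.loc[sub["gene"].isin(qset), "score"].to_numpy()
            bg = sub.loc[~sub["gene"].isin(qset), "score"].to_numpy()
            if len(fg) == 0 or len(bg) == 0:
                rows.append({"cell_type": ct, "statistic": np.nan, "p_value": np.nan, "testable": False})
                continue
            res = stats.ks_2samp(fg, bg, alternative="less")
            rows.append(
                {"cell_type": ct, "statistic": float(res.statistic), "p_value": float(res.pvalue), "testable": True}
            )
        return pd.DataFrame(rows).sort_values("cell_type", kind="mergesort").reset_index(drop=True)

    def community_analysis(self, pathway_table: pd.DataFrame, cell_type: str) -> CommunityReport | None:
        """RWR expansion + modularity partition + significance for one cell type."""
        sub = pathway_table[pathway_table["cell_type"] == cell_type]
        seeds = sorted(sub.loc[sub["p_value"] <= self.active_p, "term"])
        if not seeds:
            return None
        expanded, affinity = rwr_expand(
            self.graph, seeds, self.restart_prob, self.expansion_factor, namespace=self.namespace
        )
        node_set = set(expanded)
        edges = sorted(
            {tuple(sorted((c, p))) for c, p in self.graph.graph.edges if c in node_set and p in node_set}
        )
        partition = partition_communities(expanded, edges, seed=self.seed)
        pvalues = dict(zip(sub["term"], sub["p_value"]))
        comms = community_significance(partition, pvalues, self.active_p)
        return CommunityReport(
            seeds=seeds, expanded=expanded, affinities=affinity, communities=comms, edges=edges
        )

    # -- modes -------------------------------------------------------------

    def analyze(self, query: list[str], mode: str = "geneset-basic") -> GeneSetResult:
        """Run a gene-set mode: 'geneset-basic' (pathways + cell types) or
        'geneset-complete' (additionally community reports per cell type)."""
        if mode not in ("geneset-basic", "geneset-complete"):
            raise ValueError(f"unknown gene-set mode {mode!r}")
        matched, unmatched = self.match_query(query)
        pathways = self.pathway_scores(matched)
        cell_types = self.cell_type_enrichment(matched)
        active = (
            pathways.assign(is_active=pathways["p_value"] <= self.active_p)
            .groupby("cell_type")["is_active"]
            .sum()
            .astype(int)
        )
        cell_types = cell_types.merge(
            active.rename("n_active_pathways"), left_on="cell_type", right_index=True, how="left"
        )
        cell_types["n_active_pathways"] = cell_types["n_active_pathways"].fillna(0).astype(int)
        reports = {}
        if mode == "geneset-complete":
            for ct in self.table.cell_types:
                rep = self.community_analysis(pathways, ct)
                if rep is not None:
                    reports[ct] = rep
        return GeneSetResult(
            query=matched,
            unmatched=unmatched,
            pathways=pathways,
            cell_types=cell_types,
            community_reports=reports,
        )


# ---------------------------------------------------------------------------
# single-gene mode


def single_gene_analysis(table: GeneTermScoreTable, gene: str) -> pd.DataFrame:
    """Project a single gene's directly annotated terms out of the score table.

    Returns one row per (term, cell type) with the stored score and empirical
    P-value — a pure projection, nothing is recomputed. Raises with
    closest-symbol suggestions when the gene is absent.
    """
    df = table.data
    sub = df[df["gene"] == gene]
    if sub.empty:
        close = difflib.get_close_matches(gene, sorted(table.genes), n=3)
        raise QueryError(f"gene {gene!r} has no scored annotation; close matches: {close}")
    return sub.sort_values(["cell_type", "p_value", "term"], kind="mergesort").reset_index(drop=True)


def single_gene_cell_type_summary(table: GeneTermScoreTable, gene: str) -> pd.DataFrame:
    """Per-cell-type summary of a gene's -log10 P distribution for ranking
    the cell types most affected by the gene."""
    sub = single_gene_analysis(table, gene)
    sub = sub.assign(neglogp=-np.log10(np.clip(sub["p_value"], 1e-300, None)))
    # P=0 (top-ranked pair) maps to the cap used in community scoring
    sub.loc[sub["p_value"] <= 0, "neglogp"] = 4.0
    sub["neglogp"] = np.minimum(sub["neglogp"], 4.0)
    out = (
        sub.groupby("cell_type")["neglogp"]
        .agg(n_terms="size", median_neglogp="median", max_neglogp="max")
        .reset_index()
    )
    return out.sort_values("median_neglogp", ascending=False, kind="mergesort").reset_index(drop=True)
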