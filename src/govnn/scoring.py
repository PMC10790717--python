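"""Cell-type-specific gene-term scores (GTS) by in-silico knockout.

For every subtree VNN and every gene-term pair wired into it, the gene's
expression is zeroed in that term's input slot only, the cells are
re-classified by the root head, and the raw score for class c is minus the
change in the number of cells predicted as c. Raw scores then pass through a
correction cascade:

1. per subtree and class, subtract the median over pairs (background bias);
2. multiply by the subtree's size factor — the root accuracy in excess of
   the majority-class baseline, rescaled to [0, 1] and clamped at 0;
3. average each pair's scores over the subtrees containing it;
4. per class, rescale positive scores so the total positive mass equals the
   total negative mass, then divide by the maximum absolute score, bounding
   everything in [-1, 1];
5. assign each pair an empirical P-value: the fraction of same-class pairs
   with a strictly greater score.

The resulting table (gene, term, cell_type, score, p_value) is the contract
between the modeling and analysis phases and round-trips through CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import OntologyGraph, Subtree, extract_subtrees
from .vnn import (
    ExpressionDataset,
    TrainingConfig,
    VNNClassifier,
    VNNResults,
    compute_random_accuracy,
)

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["gene", "term", "cell_type", "score", "p_value"]


# ---------------------------------------------------------------------------
# cascade primitives (all operate on an n_pairs x n_classes score matrix)


def perturb_gene_term(
    results: VNNResults,
    X: np.ndarray,
    gene: str,
    term: str,
    baseline_counts: np.ndarray | None = None,
) -> np.ndarray:
    """Raw per-class knockout scores for one gene-term pair.

    Returns ``-(perturbed counts - baseline counts)`` over classes, where
    counts are numbers of cells the root head assigns to each class. The
    knockout zeroes the gene only in ``term``'s gene-input slot.
    """
    arch = results.architecture
    if term not in arch.specs or gene not in arch.specs[term].gene_names:
        raise KeyError(f"pair ({gene!r}, {term!r}) is not wired into this model")
    n_classes = results.model.dataset.n_classes
    if baseline_counts is None:
        baseline_counts = np.bincount(results.predict(X), minlength=n_classes)
    perturbed = np.bincount(results.predict(X, perturb=(term, gene)), minlength=n_classes)
    return -(perturbed.astype(np.float64) - baseline_counts.astype(np.float64))


def subtract_background(scores: np.ndarray) -> np.ndarray:
    """Per class, shift scores so their median over pairs is zero."""
    scores = np.asarray(scores, dtype=np.float64)
    return scores - np.median(scores, axis=0, keepdims=True)


def compute_size_factor(root_accuracy: float, class_counts) -> float:
    """Clamped, rescaled excess of root accuracy over the majority baseline."""
    if not 0.0 <= root_accuracy <= 1.0:
        raise ValueError("root accuracy must lie in [0, 1]")
    acc_random = compute_random_accuracy(class_counts)
    if acc_random >= 1.0:  # single populated class: degenerate
        return 0.0
    return max(0.0, (root_accuracy - acc_random) / (1.0 - acc_random))


def apply_size_factor(scores: np.ndarray, root_accuracy: float, class_counts) -> np.ndarray:
    return np.asarray(scores, dtype=np.float64) * compute_size_factor(root_accuracy, class_counts)


def aggregate_subtrees(per_subtree: pd.DataFrame) -> pd.DataFrame:
    """Mean score per (gene, term, cell_type) over the subtrees holding the pair.

    Input needs columns gene/term/cell_type/score (one row per subtree
    occurrence)."""
    out = (
        per_subtree.groupby(["gene", "term", "cell_type"], sort=True, as_index=False)["score"]
        .mean()
    )
    return out


def balance_and_normalize(scores: np.ndarray) -> np.ndarray:
    """Per class: rescale positives so positive and negative mass cancel,
    then divide by the maximum absolute score.

    Balancing is skipped for a class whose scores are all of one sign; an
    all-zero class stays all-zero. After normalization every class with a
    nonzero entry has max |score| exactly 1.
    """
    scores = np.asarray(scores, dtype=np.float64).copy()
    for c in range(scores.shape[1]):
        col = scores[:, c]
        pos = col > 0
        neg = col <= 0
        pos_sum = col[pos].sum()
        neg_sum = -col[neg].sum()
        if pos_sum > 0 and neg_sum > 0:
            col[pos] *= neg_sum / pos_sum
        m = np.abs(col).max()
        if m > 0:
            col /= m
        scores[:, c] = col
    return scores


def score_pvalues(scores: np.ndarray) -> np.ndarray:
    """Empirical P per entry: fraction of same-class pairs scoring strictly higher."""
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.shape[0]
    out = np.empty_like(scores)
    for c in range(scores.shape[1]):
        col = scores[:, c]
        order = np.sort(col)
        greater = n - np.searchsorted(order, col, side="right")
        out[:, c] = greater / n
    return out


# ---------------------------------------------------------------------------
# score table


@dataclass
class GeneTermScoreTable:
    """Final gene-term score table plus provenance.

    ``data`` holds one row per (gene, term, cell_type) with the final score
    in [-1, 1] and its empirical P-value.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.data["cell_type"].unique())

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.data["gene"].unique())

    def pairs(self) -> pd.DataFrame:
        return self.data[["gene", "term"]].drop_duplicates()

    def to_csv(self, path) -> None:
        df = self.data[CSV_COLUMNS].sort_values(["gene", "term", "cell_type"], kind="mergesort")
        df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "GeneTermScoreTable":
        df = pd.read_csv(path, dtype={"gene": str, "term": str, "cell_type": str})
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"malformed score CSV {path}: missing columns {missing}")
        bad = df[~np.isfinite(df["score"]) | df["score"].abs().gt(1 + 1e-9)]
        if len(bad):
            raise ValueError(f"malformed score CSV {path}: score out of [-1,1] at row {bad.index[0]}")
        return cls(data=df, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ModelingConfig:
    """Configuration of the full modeling phase (training + scoring)."""

    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0
    score_on: str = "all"  # "all" cells or "validation" held-out cells

    def subtree_seed(self, index: int) -> int:
        # distinct, reproducible per-subtree seeds below 2**31
        return int((self.seed * 1_000_003 + 7 * index + 1) % (2**31))


def score_subtree(
    results: VNNResults,
    dataset: ExpressionDataset,
    subtree_id: str,
) -> pd.DataFrame:
    """Raw -> background-corrected -> size-factor-scaled scores for one model."""
    arch = results.architecture
    X = dataset.X
    pairs = [
        (g, t)
        for t in arch.order
        for g in arch.specs[t].gene_names
    ]
    if not pairs:
        return pd.DataFrame(columns=["gene", "term", "cell_type", "score", "subtree"])
    baseline = np.bincount(results.predict(X), minlength=dataset.n_classes)
    raw = np.vstack([
        perturb_gene_term(results, X, g, t, baseline_counts=baseline) for g, t in pairs
    ])
    adj = subtract_background(raw)
    adj = apply_size_factor(adj, results.root_accuracy, results.class_counts)
    rows = []
    for (g, t), row in zip(pairs, adj):
        for c, cls in enumerate(dataset.class_names):
            rows.append((g, t, cls, row[c], subtree_id))
    return pd.DataFrame(rows, columns=["gene", "term", "cell_type", "score", "subtree"])


def run_modeling_phase(
    graph: OntologyGraph,
    dataset: ExpressionDataset,
    config: ModelingConfig | None = None,
    csv_path=None,
    subtrees: list[Subtree] | None = None,
) -> GeneTermScoreTable:
    """Train one VNN per subtree, knock out every wired gene-term pair and
    run the full correction cascade; optionally write the phase CSV.

    Deterministic for a fixed config seed: subtree order, per-subtree
    training seeds and every downstream step are derived from it.
    """
    cfg = config or ModelingConfig()
    if subtrees is None:
        subtrees = extract_subtrees(graph)
    if not subtrees:
        raise ValueError("graph has no subtrees")

    frames = []
    subtree_info = []
    for i, sub in enumerate(sorted(subtrees, key=lambda s: s.leaf)):
        tcfg = TrainingConfig(**{**vars(cfg.training), "seed": cfg.subtree_seed(i)})
        model = VNNClassifier.from_subtree(dataset, sub)
        res = model.fit(tcfg)
        frames.append(score_subtree(res, dataset, sub.leaf))
        subtree_info.append(
            {"leaf": sub.leaf, "root_accuracy": res.root_accuracy, "size_factor": res.size_factor()}
        )
        logger.info(
            "subtree %s: %d terms, root accuracy %.3f, size factor %.3f",
            sub.leaf, len(sub.members), res.root_accuracy, res.size_factor(),
        )

    per_subtree = pd.concat(frames, ignore_index=True)
    agg = aggregate_subtrees(per_subtree)

    # pivot to pairs x classes, run balancing/normalization/P-values per class
    wide = agg.pivot_table(index=["gene", "term"], columns="cell_type", values="score", sort=True)
    final = balance_and_normalize(wide.to_numpy())
    pvals = score_pvalues(final)

    classes = list(wide.columns)
    records = []
    for r, (gene, term) in enumerate(wide.index):
        for c, cls in enumerate(classes):
            records.append((gene, term, cls, final[r, c], pvals[r, c]))
    data = pd.DataFrame(records, columns=CSV_COLUMNS)

    table = GeneTermScoreTable(
        data=data,
        provenance={
            "seed": cfg.seed,
            "n_subtrees": len(subtree_info),
            "subtrees": subtree_info,
            "n_cells": dataset.n_cells,
            "n_genes": dataset.n_genes,
            "classes": list(dataset.class_names),
        },
    )
    if csv_path is not None:
        table.to_csv(csv_path)
    return table
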