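"""File formats and run configuration.

Readers/writers for the pipeline's external surfaces: OBO ontologies
(written in a minimal OBO 1.2 dialect that round-trips through obonet),
two-column TSV annotations, delimited or MatrixMarket expression matrices
with a label file, and the run configuration (YAML with strict keys).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread

from .ontology import OntologyGraph
from .synthetic import SyntheticTruth
from .vnn import ExpressionDataset, TrainingConfig


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ontology writing (reader lives in govnn.ontology via obonet)


def write_obo(graph: OntologyGraph, path) -> None:
    """Minimal OBO 1.2 serialization (id/name/namespace/is_a stanzas)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: govnn-toy\n")
        for term in sorted(graph.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {graph.names.get(term, term)}\n")
            fh.write(f"namespace: {graph.namespace.get(term, 'biological_process')}\n")
            for parent in sorted(graph.parents(term)):
                fh.write(f"is_a: {parent} ! {graph.names.get(parent, parent)}\n")


def write_annotations_tsv(graph: OntologyGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tgene\n")
        for term in sorted(graph.direct_genes):
            for gene in sorted(graph.direct_genes[term]):
                fh.write(f"{term}\t{gene}\n")


# ---------------------------------------------------------------------------
# expression


def log1p_cp10k(X: np.ndarray) -> np.ndarray:
    """Library-size normalization to 10k followed by log1p (for raw counts)."""
    X = np.asarray(X, dtype=np.float64)
    depth = X.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    return np.log1p(X / depth * 1e4)


def write_expression(dataset: ExpressionDataset, expr_path, labels_path) -> None:
    """Cells x genes CSV (header = genes, index = cell ids) + label TSV."""
    cells = [f"cell{i:05d}" for i in range(dataset.n_cells)]
    df = pd.DataFrame(dataset.X, index=cells, columns=dataset.gene_names)
    df.index.name = "cell"
    df.to_csv(expr_path, float_format="%.6g")
    with open(labels_path, "w", encoding="utf-8") as fh:
        fh.write("cell\tlabel\n")
        for cell, yi in zip(cells, dataset.y):
            fh.write(f"{cell}\t{dataset.class_names[yi]}\n")


def _read_labels(labels_path, cell_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    lab = pd.read_csv(labels_path, sep="\t", dtype=str)
    if lab.shape[1] < 2:
        raise InputError(f"label file {labels_path} needs two columns (cell, label)")
    lab = lab.set_index(lab.columns[0])[lab.columns[1]]
    missing = [c for c in cell_ids if c not in lab.index]
    if missing:
        raise InputError(f"labels missing for {len(missing)} cells (first: {missing[0]})")
    labels = [lab[c] for c in cell_ids]
    class_names = sorted(set(labels))
    lut = {c: i for i, c in enumerate(class_names)}
    return np.array([lut[v] for v in labels], dtype=np.int64), class_names


def read_expression(expr_path, labels_path, normalize: str = "none") -> ExpressionDataset:
    """Read a delimited cells x genes matrix plus labels.

    ``normalize`` is ``"none"`` (values used as-is, e.g. already
    log-normalized) or ``"log1p"`` (library-size CP10K + log1p for counts).
    """
    expr_path = Path(expr_path)
    if not expr_path.exists():
        raise InputError(f"expression file not found: {expr_path}")
    df = pd.read_csv(expr_path, index_col=0)
    X = df.to_numpy(dtype=np.float64)
    if normalize == "log1p":
        X = log1p_cp10k(X)
    elif normalize != "none":
        raise InputError(f"unknown normalization {normalize!r}")
    y, class_names = _read_labels(labels_path, [str(i) for i in df.index])
    return ExpressionDataset(X=X, y=y, gene_names=[str(c) for c in df.columns], class_names=class_names)


def read_expression_mtx(mtx_path, genes_path, cells_path, labels_path, normalize: str = "log1p") -> ExpressionDataset:
    """MatrixMarket triplet (cells x genes or genes x cells) + name/label files."""
    for p in (mtx_path, genes_path, cells_path, labels_path):
        if not Path(p).exists():
            raise InputError(f"input file not found: {p}")
    M = np.asarray(mmread(mtx_path).todense(), dtype=np.float64)
    genes = [line.strip() for line in open(genes_path, encoding="utf-8") if line.strip()]
    cells = [line.strip() for line in open(cells_path, encoding="utf-8") if line.strip()]
    if M.shape == (len(genes), len(cells)) and M.shape[0] != M.shape[1]:
        M = M.T
    if M.shape != (len(cells), len(genes)):
        raise InputError(
            f"matrix shape {M.shape} matches neither cells x genes ({len(cells)}, {len(genes)}) nor its transpose"
        )
    if normalize == "log1p":
        M = log1p_cp10k(M)
    y, class_names = _read_labels(labels_path, cells)
    return ExpressionDataset(X=M, y=y, gene_names=genes, class_names=class_names)


def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "planted": truth.planted,
                "effect_size": truth.effect_size,
                "noise_sd": truth.noise_sd,
                "seed": truth.seed,
                "cells_per_class": truth.cells_per_class,
            },
            fh,
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Declarative configuration for a full run; unknown keys are rejected."""

    ontology: str = ""
    annotations: str = ""
    expression: str = ""
    labels: str = ""
    scores: str = ""
    output_dir: str = "."
    min_genes: int = 5
    namespace: str = "biological_process"
    normalize: str = "none"
    n_perm: int = 10_000
    active_p: float = 0.01
    restart_prob: float = 0.5
    expansion_factor: int = 5
    seed: int = 0
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        if not 0 < self.active_p <= 1:
            raise InputError("active_p must be in (0, 1]")
        if not 0 < self.restart_prob <= 1:
            raise InputError("restart_prob must be in (0, 1]")
        if self.min_genes < 1 or self.n_perm < 100 or self.expansion_factor < 1:
            raise InputError("min_genes >= 1, n_perm >= 100, expansion_factor >= 1 required")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "training" in raw and isinstance(raw["training"], dict):
            tknown = {f.name for f in fields(TrainingConfig)}
            tunknown = set(raw["training"]) - tknown
            if tunknown:
                raise InputError(f"unknown training config keys: {sorted(tunknown)}")
            raw["training"] = TrainingConfig(**raw["training"])
        return cls(**raw)
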