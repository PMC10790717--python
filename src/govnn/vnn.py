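"""Visible neural networks whose wiring mirrors an ontology subtree.

Each ontology term is a small dense layer (20-50 neurons). A term's input is
the concatenation of (i) a tanh embedding of the expression of the genes
directly annotated to the term but to none of its descendants and (ii) the
output vectors of its direct child terms. Term outputs pass through
tanh + batch normalization. Every non-root term carries an auxiliary
softmax classification head; the root carries the main head. The training
objective is

    mean_i [ CE(main head, y_i) + alpha * sum_aux CE(aux head, y_i) ]
        + lambda * sum(W^2)

with alpha = 0.3 and lambda = 1e-3 by default.

The network is implemented directly in numpy (float64) with hand-derived
reverse-mode gradients and an Adam optimizer; model sizes here are small
enough that this is both fast and exactly reproducible. Follows a
model/results split: build a :class:`VNNClassifier` from data and an
architecture, call :meth:`~VNNClassifier.fit`, get back :class:`VNNResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .ontology import OntologyGraph, Subtree

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1

VIRTUAL_ROOT = "<virtual-root>"


class ArchitectureError(ValueError):
    """A term has neither gene inputs nor children, or wiring is impossible."""


class DatasetError(ValueError):
    """Expression dataset violates its contract (labels, shapes, names)."""


# ---------------------------------------------------------------------------
# data container


@dataclass
class ExpressionDataset:
    """Cells x genes expression with one class label per cell."""

    X: np.ndarray
    y: np.ndarray
    gene_names: list[str]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise DatasetError("X must be 2-D (cells x genes)")
        if self.X.shape[0] != self.y.shape[0]:
            raise DatasetError("X and y disagree on the number of cells")
        if self.X.shape[1] != len(self.gene_names):
            raise DatasetError("gene_names length does not match X columns")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise DatasetError("gene_names are not unique")
        if not np.isfinite(self.X).all():
            raise DatasetError("X contains non-finite values")
        counts = np.bincount(self.y, minlength=len(self.class_names))
        if (counts == 0).any():
            missing = [c for c, n in zip(self.class_names, counts) if n == 0]
            raise DatasetError(f"classes with zero cells: {missing}")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)


# ---------------------------------------------------------------------------
# architecture


def compute_layer_width(n_propagated_genes: int) -> int:
    """Neurons for a term annotated (directly or via descendants) with n genes.

    ``min(50, max(20, floor(0.3 * n)))`` — between 20 and 50 neurons.
    """
    if n_propagated_genes < 1:
        raise ValueError("a term must have at least one propagated gene")
    return min(50, max(20, math.floor(0.3 * n_propagated_genes)))


def compute_random_accuracy(class_counts) -> float:
    """Majority-class fraction: the accuracy of always guessing the biggest class."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts < 0).any():
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total sample count must be positive")
    return float(counts.max() / total)


@dataclass
class TermSpec:
    term: str
    gene_names: list[str]
    gene_idx: np.ndarray  # columns of X feeding this term's gene embedding
    children: list[str]
    width: int


@dataclass
class VNNArchitecture:
    """Wiring of one visible network: term order, gene slots, widths, root."""

    order: list[str]  # topological, children before parents
    specs: dict[str, TermSpec]
    root: str

    @property
    def terms(self) -> list[str]:
        return list(self.order)

    def input_dim(self, term: str) -> int:
        spec = self.specs[term]
        return len(spec.gene_idx) + sum(self.specs[c].width for c in spec.children)

    def n_parameters(self, n_classes: int = 0) -> int:
        total = 0
        for t in self.order:
            spec = self.specs[t]
            g = len(spec.gene_idx)
            total += g * g + g  # gene embedding
            total += self.input_dim(t) * spec.width + spec.width  # term linear
            total += 2 * spec.width  # batch-norm affine
            total += spec.width * n_classes + n_classes  # classification head
        return total


def _structure_graph(source: Subtree | OntologyGraph) -> tuple[nx.DiGraph, dict[str, frozenset[str]]]:
    if isinstance(source, Subtree):
        return source.graph(), dict(source.direct_genes)
    return source.graph.copy(), dict(source.direct_genes)


def build_architecture(source: Subtree | OntologyGraph, gene_names: list[str]) -> VNNArchitecture:
    """Wire a VNN mirroring a subtree (or a whole pruned graph).

    A term's gene inputs are its direct genes not annotated to any of its
    descendants within the structure; annotated genes absent from
    ``gene_names`` are dropped. Layer widths follow
    :func:`compute_layer_width` on within-structure propagated gene counts.
    Multi-rooted structures receive a virtual root concatenating the roots.
    """
    graph, direct = _structure_graph(source)
    if graph.number_of_nodes() == 0:
        raise ArchitectureError("empty structure")

    name_to_col = {g: i for i, g in enumerate(gene_names)}
    available = set(gene_names)
    direct = {t: frozenset(g for g in direct.get(t, ()) if g in available) for t in graph.nodes}

    # within-structure propagated gene sets, children-first
    topo = list(nx.topological_sort(graph))
    prop: dict[str, set[str]] = {}
    for t in topo:
        genes = set(direct[t])
        for c in graph.predecessors(t):
            genes |= prop[c]
        prop[t] = genes

    roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
    if len(roots) == 1:
        root = roots[0]
    else:
        root = VIRTUAL_ROOT
        graph.add_node(root)
        for r in roots:
            graph.add_edge(r, root)
        direct[root] = frozenset()
        prop[root] = set().union(*(prop[r] for r in roots))
        topo = list(nx.topological_sort(graph))

    specs: dict[str, TermSpec] = {}
    for t in topo:
        children = sorted(graph.predecessors(t))
        desc_genes: set[str] = set()
        for c in children:
            desc_genes |= prop[c]
        own = sorted(direct[t] - desc_genes)
        if not own and not children:
            raise ArchitectureError(f"term {t!r} has no gene inputs and no children")
        if not prop[t]:
            raise ArchitectureError(f"term {t!r} has no annotated genes in the expression matrix")
        specs[t] = TermSpec(
            term=t,
            gene_names=own,
            gene_idx=np.array([name_to_col[g] for g in own], dtype=np.int64),
            children=children,
            width=compute_layer_width(len(prop[t])),
        )
    return VNNArchitecture(order=topo, specs=specs, root=root)


# ---------------------------------------------------------------------------
# parameters, forward, backward


def init_parameters(arch: VNNArchitecture, n_classes: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-style normal init for weights; zeros for biases; identity batch norm."""
    params: dict[str, np.ndarray] = {}
    for t in arch.order:
        spec = arch.specs[t]
        g = len(spec.gene_idx)
        if g:
            params[f"{t}|Wg"] = rng.normal(0.0, 1.0 / math.sqrt(g), size=(g, g))
            params[f"{t}|bg"] = np.zeros(g)
        d_in = arch.input_dim(t)
        params[f"{t}|Wo"] = rng.normal(0.0, 1.0 / math.sqrt(d_in), size=(d_in, spec.width))
        params[f"{t}|bo"] = np.zeros(spec.width)
        params[f"{t}|gamma"] = np.ones(spec.width)
        params[f"{t}|beta"] = np.zeros(spec.width)
        params[f"{t}|Wh"] = rng.normal(0.0, 1.0 / math.sqrt(spec.width), size=(spec.width, n_classes))
        params[f"{t}|bh"] = np.zeros(n_classes)
    return params


def init_bn_state(arch: VNNArchitecture) -> dict[str, np.ndarray]:
    state = {}
    for t in arch.order:
        w = arch.specs[t].width
        state[f"{t}|mean"] = np.zeros(w)
        state[f"{t}|var"] = np.ones(w)
    return state


def _softmax(H: np.ndarray) -> np.ndarray:
    e = np.exp(H - H.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def forward(
    arch: VNNArchitecture,
    params: dict[str, np.ndarray],
    bn_state: dict[str, np.ndarray],
    X: np.ndarray,
    training: bool = False,
    perturb: tuple[str, str] | None = None,
) -> dict:
    """Run the network; returns per-term outputs, head probabilities, caches.

    ``perturb=(term, gene)`` zeroes gene's expression *in that term's gene
    slot only* — the in-silico knockout used for gene-term scoring. In
    evaluation mode batch normalization uses running statistics, so
    inference is deterministic and batch-size independent.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise DatasetError("X must be 2-D")
    cache: dict = {"O": {}, "Z": {}, "T": {}, "Tn": {}, "I": {}, "H": {}, "P": {}, "Xg": {}, "std": {}}
    for t in arch.order:
        spec = arch.specs[t]
        parts = []
        if len(spec.gene_idx):
            Xg = X[:, spec.gene_idx]
            if perturb is not None and perturb[0] == t:
                try:
                    pos = spec.gene_names.index(perturb[1])
                except ValueError as exc:
                    raise KeyError(f"gene {perturb[1]!r} is not an input of term {t!r}") from exc
                Xg = Xg.copy()
                Xg[:, pos] = 0.0
            Z = np.tanh(Xg @ params[f"{t}|Wg"] + params[f"{t}|bg"])
            cache["Xg"][t], cache["Z"][t] = Xg, Z
            parts.append(Z)
        for c in spec.children:
            parts.append(cache["O"][c])
        I = parts[0] if len(parts) == 1 else np.concatenate(parts, axis=1)
        T = np.tanh(I @ params[f"{t}|Wo"] + params[f"{t}|bo"])
        if training:
            mu = T.mean(axis=0)
            var = T.var(axis=0)
            bn_state[f"{t}|mean"] = (1 - _BN_MOMENTUM) * bn_state[f"{t}|mean"] + _BN_MOMENTUM * mu
            bn_state[f"{t}|var"] = (1 - _BN_MOMENTUM) * bn_state[f"{t}|var"] + _BN_MOMENTUM * var
        else:
            mu = bn_state[f"{t}|mean"]
            var = bn_state[f"{t}|var"]
        std = np.sqrt(var + _BN_EPS)
        Tn = (T - mu) / std
        O = params[f"{t}|gamma"] * Tn + params[f"{t}|beta"]
        cache["I"][t], cache["T"][t], cache["Tn"][t], cache["std"][t] = I, T, Tn, std
        cache["O"][t] = O
        H = np.tanh(O @ params[f"{t}|Wh"] + params[f"{t}|bh"])
        cache["H"][t] = H
        cache["P"][t] = _softmax(H)
    return cache


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    Y = np.zeros((y.shape[0], n_classes))
    Y[np.arange(y.shape[0]), y] = 1.0
    return Y


_WEIGHT_KEYS = ("Wg", "Wo", "Wh")


def objective(
    arch: VNNArchitecture,
    params: dict[str, np.ndarray],
    bn_state: dict[str, np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    alpha: float = 0.3,
    lambda_l2: float = 1e-3,
    training: bool = True,
    cache: dict | None = None,
) -> float:
    """Mean cross-entropy of the main head + alpha-weighted auxiliary heads
    + lambda times the summed squared weights."""
    if cache is None:
        cache = forward(arch, params, dict(bn_state), X, training=training)
    n = X.shape[0]
    idx = np.arange(n)
    loss = 0.0
    for t in arch.order:
        w = 1.0 if t == arch.root else alpha
        p = cache["P"][t][idx, y]
        loss += w * float(-np.log(np.clip(p, 1e-300, None)).sum()) / n
    reg = sum(
        float((v**2).sum())
        for k, v in params.items()
        if k.rsplit("|", 1)[1] in _WEIGHT_KEYS
    )
    return loss + lambda_l2 * reg


def backward(
    arch: VNNArchitecture,
    params: dict[str, np.ndarray],
    cache: dict,
    y: np.ndarray,
    n_classes: int,
    alpha: float = 0.3,
    lambda_l2: float = 1e-3,
) -> dict[str, np.ndarray]:
    """Reverse-mode gradients of :func:`objective` (training-mode batch norm)."""
    n = y.shape[0]
    Y = _one_hot(y, n_classes)
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dO: dict[str, np.ndarray] = {t: np.zeros_like(cache["O"][t]) for t in arch.order}

    for t in arch.order:
        w = 1.0 if t == arch.root else alpha
        H, P, O = cache["H"][t], cache["P"][t], cache["O"][t]
        dH = w * (P - Y) / n
        dU = dH * (1.0 - H**2)
        grads[f"{t}|Wh"] += O.T @ dU
        grads[f"{t}|bh"] += dU.sum(axis=0)
        dO[t] += dU @ params[f"{t}|Wh"].T

    for t in reversed(arch.order):
        spec = arch.specs[t]
        g = dO[t]
        Tn, T, I, std = cache["Tn"][t], cache["T"][t], cache["I"][t], cache["std"][t]
        grads[f"{t}|gamma"] += (g * Tn).sum(axis=0)
        grads[f"{t}|beta"] += g.sum(axis=0)
        dTn = g * params[f"{t}|gamma"]
        # batch-norm backward with batch statistics (biased variance)
        dT = (dTn - dTn.mean(axis=0) - Tn * (dTn * Tn).mean(axis=0)) / std
        dA = dT * (1.0 - T**2)
        grads[f"{t}|Wo"] += I.T @ dA
        grads[f"{t}|bo"] += dA.sum(axis=0)
        dI = dA @ params[f"{t}|Wo"].T
        offset = 0
        if len(spec.gene_idx):
            gdim = len(spec.gene_idx)
            dZ = dI[:, :gdim]
            Z, Xg = cache["Z"][t], cache["Xg"][t]
            dAg = dZ * (1.0 - Z**2)
            grads[f"{t}|Wg"] += Xg.T @ dAg
            grads[f"{t}|bg"] += dAg.sum(axis=0)
            offset = gdim
        for c in spec.children:
            wdt = arch.specs[c].width
            dO[c] += dI[:, offset : offset + wdt]
            offset += wdt

    for k, v in params.items():
        if k.rsplit("|", 1)[1] in _WEIGHT_KEYS:
            grads[k] += 2.0 * lambda_l2 * v
    return grads


# ---------------------------------------------------------------------------
# training configuration


@dataclass
class TrainingConfig:
    """Hyperparameters for fitting one VNN.

    ``alpha`` weights the auxiliary-head losses against the main head and
    ``lambda_l2`` scales the squared-weight penalty; the remaining fields
    are ordinary Adam/early-stopping knobs.
    """

    alpha: float = 0.3
    lambda_l2: float = 1e-3
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.lambda_l2 < 0:
            raise ValueError("alpha and lambda_l2 must be nonnegative")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


def stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split; every class keeps >= 1 training sample."""
    train_idx, val_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        n_val = min(int(round(len(idx) * fraction)), len(idx) - 1)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


# ---------------------------------------------------------------------------
# model / results


class VNNClassifier:
    """Visible-network cell-type classifier for one ontology structure.

    Parameters
    ----------
    dataset
        Expression matrix with per-cell class labels.
    architecture
        Wiring produced by :func:`build_architecture`; alternatively pass a
        :class:`~govnn.ontology.Subtree` via :meth:`from_subtree`.
    """

    def __init__(self, dataset: ExpressionDataset, architecture: VNNArchitecture):
        self.dataset = dataset
        self.architecture = architecture
        if len(np.unique(dataset.y)) < 2:
            raise DatasetError("training requires at least two classes")

    @classmethod
    def from_subtree(cls, dataset: ExpressionDataset, subtree: Subtree) -> "VNNClassifier":
        return cls(dataset, build_architecture(subtree, dataset.gene_names))

    def fit(self, config: TrainingConfig | None = None) -> "VNNResults":
        """Adam on the composite objective with early stopping on validation
        accuracy; returns the parameters of the best validation epoch."""
        cfg = config or TrainingConfig()
        data = self.dataset
        arch = self.architecture
        rng = np.random.default_rng(cfg.seed)
        tr, va = stratified_split(data.y, cfg.validation_fraction, rng)
        Xtr, ytr = data.X[tr], data.y[tr]
        Xva, yva = data.X[va], data.y[va]

        params = init_parameters(arch, data.n_classes, rng)
        bn = init_bn_state(arch)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v2 = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        best_acc = -1.0
        best_params = {k: p.copy() for k, p in params.items()}
        best_bn = {k: s.copy() for k, s in bn.items()}
        best_epoch = 0
        history: list[dict] = []
        stall = 0

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(tr))
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                if len(batch) < 2:
                    continue  # batch norm needs >= 2 samples
                Xb, yb = Xtr[batch], ytr[batch]
                cache = forward(arch, params, bn, Xb, training=True)
                loss = objective(
                    arch, params, bn, Xb, yb, data.n_classes,
                    alpha=cfg.alpha, lambda_l2=cfg.lambda_l2, cache=cache,
                )
                grads = backward(arch, params, cache, yb, data.n_classes, cfg.alpha, cfg.lambda_l2)
                step += 1
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v2[k] = beta2 * v2[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v2[k] / (1 - beta2**step)
                    params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
                epoch_loss += loss
                n_batches += 1

            val_pred = _predict_labels(arch, params, bn, Xva)
            val_acc = float((val_pred == yva).mean()) if len(yva) else float("nan")
            history.append({"epoch": epoch, "loss": epoch_loss / max(n_batches, 1), "val_accuracy": val_acc})
            if val_acc > best_acc:
                best_acc = val_acc
                best_params = {k: p.copy() for k, p in params.items()}
                best_bn = {k: s.copy() for k, s in bn.items()}
                best_epoch = epoch
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break

        return VNNResults(
            model=self,
            params=best_params,
            bn_state=best_bn,
            root_accuracy=max(best_acc, 0.0),
            class_counts=data.class_counts(),
            history=history,
            config=replace(cfg),
            best_epoch=best_epoch,
        )


def _predict_labels(arch, params, bn, X) -> np.ndarray:
    cache = forward(arch, params, dict(bn), X, training=False)
    return cache["P"][arch.root].argmax(axis=1)


@dataclass
class VNNResults:
    """Fitted visible network: best-epoch parameters plus diagnostics."""

    model: VNNClassifier
    params: dict[str, np.ndarray]
    bn_state: dict[str, np.ndarray]
    root_accuracy: float
    class_counts: np.ndarray
    history: list[dict]
    config: TrainingConfig
    best_epoch: int = 0

    @property
    def architecture(self) -> VNNArchitecture:
        return self.model.architecture

    def predict_proba(self, X: np.ndarray, perturb: tuple[str, str] | None = None) -> np.ndarray:
        cache = forward(self.architecture, self.params, dict(self.bn_state), X, training=False, perturb=perturb)
        return cache["P"][self.architecture.root]

    def predict(self, X: np.ndarray, perturb: tuple[str, str] | None = None) -> np.ndarray:
        return self.predict_proba(X, perturb=perturb).argmax(axis=1)

    def size_factor(self) -> float:
        """Clamped excess of root accuracy over the majority-class baseline,
        rescaled to [0, 1]; 0 for a classifier no better than guessing."""
        acc_random = compute_random_accuracy(self.class_counts)
        if acc_random >= 1.0:
            return 0.0
        return max(0.0, (self.root_accuracy - acc_random) / (1.0 - acc_random))

    def summary(self) -> str:
        arch = self.architecture
        data = self.model.dataset
        lines = [
            "Visible Neural Network Results",
            "==============================",
            f"Root term:            {arch.root}",
            f"Terms (layers):       {len(arch.order)}",
            f"Trainable parameters: {arch.n_parameters(data.n_classes)}",
            f"Cells:                {data.n_cells}",
            f"Genes:                {data.n_genes}",
            f"Classes:              {data.n_classes} ({', '.join(data.class_names)})",
            f"Epochs run:           {len(self.history)} (best: {self.best_epoch})",
            f"Validation accuracy:  {self.root_accuracy:.4f}",
            f"Majority baseline:    {compute_random_accuracy(self.class_counts):.4f}",
            f"Size factor:          {self.size_factor():.4f}",
        ]
        return "\n".join(lines)
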