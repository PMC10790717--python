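# Methods

## Model

`govnn` treats each Gene Ontology subtree as the scaffold of a small
feedforward classifier. The hierarchy assumption is the usual one for
visible networks: the activity of a biological process is a function of the
activities of its constituent sub-processes and of the genes annotated to
it directly. Concretely, a term's layer receives a tanh embedding of the
expression of its *exclusive* direct genes (direct genes not annotated to
any descendant inside the structure — genes shared with a descendant enter
at the most specific term) concatenated with its children's output vectors,
followed by a linear map, tanh, and batch normalization. Layer widths are
clamped to [20, 50] neurons via `min(50, max(20, floor(0.3 n)))` on the
within-structure propagated gene count n; the bracket is taken as floor.

Every non-root term carries an auxiliary softmax head so that gradient
signal reaches deep layers; the composite objective is

    mean_i [ CE(root head) + 0.3 * sum_{p != r} CE(head p) ] + 1e-3 * sum W^2

The weight penalty is implemented as the sum of squared weight-matrix
entries (biases and batch-norm affine parameters are not penalized); the
"ℓ₂ norm" wording of weight decay is conventionally ambiguous between
‖W‖₂ and ‖W‖₂², and the squared form is the standard choice with a clean
gradient.

### Training

Adam (lr 1e-3, β = 0.9/0.999), batch size 128, at most 100 epochs,
stratified 80/20 train/validation split, early stopping on validation
accuracy with patience 10, best-epoch parameters restored. None of these
are dictated by the scoring formalism; they are robust defaults and all
live in `TrainingConfig`. Batch normalization uses batch statistics during
training and running statistics at inference, so knockout scoring is
deterministic and independent of evaluation batch size. The whole network
is float64 numpy with hand-derived reverse-mode gradients; a
finite-difference check in the test suite pins the backward pass to 1e-4
relative accuracy. All randomness (init, shuffling, splits) flows from one
integer seed, which is why repeated runs are byte-identical.

A single-rooted subtree uses its root term's head as the main head;
multi-rooted structures (e.g. a whole pruned graph spanning namespaces) get
a virtual root that concatenates the roots' outputs. Gene-term scoring uses
per-subtree models.

## Ontology handling

Only `is_a` and `part_of` relations define the hierarchy (standard GO
practice). Annotations to unknown or obsolete terms are dropped with a
logged count; gene symbols are case-sensitive and deduplicated. Pruning
iterates "recompute propagated sets, drop terms below `min_genes`
(default 5)" to a fixed point and then rewires each survivor's parents to
its nearest surviving ancestors. Two consequences worth knowing:

* iteration to the fixed point is what makes pruning idempotent — removing
  a term's direct genes can push an ancestor below threshold;
* because propagated counts are monotone along child→parent edges, removal
  under this criterion is always leaf-closed, so the ancestor rewiring is a
  formality for this rule. The contraction (`contract_terms`) is exposed
  and tested separately because other removal criteria (as used in GO-slim
  style reductions) do create skipped-generation edges.

The exact pruning procedure used alongside the original scoring formalism
is not fully specified in public sources; the min-gene threshold plus
nearest-ancestor rewiring is this package's documented stand-in.

## Scoring cascade

Knockout scores are computed over all cells of the dataset (configurable in
principle to held-out cells only; using all cells maximizes the resolution
of the predicted-count change, which is integer-valued). Per subtree and
class, scores are centred by the median over pairs (midpoint convention for
even counts). The size factor rescales a subtree's scores by how much its
root beats the majority-class baseline, clamping uninformative subtrees to
zero. Pair scores are averaged over exactly the subtrees that contain the
pair. Sign balancing and the [−1, 1] rescaling are applied per cell type
(the balancing identity Σpos = Σ|neg| and the unit-max bound are enforced
per class; an all-positive, all-negative or all-zero class skips the
inapplicable step). Empirical P-values use strict exceedance, so tied
scores share a P-value and the class maximum has P = 0.

A gene-term pair is scoreable in a subtree iff the gene sits in that term's
exclusive gene slot there; a pair whose gene is always captured by a more
specific descendant never receives a score and is absent from the table.

## Analysis phase

The background universe is every gene annotated in the pruned graph.
Permutation tests draw size-matched gene sets uniformly from that universe
(the query itself is not excluded) and use add-one smoothing,
P = (1 + #{perm ≥ obs}) / (1 + n_perm), so reported P-values are never
exactly zero; n_perm defaults to 10 000. z-scores use the permutation mean
and sd (ddof 1) and are reported as missing when the sd is zero. The
cell-type K–S test is one-sided with the query sample first
(`alternative='less'`), i.e. small P means query scores are stochastically
larger than background.

The Fisher over-representation baseline uses the standard 2×2 ORA table
[[k, q−k], [p−k, N−q−p+k]] with alternative 'greater'; an exhaustive
comparison against the explicit hypergeometric tail sum is part of the
acceptance suite.

RWR runs on the undirected, unweighted parent–child term graph of one
namespace (default biological_process; a flag switches namespaces), restart
probability 0.5, uniform restart over the active-pathway seeds, solved
exactly as (I − (1−r)W)a = r·e with column-stochastic W (isolated nodes
get a self-loop so the affinity mass is conserved). The expanded set is the
seeds plus the `expansion_factor × |seeds|` (default 5×) highest-affinity
nodes. Communities come from a seeded Leiden modularity partition
(`leidenalg.ModularityVertexPartition`); the partitioning algorithm is
deliberately pluggable — any deterministic modularity partitioner satisfies
the contract. Community significance is mean(min(4, −log₁₀ P)) over member
pathways, with expanded non-seed pathways entering at their own permutation
P when testable and P = 1 otherwise; a community is active when its
significance exceeds −log₁₀(ActiveP) (ActiveP default 0.01), and active
communities smaller than the mean active-community size are dropped from
the report. Community topics are summarized mechanically as the member
pathways with the smallest P-values.

## Synthetic data

The generator emulates exactly the structure the model assumes: a small
single-rooted DAG (default 12 terms, 150 genes, every term ≥ 5 propagated
genes), and cells from C classes (default 3 × 100 cells) whose identity is
carried by the direct genes of one driver leaf per class, shifted by a
fixed effect size (default 2.0) over shared per-gene baselines
(Normal(1, 0.5)) with Gaussian log-scale noise (sd default 1.0). These
defaults are the study conditions for all planted-recovery checks: a
moderate ~2σ module shift on ~10 genes per class, learnable but not
trivial. The generator does *not* model dropout, library-size variation,
batch effects or doublets, so passing tests demonstrate correct method
mechanics and signal recovery under idealized noise — not performance on
real scRNA-seq. A negative-binomial count layer (dispersion 10) is
available behind a flag for exercising the count-normalization path.

## Problem sizes in the acceptance suite

The planted-recovery check runs the full pipeline (3 classes, ~12 terms,
~150 genes, 300 cells, ≤ 40 epochs per subtree) over five generator seeds;
the calibration check uses 200 null queries at 1000 permutations; the
Fisher-vs-hypergeometric comparison is exhaustive for universes ≤ 40 and
randomized (2000 tables) for 41–60. These sizes were chosen so each
property is tested at full strength while the whole suite stays fast on a
single CPU.

## Known limitations

* Gradient-based training at real-GO scale (thousands of subtrees) is out
  of scope; the implementation is tuned for correctness and exact
  reproducibility at desk scale, not throughput.
* Per-subtree models use a single stratified validation split rather than
  cross-validation; root-accuracy estimates on small datasets are
  correspondingly noisy (the size factor clamps, but does not remove, that
  noise).
* Whether expression should be log-normalized before entering the gene
  embeddings is data-dependent; readers expose `normalize={none, log1p}`
  and the generator emits log-scale values directly.
* Knockout perturbation is hard zeroing only; fold-change-style
  perturbations and non-ontology networks (e.g. PPI) are not supported.
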