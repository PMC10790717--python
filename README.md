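# govnn

Cell-type-specific gene and pathway activity from ontology-shaped visible
neural networks.

Standard pathway analysis (over-representation, gene-set enrichment) ignores
the biological context in which a pathway acts: a gene set may be "enriched"
for a pathway that is only active in one cell type of a tissue. `govnn`
addresses this for people who have a gene or gene list (GWAS hits, DEGs,
knockout targets) and labelled single-cell expression of the tissue of
interest. It learns how signal propagates along the Gene Ontology (GO)
hierarchy inside each cell type, then scores which pathways a query gene set
activates *per cell type*.

## The method

**Modeling phase.** The annotated GO DAG is pruned (terms with fewer than
`min_genes` propagated genes are removed, children rewired to their nearest
surviving ancestors) and decomposed into *subtrees*: each leaf term plus all
of its ancestors. Every subtree becomes a visible neural network (VNN) whose
wiring mirrors the hierarchy. For term *p* with direct-gene inputs
*g⁽ᵖ⁾* (genes of *p* not annotated to any descendant) and children
child⁽ᵖ⁾:

    Z⁽ᵖ⁾ = tanh(Linear(X_{g⁽ᵖ⁾}))
    I⁽ᵖ⁾ = concat(Z⁽ᵖ⁾, {O⁽ᵖ'⁾ : p' ∈ child⁽ᵖ⁾})
    O⁽ᵖ⁾ = BatchNorm(tanh(Linear(I⁽ᵖ⁾)))

with per-term width L⁽ᵖ⁾ = min(50, max(20, ⌊0.3·n⁽ᵖ⁾⌋)) for n⁽ᵖ⁾
propagated genes. The root carries the main softmax head predicting the
cell-type label; every other term carries an auxiliary head weighted by
α = 0.3, plus an ℓ₂ weight penalty (λ = 10⁻³).

The **gene-term score (GTS)** S_gp,c of a directly annotated pair (g, p) in
cell type c is obtained by an in-silico knockout: zero gene g's input to
term p only, re-classify all cells, and take minus the change in the number
of cells predicted as c. Raw scores are median-centred per subtree and class,
scaled by the subtree's *size factor*
max(0, (acc_root − acc_random)/(1 − acc_random)) where acc_random is the
majority-class fraction, averaged over subtrees containing the pair,
sign-balanced and normalized to [−1, 1] per class, and given empirical
P-values (fraction of same-class pairs scoring strictly higher). The phase
emits a CSV with columns `gene,term,cell_type,score,p_value`.

**Analysis phase.** For a query gene set, a gene's **GPPAS** for pathway p is
the mean of its GTSs over p and p's descendants; the pathway's **ctPAS** is
the sum of GPPASs over query genes annotated under p, tested against
size-matched random gene sets (permutation P and z-score). Cell-type-level
activation is a one-sided two-sample Kolmogorov–Smirnov test of query-gene
GTSs against the background. Active pathways (P ≤ 0.01) seed a random walk
with restart on the term graph; the expanded network is partitioned into
communities scored by mean(min(4, −log₁₀ P)). Each active pathway also
reports its most active gene (largest GPPAS) and a classical Fisher ORA
P-value as a baseline.

The VNN is implemented directly in numpy (float64) with analytic
reverse-mode gradients and Adam, which keeps training exactly reproducible
from a single seed.

## Worked example

```python
from govnn import (GeneSetAnalysis, ModelingConfig, TrainingConfig,
                   planted_fixture, run_modeling_phase)

# toy ontology (12 terms, 150 genes) + 300 cells from 3 classes whose
# identity is planted in the direct genes of one driver leaf per class
graph, cells, truth = planted_fixture(seed=1)

table = run_modeling_phase(
    graph, cells, ModelingConfig(training=TrainingConfig(max_epochs=40), seed=1))
print("pairs scored:", len(table.pairs()), "| rows:", len(table.data))

ana = GeneSetAnalysis(table, graph, n_perm=1000, seed=1)
result = ana.analyze(truth.driver_genes("ct0"), mode="geneset-basic")
print(result.cell_types.to_string(index=False))
```

prints

```
pairs scored: 176 | rows: 528
cell_type  statistic      p_value  testable  n_active_pathways
      ct0   0.987730 6.622191e-18  True                      9
      ct1   0.006135 9.934744e-01  True                      0
      ct2   0.012270 9.860207e-01  True                      0
```

Querying the ten genes planted for class `ct0` singles out `ct0` both by the
K–S enrichment (P ≈ 7·10⁻¹⁸ versus ≈ 1 for the other classes) and by the
active-pathway count (9 versus 0). The top pathway rows for `ct0` carry
permutation P ≈ 0.001 — the smoothed minimum at 1000 permutations — and the
planted driver term `GO:7000009` is among them, with the most active gene
drawn from the planted module.

The same pipeline is available from the shell:

```
govnn simulate --out fix --seed 1
govnn model --ontology fix/ontology.obo --annotations fix/annotations.tsv \
            --expression fix/expression.csv --labels fix/labels.tsv --out run --seed 1
govnn analyze --scores run/gts.csv --ontology fix/ontology.obo \
              --annotations fix/annotations.tsv --genes query.txt \
              --mode geneset-complete --out results
```

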