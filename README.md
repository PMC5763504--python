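# tdfe — tensor-decomposition based unsupervised feature extraction

`tdfe` selects genes that behave as coordinated outliers in multi-way
expression designs (gene × tissue × treatment × ...), without using any
per-gene test statistic defined from the experimental labels.  It is aimed
at transcriptomics studies where the quantity of interest is not
"differential in condition A vs B" but "coexpressed across a specific
combination of conditions" — for example, genes responding to stress in a
specific subset of tissues.

## Method

An expression array is formatted as a tensor *x*<sub>i,j₁,…,j_m</sub>
(gene *i*, condition indices *j_k*) and decomposed by full higher-order
singular value decomposition (HOSVD):

> *x*<sub>i,j₁,…,j_m</sub> = Σ<sub>ℓ₁…ℓ_{m+1}</sub>
> *G*(ℓ₁,…,ℓ_{m+1}) · *x*<sub>ℓ_{m+1},i</sub> · Π<sub>k</sub> *x*<sub>ℓ_k,j_k</sub>

where each factor matrix is orthonormal and *G* is the core tensor.
Condition singular value vectors with an interpretable pattern (e.g. a
control-vs-treated sign flip, or coexpression of a tissue subset) are
identified by projection contrasts; the gene singular value vectors most
strongly coupled to them — the set **Ω** — are read off the core-tensor
ranking (largest |*G*| with the condition indices fixed).  Each gene then
receives

> *S*<sub>i</sub> = Σ<sub>ℓ∈Ω</sub> (*x*<sub>ℓ,i</sub> / σ<sub>ℓ</sub>)²,
> &nbsp;&nbsp; *P*<sub>i</sub> = Pr[χ²<sub>|Ω|</sub> > *S*<sub>i</sub>],

and genes with Benjamini–Hochberg adjusted *P* < 0.01 are selected as
outliers.  A built-in benchmark plants block signals in a synthetic
gene × tissue × treatment tensor and scores recovery (TPR/FPR/AUC and
cluster recovery of the planted sets).  A five-mode pipeline for a murine
stress (PTSD) study — GEO Series Matrix in, selected probes and
per-condition validation t-tests out — is included.

## Worked example

```python
from tdfe import SyntheticSpec, generate, hosvd, choose_omega, run_selection
from tdfe import cluster_genes, confusion_table

spec = SyntheticSpec(seed=1)            # 30,000 genes × 10 tissues × 10 treatments
tensor, truth = generate(spec)           # 10 sets × 100 genes planted, N(4,1)
decomp = hosvd(tensor)
omega = choose_omega(decomp, n_vectors=11)          # core-ranked gene vectors
result = run_selection(decomp.factors[0], omega, threshold=0.01)
print(len(result.selected))                          # 830
print(sum(truth.is_active[list(result.selected)]))   # 829

labels = cluster_genes(decomp.factors[0], result.selected, method="ward", k=11)
table = confusion_table(labels, truth, result.selected)
print(all(table[s].max() > table[s].sum() / 2 for s in range(10)))  # True
```

Of the 30,000 genes, 830 are selected at BH-adjusted *P* < 0.01; 829 of
them belong to the 1,000 planted signal genes (one false positive), and
Ward clustering of the selected genes in the space of the first ten gene
singular value vectors recovers every planted set with a strict-majority
cluster.

The same pipeline is available from the shell:

```
tdfe simulate --seed 1 --trials 10 --out-dir runs/sim
tdfe geo-pipeline GSE68077_series_matrix.txt --out-dir runs/geo
tdfe ttest GSE68077_series_matrix.txt runs/geo/selected_probes.txt
```

(The Series Matrix file is a local path; the tool never downloads.)

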