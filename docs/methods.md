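# Methods

## Model and procedure

`tdfe` treats a multi-way expression design as a dense real tensor with one
gene mode and one mode per experimental factor.  The analysis has four
stages.

**1. Decomposition.**  The tensor is decomposed by full (untruncated)
higher-order SVD: the factor matrix of every mode is the matrix of left
singular vectors of that mode's unfolding, and the core tensor is the data
contracted with all factor transposes.  No Tucker-rank optimization (HOOI)
is performed — the plain HOSVD is the method; it is exact, norm-preserving
and all-orthogonal, so the magnitude of a core entry
*G*(ℓ₁,…,ℓ_{m+1}) measures how much the combination of one singular value
vector per mode contributes to the data.

**2. Vector identification.**  Condition vectors of interest are found by
projection contrasts on the factor columns: a treatment-difference vector
maximizes |(+1,−1)·column|, a tissue-coexpression vector maximizes the
absolute projection of a ±1 membership vector.  This replaces visual
inspection of factor plots with a deterministic rule; both choices can be
overridden.

**3. Ω choice.**  With the identified condition indices fixed, core entries
are ranked by |*G*| (ties broken by lexicographic index) and distinct
gene-mode indices are collected from the top until the requested number is
reached.  These gene singular value vectors form Ω.

**4. Selection.**  Each gene's statistic is the sum over Ω of its squared
standardized components, S_i = Σ_{ℓ∈Ω} (x_{ℓ,i}/σ_ℓ)², where σ_ℓ is the
sample standard deviation (denominator n−1, the R `sd` convention) of
vector ℓ over all genes.  Under the null that standardized components are
independent standard normals, S_i ~ χ² with |Ω| degrees of freedom; the raw
P-value is the upper tail.  Adjustment is Benjamini–Hochberg by default;
selection is strict ("adjusted P **less than** the threshold", default
0.01), so ties at exactly the threshold are excluded.  An empirical-null
local-FDR adjustment (probit-transformed P-values through statsmodels'
`local_fdr`) is available but flagged experimental; all headline numbers
use BH.

The χ² assumption is a working approximation: gene singular value vectors
are unit-norm and mutually orthogonal, so their components are neither
exactly normal nor independent.  The null-calibration test shows the
approximation is accurate in the bulk (the fraction of raw P below α
matches α within binomial error for i.i.d. normal factors); what matters
operationally is the extreme tail, where genuine outliers concentrate.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `n_vectors` (Ω size, staged/GEO) | 3 | distinct gene vectors coupled to the fixed condition vectors |
| `n_omega` (synthetic benchmark) | 11 | one background direction + one per planted set |
| `threshold` | 0.01 | BH-adjusted P cut, strict inequality |
| `first_vectors` (clustering) | 10 | gene-factor coordinates used as cluster space |
| `k` (clustering) | 11 | Ward cut size / max mixture components (10 sets + background) |

The Ω size of 11 for the synthetic benchmark reflects the generator's
structure (10 planted set directions plus the global-mean direction); it is
a flag, not a constant.

## Synthetic generator

`SyntheticSpec` defaults describe the benchmark conditions: 30,000 genes ×
10 tissues × 10 treatments; 10 gene sets of 100 genes; the genes of set *t*
are expressed under treatment *t* in 4 of the 10 tissues with values drawn
N(4, 1); every other cell is N(0, 1); each (tissue, treatment) sample is
then standardized to mean 0, variance 1 across genes (population
denominator).  The exact tissue layout of the blocks is not part of the
method's contract; the default mask assigns treatment *t* the tissues
{t, t+1, t+2, t+3 (cyclic)}, and a seeded random mask is available.  The
method is pattern-agnostic, so recovery results do not depend on this
choice.

What the generator does *not* emulate: probe-level noise structure,
correlated gene-gene backgrounds, batch effects, missing design cells, or
non-Gaussian expression distributions.  Passing benchmarks therefore
demonstrate correct mechanics and calibration under idealized noise, not
performance on any particular real platform.

A note on scale: the selection statistic's separation between planted and
background genes grows with the gene count (set-direction components scale
like 1/√(set size) while σ_ℓ scales like 1/√n), so at the full 30,000-gene
default the BH-0.01 selection recovers most planted genes (~830 selected,
one false positive in the worked example), while desk-scale runs at 3,000
genes select very few genes at 0.01 even though the AUC is ≈ 1 and the FPR
is ≈ 0.  Benchmark assertions at reduced scale therefore bound FPR and AUC
rather than TPR; cluster-recovery checks run at the full default size
(a single trial takes seconds).

## Cluster recovery

Selected genes are clustered in the space of the first `first_vectors`
gene singular value vectors: Ward agglomeration (scipy `linkage`/`fcluster`)
cut into exactly k clusters, or Gaussian mixtures with 1..k components and
the count chosen by minimum BIC (fixed random state for determinism).
Recovery is summarized by a (sets+1) × clusters confusion table — the last
row is background — and the criterion "every planted set has a
strict-majority cluster".  Greedy Ward agglomeration is not guaranteed to
find the globally SS-optimal partition under merge ties (e.g. equally
spaced collinear points), which the tests document by comparing against an
independent greedy Lance–Williams oracle.

## Study pipeline (five-mode design)

The murine stress-study pipeline parses a GEO Series Matrix text file,
removes probes whose names start with "EA", standardizes each sample to
mean 0 / variance 1 (population denominator, applied **before** replicate
averaging — the order matters and is asserted by a fixture), and averages
replicates into a gene × treatment(2) × tissue(10) × duration(2) × rest(3)
tensor, zero-filling design cells that were never measured (6 weeks of rest
after 5 days of stress).  Values are used as deposited — no log transform.
All label-dialect knowledge for the sample characteristics lives in a
single keyword table in `tdfe.geo`, so a different metadata wording touches
one mapping.  The tool never downloads; it takes a local file path.

Validation t-tests compare control vs treated samples of the selected
probe set in each (tissue, duration, rest) combination having both groups
(40 in the encoded study design).  The default form is a Welch two-sample
test on per-sample mean expression of the probe set; a paired-by-probe
variant is available because the aggregation level of such summary tests
is a genuine modelling choice.  P-values are BH-adjusted across the
combinations.

## Numerical choices

- Unfolding column order: remaining modes in original order, earlier modes
  varying slowest; frozen so serialized unfoldings and tests are stable
  (reconstruction is convention-invariant).
- Factor rank: min(dim, product of other dims) columns per mode — beyond
  that the singular values are exactly zero; this keeps the gene factor at
  n_genes × (product of condition dims) instead of n_genes².
- Sign convention: each factor column's largest-|entry| component is made
  positive, the core absorbs the flip.  The selection statistic is
  sign-invariant; the convention only makes logged vectors reproducible.
  Signed core values under other conventions may differ in sign.
- Tie-breaks: lexicographic lowest index everywhere (core ranking, contrast
  identification), for determinism.
- Degenerate inputs raise: non-finite tensors, zero-variance vectors in Ω,
  constant sample columns, empty Ω, thresholds outside (0,1).
- Zero-variance t-test groups yield t = 0, P = 1 (no evidence) rather than
  NaN.

## Limitations

- Full HOSVD densifies: memory is O(Π dims) and the SVD of the gene-mode
  unfolding dominates cost.  Fine up to ~10⁵ genes × a few hundred
  condition cells; not intended for single-cell-sized condition modes.
- The χ² null is approximate (see above); adjusted P-values are best read
  as a ranking with FDR-scale calibration, not exact error probabilities.
- Ω identification assumes the contrasts of interest are expressible as ±1
  patterns on single modes.
- The Series Matrix parser handles the standard single-platform layout;
  multi-platform series should be split upstream.
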