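"""Outlier gene selection from gene singular value vectors.

Given the gene-mode factor matrix of a HOSVD and a chosen set Ω of gene
singular value vectors, each gene i receives the statistic

    S_i = sum_{l in Ω} (x_{l,i} / sigma_l)^2,

where ``x_{l,i}`` is gene i's component in the l-th gene singular value
vector and ``sigma_l`` that vector's standard deviation over all genes.
Under the null that the standardized components are independent standard
normals, S_i follows a chi-squared distribution with |Ω| degrees of freedom;
the raw P-value is its upper tail.  P-values are then adjusted for
multiplicity (Benjamini–Hochberg by default) and genes with adjusted
P strictly below the threshold are selected as outliers.

``sigma_l`` uses the sample standard deviation (denominator n-1), the
convention of R's ``sd``; with tens of thousands of components the choice is
numerically immaterial but is frozen here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tensor import HOSVDResult, rank_core

__all__ = [
    "OmegaSet",
    "SelectionResult",
    "score_genes",
    "adjust_pvalues",
    "select_genes",
    "choose_omega",
    "run_selection",
]


@dataclass(frozen=True)
class OmegaSet:
    """The set Ω of gene singular value vectors used for selection.

    Indices are 1-based ℓ values into the gene-mode factor's columns.
    """

    indices: tuple[int, ...]
    provenance: str = "manual"  # "manual" | "core-ranked"

    def __post_init__(self) -> None:
        idx = tuple(sorted({int(i) for i in self.indices}))
        if not idx:
            raise ValueError("Ω must be non-empty")
        if idx[0] < 1:
            raise ValueError("Ω indices are 1-based and must be >= 1")
        if self.provenance not in ("manual", "core-ranked"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class SelectionResult:
    """Per-gene statistic, P-values and the selected outlier genes."""

    statistic: np.ndarray
    p_raw: np.ndarray
    omega: OmegaSet
    sigma: dict[int, float]
    p_adjusted: np.ndarray | None = None
    adjust_method: str | None = None
    threshold: float | None = None
    selected: tuple | None = None
    gene_ids: tuple | None = None


def score_genes(gene_factor: np.ndarray, omega: OmegaSet) -> SelectionResult:
    """Compute S_i and its raw chi-squared upper-tail P for every gene.

    ``gene_factor`` is (n_genes × rank) with gene singular value vectors as
    columns.  Raises if Ω points past the factor rank or at a zero-variance
    vector.
    """
    gene_factor = np.asarray(gene_factor, dtype=float)
    rank = gene_factor.shape[1]
    if max(omega.indices) > rank:
        raise ValueError(
            f"Ω index {max(omega.indices)} exceeds gene-factor rank {rank}"
        )
    cols = gene_factor[:, [l - 1 for l in omega.indices]]
    sigma = cols.std(axis=0, ddof=1)
    if np.any(sigma <= 0) or not np.all(np.isfinite(sigma)):
        bad = [l for l, s in zip(omega.indices, sigma) if not s > 0]
        raise ValueError(f"zero-variance gene singular value vector(s) in Ω: {bad}")
    statistic = np.sum((cols / sigma) ** 2, axis=1)
    p_raw = stats.chi2.sf(statistic, df=len(omega))
    return SelectionResult(
        statistic=statistic,
        p_raw=p_raw,
        omega=omega,
        sigma={l: float(s) for l, s in zip(omega.indices, sigma)},
    )


def adjust_pvalues(p_raw: Sequence[float], method: str = "BH") -> np.ndarray:
    """Adjust raw P-values for multiplicity.

    ``"BH"`` is the Benjamini–Hochberg step-up with cumulative-minimum
    enforcement, capped at 1.  ``"local-fdr"`` is an experimental
    empirical-null local false discovery rate estimate on probit-transformed
    P-values; it is provided for exploration and is not used for any
    headline selection.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_raw must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("P-values must lie in [0, 1]")
    if method == "BH":
        return multipletests(p, method="fdr_bh")[1]
    if method == "local-fdr":
        from statsmodels.stats.multitest import local_fdr

        z = stats.norm.isf(np.clip(p, 1e-300, 1 - 1e-16))
        fdr = local_fdr(z)
        return np.clip(fdr, 0.0, 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


def select_genes(
    result: SelectionResult,
    threshold: float,
    gene_ids: Sequence | None = None,
) -> list:
    """Genes with adjusted P strictly below ``threshold``, in input order.

    Ties at exactly the threshold are excluded ("less than").
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if result.p_adjusted is None:
        raise ValueError("adjust P-values before selecting (p_adjusted is None)")
    ids = list(gene_ids) if gene_ids is not None else list(range(len(result.p_raw)))
    if len(ids) != len(result.p_raw):
        raise ValueError("gene_ids length does not match the number of genes")
    return [g for g, p in zip(ids, result.p_adjusted) if p < threshold]


def choose_omega(
    result: HOSVDResult,
    fixed: Mapping[int | str, int] | None = None,
    n_vectors: int = 3,
    gene_mode: int | str = 0,
) -> OmegaSet:
    """Pick Ω by walking the core-tensor ranking.

    Core entries matching the ``fixed`` condition-mode indices are visited in
    decreasing |G|; distinct gene-mode ℓ indices are collected until
    ``n_vectors`` are found.  This automates reading the top-ranked core
    table: the gene singular value vectors most strongly coupled to the fixed
    condition vectors.
    """
    if n_vectors < 1:
        raise ValueError("n_vectors must be >= 1")
    k_gene = result.mode_index(gene_mode)
    seen: list[int] = []
    for entry in rank_core(result, fixed):
        l_gene = entry.index_tuple[k_gene]
        if l_gene not in seen:
            seen.append(l_gene)
        if len(seen) == n_vectors:
            return OmegaSet(indices=tuple(seen), provenance="core-ranked")
    raise ValueError(
        f"only {len(seen)} distinct gene-mode indices available, {n_vectors} requested"
    )


def run_selection(
    gene_factor: np.ndarray,
    omega: OmegaSet,
    threshold: float = 0.01,
    method: str = "BH",
    gene_ids: Sequence | None = None,
) -> SelectionResult:
    """Score, adjust and select in one pass; returns a complete result."""
    result = score_genes(gene_factor, omega)
    p_adj = adjust_pvalues(result.p_raw, method=method)
    result = replace(result, p_adjusted=p_adj, adjust_method=method, threshold=threshold)
    ids = tuple(gene_ids) if gene_ids is not None else tuple(range(len(result.p_raw)))
    selected = tuple(select_genes(result, threshold, gene_ids=ids))
    return replace(result, selected=selected, gene_ids=ids)
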