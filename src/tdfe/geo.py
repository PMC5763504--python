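"""Five-mode PTSD study pipeline: GEO Series Matrix → tensor → selection.

The study (GEO accession GSE68077) profiled mice exposed to restraint stress
versus controls, across ten tissues, two stress durations and up to three
rest periods after stress.  The pipeline here:

1. parses the Series Matrix text file (``!``-prefixed metadata lines plus a
   tab-delimited expression table between the table begin/end markers),
2. removes probes whose names start with ``"EA"``,
3. standardizes every sample column to mean 0 and variance 1 (population
   denominator, so the stated variance is exactly 1),
4. averages replicates into the cells of a five-mode tensor
   gene × treatment(2) × tissue(10) × duration(2) × rest(3), zero-filling
   design cells with no samples (e.g. 6 weeks of rest after 5 days of
   stress was not measured),
5. decomposes the tensor by HOSVD, identifies the treatment-difference
   singular value vector (contrast +1/-1 over control/stress) and the
   tissue vector expressing amygdala/hippocampus/heart coexpression
   (membership contrast), walks the core ranking for Ω, and selects outlier
   probes at an adjusted-P threshold,
6. validates the selected probe set by Welch t-tests between control and
   treated samples in every (tissue, duration, rest) combination that has
   both groups, with BH adjustment across combinations.

Index codes follow the study design: treatment 1=control, 2=stress; tissues
1..10 = AY (amygdala), HC (hippocampus), MPFC (medial prefrontal cortex),
SE (septal nucleus), ST (striatum), VS (ventral striatum), blood, heart,
hemibrain, spleen; stress duration 1=10 days, 2=5 days; rest period
1=1.5 weeks, 2=24 hours, 3=6 weeks.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .selection import OmegaSet, SelectionResult, choose_omega, run_selection
from .tensor import DenseTensor, HOSVDResult, find_contrast_vector, hosvd

__all__ = [
    "TISSUES",
    "DURATIONS",
    "REST_PERIODS",
    "TREATMENTS",
    "SampleRecord",
    "StudyDesign",
    "ExpressionMatrix",
    "parse_series_matrix",
    "filter_probes",
    "standardize_samples",
    "assemble_tensor",
    "run_ptsd_analysis",
    "ttest_combinations",
    "TABLE_REPLICATES",
    "testable_combinations",
]

# ordered category labels; position+1 is the design index code
TREATMENTS = ("control", "stress")
TISSUES = ("AY", "HC", "MPFC", "SE", "ST", "VS", "blood", "heart", "hemibrain", "spleen")
DURATIONS = ("10 days", "5 days")
REST_PERIODS = ("1.5 weeks", "24 hours", "6 weeks")

# All label-dialect knowledge for sample characteristics lives in this one
# mapping: lower-cased keyword -> (field, 1-based index code).  Longer
# keywords are matched first so "ventral striatum" wins over "striatum".
_KEYWORDS: list[tuple[str, str, int]] = [
    ("medial prefrontal cortex", "tissue", 3),
    ("ventral striatum", "tissue", 6),
    ("septal nucleus", "tissue", 4),
    ("hippocampus", "tissue", 2),
    ("hemibrain", "tissue", 9),
    ("amygdala", "tissue", 1),
    ("striatum", "tissue", 5),
    ("spleen", "tissue", 10),
    ("blood", "tissue", 7),
    ("heart", "tissue", 8),
    ("mpfc", "tissue", 3),
    ("10 days", "duration", 1),
    ("10 day", "duration", 1),
    ("5 days", "duration", 2),
    ("5 day", "duration", 2),
    ("1.5 weeks", "rest", 1),
    ("1.5 week", "rest", 1),
    ("24 hours", "rest", 2),
    ("24 hrs", "rest", 2),
    ("24 hr", "rest", 2),
    ("24h", "rest", 2),
    ("6 weeks", "rest", 3),
    ("6 week", "rest", 3),
    ("control", "treatment", 1),
    ("non-stressed", "treatment", 1),
    ("unstressed", "treatment", 1),
    ("stress", "treatment", 2),
]


@dataclass(frozen=True)
class SampleRecord:
    """Design annotation of one sample (all condition codes 1-based)."""

    sample_id: str
    treatment: int
    tissue: int
    duration: int
    rest: int
    replicate: int = 1


@dataclass(frozen=True)
class StudyDesign:
    """Per-sample annotations mapping expression columns into tensor cells."""

    records: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        for r in self.records:
            if r.treatment not in (1, 2):
                raise ValueError(f"{r.sample_id}: treatment code {r.treatment}")
            if not 1 <= r.tissue <= len(TISSUES):
                raise ValueError(f"{r.sample_id}: tissue code {r.tissue}")
            if r.duration not in (1, 2):
                raise ValueError(f"{r.sample_id}: duration code {r.duration}")
            if not 1 <= r.rest <= len(REST_PERIODS):
                raise ValueError(f"{r.sample_id}: rest code {r.rest}")

    def __len__(self) -> int:
        return len(self.records)

    def by_sample(self) -> dict[str, SampleRecord]:
        return {r.sample_id: r for r in self.records}

    def replicate_counts(self) -> dict[tuple[int, int, int, int], int]:
        """Counts per (treatment, tissue, duration, rest) design cell."""
        counts: dict[tuple[int, int, int, int], int] = {}
        for r in self.records:
            key = (r.treatment, r.tissue, r.duration, r.rest)
            counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probes × samples expression values (pandas DataFrame wrapper)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe identifiers: {dupes[:5]}")

    @property
    def probes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def _parse_characteristics(sample_id: str, text: str) -> SampleRecord | None:
    """Extract design codes from the concatenated metadata of one sample."""
    low = text.lower()
    found: dict[str, int] = {}
    for keyword, fld, code in _KEYWORDS:
        if fld not in found and keyword in low:
            found[fld] = code
    missing = [f for f in ("treatment", "tissue", "duration", "rest") if f not in found]
    if missing:
        return None
    return SampleRecord(
        sample_id=sample_id,
        treatment=found["treatment"],
        tissue=found["tissue"],
        duration=found["duration"],
        rest=found["rest"],
    )


def parse_series_matrix(path) -> tuple[ExpressionMatrix, StudyDesign]:
    """Parse a GEO Series Matrix text file.

    Returns the expression table (probes × samples) and the per-sample study
    design parsed from the ``!Sample_*`` metadata lines.  Samples whose
    characteristics cannot be mapped to all four design fields are reported
    in a single error rather than silently dropped.
    """
    meta_rows: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                meta_rows.append(
                    [f.strip('"') for f in line.split("\t")]
                )
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix_table_begin/end block found")

    table = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    table.index = table.index.astype(str)
    matrix = ExpressionMatrix(data=table.astype(float))

    accessions: list[str] = []
    per_sample_text: list[list[str]] = []
    for row in meta_rows:
        key, values = row[0], row[1:]
        if key == "!Sample_geo_accession":
            accessions = values
            per_sample_text = [[] for _ in values]
        elif accessions and len(values) == len(accessions):
            for i, v in enumerate(values):
                per_sample_text[i].append(v)
    if not accessions:
        raise ValueError(f"{path}: no !Sample_geo_accession metadata line")

    records: list[SampleRecord] = []
    unparseable: list[str] = []
    meta_by_acc = dict(zip(accessions, per_sample_text))
    for sample_id in matrix.samples:
        text = " | ".join(meta_by_acc.get(sample_id, []))
        rec = _parse_characteristics(sample_id, text)
        if rec is None:
            unparseable.append(sample_id)
        else:
            records.append(rec)
    if unparseable:
        raise ValueError(
            "samples with unparseable design characteristics: "
            + ", ".join(unparseable)
        )

    # replicate indices within each design cell, in column order
    counters: dict[tuple[int, int, int, int], int] = {}
    numbered = []
    for r in records:
        key = (r.treatment, r.tissue, r.duration, r.rest)
        counters[key] = counters.get(key, 0) + 1
        numbered.append(
            SampleRecord(
                r.sample_id, r.treatment, r.tissue, r.duration, r.rest,
                replicate=counters[key],
            )
        )
    return matrix, StudyDesign(records=tuple(numbered))


def filter_probes(
    matrix: ExpressionMatrix, prefix: str = "EA", allow_empty_prefix: bool = False
) -> ExpressionMatrix:
    """Drop probes whose identifier starts with ``prefix`` (case-sensitive).

    An empty prefix would drop every probe, so it must be confirmed with
    ``allow_empty_prefix=True``.
    """
    if prefix == "" and not allow_empty_prefix:
        raise ValueError("empty prefix removes every probe; pass allow_empty_prefix=True")
    keep = ~matrix.data.index.str.startswith(prefix)
    return ExpressionMatrix(data=matrix.data.loc[keep])


def standardize_samples(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each sample column to mean 0 and variance 1.

    Uses the population denominator (n) so the per-sample variance is exactly
    1 after the transform.  A constant column has no scale and raises.
    """
    data = matrix.data
    std = data.std(axis=0, ddof=0)
    if (std <= 0).any():
        bad = std.index[std <= 0].tolist()
        raise ValueError(f"constant expression column(s): {bad}")
    return ExpressionMatrix(data=(data - data.mean(axis=0)) / std)


def assemble_tensor(matrix: ExpressionMatrix, design: StudyDesign) -> DenseTensor:
    """Average replicates into the gene × treatment × tissue × duration × rest tensor.

    Each design cell holds the mean over its replicate samples; cells with no
    samples are exact zeros (missing observations).  Mode order is fixed as
    (gene, treatment, tissue, duration, rest).
    """
    by_sample = design.by_sample()
    missing = [s for s in matrix.samples if s not in by_sample]
    if missing:
        raise ValueError(f"samples not covered by the design: {missing}")

    n_genes = len(matrix.probes)
    shape = (n_genes, len(TREATMENTS), len(TISSUES), len(DURATIONS), len(REST_PERIODS))
    total = np.zeros(shape)
    count = np.zeros(shape[1:], dtype=int)
    values = matrix.data.to_numpy()
    for col, sample in enumerate(matrix.samples):
        r = by_sample[sample]
        cell = (r.treatment - 1, r.tissue - 1, r.duration - 1, r.rest - 1)
        total[(slice(None),) + cell] += values[:, col]
        count[cell] += 1
    with np.errstate(invalid="ignore"):
        avg = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return DenseTensor(
        values=avg,
        mode_names=("gene", "treatment", "tissue", "duration", "rest"),
        mode_categories=(
            tuple(matrix.probes),
            TREATMENTS,
            TISSUES,
            DURATIONS,
            REST_PERIODS,
        ),
    )


def run_ptsd_analysis(
    tensor: DenseTensor,
    omega_override: OmegaSet | None = None,
    threshold: float = 0.01,
    n_omega: int = 3,
    coexpressed_tissues: Sequence[str] = ("AY", "HC", "heart"),
    l1_override: int | None = None,
    l2_override: int | None = None,
    adjust_method: str = "BH",
) -> tuple[SelectionResult, dict]:
    """HOSVD the study tensor and select outlier probes.

    The treatment-difference vector ℓ1 is found with the (+1, -1) contrast
    over the treatment mode; the tissue-coexpression vector ℓ2 with a ±1
    membership contrast over ``coexpressed_tissues``.  Ω is then the first
    ``n_omega`` distinct gene-mode indices in the core ranking with
    (ℓ1, ℓ2) fixed, unless overridden.  Returns the selection plus a run
    manifest dict (chosen ℓ indices, Ω, counts).
    """
    if tensor.ndim != 5:
        raise ValueError("expected a five-mode study tensor")
    decomp = hosvd(tensor)

    l1 = l1_override or find_contrast_vector(decomp, "treatment", (1.0, -1.0))
    tissue_cats = tensor.mode_categories[tensor.mode_index("tissue")]
    membership = np.array(
        [1.0 if t in coexpressed_tissues else -1.0 for t in tissue_cats]
    )
    l2 = l2_override or find_contrast_vector(decomp, "tissue", membership)

    if omega_override is not None:
        omega = omega_override
    else:
        omega = choose_omega(
            decomp,
            fixed={"treatment": l1, "tissue": l2},
            n_vectors=n_omega,
            gene_mode="gene",
        )
    probes = tensor.mode_categories[0]
    result = run_selection(
        decomp.factors[0], omega, threshold=threshold,
        method=adjust_method, gene_ids=probes,
    )
    manifest = {
        "l1_treatment": int(l1),
        "l2_tissue": int(l2),
        "omega": list(omega.indices),
        "omega_provenance": omega.provenance,
        "threshold": threshold,
        "adjust_method": adjust_method,
        "n_probes": len(probes),
        "n_selected": len(result.selected),
    }
    return result, manifest


def ttest_combinations(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    probes: Sequence[str],
    threshold: float = 0.01,
    mode: str = "set-mean",
) -> pd.DataFrame:
    """t-test the probe set between control and treated per design combination.

    For every (tissue, duration, rest) combination with both groups present:

    * ``"set-mean"`` (default): Welch two-sample t-test on the per-sample
      mean expression of the probe set (one value per sample);
    * ``"paired-by-probe"``: paired t-test across probes of the per-group
      mean expression (pairs are probes).

    P-values are BH-adjusted across the combinations; ``significant`` flags
    adjusted P < ``threshold``.  Combinations with one group empty are
    skipped (they are not testable), not errors.
    """
    probes = list(probes)
    if not probes:
        raise ValueError("probe list must be non-empty")
    if mode not in ("set-mean", "paired-by-probe"):
        raise ValueError(f"unknown t-test mode {mode!r}")
    sub = matrix.data.loc[probes]
    by_sample = design.by_sample()

    groups: dict[tuple[int, int, int], dict[int, list[str]]] = {}
    for sample in matrix.samples:
        r = by_sample.get(sample)
        if r is None:
            continue
        combo = (r.tissue, r.duration, r.rest)
        groups.setdefault(combo, {1: [], 2: []})[r.treatment].append(sample)

    rows = []
    for combo in sorted(groups):
        ctrl, trt = groups[combo][1], groups[combo][2]
        if not ctrl or not trt:
            continue
        if mode == "set-mean":
            a = sub[ctrl].mean(axis=0).to_numpy()
            b = sub[trt].mean(axis=0).to_numpy()
            t, p = stats.ttest_ind(b, a, equal_var=False)
        else:
            a = sub[ctrl].mean(axis=1).to_numpy()
            b = sub[trt].mean(axis=1).to_numpy()
            t, p = stats.ttest_rel(b, a)
        if np.isnan(p):  # zero-variance degenerate groups: no evidence
            t, p = 0.0, 1.0
        tissue, duration, rest = combo
        rows.append(
            {
                "tissue": TISSUES[tissue - 1],
                "duration": DURATIONS[duration - 1],
                "rest": REST_PERIODS[rest - 1],
                "n_control": len(ctrl),
                "n_treated": len(trt),
                "t": float(t),
                "p_raw": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        from .selection import adjust_pvalues

        out["p_adjusted"] = adjust_pvalues(out["p_raw"].to_numpy(), method="BH")
        out["significant"] = out["p_adjusted"] < threshold
    return out


# Replicate counts of the study design (control, treated) per tissue and
# testable (duration, rest) cell; the remaining (duration, rest) cells were
# not measured.  Encoded from the published sample table of GSE68077.
TABLE_REPLICATES: dict[str, dict[tuple[str, str], tuple[int, int]]] = {
    "AY":        {("5 days", "24 hours"): (3, 2), ("5 days", "1.5 weeks"): (5, 4),
                  ("10 days", "24 hours"): (3, 4), ("10 days", "6 weeks"): (3, 4)},
    "HC":        {("5 days", "24 hours"): (3, 5), ("5 days", "1.5 weeks"): (4, 5),
                  ("10 days", "24 hours"): (5, 4), ("10 days", "6 weeks"): (4, 5)},
    "MPFC":      {("5 days", "24 hours"): (4, 5), ("5 days", "1.5 weeks"): (5, 5),
                  ("10 days", "24 hours"): (3, 4), ("10 days", "6 weeks"): (4, 4)},
    "SE":        {("5 days", "24 hours"): (3, 2), ("5 days", "1.5 weeks"): (2, 3),
                  ("10 days", "24 hours"): (3, 3), ("10 days", "6 weeks"): (3, 3)},
    "ST":        {("5 days", "24 hours"): (5, 5), ("5 days", "1.5 weeks"): (5, 5),
                  ("10 days", "24 hours"): (5, 4), ("10 days", "6 weeks"): (4, 4)},
    "VS":        {("5 days", "24 hours"): (5, 5), ("5 days", "1.5 weeks"): (5, 5),
                  ("10 days", "24 hours"): (3, 4), ("10 days", "6 weeks"): (5, 4)},
    "blood":     {("5 days", "24 hours"): (5, 5), ("5 days", "1.5 weeks"): (5, 5),
                  ("10 days", "24 hours"): (4, 5), ("10 days", "6 weeks"): (4, 5)},
    "heart":     {("5 days", "24 hours"): (5, 5), ("5 days", "1.5 weeks"): (4, 5),
                  ("10 days", "24 hours"): (5, 5), ("10 days", "6 weeks"): (5, 5)},
    "hemibrain": {("5 days", "24 hours"): (5, 5), ("5 days", "1.5 weeks"): (4, 5),
                  ("10 days", "24 hours"): (5, 5), ("10 days", "6 weeks"): (5, 5)},
    "spleen":    {("5 days", "24 hours"): (5, 5), ("5 days", "1.5 weeks"): (5, 5),
                  ("10 days", "24 hours"): (5, 4), ("10 days", "6 weeks"): (5, 5)},
}


def testable_combinations(
    replicates: dict[str, dict[tuple[str, str], tuple[int, int]]] = TABLE_REPLICATES,
) -> list[tuple[str, str, str]]:
    """(tissue, duration, rest) combinations with both control and treated samples."""
    combos = []
    for tissue, cells in replicates.items():
        for (duration, rest), (n_ctrl, n_trt) in cells.items():
            if n_ctrl > 0 and n_trt > 0:
                combos.append((tissue, duration, rest))
    return combos
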