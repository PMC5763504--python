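"""Shared fixtures: seeded tensors and synthetic GEO Series Matrix files."""

from __future__ import annotations

import numpy as np
import pytest

from tdfe.geo import DURATIONS, REST_PERIODS, TISSUES

# (duration, rest) design cells actually measured in the study
MEASURED_CELLS = [
    ("5 days", "24 hours"),
    ("5 days", "1.5 weeks"),
    ("10 days", "24 hours"),
    ("10 days", "6 weeks"),
]

_TISSUE_LABEL = {
    "AY": "amygdala",
    "HC": "hippocampus",
    "MPFC": "medial prefrontal cortex",
    "SE": "septal nucleus",
    "ST": "striatum",
    "VS": "ventral striatum",
    "blood": "blood",
    "heart": "heart",
    "hemibrain": "hemibrain",
    "spleen": "spleen",
}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def write_series_matrix(path, probes, sample_specs, values) -> None:
    """Write a synthetic GEO Series Matrix text file.

    ``sample_specs`` is a list of (sample_id, tissue, duration, rest,
    treatment) with the short tissue code and human-readable labels;
    ``values`` is probes × samples.
    """
    values = np.asarray(values)
    ids = [s[0] for s in sample_specs]
    lines = [
        "!Series_title\t\"synthetic stress-study fixture\"",
        "!Sample_title\t" + "\t".join(f'"{s[0]} profile"' for s in sample_specs),
        "!Sample_geo_accession\t" + "\t".join(f'"{i}"' for i in ids),
        "!Sample_characteristics_ch1\t"
        + "\t".join(f'"tissue: {_TISSUE_LABEL[s[1]]}"' for s in sample_specs),
        "!Sample_characteristics_ch1\t"
        + "\t".join(
            f'"stress duration: {s[2]}, rest period: {s[3]}"' for s in sample_specs
        ),
        "!Sample_characteristics_ch1\t"
        + "\t".join(f'"treatment: {s[4]}"' for s in sample_specs),
        "!series_matrix_table_begin",
        '"ID_REF"\t' + "\t".join(f'"{i}"' for i in ids),
    ]
    for p, row in zip(probes, values):
        lines.append(p + "\t" + "\t".join(f"{v:.6g}" for v in row))
    lines.append("!series_matrix_table_end")
    path.write_text("\n".join(lines) + "\n")


def planted_study(
    seed: int = 0,
    n_probes: int = 120,
    n_signal: int = 20,
    effect: float = 3.0,
    tissue_subset=("AY", "HC", "MPFC", "heart"),
    replicates: int = 3,
):
    """Build a small stress study with probes planted to respond in a few tissues.

    Returns (probes, sample_specs, values, signal_probes).  The first
    ``n_signal`` probes are shifted by ``effect`` in stress samples of
    tissues AY, HC and heart (where present in ``tissue_subset``).
    """
    rng = np.random.default_rng(seed)
    probes = [f"A_51_P{i:05d}" for i in range(n_probes)]
    sample_specs = []
    cols = []
    responsive = {"AY", "HC", "heart"}
    k = 0
    for tissue in tissue_subset:
        for duration, rest in MEASURED_CELLS:
            for treatment in ("control", "stress"):
                for _ in range(replicates):
                    k += 1
                    sample_specs.append(
                        (f"GSM{k:04d}", tissue, duration, rest, treatment)
                    )
                    col = rng.normal(size=n_probes)
                    if treatment == "stress" and tissue in responsive:
                        col[:n_signal] += effect
                    cols.append(col)
    values = np.column_stack(cols)
    return probes, sample_specs, values, probes[:n_signal]


@pytest.fixture
def series_matrix_file(tmp_path):
    """A parseable synthetic Series Matrix file with a planted stress effect."""
    probes, specs, values, signal = planted_study()
    path = tmp_path / "synthetic_series_matrix.txt"
    write_series_matrix(path, probes, specs, values)
    return path, probes, specs, signal
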