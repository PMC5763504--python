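"""Text serialization of tensors and decompositions.

A tensor is stored as a directory holding its mode-0 unfolding as TSV (rows
labelled by the mode-0 categories, columns by the remaining categories
joined with ``|`` in the unfolding's lexicographic order) plus a
``meta.json`` with mode names, category labels and the shape.  A
decomposition directory holds the core as a long-format TSV of 1-based
ℓ-index tuples with values, one TSV per factor matrix, and ``meta.json``.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tensor import DenseTensor, HOSVDResult, fold, unfold

__all__ = ["save_tensor", "load_tensor", "save_hosvd", "load_hosvd"]


def save_tensor(tensor: DenseTensor, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "mode_names": list(tensor.mode_names),
        "mode_categories": [list(c) for c in tensor.mode_categories],
        "shape": list(tensor.shape),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    cols = [
        "|".join(combo)
        for combo in itertools.product(*tensor.mode_categories[1:])
    ] or ["value"]
    frame = pd.DataFrame(
        unfold(tensor, 0), index=list(tensor.mode_categories[0]), columns=cols
    )
    frame.to_csv(path / "unfolding.tsv", sep="\t", index_label="id")


def load_tensor(path) -> DenseTensor:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    frame = pd.read_csv(path / "unfolding.tsv", sep="\t", index_col=0)
    values = fold(frame.to_numpy(), 0, meta["shape"])
    return DenseTensor(
        values=values,
        mode_names=tuple(meta["mode_names"]),
        mode_categories=tuple(tuple(c) for c in meta["mode_categories"]),
    )


def save_hosvd(result: HOSVDResult, path, gene_ids=None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "mode_names": list(result.mode_names),
        "core_shape": list(result.core.shape),
        "factor_shapes": [list(f.shape) for f in result.factors],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))

    idx = np.indices(result.core.shape).reshape(result.core.ndim, -1).T + 1
    core = pd.DataFrame(idx, columns=[f"l{k+1}" for k in range(result.core.ndim)])
    core["G"] = result.core.ravel()
    core.to_csv(path / "core.tsv", sep="\t", index=False)

    for k, (name, factor) in enumerate(zip(result.mode_names, result.factors)):
        frame = pd.DataFrame(
            factor, columns=[f"l{j+1}" for j in range(factor.shape[1])]
        )
        frame.to_csv(path / f"factor{k}_{name}.tsv", sep="\t", index=False)
    if gene_ids is not None:
        (path / "gene_ids.txt").write_text("\n".join(map(str, gene_ids)) + "\n")


def load_hosvd(path) -> tuple[HOSVDResult, list[str] | None]:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    core_long = pd.read_csv(path / "core.tsv", sep="\t")
    core = core_long["G"].to_numpy().reshape(meta["core_shape"])
    factors = []
    for k, name in enumerate(meta["mode_names"]):
        frame = pd.read_csv(path / f"factor{k}_{name}.tsv", sep="\t")
        factors.append(frame.to_numpy())
    gene_ids = None
    ids_path = path / "gene_ids.txt"
    if ids_path.exists():
        gene_ids = ids_path.read_text().splitlines()
    result = HOSVDResult(
        core=core, factors=tuple(factors), mode_names=tuple(meta["mode_names"])
    )
    return result, gene_ids
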