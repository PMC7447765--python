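"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (genes x arrays, first column gene ids),
sample metadata as a two-plus-column TSV (array_id, population), effect
tables as gene x population TSV, and generator configurations as YAML or
JSON. The optional GEO series-matrix loader accepts the deposited study
data (GSE148447) but nothing in the package requires it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ExpressionDataset, GroundTruth
from .simulate import GeneratorConfig

__all__ = [
    "read_expression",
    "write_dataset",
    "write_ground_truth",
    "read_effect_table",
    "write_effect_table",
    "read_generator_config",
    "write_json",
]

log = logging.getLogger(__name__)


def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    log_transform: str = "none",
) -> ExpressionDataset:
    """Load an expression TSV plus its array metadata.

    ``log_transform='log2_offset'`` maps RPKM-scale values through
    log2(x + 1); ``'none'`` takes the matrix as already log-scale. Genes
    with zero variance across all arrays are dropped (their count is
    logged); matrix columns and metadata arrays must agree exactly.
    """
    if log_transform not in ("none", "log2_offset"):
        raise ValueError(f"unknown log_transform {log_transform!r}")
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "array_id" not in meta.columns or "population" not in meta.columns:
        raise ValueError("metadata needs 'array_id' and 'population' columns")
    mat.columns = mat.columns.astype(str)
    meta_arrays = set(meta["array_id"])
    mat_arrays = set(mat.columns)
    if meta_arrays != mat_arrays:
        raise ValueError(
            "matrix/metadata array mismatch: "
            f"only in matrix {sorted(mat_arrays - meta_arrays)[:5]}, "
            f"only in metadata {sorted(meta_arrays - mat_arrays)[:5]}"
        )
    values = mat.astype(float)
    if log_transform == "log2_offset":
        if (values.to_numpy() < 0).any():
            raise ValueError("negative RPKM values in expression matrix")
        values = np.log2(values + 1.0)
    var = values.var(axis=1, ddof=0)
    flat = var == 0.0
    if flat.any():
        log.info("dropping %d zero-variance gene(s)", int(flat.sum()))
        values = values.loc[~flat]
    pop = dict(zip(meta["array_id"], meta["population"]))
    # preserve metadata's array order (it defines the design order)
    values = values[[a for a in meta["array_id"]]]
    return ExpressionDataset(values=values, array_population=pop)


def write_dataset(dataset: ExpressionDataset, out_dir: str | Path, stem: str = "expression") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.values.to_csv(out / f"{stem}.tsv", sep="\t", index_label="gene_id")
    dataset.metadata_frame().to_csv(out / f"{stem}_metadata.tsv", sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.sample_effects.rename("effect").to_csv(
        out / "truth_sample_effects.tsv", sep="\t", index_label="array_id"
    )
    truth.gene_effects.rename("effect").to_csv(
        out / "truth_gene_effects.tsv", sep="\t", index_label="gene_id"
    )
    truth.gene_cellpop_effects.to_csv(
        out / "truth_gene_cellpop_effects.tsv", sep="\t", index_label="gene_id"
    )
    if truth.de_labels is not None:
        truth.de_labels.astype(int).to_csv(
            out / "truth_de_labels.tsv", sep="\t", index_label="gene_id"
        )


def read_effect_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_effect_table(effects: pd.DataFrame, path: str | Path) -> None:
    effects.to_csv(path, sep="\t", index_label="gene_id")


def read_generator_config(path: str | Path) -> GeneratorConfig:
    """GeneratorConfig from YAML or JSON (by extension)."""
    p = Path(path)
    with open(p) as fh:
        raw = json.load(fh) if p.suffix == ".json" else yaml.safe_load(fh)
    raw = dict(raw)
    raw["populations"] = [(str(a), int(b)) for a, b in raw["populations"]]
    if raw.get("mixture_params"):
        raw["mixture_params"] = {
            str(k): tuple(float(x) for x in v) for k, v in raw["mixture_params"].items()
        }
    return GeneratorConfig(**raw)


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, no timestamps."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
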