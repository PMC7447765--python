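"""Core data containers for the two-stage differential-expression pipeline.

The central object is :class:`ExpressionDataset`: a complete genes × arrays
matrix of log-expression values together with a map from each array to the
cell population it was sorted from. Everything downstream (the crossed
random-effects fit, the scale-mixture stage) consumes this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "GroundTruth"]


@dataclass
class ExpressionDataset:
    """A complete log-expression matrix with array→population metadata.

    Parameters
    ----------
    values
        DataFrame of log-expression values, rows indexed by gene id,
        columns by array id. No missing values are permitted.
    array_population
        Mapping from array id to population label. Must cover every
        column of ``values``.
    """

    values: pd.DataFrame
    array_population: dict[str, str]

    def __post_init__(self) -> None:
        v = self.values
        if v.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if v.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate array ids")
        missing = [a for a in v.columns if a not in self.array_population]
        if missing:
            raise ValueError(f"arrays missing from metadata: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance (design) order."""
        seen: list[str] = []
        for a in self.array_ids:
            p = self.array_population[a]
            if p not in seen:
                seen.append(p)
        return seen

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def arrays_in(self, population: str) -> list[str]:
        return [a for a in self.array_ids if self.array_population[a] == population]

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "array_id": self.array_ids,
                "population": [self.array_population[a] for a in self.array_ids],
            }
        )


@dataclass
class GroundTruth:
    """Simulation truth stored alongside a generated dataset.

    ``de_labels`` is only populated when the gene-by-population effects were
    drawn from the two-component mixture; it records, per gene × population,
    whether the draw came from the wide (differentially expressed) component.
    """

    sample_effects: pd.Series
    gene_effects: pd.Series
    gene_cellpop_effects: pd.DataFrame
    de_labels: pd.DataFrame | None = None
    fixed_effects: dict[str, float] = field(default_factory=dict)
    grand_mean: float = 0.0

    def __post_init__(self) -> None:
        g = self.gene_cellpop_effects
        if len(self.gene_effects) != g.shape[0]:
            raise ValueError("gene_effects / gene_cellpop_effects dimension mismatch")
        if self.de_labels is not None and self.de_labels.shape != g.shape:
            raise ValueError("de_labels dimensions do not match gene_cellpop_effects")
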