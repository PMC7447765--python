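import numpy as np
import pandas as pd
import pytest

from demix.data import ExpressionDataset
from demix.lmm import fit_reml
from demix.reference import reference_config
from demix.simulate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def reference_sim():
    """One gaussian-mode dataset at the reference study conditions, with
    its REML fit and ground truth (shared across tests; seed fixed)."""
    dataset, truth = generate_dataset(reference_config(n_genes=2000, seed=1))
    fit = fit_reml(dataset)
    assert fit.converged
    return dataset, truth, fit


@pytest.fixture(scope="session")
def balanced_toy():
    """A balanced 2-population x 3-array design, 40 genes, known variances."""
    cfg = GeneratorConfig(
        n_genes=40,
        populations=[("p1", 3), ("p2", 3)],
        grand_mean=5.0,
        cellpop_effects={"p2": 0.7},
        var_sample=0.2,
        var_gene=1.5,
        gene_cellpop_mode="gaussian",
        var_gene_cellpop=0.4,
        var_resid=0.3,
        seed=11,
    )
    return generate_dataset(cfg)


def constant_dataset(value: float = 7.0, n_genes: int = 20) -> ExpressionDataset:
    arrays = ["a1", "a2", "b1", "b2"]
    pops = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    values = pd.DataFrame(
        np.full((n_genes, 4), value),
        index=[f"g{i}" for i in range(n_genes)],
        columns=arrays,
    )
    return ExpressionDataset(values=values, array_population=pops)
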