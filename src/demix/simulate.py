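"""Synthetic expression data with the generative structure the model assumes.

Log-expression is decomposed as

    y[g, a] = mu + beta[pop(a)] + S[a] + G[g] + GC[g, pop(a)] + eps[g, a]

with independent zero-mean normal array effects S, gene effects G and
residuals eps. The gene-by-population interaction GC is either plain normal
("gaussian" mode) or, per population, a two-component zero-mean normal scale
mixture ("mixture" mode) in which the wide component marks differentially
expressed gene/population pairs. Ground truth (every drawn effect plus the
mixture component labels) is returned for recovery testing.

Each random term draws from its own child stream of a single seed sequence,
so enlarging ``n_genes`` leaves the array effects unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionDataset, GroundTruth

__all__ = ["GeneratorConfig", "generate_dataset", "generate_mixture_sample"]

# fixed child-stream indices per random term
_STREAMS = {"sample": 0, "gene": 1, "gene_cellpop": 2, "resid": 3}


@dataclass
class GeneratorConfig:
    """Parameters of the generative model.

    ``populations`` is an ordered list of (label, replicate-array count).
    Variances are on the log-expression scale. In mixture mode,
    ``mixture_params`` maps each population label to (pi1, sigma0, sigma1):
    the proportion of differentially expressed genes and the SDs of the
    narrow (non-DE) and wide (DE) components.
    """

    n_genes: int
    populations: list[tuple[str, int]]
    grand_mean: float = 7.0
    cellpop_effects: dict[str, float] = field(default_factory=dict)
    var_sample: float = 0.0
    var_gene: float = 0.0
    gene_cellpop_mode: str = "gaussian"
    var_gene_cellpop: float = 0.0
    mixture_params: dict[str, tuple[float, float, float]] | None = None
    var_resid: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.populations:
            raise ValueError("at least one population is required")
        labels = [p for p, _ in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        for p, r in self.populations:
            if r < 1:
                raise ValueError(f"population {p!r} has replicate count {r} < 1")
        for name in ("var_sample", "var_gene", "var_gene_cellpop", "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gene_cellpop_mode not in ("gaussian", "mixture"):
            raise ValueError(f"unknown gene_cellpop_mode {self.gene_cellpop_mode!r}")
        if self.gene_cellpop_mode == "mixture":
            if self.mixture_params is None:
                raise ValueError("mixture mode requires mixture_params")
            missing = set(labels) - set(self.mixture_params)
            if missing:
                raise ValueError(f"mixture_params missing populations: {sorted(missing)}")
            for p, (pi1, s0, s1) in self.mixture_params.items():
                _check_mixture(pi1, s0, s1, context=f"population {p!r}")
        unknown = set(self.cellpop_effects) - set(labels)
        if unknown:
            raise ValueError(f"cellpop_effects for undeclared populations: {sorted(unknown)}")

    @property
    def population_labels(self) -> list[str]:
        return [p for p, _ in self.populations]

    @property
    def n_arrays(self) -> int:
        return sum(r for _, r in self.populations)


def _check_mixture(pi1: float, sigma0: float, sigma1: float, context: str = "") -> None:
    where = f" ({context})" if context else ""
    if not 0.0 <= pi1 <= 1.0:
        raise ValueError(f"pi1 must lie in [0, 1]{where}")
    if not sigma1 > sigma0 > 0:
        raise ValueError(f"require sigma1 > sigma0 > 0{where}")


def generate_mixture_sample(
    pi1: float, sigma0: float, sigma1: float, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n values from (1-pi1)·N(0, sigma0²) + pi1·N(0, sigma1²).

    Returns the draws and an integer label array (1 = wide/DE component).
    """
    _check_mixture(pi1, sigma0, sigma1)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < pi1).astype(int)
    z = rng.standard_normal(n)
    sd = np.where(labels == 1, sigma1, sigma0)
    return z * sd, labels


def generate_dataset(config: GeneratorConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a complete log-expression dataset plus its ground truth.

    Deterministic given ``config.seed``: the same configuration always yields
    a bitwise-identical dataset.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(_STREAMS))
    rng = {name: np.random.default_rng(children[i]) for name, i in _STREAMS.items()}

    pops = config.population_labels
    n_g, n_a = config.n_genes, config.n_arrays
    gene_ids = [f"g{i:05d}" for i in range(n_g)]
    array_ids: list[str] = []
    array_pop: dict[str, str] = {}
    for p, r in config.populations:
        for k in range(r):
            aid = f"{p}_r{k + 1}"
            array_ids.append(aid)
            array_pop[aid] = p

    S = rng["sample"].standard_normal(n_a) * np.sqrt(config.var_sample)
    G = rng["gene"].standard_normal(n_g) * np.sqrt(config.var_gene)

    de_labels: pd.DataFrame | None = None
    if config.gene_cellpop_mode == "gaussian":
        GC = rng["gene_cellpop"].standard_normal((n_g, len(pops))) * np.sqrt(
            config.var_gene_cellpop
        )
    else:
        assert config.mixture_params is not None
        GC = np.empty((n_g, len(pops)))
        lab = np.empty((n_g, len(pops)), dtype=bool)
        r = rng["gene_cellpop"]
        for j, p in enumerate(pops):
            pi1, s0, s1 = config.mixture_params[p]
            comp = r.random(n_g) < pi1
            z = r.standard_normal(n_g)
            GC[:, j] = z * np.where(comp, s1, s0)
            lab[:, j] = comp
        de_labels = pd.DataFrame(lab, index=gene_ids, columns=pops)

    eps = rng["resid"].standard_normal((n_g, n_a)) * np.sqrt(config.var_resid)

    beta = np.array([config.cellpop_effects.get(p, 0.0) for p in pops])
    pop_idx = np.array([pops.index(array_pop[a]) for a in array_ids])
    values = (
        config.grand_mean
        + beta[pop_idx][None, :]
        + S[None, :]
        + G[:, None]
        + GC[:, pop_idx]
        + eps
    )

    dataset = ExpressionDataset(
        values=pd.DataFrame(values, index=gene_ids, columns=array_ids),
        array_population=array_pop,
    )
    truth = GroundTruth(
        sample_effects=pd.Series(S, index=array_ids),
        gene_effects=pd.Series(G, index=gene_ids),
        gene_cellpop_effects=pd.DataFrame(GC, index=gene_ids, columns=pops),
        de_labels=de_labels,
        fixed_effects={p: float(b) for p, b in zip(pops, beta)},
        grand_mean=config.grand_mean,
    )
    return dataset, truth
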