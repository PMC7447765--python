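"""Reference parameter values from the bovine mammary cell-sorting study.

Four epithelial subpopulations sorted by CD49f and P-Cadherin surface
expression (data deposited as GEO series GSE148447) were profiled on
3/2/3/3 replicate arrays. Fitting the crossed random-effects model to the
normalized log-expression values gave the variance components below, and the
second-stage scale-mixture fit gave per-population mixture parameters, DE
counts and model-based false discovery rates. These published estimates
serve two roles here: as generator truth for parameter-recovery simulations,
and as worked-example inputs for the FDR arithmetic.

The residual variance was not reported; the fixture uses 0.25, small
relative to the between-gene variance of 5.44. Because every population has
replicate arrays, the choice does not confound the gene-by-population
component. Cell-population fixed effects default to zero (arrays were
normalized before modelling, so no population-level shift is expected) and
the grand mean to 7, a typical log-RPKM magnitude; neither affects any
variance target. The number of genes on the arrays was not reported either;
the fixture simulates 2,000, enough to pin the gene-level components while
keeping each fit instantaneous.
"""

from __future__ import annotations

from .simulate import GeneratorConfig

__all__ = [
    "POPULATIONS",
    "VARIANCE_COMPONENTS",
    "MIXTURE_PARAMS",
    "N_DE",
    "FDR",
    "reference_config",
]

#: population label -> replicate array count, in the study's column order
POPULATIONS: list[tuple[str, int]] = [
    ("CD49f_neg/P-cad_neg", 3),
    ("CD49f_mid/P-cad_mid", 2),
    ("CD49f_mid/P-cad_high", 3),
    ("CD49f_high/P-cad_neg", 3),
]

#: fitted variance components (sigma^2) on the log-expression scale
VARIANCE_COMPONENTS: dict[str, float] = {
    "var_sample": 0.036,
    "var_gene": 5.44,
    "var_gene_cellpop": 0.672,
    "var_resid": 0.25,  # unreported; fixture choice, see module docstring
}

#: per-population (pi1, sigma0, sigma1) of the fitted two-component mixture
MIXTURE_PARAMS: dict[str, tuple[float, float, float]] = {
    "CD49f_neg/P-cad_neg": (0.227, 0.302, 1.290),
    "CD49f_mid/P-cad_mid": (0.225, 0.204, 0.612),
    "CD49f_mid/P-cad_high": (0.307, 0.350, 1.119),
    "CD49f_high/P-cad_neg": (0.375, 0.261, 1.109),
}

#: number of genes called DE per population at posterior > 0.8
N_DE: dict[str, int] = {
    "CD49f_neg/P-cad_neg": 1433,
    "CD49f_mid/P-cad_mid": 980,
    "CD49f_mid/P-cad_high": 1644,
    "CD49f_high/P-cad_neg": 2669,
}

#: model-based false discovery rate of each call set
FDR: dict[str, float] = {
    "CD49f_neg/P-cad_neg": 0.030,
    "CD49f_mid/P-cad_mid": 0.041,
    "CD49f_mid/P-cad_high": 0.035,
    "CD49f_high/P-cad_neg": 0.029,
}


def reference_config(
    n_genes: int = 2000,
    mode: str = "gaussian",
    seed: int = 0,
) -> GeneratorConfig:
    """Generator configuration emulating the study design.

    ``mode='gaussian'`` draws the gene-by-population effects as plain normals
    with the fitted interaction variance (the setting for variance-component
    recovery); ``mode='mixture'`` draws them from the fitted per-population
    two-component mixtures, which marks ground-truth DE pairs.
    """
    kwargs = dict(
        n_genes=n_genes,
        populations=list(POPULATIONS),
        grand_mean=7.0,
        var_sample=VARIANCE_COMPONENTS["var_sample"],
        var_gene=VARIANCE_COMPONENTS["var_gene"],
        var_resid=VARIANCE_COMPONENTS["var_resid"],
        gene_cellpop_mode=mode,
        seed=seed,
    )
    if mode == "gaussian":
        kwargs["var_gene_cellpop"] = VARIANCE_COMPONENTS["var_gene_cellpop"]
    else:
        kwargs["mixture_params"] = dict(MIXTURE_PARAMS)
    return GeneratorConfig(**kwargs)
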