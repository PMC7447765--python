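"""Fit the crossed random-effects model to the simulated cohort.

REML estimates of the four variance components, the Wald F-test of the
cell-population fixed effect, and the gene-by-population BLUPs that feed
stage two. Reads results/cohort/, writes results/lmm/.
"""

from pathlib import Path

from demix.io import read_expression, write_effect_table, write_json
from demix.lmm import cellpop_f_test, extract_gene_cellpop_effects, fit_reml

COHORT = Path("results/cohort")
OUT = Path("results/lmm")


def main() -> None:
    dataset = read_expression(COHORT / "expression.tsv",
                              COHORT / "expression_metadata.tsv")
    fit = fit_reml(dataset)
    assert fit.converged, "REML did not converge"
    vc = fit.variance_components
    ftest = cellpop_f_test(fit)
    OUT.mkdir(parents=True, exist_ok=True)
    write_json(
        {**vc.as_dict(), "reml_loglik": fit.reml_loglik,
         "n_iterations": fit.n_iterations,
         "f_statistic": ftest.f_statistic, "p_value": ftest.p_value},
        OUT / "lmm_report.json",
    )
    write_effect_table(extract_gene_cellpop_effects(fit), OUT / "effects.tsv")
    print(f"REML converged in {fit.n_iterations} iterations")
    print(f"  array (sample) variance:     {vc.var_sample:.4f} +/- {vc.se_sample:.4f}")
    print(f"  gene variance:               {vc.var_gene:.3f} +/- {vc.se_gene:.3f}")
    print(f"  gene x population variance:  {vc.var_gene_cellpop:.4f} +/- {vc.se_gene_cellpop:.4f}")
    print(f"  residual variance:           {vc.var_resid:.4f} +/- {vc.se_resid:.4f}")
    print(f"cell-population effect: F({ftest.numerator_df},{ftest.denominator_df}) "
          f"= {ftest.f_statistic:.2f}, P = {ftest.p_value:.2f}")


if __name__ == "__main__":
    main()
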