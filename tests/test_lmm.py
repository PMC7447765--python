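"""REML fitter: oracles (ANOVA estimators, dense Henderson solve, lme4),
invariants and the fixed-effect test."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from demix.data import ExpressionDataset
from demix.lmm import (
    DesignError,
    cellpop_f_test,
    extract_gene_cellpop_effects,
    fit_reml,
    raw_gene_cellpop_means,
)
from demix.reference import reference_config
from demix.simulate import GeneratorConfig, generate_dataset

from conftest import constant_dataset


def anova_mom_estimates(dataset: ExpressionDataset) -> dict[str, float]:
    """Expected-mean-squares (method-of-moments) estimators for a balanced
    crossed design: the independent oracle for REML on balanced toys."""
    Y = dataset.values.to_numpy()
    pops = dataset.populations
    Gn, A = Y.shape
    P = len(pops)
    r = A // P
    pop_idx = np.array(
        [pops.index(dataset.array_population[a]) for a in dataset.array_ids]
    )
    ybar_a = Y.mean(axis=0)
    ybar_g = Y.mean(axis=1)
    ybar = Y.mean()
    ybar_p = np.array([ybar_a[pop_idx == j].mean() for j in range(P)])
    ybar_gp = np.stack([Y[:, pop_idx == j].mean(axis=1) for j in range(P)], axis=1)
    ms_s = Gn * np.sum((ybar_a - ybar_p[pop_idx]) ** 2) / (P * (r - 1))
    ms_g = P * r * np.sum((ybar_g - ybar) ** 2) / (Gn - 1)
    ms_gc = (
        r
        * ((ybar_gp - ybar_g[:, None] - ybar_p[None, :] + ybar) ** 2).sum()
        / ((Gn - 1) * (P - 1))
    )
    resid = Y - ybar_gp[:, pop_idx] - ybar_a[None, :] + ybar_p[pop_idx][None, :]
    ms_e = (resid**2).sum() / ((Gn - 1) * P * (r - 1))
    return {
        "var_resid": ms_e,
        "var_gene_cellpop": (ms_gc - ms_e) / r,
        "var_gene": (ms_g - ms_gc) / (P * r),
        "var_sample": (ms_s - ms_e) / Gn,
    }


def henderson_dense(dataset: ExpressionDataset, vs, vg, vgc, ve):
    """Dense mixed-model-equations solve: the BLUP oracle on small designs."""
    Y = dataset.values.to_numpy()
    Gn, A = Y.shape
    pops = dataset.populations
    P = len(pops)
    pop_idx = np.array(
        [pops.index(dataset.array_population[a]) for a in dataset.array_ids]
    )
    y = Y.ravel()
    Xa = np.zeros((A, P))
    Xa[:, 0] = 1.0
    for j in range(1, P):
        Xa[pop_idx == j, j] = 1.0
    X = np.tile(Xa, (Gn, 1))
    Zs = np.tile(np.eye(A), (Gn, 1))
    Zg = np.kron(np.eye(Gn), np.ones((A, 1)))
    Zp = np.zeros((A, P))
    Zp[np.arange(A), pop_idx] = 1.0
    Zgc = np.kron(np.eye(Gn), Zp)
    Z = np.hstack([Zs, Zg, Zgc])
    Ginv = np.diag(
        np.concatenate([np.full(A, 1 / vs), np.full(Gn, 1 / vg), np.full(Gn * P, 1 / vgc)])
    )
    lhs = np.block(
        [[X.T @ X / ve, X.T @ Z / ve], [Z.T @ X / ve, Z.T @ Z / ve + Ginv]]
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y]) / ve
    sol = np.linalg.solve(lhs, rhs)
    beta, u = sol[:P], sol[P:]
    return beta, u[:A], u[A : A + Gn], u[A + Gn :].reshape(Gn, P)


def test_constant_dataset_gives_zero_components_and_the_constant_mean():
    fit = fit_reml(constant_dataset(7.0))
    vc = fit.variance_components
    assert vc.var_sample == 0.0
    assert vc.var_gene == 0.0
    assert vc.var_gene_cellpop == 0.0
    assert vc.var_resid == 0.0
    assert fit.fixed_effects["estimate"].iloc[0] == pytest.approx(7.0, abs=1e-8)
    assert (extract_gene_cellpop_effects(fit).to_numpy() == 0).all()


def test_balanced_design_matches_anova_estimators(balanced_toy):
    dataset, _ = balanced_toy
    fit = fit_reml(dataset)
    assert fit.converged
    mom = anova_mom_estimates(dataset)
    assert all(v > 0 for v in mom.values())  # interior solution required
    vc = fit.variance_components.as_dict()
    for k, v in mom.items():
        assert vc[k] == pytest.approx(v, rel=1e-4, abs=1e-8), k


def test_blups_and_betas_match_dense_henderson_solve():
    cfg = GeneratorConfig(
        n_genes=6,
        populations=[("p1", 2), ("p2", 2)],
        grand_mean=3.0,
        cellpop_effects={"p2": 0.5},
        var_sample=0.1,
        var_gene=2.0,
        gene_cellpop_mode="gaussian",
        var_gene_cellpop=0.5,
        var_resid=0.3,
        seed=7,
    )
    dataset, _ = generate_dataset(cfg)
    fit = fit_reml(dataset)
    vc = fit.variance_components
    beta, S, G, GC = henderson_dense(
        dataset, vc.var_sample, vc.var_gene, vc.var_gene_cellpop, vc.var_resid
    )
    np.testing.assert_allclose(beta, fit.fixed_effects["estimate"], atol=1e-8)
    np.testing.assert_allclose(S, fit.sample_blups, atol=1e-8)
    np.testing.assert_allclose(G, fit.gene_blups, atol=1e-8)
    np.testing.assert_allclose(GC, fit.gene_cellpop_blups.to_numpy(), atol=1e-8)


def test_blup_shrinkage_on_balanced_design(balanced_toy):
    """Shrinkage: BLUP interaction estimates are smaller than the raw
    double-centered cell means, gene by gene in aggregate."""
    dataset, _ = balanced_toy
    fit = fit_reml(dataset)
    blup = fit.gene_cellpop_blups.to_numpy()
    raw = raw_gene_cellpop_means(dataset).to_numpy()
    assert np.sum(blup**2) < np.sum(raw**2)
    # per-population centered columns shrink toward zero as well
    bc = blup - blup.mean(axis=1, keepdims=True)
    rc = raw - raw.mean(axis=1, keepdims=True)
    assert np.all(np.abs(bc) <= np.abs(rc) + 0.05 * np.abs(rc).max())


def test_permutation_invariance():
    dataset, _ = generate_dataset(reference_config(n_genes=60, seed=21))
    fit = fit_reml(dataset)
    rng = np.random.default_rng(0)
    g_perm = rng.permutation(dataset.n_genes)
    a_perm = rng.permutation(dataset.n_arrays)
    values = dataset.values.iloc[g_perm, a_perm]
    permuted = ExpressionDataset(values=values, array_population=dataset.array_population)
    fit_p = fit_reml(permuted)
    a = fit.variance_components.as_dict()
    b = fit_p.variance_components.as_dict()
    for k in a:
        assert a[k] == pytest.approx(b[k], rel=1e-6, abs=1e-10)
    pd.testing.assert_frame_equal(
        fit.gene_cellpop_blups,
        fit_p.gene_cellpop_blups.loc[fit.gene_cellpop_blups.index,
                                     fit.gene_cellpop_blups.columns],
        rtol=1e-6, atol=1e-9,
    )


def test_restricted_loglik_is_monotone(reference_sim):
    _, _, fit = reference_sim
    trace = np.array(fit.loglik_trace)
    assert np.all(np.diff(trace) >= -1e-6 * (np.abs(trace[:-1]) + 1.0))


def test_reference_recovery_single_fit(reference_sim):
    """One fit at the reference conditions recovers each generating variance
    well within a loose window (the tight multi-replicate check lives in the
    acceptance suite)."""
    _, truth, fit = reference_sim
    vc = fit.variance_components
    assert vc.var_gene == pytest.approx(5.44, rel=0.15)
    assert vc.var_gene_cellpop == pytest.approx(0.672, rel=0.15)
    assert abs(vc.var_sample - 0.036) < 0.08
    assert vc.var_resid == pytest.approx(0.25, rel=0.15)
    assert vc.se_gene > 0 and vc.se_gene_cellpop > 0


def test_blup_correlation_with_truth(reference_sim):
    """BLUPs track the generating interaction effects; after removing each
    gene's profile mean (which the design attributes to the gene effect)
    the correlation is high."""
    _, truth, fit = reference_sim
    blup = fit.gene_cellpop_blups.to_numpy()
    true = truth.gene_cellpop_effects.to_numpy()
    raw_corr = np.corrcoef(blup.ravel(), true.ravel())[0, 1]
    cen = lambda m: m - m.mean(axis=1, keepdims=True)
    cen_corr = np.corrcoef(cen(blup).ravel(), cen(true).ravel())[0, 1]
    assert raw_corr > 0.75
    assert cen_corr > 0.9


def test_gene_cellpop_blups_center_near_zero(reference_sim):
    _, _, fit = reference_sim
    col_means = fit.gene_cellpop_blups.mean(axis=0)
    assert (col_means.abs() < 0.05).all()


def test_f_test_trivial_cases():
    # identical population means, no noise -> F ~ 0, p ~ 1
    fit = fit_reml(constant_dataset(4.0))
    res = cellpop_f_test(fit)
    assert res.f_statistic == pytest.approx(0.0, abs=1e-6)
    assert res.p_value == pytest.approx(1.0, abs=1e-6)
    assert res.numerator_df == 1 and res.denominator_df == 2
    # one population shifted by a huge constant -> tiny p
    dataset, _ = generate_dataset(
        GeneratorConfig(
            n_genes=30,
            populations=[("a", 3), ("b", 3)],
            grand_mean=5.0,
            cellpop_effects={"b": 50.0},
            var_sample=0.01,
            var_gene=1.0,
            gene_cellpop_mode="gaussian",
            var_gene_cellpop=0.1,
            var_resid=0.1,
            seed=2,
        )
    )
    assert cellpop_f_test(fit_reml(dataset)).p_value < 1e-3


def test_f_test_type_one_error_is_controlled():
    """With no true population effect, the Wald F at denominator df
    (arrays - populations) rejects at 0.05 no more often than the binomial
    band allows (the simplified df makes it conservative, never liberal)."""
    n = 120
    rejections = 0
    for s in range(n):
        dataset, _ = generate_dataset(reference_config(n_genes=80, seed=3000 + s))
        rejections += cellpop_f_test(fit_reml(dataset)).p_value < 0.05
    rate = rejections / n
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


@pytest.mark.parametrize(
    "populations,n_genes,match",
    [
        ([("only", 3)], 5, "single population"),
        ([("a", 1), ("b", 1)], 5, "confounded"),
        ([("a", 2), ("b", 2)], 1, "2 genes"),
    ],
)
def test_unidentifiable_designs_are_rejected(populations, n_genes, match):
    cfg = GeneratorConfig(
        n_genes=n_genes, populations=populations, grand_mean=1.0, var_resid=0.1, seed=0
    )
    dataset, _ = generate_dataset(cfg)
    with pytest.raises(DesignError, match=match):
        fit_reml(dataset)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_matches_lme4_reml(tmp_path):
    """Independent oracle: lme4's REML on the same data agrees on variance
    components and fixed effects."""
    dataset, _ = generate_dataset(reference_config(n_genes=120, seed=3))
    fit = fit_reml(dataset)
    df = dataset.values.stack().rename("y").reset_index()
    df.columns = ["gene", "array", "y"]
    df["pop"] = df["array"].map(dataset.array_population)
    data_path = tmp_path / "data.tsv"
    df.to_csv(data_path, sep="\t", index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.delim("{data_path}")
            d$pop <- factor(d$pop, levels = unique(d$pop))
            m <- lmer(y ~ pop + (1|array) + (1|gene) + (1|gene:pop),
                      data = d, REML = TRUE)
            vc <- as.data.frame(VarCorr(m))
            for (i in seq_len(nrow(vc))) cat(vc$grp[i], vc$vcov[i], "\\n")
            cat("beta", fixef(m), "\\n")
            """
        )
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    ref = {}
    for line in out.stdout.strip().splitlines():
        parts = line.split()
        if parts[0] == "beta":
            ref["beta"] = [float(x) for x in parts[1:]]
        else:
            ref[parts[0]] = float(parts[1])
    vc = fit.variance_components
    assert vc.var_sample == pytest.approx(ref["array"], rel=1e-3, abs=1e-6)
    assert vc.var_gene == pytest.approx(ref["gene"], rel=1e-3)
    assert vc.var_gene_cellpop == pytest.approx(ref["gene:pop"], rel=1e-3)
    assert vc.var_resid == pytest.approx(ref["Residual"], rel=1e-3)
    np.testing.assert_allclose(fit.fixed_effects["estimate"], ref["beta"], atol=1e-4)
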