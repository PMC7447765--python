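"""REML fit of the crossed random-effects model for log-expression.

The model for gene g on array a (array a sorted from population p(a)) is

    y[g,a] = mu + beta[p(a)] + S[a] + G[g] + GC[g,p(a)] + eps[g,a]

with independent random effects S ~ N(0, sigma_S^2) (array), G ~ N(0,
sigma_G^2) (gene), GC ~ N(0, sigma_GCP^2) (gene-by-population) and residual
eps ~ N(0, sigma_e^2). Variance components are estimated by REML; random
effects by BLUP from the mixed-model equations at the converged components.

Because the fixed effects are array-level and every gene is observed on
every array, the restricted likelihood collapses: rotating the gene
dimension onto the gene-mean direction and its orthogonal complement
block-diagonalizes the marginal covariance into one (A x A) block
M = C + n_genes * sigma_S^2 * I for the gene-mean component and n_genes - 1
identical (A x A) blocks C = sigma_G^2 J + sigma_GCP^2 B + sigma_e^2 I for
the contrasts, where B indicates array pairs from the same population. The
likelihood, its score and the average-information matrix then depend on the
data only through the A-vector of per-array gene means and the A x A
within-gene cross-product matrix, so each iteration costs O(A^3) regardless
of the number of genes, without ever materializing the dense covariance.

Estimation follows a stabilized schedule: EM-REML steps first (each is a
scaled gradient step, guaranteed not to decrease the restricted likelihood),
then average-information updates with step-halving back to the EM step
whenever an AI proposal would decrease the likelihood. Negative proposals
are truncated at a small positive floor; a component pinned at the floor for
three consecutive iterations is reported as zero and removed from the
update set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionDataset

__all__ = [
    "VarianceComponents",
    "FixedEffectTest",
    "LMMFit",
    "DesignError",
    "NotConvergedError",
    "fit_reml",
    "extract_gene_cellpop_effects",
    "raw_gene_cellpop_means",
    "cellpop_f_test",
]

_COMPONENTS = ("var_sample", "var_gene", "var_gene_cellpop", "var_resid")
_FLOOR = 1e-10
_PIN_ITERS = 3


class DesignError(ValueError):
    """The design cannot identify all variance components."""


class NotConvergedError(RuntimeError):
    """A downstream stage was handed a fit that did not converge."""


@dataclass
class VarianceComponents:
    """REML point estimates and standard errors of the four components."""

    var_sample: float
    var_gene: float
    var_gene_cellpop: float
    var_resid: float
    se_sample: float = float("nan")
    se_gene: float = float("nan")
    se_gene_cellpop: float = float("nan")
    se_resid: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "var_sample": self.var_sample,
            "var_gene": self.var_gene,
            "var_gene_cellpop": self.var_gene_cellpop,
            "var_resid": self.var_resid,
            "se_sample": self.se_sample,
            "se_gene": self.se_gene,
            "se_gene_cellpop": self.se_gene_cellpop,
            "se_resid": self.se_resid,
        }


@dataclass
class FixedEffectTest:
    """Wald F-test of equality of the population means."""

    f_statistic: float
    numerator_df: int
    denominator_df: int
    p_value: float


@dataclass
class LMMFit:
    variance_components: VarianceComponents
    fixed_effects: pd.DataFrame  # term, estimate, se
    gene_cellpop_blups: pd.DataFrame  # gene x population
    sample_blups: pd.Series
    gene_blups: pd.Series
    reml_loglik: float
    n_iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    populations: list[str] = field(default_factory=list)
    n_genes: int = 0
    n_arrays: int = 0
    # GLS covariance of the fixed-effect estimates, term order as fixed_effects
    beta_cov: np.ndarray | None = None

    def require_converged(self) -> None:
        if not self.converged:
            raise NotConvergedError(
                "REML did not converge; refusing to use this fit downstream"
            )


def _design(dataset: ExpressionDataset):
    """Array-level design pieces: X (intercept + population dummies), the
    same-population indicator B, and the array->population index."""
    pops = dataset.populations
    arrays = dataset.array_ids
    pop_idx = np.array([pops.index(dataset.array_population[a]) for a in arrays])
    A, P = len(arrays), len(pops)
    X = np.zeros((A, P))
    X[:, 0] = 1.0
    for j in range(1, P):
        X[pop_idx == j, j] = 1.0
    B = (pop_idx[:, None] == pop_idx[None, :]).astype(float)
    Z_pop = np.zeros((A, P))
    Z_pop[np.arange(A), pop_idx] = 1.0
    return pops, pop_idx, X, B, Z_pop


def _check_identifiable(dataset: ExpressionDataset) -> None:
    pops = dataset.populations
    if dataset.n_genes < 2:
        raise DesignError("need at least 2 genes to separate Gene from the mean")
    if len(pops) < 2:
        raise DesignError(
            "single population: CellPop is confounded with the constant and "
            "Gene.CellPop with Gene"
        )
    counts = [len(dataset.arrays_in(p)) for p in pops]
    if max(counts) < 2:
        raise DesignError(
            "every population has a single array: Gene.CellPop and the "
            "residual are confounded (and Sample with CellPop)"
        )


def _loglik_parts(theta: np.ndarray, suff: dict) -> tuple[float, dict]:
    """Restricted log-likelihood and intermediates at variance components
    theta = (var_sample, var_gene, var_gene_cellpop, var_resid)."""
    vs, vg, vgc, ve = theta
    A = suff["A"]
    Gn = suff["G"]
    J = suff["J"]
    B = suff["B"]
    X = suff["X"]
    W = suff["W"]
    ybar = suff["ybar"]

    C = vg * J + vgc * B + ve * np.eye(A)
    M = C + Gn * vs * np.eye(A)

    sign_c, logdet_c = np.linalg.slogdet(C)
    sign_m, logdet_m = np.linalg.slogdet(M)
    if sign_c <= 0 or sign_m <= 0:
        return -np.inf, {}
    Cinv = np.linalg.inv(C)
    Minv = np.linalg.inv(M)

    XtMiX = X.T @ Minv @ X
    sign_x, logdet_x = np.linalg.slogdet(Gn * XtMiX)
    if sign_x <= 0:
        return -np.inf, {}
    XtMiX_inv = np.linalg.inv(XtMiX)
    beta = XtMiX_inv @ (X.T @ (Minv @ ybar))
    resid = ybar - X @ beta
    Mi_r = Minv @ resid

    n, p = Gn * A, X.shape[1]
    quad = float(np.sum(Cinv * W)) + Gn * float(resid @ Mi_r)
    ll = -0.5 * (
        (Gn - 1) * logdet_c
        + logdet_m
        + logdet_x
        + quad
        + (n - p) * np.log(2.0 * np.pi)
    )
    aux = {
        "C": C, "M": M, "Cinv": Cinv, "Minv": Minv,
        "beta": beta, "resid": resid, "Mi_r": Mi_r,
        "XtMiX_inv": XtMiX_inv,
    }
    return float(ll), aux


def _score_ai(theta: np.ndarray, suff: dict, aux: dict) -> tuple[np.ndarray, np.ndarray]:
    """REML score vector and average-information matrix (4 x 4)."""
    A = suff["A"]
    Gn = suff["G"]
    J, B, X, W = suff["J"], suff["B"], suff["X"], suff["W"]
    I = np.eye(A)
    Cinv, Minv = aux["Cinv"], aux["Minv"]
    XtMiX_inv, Mi_r = aux["XtMiX_inv"], aux["Mi_r"]

    # derivative of C / of M w.r.t. each component
    C_d = [np.zeros((A, A)), J, B, I]
    M_d = [Gn * I, J, B, I]

    MiX = Minv @ X
    P_M = Minv - MiX @ XtMiX_inv @ MiX.T  # projected inverse, mean block
    g_m = Mi_r  # P_M @ ybar == Minv @ resid

    score = np.zeros(4)
    u_c = []  # Cinv Ci Cinv terms reused for AI
    for i in range(4):
        Ci, Mi = C_d[i], M_d[i]
        tr_c = (Gn - 1) * np.sum(Cinv * Ci) if Ci.any() else 0.0
        CiCiCi = Cinv @ Ci @ Cinv if Ci.any() else None
        quad_c = np.sum(CiCiCi * W) if CiCiCi is not None else 0.0
        tr_m = np.sum(P_M * Mi)
        quad_m = Gn * float(g_m @ Mi @ g_m)
        score[i] = -0.5 * (tr_c - quad_c + tr_m - quad_m)
        u_c.append(CiCiCi)

    ai = np.zeros((4, 4))
    for i in range(4):
        for j in range(i, 4):
            t = 0.0
            if u_c[i] is not None and C_d[j].any():
                t += np.sum((u_c[i] @ C_d[j] @ Cinv) * W)
            v_i = M_d[i] @ g_m
            v_j = M_d[j] @ g_m
            t += Gn * float(v_i @ P_M @ v_j)
            ai[i, j] = ai[j, i] = 0.5 * t
    return score, ai


def fit_reml(
    dataset: ExpressionDataset,
    max_iter: int = 200,
    em_iters: int = 10,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
) -> LMMFit:
    """Estimate the four variance components by REML and solve the BLUPs.

    Raises :class:`DesignError` when the design cannot separate the
    components. A fit that exhausts ``max_iter`` is returned with
    ``converged=False``; downstream stages refuse to consume it.
    """
    _check_identifiable(dataset)
    pops, pop_idx, X, B, Z_pop = _design(dataset)
    Y = dataset.values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("expression matrix contains missing values")
    Gn, A = Y.shape
    P = len(pops)

    ybar = Y.mean(axis=0)
    Yc = Y - ybar
    W = Yc.T @ Yc
    suff = {"A": A, "G": Gn, "J": np.ones((A, A)), "B": B, "X": X, "W": W, "ybar": ybar}

    # data-driven starting values; EM iterations absorb rough choices
    gene_means = Y.mean(axis=1)
    v_between = float(np.var(gene_means))
    v_within = float(np.mean(np.var(Yc, axis=1))) if A > 1 else 0.0
    theta = np.array(
        [
            max(float(np.var(ybar)) * 0.25, _FLOOR),
            max(v_between, _FLOOR),
            max(v_within * 0.5, _FLOOR),
            max(v_within * 0.5, _FLOOR),
        ]
    )
    q = np.array([A, Gn, Gn * P, Gn * A], dtype=float)  # levels per term

    ll, aux = _loglik_parts(theta, suff)
    trace = [ll]
    pin_count = np.zeros(4, dtype=int)
    pinned = np.zeros(4, dtype=bool)
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        score, ai = _score_ai(theta, suff, aux)
        free = ~pinned

        def em_step() -> np.ndarray:
            new = theta.copy()
            new[free] = theta[free] + (2.0 * theta[free] ** 2 / q[free]) * score[free]
            return np.maximum(new, _FLOOR)

        accepted = None
        if it > em_iters and free.any():
            ai_f = ai[np.ix_(free, free)]
            try:
                delta = np.linalg.solve(ai_f, score[free])
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(10):
                    cand = theta.copy()
                    cand[free] = np.maximum(theta[free] + step * delta, _FLOOR)
                    ll_c, aux_c = _loglik_parts(cand, suff)
                    if ll_c >= ll - 1e-10:
                        accepted = (cand, ll_c, aux_c)
                        break
                    step *= 0.5
        if accepted is None:
            cand = em_step()
            ll_c, aux_c = _loglik_parts(cand, suff)
            accepted = (cand, ll_c, aux_c)

        new_theta, new_ll, new_aux = accepted
        d_ll = abs(new_ll - ll) / (abs(ll) + 1.0)
        d_par = float(np.max(np.abs(new_theta - theta) / (np.abs(theta) + 1e-12)))

        at_floor = new_theta <= 10.0 * _FLOOR
        pin_count = np.where(at_floor, pin_count + 1, 0)
        pinned = pinned | (pin_count >= _PIN_ITERS)

        theta, ll, aux = new_theta, new_ll, new_aux
        trace.append(ll)

        if d_ll < tol_loglik and d_par < tol_param:
            converged = True
            break
        if pinned.all():
            converged = True
            break

    # standard errors from the inverse average information over free components
    score, ai = _score_ai(theta, suff, aux)
    se = np.zeros(4)
    free = ~(theta <= 10.0 * _FLOOR)
    if free.any():
        ai_f = ai[np.ix_(free, free)]
        try:
            cov = np.linalg.inv(ai_f)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(ai_f)
        se[free] = np.sqrt(np.maximum(np.diag(cov), 0.0))

    report_theta = np.where(theta <= 10.0 * _FLOOR, 0.0, theta)
    vc = VarianceComponents(
        var_sample=float(report_theta[0]),
        var_gene=float(report_theta[1]),
        var_gene_cellpop=float(report_theta[2]),
        var_resid=float(report_theta[3]),
        se_sample=float(se[0]),
        se_gene=float(se[1]),
        se_gene_cellpop=float(se[2]),
        se_resid=float(se[3]),
    )

    # fixed effects (GLS on the gene-mean block) and BLUPs at the optimum
    beta = aux["beta"]
    beta_cov = aux["XtMiX_inv"] / Gn
    beta_se = np.sqrt(np.maximum(np.diag(beta_cov), 0.0))
    terms = ["(intercept)"] + [f"pop[{p}]" for p in pops[1:]]
    fixed = pd.DataFrame({"term": terms, "estimate": beta, "se": beta_se})

    # BLUP multipliers use the reported components, so an effect whose
    # variance is estimated as zero gets exactly-zero predictions
    vs, vg, vgc, _ = report_theta
    Mi_r = aux["Mi_r"]
    Cinv = aux["Cinv"]
    resid_rows = Yc @ Cinv + Mi_r[None, :]  # t[g] = Cinv (e_g - ebar) + Minv ebar
    sample_blups = pd.Series(vs * Gn * Mi_r, index=dataset.array_ids)
    gene_blups = pd.Series(vg * resid_rows.sum(axis=1), index=dataset.gene_ids)
    gc_blups = pd.DataFrame(
        vgc * (resid_rows @ Z_pop), index=dataset.gene_ids, columns=pops
    )

    return LMMFit(
        variance_components=vc,
        fixed_effects=fixed,
        gene_cellpop_blups=gc_blups,
        sample_blups=sample_blups,
        gene_blups=gene_blups,
        reml_loglik=float(ll),
        n_iterations=it,
        converged=converged,
        loglik_trace=trace,
        populations=pops,
        n_genes=Gn,
        n_arrays=A,
        beta_cov=beta_cov,
    )


def extract_gene_cellpop_effects(fit: LMMFit) -> pd.DataFrame:
    """Gene x population matrix of BLUP interaction estimates (stage-two input)."""
    fit.require_converged()
    return fit.gene_cellpop_blups.copy()


def raw_gene_cellpop_means(dataset: ExpressionDataset) -> pd.DataFrame:
    """Unshrunken per-cell interaction means (double-centered population
    means), provided for sensitivity analysis against the BLUPs."""
    pops = dataset.populations
    cell = pd.DataFrame(
        {p: dataset.values[dataset.arrays_in(p)].mean(axis=1) for p in pops}
    )
    centered = cell.sub(cell.mean(axis=1), axis=0)
    return centered.sub(centered.mean(axis=0), axis=1)


def cellpop_f_test(fit: LMMFit) -> FixedEffectTest:
    """Wald F-test of equality of the population means.

    Denominator degrees of freedom are taken from the array stratum
    (n_arrays - n_populations), a deliberate simplification relative to
    adjusted-df methods.
    """
    fit.require_converged()
    P = len(fit.populations)
    if P < 2:
        raise DesignError("fixed-effect test undefined with a single population")
    beta = fit.fixed_effects["estimate"].to_numpy()
    cov = fit.beta_cov
    assert cov is not None
    L = np.zeros((P - 1, P))
    L[:, 1:] = np.eye(P - 1)  # population contrasts vs the reference
    lb = L @ beta
    lcov = L @ cov @ L.T
    f = float(lb @ np.linalg.solve(lcov, lb)) / (P - 1)
    f = max(f, 0.0)
    df2 = fit.n_arrays - P
    if df2 < 1:
        raise DesignError("no residual arrays left for the denominator stratum")
    p_value = float(stats.f.sf(f, P - 1, df2))
    return FixedEffectTest(
        f_statistic=f, numerator_df=P - 1, denominator_df=df2, p_value=p_value
    )
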