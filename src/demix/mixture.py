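"""Stage two: a two-component zero-mean normal scale mixture over effect
estimates, fitted per population by EM.

The gene-by-population interaction estimates from the mixed model are
modelled as draws from

    f(x) = (1 - pi1) N(x; 0, sigma0^2) + pi1 N(x; 0, sigma1^2),

with the narrow component carrying non-differentially-expressed genes and
the wide component (sigma1 > sigma0) the differentially expressed ones. The
posterior probability of the wide component is the DE probability; a gene is
called DE when it exceeds the threshold (0.8 by default), and the
model-based false discovery rate of a call set is the mean of
(1 - posterior) over the called genes.

Because both component means are fixed at zero, the EM M-step is closed
form: the mixing weight is the mean responsibility and each variance the
responsibility-weighted mean square. The likelihood has a degenerate spike
as sigma0 -> 0 at any sample point equal to zero; the fitter guards against
it with a floor on the SDs and a small multi-start over jittered
initializations, keeping the best converged solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MixtureParams",
    "MixtureFit",
    "DECalls",
    "DegenerateInputError",
    "fit_scale_mixture",
    "posterior_de",
    "classify_and_fdr",
    "de_threshold_effect",
    "overall_fdr",
]


class DegenerateInputError(ValueError):
    """Input has no spread; the scale mixture is unfittable."""


@dataclass
class MixtureParams:
    """(pi1, sigma0, sigma1) with the ordering convention sigma0 <= sigma1."""

    pi1: float
    sigma0: float
    sigma1: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError("pi1 must lie in [0, 1]")
        if not 0.0 < self.sigma0 <= self.sigma1:
            raise ValueError("require 0 < sigma0 <= sigma1")


@dataclass
class MixtureFit:
    params: MixtureParams
    posteriors: np.ndarray
    loglik_trace: list[float]
    n_iterations: int
    converged: bool

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def require_converged(self) -> None:
        if not self.converged:
            raise RuntimeError("mixture EM did not converge; refusing to classify")


@dataclass
class DECalls:
    """DE classification of one population's effect estimates."""

    population: str
    threshold: float
    de_genes: dict[str, int]  # gene id -> sign (+1 over-, -1 underexpressed)
    fdr: float | None  # None when the call set is empty
    effect_cutoff: float  # |effect| above which a gene is called
    posteriors: dict[str, float] = field(default_factory=dict)

    @property
    def n_de(self) -> int:
        return len(self.de_genes)

    @property
    def up(self) -> set[str]:
        return {g for g, s in self.de_genes.items() if s > 0}

    @property
    def down(self) -> set[str]:
        return {g for g, s in self.de_genes.items() if s < 0}


def _loglik(x: np.ndarray, pi1: float, s0: float, s1: float) -> float:
    l0 = stats.norm.logpdf(x, scale=s0) + math.log(max(1.0 - pi1, 1e-300))
    l1 = stats.norm.logpdf(x, scale=s1) + math.log(max(pi1, 1e-300))
    return float(np.logaddexp(l0, l1).sum())


def _em(
    x: np.ndarray, pi1: float, s0: float, s1: float, floor: float,
    tol: float, max_iter: int,
) -> tuple[float, float, float, np.ndarray, list[float], bool, int]:
    trace: list[float] = []
    ll_prev = -np.inf
    converged = False
    it = 0
    x2 = x * x
    r1 = np.empty_like(x)
    for it in range(1, max_iter + 1):
        # E-step: responsibility of the wide component
        l0 = stats.norm.logpdf(x, scale=s0) + math.log(max(1.0 - pi1, 1e-300))
        l1 = stats.norm.logpdf(x, scale=s1) + math.log(max(pi1, 1e-300))
        ll = float(np.logaddexp(l0, l1).sum())
        trace.append(ll)
        r1 = 1.0 / (1.0 + np.exp(l0 - l1))
        # M-step: closed form for a zero-mean scale mixture
        w1 = float(r1.sum())
        w0 = len(x) - w1
        pi1 = w1 / len(x)
        if w0 > 0:
            s0 = max(math.sqrt(float(((1.0 - r1) * x2).sum()) / w0), floor)
        if w1 > 0:
            s1 = max(math.sqrt(float((r1 * x2).sum()) / w1), floor)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    if s1 < s0:  # enforce the label-ordering convention
        s0, s1, pi1 = s1, s0, 1.0 - pi1
        r1 = 1.0 - r1
    return pi1, s0, s1, r1, trace, converged, it


def fit_scale_mixture(
    effects: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 20000,
    n_starts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """EM maximum-likelihood fit of the two-component zero-mean mixture.

    Runs ``n_starts`` EM chains (the default initialization pi1 = 0.25,
    sigma0 = 0.5 SD(x), sigma1 = 2 SD(x), plus jittered variants from a
    fixed sub-seeded RNG) and keeps the best converged log-likelihood.
    """
    x = np.asarray(effects, dtype=float).ravel()
    if x.size < 10 or not np.isfinite(x).all():
        raise ValueError("need at least 10 finite effect estimates")
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateInputError("all effect estimates identical; no spread to model")
    floor = 1e-6 * sd

    rng = np.random.default_rng(seed)
    starts = [(0.25, 0.5 * sd, 2.0 * sd)]
    for _ in range(n_starts - 1):
        starts.append(
            (
                float(rng.uniform(0.05, 0.6)),
                0.5 * sd * float(rng.uniform(0.4, 1.2)),
                2.0 * sd * float(rng.uniform(0.6, 1.8)),
            )
        )

    # keep the best-likelihood converged chain; fall back to the best
    # unconverged one (returned flagged) only when no chain converges
    best: tuple | None = None
    for pi0, a0, a1 in starts:
        res = _em(x, pi0, a0, a1, floor, tol, max_iter)
        if best is None:
            best = res
            continue
        better_ll = res[4][-1] > best[4][-1]
        if (res[5] and not best[5]) or (res[5] == best[5] and better_ll):
            best = res
    assert best is not None
    pi1, s0, s1, r1, trace, converged, it = best
    return MixtureFit(
        params=MixtureParams(pi1=pi1, sigma0=s0, sigma1=s1),
        posteriors=r1,
        loglik_trace=trace,
        n_iterations=it,
        converged=converged,
    )


def posterior_de(x, params: MixtureParams):
    """Posterior probability that x was drawn from the wide (DE) component.

    Symmetric in x and non-decreasing in |x| when sigma1 > sigma0; when the
    two SDs coincide the densities cancel and the posterior is pi1
    everywhere.
    """
    x = np.asarray(x, dtype=float)
    if params.pi1 == 0.0:
        return np.zeros_like(x) if x.ndim else 0.0
    if params.pi1 == 1.0:
        return np.ones_like(x) if x.ndim else 1.0
    l0 = stats.norm.logpdf(x, scale=params.sigma0) + math.log(1.0 - params.pi1)
    l1 = stats.norm.logpdf(x, scale=params.sigma1) + math.log(params.pi1)
    out = 1.0 / (1.0 + np.exp(l0 - l1))
    return float(out) if out.ndim == 0 else out


def de_threshold_effect(params: MixtureParams, threshold: float = 0.8) -> float:
    """The |effect| cutoff c with posterior_de(c) = threshold.

    Classification at a posterior threshold is equivalent to the symmetric
    rule |x| > c; returns 0 when even x = 0 exceeds the threshold and
    infinity when no effect does (e.g. sigma0 == sigma1 with pi1 below the
    threshold).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if posterior_de(0.0, params) > threshold:
        return 0.0
    if params.sigma1 == params.sigma0:
        return math.inf
    hi = 10.0 * params.sigma1
    while posterior_de(hi, params) <= threshold:
        hi *= 2.0
        if hi > 1e12 * params.sigma1:
            return math.inf
    return float(
        optimize.brentq(lambda v: posterior_de(v, params) - threshold, 0.0, hi)
    )


def classify_and_fdr(
    fit: MixtureFit,
    effects,
    gene_ids,
    population: str = "",
    threshold: float = 0.8,
) -> DECalls:
    """Call DE genes at the posterior threshold and compute the model-based
    FDR of the call set (mean of 1 - posterior over called genes).

    An empty call set reports fdr = None (undefined), never 0.
    """
    fit.require_converged()
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    x = np.asarray(effects, dtype=float).ravel()
    gene_ids = list(gene_ids)
    if len(gene_ids) != x.size or x.size != fit.posteriors.size:
        raise ValueError("effects, gene_ids and fit posteriors are misaligned")
    post = posterior_de(x, fit.params)
    called = post > threshold
    de: dict[str, int] = {}
    for g, xi, ci in zip(gene_ids, x, called):
        if not ci:
            continue
        if xi == 0.0:
            continue  # sign undefined at exactly zero (measure-zero event)
        de[g] = 1 if xi > 0 else -1
    fdr = float(np.mean(1.0 - post[called])) if called.any() else None
    return DECalls(
        population=population,
        threshold=threshold,
        de_genes=de,
        fdr=fdr,
        effect_cutoff=de_threshold_effect(fit.params, threshold),
        posteriors=dict(zip(gene_ids, post.tolist())),
    )


def overall_fdr(calls: list[DECalls]) -> float:
    """DE-count-weighted mean FDR across populations.

    Equals sum(n_de_i * fdr_i) / sum(n_de_i) over the non-empty call sets;
    undefined (raises) when every call set is empty.
    """
    num = 0.0
    den = 0
    for c in calls:
        if c.n_de > 0:
            if c.fdr is None:
                raise ValueError(f"call set {c.population!r} has genes but no fdr")
            num += c.n_de * c.fdr
            den += c.n_de
    if den == 0:
        raise ValueError("overall FDR undefined: all call sets are empty")
    return num / den
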