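"""Scale-mixture EM: grid-search oracle, closed-form posteriors, FDR logic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from demix.mixture import (
    DegenerateInputError,
    MixtureParams,
    classify_and_fdr,
    de_threshold_effect,
    fit_scale_mixture,
    overall_fdr,
    posterior_de,
)
from demix.reference import FDR, MIXTURE_PARAMS, N_DE
from demix.simulate import generate_mixture_sample

STEM = MixtureParams(*MIXTURE_PARAMS["CD49f_high/P-cad_neg"])  # (0.375, 0.261, 1.109)


def mixture_loglik(x, pi1, s0, s1):
    f = (1 - pi1) * stats.norm.pdf(x, scale=s0) + pi1 * stats.norm.pdf(x, scale=s1)
    return float(np.log(f).sum())


def test_em_attains_grid_search_likelihood():
    """On a 40-point sample the EM solution's log-likelihood is within 1e-3
    of an exhaustive grid search around it (grid step 0.01 on pi1, 0.005 on
    the SDs)."""
    x, _ = generate_mixture_sample(0.4, 0.3, 1.2, 40, seed=17)
    fit = fit_scale_mixture(x)
    p = fit.params
    best = -np.inf
    for pi1 in np.arange(max(p.pi1 - 0.15, 0.01), min(p.pi1 + 0.15, 0.99), 0.01):
        for s0 in np.arange(max(p.sigma0 - 0.1, 0.01), p.sigma0 + 0.1, 0.005):
            for s1 in np.arange(max(p.sigma1 - 0.2, s0), p.sigma1 + 0.2, 0.005):
                best = max(best, mixture_loglik(x, pi1, s0, s1))
    assert fit.loglik >= best - 1e-3


def test_em_trace_is_monotone_and_ordered():
    x, _ = generate_mixture_sample(0.3, 0.25, 1.1, 3000, seed=5)
    fit = fit_scale_mixture(x)
    trace = np.array(fit.loglik_trace)
    assert np.all(np.diff(trace) >= -1e-8)
    assert fit.params.sigma0 <= fit.params.sigma1
    # determinism: refitting yields the identical reported solution
    fit2 = fit_scale_mixture(x)
    assert fit2.params == fit.params


def test_single_gaussian_input_collapses():
    """Data from one N(0,1): both SDs land near 1 and the mixture gains
    almost nothing over the single-Gaussian log-likelihood."""
    rng = np.random.default_rng(1)
    x = rng.standard_normal(2000)
    fit = fit_scale_mixture(x)
    single = float(stats.norm.logpdf(x, scale=x.std()).sum())
    assert fit.loglik >= single - 1e-6
    assert fit.loglik - single < 2.0  # no real structure to exploit
    assert 0.8 < fit.params.sigma0 <= fit.params.sigma1 < 1.25


def test_parameter_recovery_stem_population():
    x, _ = generate_mixture_sample(0.375, 0.261, 1.109, 20000, seed=5)
    fit = fit_scale_mixture(x)
    assert fit.converged
    assert fit.params.pi1 == pytest.approx(0.375, abs=0.03)
    assert fit.params.sigma0 == pytest.approx(0.261, abs=0.02)
    assert fit.params.sigma1 == pytest.approx(1.109, abs=0.04)


def test_posterior_closed_form_values():
    # at x = 0 the ratio reduces to (pi1/s1) / (pi1/s1 + (1-pi1)/s0)
    expect0 = (0.375 / 1.109) / (0.375 / 1.109 + 0.625 / 0.261)
    assert posterior_de(0.0, STEM) == pytest.approx(expect0, abs=1e-9)
    assert posterior_de(0.0, STEM) == pytest.approx(0.124, abs=0.001)
    # 3 units is ~11.5 narrow-component SDs: posterior saturates
    assert posterior_de(3.0, STEM) > 0.999
    # equal SDs: densities cancel, posterior is pi1 everywhere
    eq = MixtureParams(0.3, 0.5, 0.5)
    for x in (-2.0, 0.0, 0.7):
        assert posterior_de(x, eq) == pytest.approx(0.3, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.floats(-5, 5))
def test_posterior_symmetric_and_monotone_in_abs_x(x):
    p = posterior_de(x, STEM)
    assert 0.0 <= p <= 1.0
    assert p == pytest.approx(posterior_de(-x, STEM), abs=1e-12)
    assert posterior_de(abs(x) + 0.1, STEM) >= p - 1e-12


def test_classification_is_a_symmetric_threshold_rule():
    """Calling at posterior > 0.8 equals the rule |x| > c; c for the stem
    population is about 0.69 (bisection on the closed form as oracle)."""
    lo, hi = 0.0, 5.0
    for _ in range(200):  # independent bisection oracle
        mid = 0.5 * (lo + hi)
        if posterior_de(mid, STEM) > 0.8:
            hi = mid
        else:
            lo = mid
    c_oracle = 0.5 * (lo + hi)
    c = de_threshold_effect(STEM, 0.8)
    assert c == pytest.approx(c_oracle, abs=1e-6)
    assert c == pytest.approx(0.69, abs=0.01)

    x, _ = generate_mixture_sample(0.375, 0.261, 1.109, 2000, seed=3)
    fit = fit_scale_mixture(x)
    calls = classify_and_fdr(fit, x, [f"g{i}" for i in range(len(x))], "stem")
    c_fit = de_threshold_effect(fit.params, 0.8)
    expected = {f"g{i}" for i, xi in enumerate(x) if abs(xi) > c_fit}
    assert set(calls.de_genes) == expected
    # signs follow the effect estimate
    assert all((x[int(g[1:])] > 0) == (s > 0) for g, s in calls.de_genes.items())


def test_fdr_bounded_by_one_minus_threshold():
    x, _ = generate_mixture_sample(0.375, 0.261, 1.109, 5000, seed=9)
    fit = fit_scale_mixture(x)
    calls = classify_and_fdr(fit, x, [f"g{i}" for i in range(len(x))], "stem")
    assert calls.n_de > 0
    assert calls.fdr is not None and calls.fdr < 0.2
    assert calls.fdr == pytest.approx(
        np.mean([1 - calls.posteriors[g] for g in calls.de_genes]), abs=1e-12
    )


def test_empty_call_set_has_undefined_fdr():
    from demix.mixture import MixtureFit

    x = np.linspace(-0.1, 0.1, 20)  # every posterior below the threshold
    fit = MixtureFit(
        params=STEM,
        posteriors=posterior_de(x, STEM),
        loglik_trace=[0.0],
        n_iterations=1,
        converged=True,
    )
    calls = classify_and_fdr(fit, x, [f"g{i}" for i in range(len(x))], "p")
    assert calls.n_de == 0
    assert calls.fdr is None
    with pytest.raises(ValueError, match="undefined"):
        overall_fdr([calls])


def test_threshold_validation_and_degenerate_input():
    x, _ = generate_mixture_sample(0.3, 0.3, 1.0, 100, seed=1)
    fit = fit_scale_mixture(x)
    with pytest.raises(ValueError, match="threshold"):
        classify_and_fdr(fit, x, [f"g{i}" for i in range(len(x))], "p", threshold=1.5)
    with pytest.raises(DegenerateInputError):
        fit_scale_mixture(np.zeros(100))
    with pytest.raises(ValueError, match="finite"):
        fit_scale_mixture(np.array([1.0, np.nan] * 10))


class _Calls:
    def __init__(self, n_de, fdr):
        self.n_de, self.fdr, self.population = n_de, fdr, "x"


def test_overall_fdr_arithmetic():
    assert overall_fdr([_Calls(10, 0.05)]) == pytest.approx(0.05)
    assert overall_fdr([_Calls(100, 0.02), _Calls(100, 0.04)]) == pytest.approx(0.03)


def test_overall_fdr_reference_study_values():
    """The DE-count-weighted mean of the study's four per-population FDRs
    reproduces its overall 3.2% false-discovery figure."""
    calls = [_Calls(N_DE[p], FDR[p]) for p in N_DE]
    assert round(overall_fdr(calls), 3) == 0.032
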