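"""MCMC engine: correctness oracles, determinism, summaries, diagnostics."""

import numpy as np
import pytest
from scipy.integrate import quad

from spatzip import (
    ModelSpec,
    ObservedData,
    PCMixingPrior,
    SamplerConfig,
    diagnostics,
    fit,
    posterior_summary,
)
from spatzip.inference import PosteriorSamples, _split_rhat
from spatzip.priors import pc_prec_lambda, pc_prec_logpdf


def test_same_seed_identical_draws(path3_precision):
    data = ObservedData(o=np.array([2.0, 0.0, 5.0]), E=np.ones(3))
    spec = ModelSpec(family="poisson", latent="bym2", data=data, precision=path3_precision)
    cfg = SamplerConfig(n_iter=200, n_burnin=50, seed=3)
    s1, s2 = fit(spec, cfg), fit(spec, cfg)
    for key in s1.draws:
        assert np.array_equal(s1.draws[key], s2.draws[key])
    assert np.array_equal(s1.gamma, s2.gamma)


def test_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(n_iter=100, n_burnin=100)
    with pytest.raises(ValueError):
        SamplerConfig(thin=0)


def test_nearly_pooled_poisson_matches_analytic_mode(lattice22_precision):
    # with gamma pinned near zero (huge tau, phi=0) the model reduces to
    # o ~ Poisson(E e^alpha) with a flat-ish prior: posterior of alpha is
    # log-gamma with mode log(sum o / sum E)
    o = np.array([7.0, 3.0, 5.0, 4.0])
    E = np.full(4, 2.0)
    data = ObservedData(o=o, E=E)
    spec = ModelSpec(family="poisson", latent="bym2", data=data, precision=lattice22_precision)
    cfg = SamplerConfig(
        n_iter=4000, n_burnin=500, seed=9, fixed_hyper={"tau_gamma": 1e8, "phi": 0.0}
    )
    s = fit(spec, cfg)
    alpha = s.draws["alpha_o"]
    mode = np.log(o.sum() / E.sum())
    # posterior mean of log-gamma(sum o, sum E) = digamma(sum o) - log(sum E)
    from scipy.special import digamma

    expected = digamma(o.sum()) - np.log(E.sum())
    mcse = alpha.std(ddof=1) / np.sqrt(max(float(diagnostics(s, ["alpha_o"]).loc["alpha_o", "ess"]), 1.0))
    assert abs(alpha.mean() - expected) < max(3 * mcse, 0.02)
    assert abs(alpha.mean() - mode) < 0.05


def test_no_data_posterior_equals_prior(lattice33_precision):
    # with every response missing the chain must sample the prior
    n = 9
    data = ObservedData(o=np.full(n, np.nan), E=np.ones(n), z=np.full(n, np.nan))
    spec = ModelSpec(family="joint", latent="bym2", data=data, precision=lattice33_precision)
    cfg = SamplerConfig(n_iter=6000, n_burnin=1000, seed=17)
    s = fit(spec, cfg)

    prior_phi = spec.pc_phi
    num, _ = quad(lambda p: p * np.exp(prior_phi.logpdf(p)), 0, prior_phi.phi_grid[-1], limit=300)
    phi_mean_prior = num  # density integrates to 1
    phi = s.draws["phi"]
    ess = max(float(diagnostics(s, ["phi"]).loc["phi", "ess"]), 10.0)
    mcse = phi.std(ddof=1) / np.sqrt(ess)
    assert abs(phi.mean() - phi_mean_prior) < max(3 * mcse, 0.04)

    # 1/tau = sigma^2 with sigma ~ Exponential(lam): E[sigma^2] = 2/lam^2
    lam = pc_prec_lambda(1.0, 0.01)
    inv_tau = s.draws["inv_tau_gamma"]
    ess_t = max(float(diagnostics(s, ["inv_tau_gamma"]).loc["inv_tau_gamma", "ess"]), 10.0)
    mcse_t = inv_tau.std(ddof=1) / np.sqrt(ess_t)
    assert abs(inv_tau.mean() - 2.0 / lam**2) < max(3 * mcse_t, 0.03)


def test_posterior_summary_constant_and_quantiles():
    draws = {"a": np.full(50, 3.25), "b": np.arange(100, dtype=float)}
    s = PosteriorSamples(draws=draws, gamma=None, ll_o=np.zeros((50, 1)), ll_z=None)
    summ = posterior_summary(s)
    assert summ.loc["a", "mean"] == 3.25 and summ.loc["a", "sd"] == 0.0
    # quantile oracle: sorted-array interpolation on 100 draws
    b = np.sort(draws["b"])
    h = 0.025 * 99
    lo = b[int(h)] + (h - int(h)) * (b[int(h) + 1] - b[int(h)])
    assert summ.loc["b", "q2.5"] == pytest.approx(lo, abs=1e-12)


def test_summary_transform_order(path3_precision):
    # summaries of 1/tau use per-draw transforms, not 1/mean(tau)
    data = ObservedData(o=np.array([2.0, 0.0, 5.0]), E=np.ones(3))
    spec = ModelSpec(family="poisson", latent="bym2", data=data, precision=path3_precision)
    s = fit(spec, SamplerConfig(n_iter=400, n_burnin=100, seed=21))
    tau = s.draws["tau_gamma"]
    summ = posterior_summary(s, ["inv_tau_gamma"])
    assert summ.loc["inv_tau_gamma", "mean"] == pytest.approx(np.mean(1.0 / tau), rel=1e-12)
    assert summ.loc["inv_tau_gamma", "mean"] != pytest.approx(1.0 / np.mean(tau), rel=1e-6)


def test_summary_empty_chain_rejected():
    s = PosteriorSamples(draws={"a": np.empty(0)}, gamma=None, ll_o=np.empty((0, 1)), ll_z=None)
    with pytest.raises(ValueError):
        posterior_summary(s)


def test_diagnostics_iid_chain():
    rng = np.random.default_rng(0)
    draws = {"x": rng.standard_normal(4000)}
    s = PosteriorSamples(draws=draws, gamma=None, ll_o=np.zeros((10, 1)), ll_z=None)
    d = diagnostics(s)
    assert d.loc["x", "rhat"] == pytest.approx(1.0, abs=0.02)
    assert 0.8 * 4000 < d.loc["x", "ess"] < 1.2 * 4000
    assert not d.loc["x", "flag"]


def test_diagnostics_detects_duplicated_halves():
    rng = np.random.default_rng(1)
    half = rng.standard_normal(500) + 3.0
    bad = np.concatenate([half, half - 6.0])  # two shifted halves
    assert _split_rhat(bad) > 1.5
    s = PosteriorSamples(draws={"x": bad}, gamma=None, ll_o=np.zeros((10, 1)), ll_z=None)
    assert diagnostics(s).loc["x", "flag"]


def test_three_region_grid_oracle(path3_precision):
    """MCMC posterior mean of gamma matches dense-grid numeric integration."""
    from spatzip.priors import FixedEffectPriors, NormalPrior

    o = np.array([4.0, 1.0, 7.0])
    E = np.full(3, 2.0)
    data = ObservedData(o=o, E=E)
    fp = FixedEffectPriors(intercept_o=NormalPrior(0.0, 0.25))
    spec = ModelSpec(
        family="poisson", latent="bym2", data=data, precision=path3_precision,
        fixed_priors=fp,
    )
    tau, phi = 1.0, 0.5
    cfg = SamplerConfig(
        n_iter=6000, n_burnin=1000, seed=33, fixed_hyper={"tau_gamma": tau, "phi": phi}
    )
    s = fit(spec, cfg)

    # dense grid over (gamma1..3, alpha)
    import arviz as az

    V, sv = path3_precision.eig_pinv(scaled=True)
    cov = ((1 - phi) + phi * sv) / tau
    Cinv = (V * (1.0 / cov)) @ V.T
    g = np.linspace(-2.2, 2.2, 37)
    a = np.linspace(-1.6, 1.6, 37)
    G1, G2, G3, A = np.meshgrid(g, g, g, a, indexing="ij")
    gam = np.stack([G1, G2, G3], axis=-1)
    quad_form = np.einsum("...i,ij,...j->...", gam, Cinv, gam)
    log_prior = -0.5 * quad_form - 0.5 * A**2 / 0.25
    eta = gam + A[..., None]
    loglik = (o * eta - E[0] * np.exp(eta)).sum(axis=-1)
    w = np.exp(log_prior + loglik - (log_prior + loglik).max())
    w /= w.sum()
    oracle_mean = np.array([(w * G1).sum(), (w * G2).sum(), (w * G3).sum()])

    got = s.gamma.mean(axis=0)
    sd = s.gamma.std(axis=0, ddof=1)
    ess = np.array(
        [max(float(az.ess(s.gamma[None, :, i])), 50.0) for i in range(3)]
    )
    mcse = sd / np.sqrt(ess)
    assert np.all(np.abs(got - oracle_mean) < np.maximum(3 * mcse, 0.03))


def test_init_override_and_bym_family(path3_precision):
    data = ObservedData(o=np.array([2.0, 3.0, 1.0]), E=np.ones(3))
    spec = ModelSpec(family="poisson", latent="bym", data=data, precision=path3_precision)
    s = fit(spec, SamplerConfig(n_iter=300, n_burnin=100, seed=2, init={"tau_v": 2.0}))
    assert {"tau_v", "tau_u", "inv_tau_v", "inv_tau_u"} <= set(s.draws)
    assert np.all(s.draws["tau_v"] > 0)
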