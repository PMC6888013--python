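"""Joint response layout, linear predictors, latent priors, log-posterior."""

import math

import numpy as np
import pytest
from scipy.special import expit

from spatzip import (
    ModelSpec,
    ObservedData,
    build_joint_response,
    extract_joint_response,
    latent_logpdf,
    linear_predictors,
    log_posterior,
)
from spatzip.models import hyper_logprior, fixed_logprior, observation_loglik


def test_joint_response_layout():
    z = np.array([1.0, 0.0, 1.0])
    o = np.array([2.0, np.nan, 7.0])
    Y = build_joint_response(z, o)
    assert Y.shape == (6, 2)
    # occurrence block in column 1, count block in column 2, misaligned
    assert Y[0, 0] == 1 and Y[1, 0] == 0 and Y[2, 0] == 1
    assert Y[3, 1] == 2 and np.isnan(Y[4, 1]) and Y[5, 1] == 7
    assert np.isnan(Y[:3, 1]).all() and np.isnan(Y[3:, 0]).all()
    # exactly one non-missing cell per row
    assert (np.isfinite(Y).sum(axis=1) <= 1).all()


def test_joint_response_all_zero_occurrence():
    Y = build_joint_response(np.zeros(4), np.full(4, np.nan))
    assert np.isnan(Y[4:, 1]).all()


def test_joint_response_round_trip():
    z = np.array([1.0, 0.0, 1.0, 1.0])
    o = np.array([3.0, np.nan, 1.0, 9.0])
    z2, o2 = extract_joint_response(build_joint_response(z, o))
    assert np.array_equal(z, z2)
    assert np.array_equal(np.isnan(o), np.isnan(o2)) and np.nansum(o) == np.nansum(o2)


def test_joint_response_inconsistency_rejected():
    with pytest.raises(ValueError, match="inconsistency"):
        build_joint_response(np.array([1.0, 0.0]), np.array([2.0, 3.0]))


def _joint_spec(precision, z, o, E=None):
    n = len(z)
    data = ObservedData(
        o=np.asarray(o, float),
        E=np.full(n, 1.0) if E is None else np.asarray(E, float),
        z=np.asarray(z, float),
    )
    return ModelSpec(family="joint", latent="bym2", data=data, precision=precision)


def test_linear_predictors_constant_and_decoupled(path3_precision):
    spec = _joint_spec(path3_precision, [1, 0, 1], [2, np.nan, 1])
    log_th, logit_p = linear_predictors(
        spec, np.zeros(3), {"alpha_o": 0.4, "alpha_z": -1.1, "beta": 2.0}
    )
    assert np.allclose(np.exp(log_th), math.exp(0.4))
    assert np.allclose(expit(logit_p), expit(-1.1))
    # beta = 0 decouples the occurrence side from gamma
    gamma = np.array([0.5, -0.2, 0.1])
    _, lp0 = linear_predictors(spec, gamma, {"alpha_o": 0, "alpha_z": 0.3, "beta": 0.0})
    assert np.allclose(lp0, 0.3)


def test_linear_predictors_scalar_check(path3_precision):
    spec = _joint_spec(path3_precision, [1, 1, 1], [2, 1, 1])
    gamma = np.array([0.2, 0.0, -0.1])
    log_th, logit_p = linear_predictors(
        spec, gamma, {"alpha_o": 0.5, "alpha_z": -0.4, "beta": 1.5}
    )
    assert log_th[0] == pytest.approx(0.5 + 0.2)
    assert logit_p[2] == pytest.approx(-0.4 + 1.5 * (-0.1))


def test_bym2_latent_prior_matches_dense_gaussian(path3_precision):
    # marginal gamma ~ N(0, (1/tau)((1-phi) I + phi pinv(Q*)))
    tau, phi = 1.7, 0.6
    S = np.linalg.pinv(path3_precision.Q_star.toarray())
    C = ((1 - phi) * np.eye(3) + phi * S) / tau
    gamma = np.array([0.3, -0.5, 0.2])
    expected = (
        -1.5 * np.log(2 * np.pi)
        - 0.5 * np.log(np.linalg.det(C))
        - 0.5 * gamma @ np.linalg.solve(C, gamma)
    )
    spec = _joint_spec(path3_precision, [1, 1, 1], [1, 1, 1])
    got = latent_logpdf(spec, gamma, {"tau_gamma": tau, "phi": phi})
    assert got == pytest.approx(expected, abs=1e-8)


def test_bym2_prior_draw_covariance(path3_precision):
    # empirical covariance of prior draws matches tau^-1((1-phi)I + phi pinv(Q*))
    tau, phi = 2.0, 0.7
    V, s = path3_precision.eig_pinv(scaled=True)
    cov_eigs = ((1 - phi) + phi * s) / tau
    rng = np.random.default_rng(5)
    draws = (V * np.sqrt(cov_eigs)) @ rng.standard_normal((3, 40000))
    emp = draws @ draws.T / 40000
    target = ((1 - phi) * np.eye(3) + phi * np.linalg.pinv(path3_precision.Q_star.toarray())) / tau
    assert np.max(np.abs(emp - target)) < 0.02


def test_bym2_phi_limits(path3_precision):
    spec = _joint_spec(path3_precision, [1, 1, 1], [1, 1, 1])
    gamma = np.array([0.4, -0.1, -0.3])
    # phi = 0: iid normal with precision tau
    tau = 3.0
    iid = -1.5 * np.log(2 * np.pi / tau) - 0.5 * tau * float(gamma @ gamma)
    assert latent_logpdf(spec, gamma, {"tau_gamma": tau, "phi": 0.0}) == pytest.approx(
        iid, abs=1e-10
    )


def test_log_posterior_prior_only_additivity(path3_precision):
    # all responses missing -> log-posterior equals the log-prior alone
    data = ObservedData(
        o=np.full(3, np.nan), E=np.ones(3), z=np.full(3, np.nan)
    )
    spec = ModelSpec(family="joint", latent="bym2", data=data, precision=path3_precision)
    state = {
        "gamma": np.array([0.1, -0.2, 0.1]),
        "alpha_o": 0.3,
        "alpha_z": -0.9,
        "beta": 1.2,
        "tau_gamma": 1.5,
        "phi": 0.4,
    }
    expected = (
        latent_logpdf(spec, state["gamma"], state)
        + hyper_logprior(spec, state)
        + fixed_logprior(spec, state)
    )
    assert log_posterior(spec, state) == pytest.approx(expected, abs=1e-10)


def test_log_posterior_two_region_hand_computed():
    from spatzip import build_lattice_graph, icar_precision, scale_icar

    precision = scale_icar(icar_precision(build_lattice_graph(1, 2)))
    data = ObservedData(o=np.array([3.0, np.nan]), E=np.array([2.0, 2.0]), z=np.array([1.0, 0.0]))
    spec = ModelSpec(family="joint", latent="bym2", data=data, precision=precision)
    state = {
        "gamma": np.array([0.2, -0.1]),
        "alpha_o": 0.1,
        "alpha_z": -0.5,
        "beta": 1.0,
        "tau_gamma": 2.0,
        "phi": 0.3,
    }
    # hand: truncated Poisson at region 0, Bernoulli at both
    mu0 = 2.0 * math.exp(0.1 + 0.2)
    ll = 3 * math.log(mu0) - mu0 - math.log(6.0) - math.log(1 - math.exp(-mu0))
    p = expit(-0.5 + 1.0 * np.array([0.2, -0.1]))
    ll += math.log(p[0]) + math.log(1 - p[1])
    expected = (
        ll
        + latent_logpdf(spec, state["gamma"], state)
        + hyper_logprior(spec, state)
        + fixed_logprior(spec, state)
    )
    assert log_posterior(spec, state) == pytest.approx(expected, abs=1e-10)


def test_log_posterior_out_of_support(path3_precision):
    spec = _joint_spec(path3_precision, [1, 1, 1], [1, 1, 1])
    state = {
        "gamma": np.zeros(3),
        "alpha_o": 0.0,
        "alpha_z": 0.0,
        "beta": 1.0,
        "tau_gamma": -1.0,
        "phi": 0.5,
    }
    assert log_posterior(spec, state) == -np.inf


def test_poisson_loglik_unimodal_in_theta(path3_precision):
    # increasing theta toward o/E never decreases the Poisson term pre-mode
    data = ObservedData(o=np.array([4.0, 2.0, 1.0]), E=np.ones(3))
    spec = ModelSpec(family="poisson", latent="bym2", data=data, precision=path3_precision)
    lls = []
    for a in np.log([0.5, 1.0, 2.0, 4.0]):  # theta up to o/E = 4 in region 0
        ll_o, _ = observation_loglik(spec, np.array([a, 0.0, 0.0]), None)
        lls.append(ll_o[0])
    assert np.all(np.diff(lls) > 0)


def test_joint_requires_z(path3_precision):
    data = ObservedData(o=np.array([1.0, 2.0, 0.0]), E=np.ones(3))
    with pytest.raises(ValueError, match="requires occurrence"):
        ModelSpec(family="joint", latent="bym2", data=data, precision=path3_precision)
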