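"""Posterior computation: adaptive blocked MCMC for the spatial models.

The sampler works with the *marginalized* latent field: the likelihood
depends on (v, u*) only through gamma, whose prior is Gaussian with a
covariance that is diagonal in the (fixed) eigenbasis of the ICAR
precision.  Three blocks are updated per iteration:

1. **hyperparameters** (log tau, logit phi internally) by an adaptive
   random walk proposed *jointly with a refresh of the Gaussian block*,
   which removes the strong coupling between the precision and the scale
   of the field;
2. **the Gaussian block** x = (gamma, alpha_o, delta) by a one-step-Newton
   Gaussian approximation proposal (Taylor expansion of the log-likelihood
   around the current state, Metropolis-corrected) — for count data this
   proposal is close to the full conditional and mixes almost like i.i.d.
   sampling;
3. **remaining fixed effects** (alpha_z, beta, omega, or the ZIP zero
   probability) by a small adaptive random walk.

Every stochastic step is driven by one seeded generator, so runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import expit, gammaln, logit

from .models import ModelSpec

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "fit",
    "posterior_summary",
    "diagnostics",
]

_ETA_CLIP = 300.0  # keeps exp(eta) finite; never active near the posterior


@dataclass
class SamplerConfig:
    """MCMC run configuration.

    ``fixed_hyper`` pins latent hyperparameters (e.g. {"tau_gamma": 1.0,
    "phi": 0.3}) and skips their updates — useful for validation against
    numeric integration.  ``init`` overrides the default data-driven
    initialization for any parameter.
    """

    n_iter: int = 2500
    n_burnin: int = 500
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.35
    fixed_hyper: dict | None = None
    init: dict | None = None
    store_gamma: bool = True

    def __post_init__(self):
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0,1)")


@dataclass
class PosteriorSamples:
    """Post-burn-in, thinned MCMC draws with per-observation log-likelihoods.

    ``draws`` maps scalar parameter names to 1-d arrays (natural scale;
    variance parameters are stored per draw, so e.g. the summary of
    ``inv_tau_gamma`` is the mean of 1/tau over draws, not 1/mean(tau)).
    ``ll_o`` / ``ll_z`` hold per-draw per-region log-likelihood
    contributions (NaN where the observation is missing), feeding DIC/CPO.
    """

    draws: dict
    gamma: np.ndarray | None
    ll_o: np.ndarray
    ll_z: np.ndarray | None
    spec: ModelSpec | None = None
    config: SamplerConfig | None = None
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def posterior_mean_state(self) -> dict:
        """Plug-in state at posterior means (natural parameterization)."""
        state = {k: float(np.mean(v)) for k, v in self.draws.items()}
        if self.gamma is not None:
            state["gamma"] = self.gamma.mean(axis=0)
        return state


# ---------------------------------------------------------------------------
# per-family likelihood evaluations with derivatives w.r.t. the predictors


def _log1m_exp_neg(mu):
    with np.errstate(divide="ignore"):
        return np.where(
            mu > 0.693,
            np.log1p(-np.exp(-np.minimum(mu, 745.0))),
            np.log(-np.expm1(-np.maximum(mu, 1e-300))),
        )


def _trunc_pois_terms(o, E, eta, lgam):
    """(ll, g, h) of the zero-truncated Poisson w.r.t. eta = log theta."""
    mu = E * np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    ll = o * np.log(mu) - mu - lgam - _log1m_exp_neg(mu)
    with np.errstate(over="ignore", invalid="ignore"):
        em1 = np.expm1(mu)
        r = np.where(mu < 1e-6, 1.0 - mu / 2.0, mu / em1)
        emu = em1 + 1.0
        rp = np.where(
            mu < 1e-6, -0.5 + mu / 6.0, (em1 - mu * emu) / np.square(em1)
        )
        rp = np.nan_to_num(rp, nan=0.0, posinf=0.0, neginf=0.0)
    g = o - mu - r
    h = -mu * (1.0 + rp)
    return ll, g, h


class _LikEval:
    """Per-state likelihood value, gradient and curvature pieces."""

    __slots__ = ("ll", "ll_o", "ll_z", "g_o", "hneg_o", "g_z", "hneg_z")


class _Ctx:
    """Preprocessed data and masks for one fit."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        d = spec.data
        self.n = d.n
        self.E = d.E
        self.o = d.o
        self.obs = np.isfinite(d.o)
        self.lgam = gammaln(np.nan_to_num(d.o) + 1.0)
        if spec.family == "joint":
            self.z = d.z
            self.zobs = np.isfinite(d.z)
            self.cobs = self.obs & (np.nan_to_num(d.z) == 1.0)
        else:
            self.z = None
            self.zobs = None
            self.cobs = self.obs
        self.X = d.x  # (n, k) or None
        self.k = 0 if self.X is None else self.X.shape[1]
        self.Y = d.y if spec.family == "joint" else None
        self.m_cov = 0 if self.Y is None else self.Y.shape[1]

    def eval(self, eta_o: np.ndarray, eta_z) -> _LikEval:
        """Evaluate log-likelihood and derivatives w.r.t. (eta_o, eta_z)."""
        sp = self.spec
        out = _LikEval()
        n = self.n
        ll_o = np.full(n, np.nan)
        g_o = np.zeros(n)
        h_o = np.zeros(n)
        fam = sp.family
        if fam == "poisson":
            m = self.obs
            mu = self.E[m] * np.exp(np.clip(eta_o[m], -_ETA_CLIP, _ETA_CLIP))
            ll_o[m] = self.o[m] * np.log(mu) - mu - self.lgam[m]
            g_o[m] = self.o[m] - mu
            h_o[m] = -mu
            out.ll_z = None
            out.g_z = out.hneg_z = None
        elif fam == "joint":
            m = self.cobs
            if np.any(m):
                ll_o[m], g_o[m], h_o[m] = _trunc_pois_terms(
                    self.o[m], self.E[m], eta_o[m], self.lgam[m]
                )
            zm = self.zobs
            p = expit(eta_z)
            ll_z = np.full(n, np.nan)
            with np.errstate(divide="ignore"):
                ll_z[zm] = np.where(
                    self.z[zm] == 1.0, np.log(p[zm]), np.log1p(-p[zm])
                )
            g_z = np.zeros(n)
            h_z = np.zeros(n)
            g_z[zm] = self.z[zm] - p[zm]
            h_z[zm] = -p[zm] * (1.0 - p[zm])
            out.ll_z = ll_z
            out.g_z = g_z
            out.hneg_z = np.maximum(-h_z, 0.0)
        else:  # zip0 / zip1 with scalar zero probability
            p = expit(float(eta_z))
            m = self.obs
            oo, EE, ee = self.o[m], self.E[m], eta_o[m]
            mu = EE * np.exp(np.clip(ee, -_ETA_CLIP, _ETA_CLIP))
            pois = oo * np.log(mu) - mu - self.lgam[m]
            gm = np.empty(mu.shape)
            hm = np.empty(mu.shape)
            llm = np.empty(mu.shape)
            pos = oo > 0
            if fam == "zip1":
                llm[pos] = np.log(p) + pois[pos]
                gm[pos] = oo[pos] - mu[pos]
                hm[pos] = -mu[pos]
                z0 = ~pos
                zero_term = np.logaddexp(np.log1p(-p), np.log(p) - mu[z0])
                llm[z0] = zero_term
                w = np.exp(np.log(p) - mu[z0] - zero_term)
                gm[z0] = -w * mu[z0]
                hm[z0] = w * mu[z0] * ((1.0 - w) * mu[z0] - 1.0)
            else:  # zip0
                llt, gt, ht = _trunc_pois_terms(
                    oo[pos], EE[pos], ee[pos], self.lgam[m][pos]
                )
                llm[pos] = np.log(p) + llt
                gm[pos] = gt
                hm[pos] = ht
                llm[~pos] = np.log1p(-p)
                gm[~pos] = 0.0
                hm[~pos] = 0.0
            ll_o[m] = llm
            g_o[m] = gm
            h_o[m] = hm
            out.ll_z = None
            out.g_z = out.hneg_z = None
        out.ll_o = ll_o
        out.g_o = g_o
        out.hneg_o = np.maximum(-h_o, 0.0)
        out.ll = float(np.nansum(ll_o)) + (
            float(np.nansum(out.ll_z)) if out.ll_z is not None else 0.0
        )
        return out


# ---------------------------------------------------------------------------
# the sampler


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of one chain (classic between/within formula on halves)."""
    m = x.shape[0] // 2
    halves = np.stack([x[:m], x[m : 2 * m]])
    w = halves.var(axis=1, ddof=1).mean()
    b = m * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0 if b <= 0 else np.inf
    var_plus = (m - 1) / m * w + b / m
    return float(np.sqrt(var_plus / w))


def fit(spec: ModelSpec, cfg: SamplerConfig) -> PosteriorSamples:
    """Run the blocked adaptive MCMC and return posterior draws."""
    rng = np.random.default_rng(cfg.seed)
    ctx = _Ctx(spec)
    n = ctx.n

    # --- eigen-structure of the marginal latent covariance -----------------
    scaled = spec.latent == "bym2"
    V, s = spec.precision.eig_pinv(scaled=scaled)
    fixed_hyper = cfg.fixed_hyper or {}

    if spec.latent == "bym2":
        hyper_names = ("tau_gamma", "phi")

        def cov_eigs(psi):
            tau = np.exp(psi[0])
            phi = expit(psi[1])
            return ((1.0 - phi) + phi * s) / tau

        def hyper_nat(psi):
            return {"tau_gamma": float(np.exp(psi[0])), "phi": float(expit(psi[1]))}

        phi_max = spec.pc_phi.phi_grid[-1]

        def hyper_logprior_int(psi):
            tau = np.exp(psi[0])
            phi = expit(psi[1])
            if phi >= phi_max:
                return -np.inf
            lp = spec.pc_prec.logpdf(tau) + psi[0]  # + log|d tau/d psi|
            lp += spec.pc_phi.logpdf(phi) + np.log(phi * (1.0 - phi))
            return float(lp)

        psi0 = np.array(
            [
                np.log(fixed_hyper.get("tau_gamma", 1.0)),
                logit(np.clip(fixed_hyper.get("phi", 0.5), 1e-6, 1 - 1e-6)),
            ]
        )
    else:
        hyper_names = ("tau_v", "tau_u")

        def cov_eigs(psi):
            return 1.0 / np.exp(psi[0]) + s / np.exp(psi[1])

        def hyper_nat(psi):
            return {"tau_v": float(np.exp(psi[0])), "tau_u": float(np.exp(psi[1]))}

        def hyper_logprior_int(psi):
            tv, tu = np.exp(psi)
            return float(
                spec.gamma_prec.logpdf(tv)
                + psi[0]
                + spec.gamma_prec.logpdf(tu)
                + psi[1]
            )

        psi0 = np.array(
            [
                np.log(fixed_hyper.get("tau_v", 1.0)),
                np.log(fixed_hyper.get("tau_u", 1.0)),
            ]
        )

    sample_hyper = not all(h in fixed_hyper for h in hyper_names)
    if fixed_hyper and not sample_hyper:
        pass  # fully pinned
    elif fixed_hyper and sample_hyper:
        raise ValueError("fixed_hyper must pin all latent hyperparameters or none")

    # --- Gaussian-block layout: x = (gamma, alpha_o, delta) ----------------
    k = ctx.k
    m_dim = n + 1 + k
    fp = spec.fixed_priors
    prec_fix = np.concatenate(
        [[1.0 / fp.intercept_o.var], np.full(k, 1.0 / fp.delta.var)]
    )
    mean_fix = np.concatenate([[fp.intercept_o.mean], np.full(k, fp.delta.mean)])

    # --- B block (non-Gaussian-side fixed effects) -------------------------
    if spec.family == "joint":
        b_names = ["alpha_z", "beta"] + [f"omega_{j}" for j in range(ctx.m_cov)]
        b_prior_mean = np.concatenate(
            [[fp.intercept_z.mean, fp.beta.mean], np.full(ctx.m_cov, fp.omega.mean)]
        )
        b_prior_prec = np.concatenate(
            [
                [1.0 / fp.intercept_z.var, 1.0 / fp.beta.var],
                np.full(ctx.m_cov, 1.0 / fp.omega.var),
            ]
        )
    elif spec.family in ("zip0", "zip1"):
        b_names = ["logit_p"]
        b_prior_mean = np.array([spec.zero_prob_prior.mean])
        b_prior_prec = np.array([1.0 / spec.zero_prob_prior.var])
    else:
        b_names = []
        b_prior_mean = np.zeros(0)
        b_prior_prec = np.zeros(0)
    b_dim = len(b_names)

    def eta_of(x, zeta):
        gamma = x[:n]
        eta_o = x[n] + gamma
        if k:
            eta_o = eta_o + ctx.X @ x[n + 1 :]
        if spec.family == "joint":
            eta_z = zeta[0] + zeta[1] * gamma
            if ctx.m_cov:
                eta_z = eta_z + ctx.Y @ zeta[2:]
        elif b_dim:
            eta_z = float(zeta[0])
        else:
            eta_z = None
        return eta_o, eta_z

    def build_W(lik: _LikEval, zeta):
        """Negative likelihood curvature in the x coordinates (clamped PSD)."""
        ho = lik.hneg_o.copy()
        d1 = ho.copy()
        if spec.family == "joint":
            d1 += zeta[1] ** 2 * lik.hneg_z
        W = np.zeros((m_dim, m_dim))
        idx = np.arange(n)
        W[idx, idx] = d1
        W[:n, n] = ho
        W[n, :n] = ho
        W[n, n] = ho.sum()
        if k:
            hX = ho[:, None] * ctx.X
            W[:n, n + 1 :] = hX
            W[n + 1 :, :n] = hX.T
            W[n, n + 1 :] = ho @ ctx.X
            W[n + 1 :, n] = W[n, n + 1 :]
            W[n + 1 :, n + 1 :] = ctx.X.T @ hX
        return W

    def grad_x(lik: _LikEval, zeta):
        g = lik.g_o.copy()
        if spec.family == "joint":
            g = g + zeta[1] * lik.g_z
        out = np.empty(m_dim)
        out[:n] = g
        out[n] = lik.g_o.sum()
        if k:
            out[n + 1 :] = ctx.X.T @ lik.g_o
        return out

    def build_P0(Cinv):
        P0 = np.zeros((m_dim, m_dim))
        P0[:n, :n] = Cinv
        fi = np.arange(n, m_dim)
        P0[fi, fi] = prec_fix
        return P0

    # constant part of the prior gradient from nonzero fixed-effect means
    prec_fix_grad = np.zeros(m_dim)
    prec_fix_grad[n:] = prec_fix * mean_fix
    _ii = np.arange(m_dim)

    def a_prior_quad(x, Cinv):
        """Prior log-density of the Gaussian block up to the determinant."""
        gamma = x[:n]
        resid = x[n:] - mean_fix
        return -0.5 * (
            float(gamma @ (Cinv @ gamma)) + float(resid @ (prec_fix * resid))
        )

    def a_prior_logdens(x, Cinv, logdetC):
        return -0.5 * logdetC + a_prior_quad(x, Cinv)

    def _factor(lik, zeta, P0):
        P = P0 + build_W(lik, zeta)
        P[_ii, _ii] += 1e-8
        try:
            return np.linalg.cholesky(P)
        except np.linalg.LinAlgError:
            P[_ii, _ii] += 1e-4
            return np.linalg.cholesky(P)

    def find_mode(x_start, zeta, P0, Cinv):
        """Damped Newton to the conditional mode of the Gaussian block.

        Returns the independence-proposal cache (mu, L, sum log diag L):
        mean with the final Newton shift, precision P0 + W at the mode.
        The mode is a function of (hyper, zeta, data) alone up to the
        convergence tolerance, which keeps the proposal valid within Gibbs.
        """
        x = x_start.copy()
        lik = ctx.eval(*eta_of(x, zeta))
        f = lik.ll + a_prior_quad(x, Cinv)
        for _ in range(60):
            L = _factor(lik, zeta, P0)
            gpost = grad_x(lik, zeta) - P0 @ x + prec_fix_grad
            dx = cho_solve((L, True), gpost)
            step = 1.0
            x_new, lik_new, f_new = x, lik, f
            for _ in range(12):
                x_try = x + step * dx
                lik_try = ctx.eval(*eta_of(x_try, zeta))
                f_try = lik_try.ll + a_prior_quad(x_try, Cinv)
                if np.isfinite(f_try) and f_try >= f - 1e-10:
                    x_new, lik_new, f_new = x_try, lik_try, f_try
                    break
                step *= 0.5
            moved = step * float(np.max(np.abs(dx)))
            x, lik, f = x_new, lik_new, f_new
            if moved < 1e-8 * (1.0 + float(np.max(np.abs(x)))):
                break
        L = _factor(lik, zeta, P0)
        gpost = grad_x(lik, zeta) - P0 @ x + prec_fix_grad
        mu = x + cho_solve((L, True), gpost)
        return {"mu": mu, "L": L, "sld": float(np.sum(np.log(np.diag(L))))}

    def logq(xq, cache):
        d = cache["L"].T @ (xq - cache["mu"])
        return cache["sld"] - 0.5 * float(d @ d)

    def sample_from(cache):
        eps = rng.standard_normal(m_dim)
        return cache["mu"] + solve_triangular(
            cache["L"], eps, lower=True, trans="T"
        )

    # --- initialization ----------------------------------------------------
    init = cfg.init or {}
    obs_cells = ctx.cobs
    tot_o = np.nansum(ctx.o[obs_cells]) if np.any(obs_cells) else 0.0
    tot_E = ctx.E[obs_cells].sum() if np.any(obs_cells) else 1.0
    alpha_o0 = init.get("alpha_o", np.log((tot_o + 0.5) / (tot_E + 0.5)))
    x = np.zeros(m_dim)
    x[n] = alpha_o0
    x[:n] = init.get("gamma", np.zeros(n))
    zeta = np.zeros(b_dim)
    if spec.family == "joint":
        zbar = float(np.nanmean(ctx.z)) if np.any(ctx.zobs) else 0.5
        zeta[0] = init.get("alpha_z", logit(np.clip(zbar, 0.02, 0.98)))
        zeta[1] = init.get("beta", 1.0)
    elif b_dim:
        frac_pos = float(np.mean(ctx.o[ctx.obs] > 0)) if np.any(ctx.obs) else 0.5
        zeta[0] = init.get("logit_p", logit(np.clip(frac_pos, 0.05, 0.95)))
    psi = psi0.copy()
    for name in hyper_names:
        if name in init:
            i = hyper_names.index(name)
            val = init[name]
            psi[i] = logit(val) if name == "phi" else np.log(val)

    cov = cov_eigs(psi)
    logdetC = float(np.sum(np.log(cov)))
    Cinv = (V * (1.0 / cov)) @ V.T
    P0 = build_P0(Cinv)

    lik = ctx.eval(*eta_of(x, zeta))
    if not np.isfinite(lik.ll):
        raise RuntimeError(
            f"non-finite log-likelihood at initialization; state: alpha_o={x[n]:.3g}, "
            f"zeta={zeta}, psi={psi}"
        )
    # deterministic warm start at the conditional mode
    cache = find_mode(x, zeta, P0, Cinv)
    x = cache["mu"].copy()
    lik = ctx.eval(*eta_of(x, zeta))

    # --- adaptation state --------------------------------------------------
    ls_b = np.log(0.1)
    ls_c = 0.0
    c_step0 = np.array([0.25, 0.4])
    psi_mean = psi.copy()
    psi_cov = np.diag(c_step0**2) if sample_hyper else None
    acc = {"latent": 0, "hyper": 0, "fixed": 0}
    tries = {"latent": 0, "hyper": 0, "fixed": 0}

    keep = (cfg.n_iter - cfg.n_burnin) // cfg.thin
    draws: dict[str, np.ndarray] = {name: np.empty(keep) for name in b_names}
    draws["alpha_o"] = np.empty(keep)
    for j in range(k):
        draws[f"delta_{j}"] = np.empty(keep)
    for name in hyper_names:
        draws[name] = np.empty(keep)
    if spec.latent == "bym2":
        draws["inv_tau_gamma"] = np.empty(keep)
    else:
        draws["inv_tau_v"] = np.empty(keep)
        draws["inv_tau_u"] = np.empty(keep)
    if b_dim and spec.family in ("zip0", "zip1"):
        draws["p"] = np.empty(keep)
    draws["loglik"] = np.empty(keep)
    gamma_store = np.empty((keep, n)) if cfg.store_gamma else None
    ll_o_store = np.empty((keep, n))
    ll_z_store = np.empty((keep, n)) if spec.family == "joint" else None

    kept = 0
    for it in range(cfg.n_iter):
        rm = 2.0 / (it + 20.0) ** 0.7  # diminishing adaptation rate

        # ---- hyperparameter block (jointly with a latent refresh) --------
        if sample_hyper:
            tries["hyper"] += 1
            if it >= 100:
                prop_cov = 2.88 * psi_cov + 1e-8 * np.eye(len(psi))
                Lc = np.exp(ls_c) * np.linalg.cholesky(prop_cov)
            else:
                Lc = np.exp(ls_c) * np.diag(c_step0)
            psi_p = psi + Lc @ rng.standard_normal(len(psi))
            hp_new = hyper_logprior_int(psi_p)
            if np.isfinite(hp_new):
                cov_p = cov_eigs(psi_p)
                logdetC_p = float(np.sum(np.log(cov_p)))
                Cinv_p = (V * (1.0 / cov_p)) @ V.T
                P0_p = build_P0(Cinv_p)
                cache_p = find_mode(cache["mu"], zeta, P0_p, Cinv_p)
                x_p = sample_from(cache_p)
                lik_p = ctx.eval(*eta_of(x_p, zeta))
                logr = (
                    lik_p.ll
                    + a_prior_logdens(x_p, Cinv_p, logdetC_p)
                    + hp_new
                    + logq(x, cache)
                    - lik.ll
                    - a_prior_logdens(x, Cinv, logdetC)
                    - hyper_logprior_int(psi)
                    - logq(x_p, cache_p)
                )
                if np.log(rng.uniform()) < logr:
                    psi, x, lik, cache = psi_p, x_p, lik_p, cache_p
                    cov, logdetC, Cinv, P0 = cov_p, logdetC_p, Cinv_p, P0_p
                    acc["hyper"] += 1
                    a_ind = 1.0
                else:
                    a_ind = 0.0
            else:
                a_ind = 0.0
            ls_c += rm * (a_ind - cfg.target_accept)
            dpsi = psi - psi_mean
            psi_mean = psi_mean + rm * dpsi
            psi_cov = psi_cov + rm * (np.outer(dpsi, dpsi) - psi_cov)

        # ---- Gaussian block: independence refresh from the mode proposal --
        for _ in range(2):
            tries["latent"] += 1
            x_p = sample_from(cache)
            lik_p = ctx.eval(*eta_of(x_p, zeta))
            logr = (
                lik_p.ll
                + a_prior_quad(x_p, Cinv)
                - logq(x_p, cache)
                - lik.ll
                - a_prior_quad(x, Cinv)
                + logq(x, cache)
            )
            if np.log(rng.uniform()) < logr:
                x, lik = x_p, lik_p
                acc["latent"] += 1

        # ---- remaining fixed effects -------------------------------------
        if b_dim:
            tries["fixed"] += 1
            zeta_p = zeta + np.exp(ls_b) * rng.standard_normal(b_dim)
            lik_p = ctx.eval(*eta_of(x, zeta_p))
            dpri = -0.5 * float(
                ((zeta_p - b_prior_mean) ** 2 - (zeta - b_prior_mean) ** 2)
                @ b_prior_prec
            )
            logr = lik_p.ll - lik.ll + dpri
            if np.log(rng.uniform()) < logr:
                zeta, lik = zeta_p, lik_p
                acc["fixed"] += 1
                a_ind = 1.0
                # the independence proposal conditions on zeta: re-center it
                cache = find_mode(cache["mu"], zeta, P0, Cinv)
            else:
                a_ind = 0.0
            ls_b += rm * (a_ind - 0.3)

        # ---- storage ------------------------------------------------------
        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0 and kept < keep:
            nat = hyper_nat(psi)
            for name, val in nat.items():
                draws[name][kept] = val
            if spec.latent == "bym2":
                draws["inv_tau_gamma"][kept] = 1.0 / nat["tau_gamma"]
            else:
                draws["inv_tau_v"][kept] = 1.0 / nat["tau_v"]
                draws["inv_tau_u"][kept] = 1.0 / nat["tau_u"]
            draws["alpha_o"][kept] = x[n]
            for j in range(k):
                draws[f"delta_{j}"][kept] = x[n + 1 + j]
            for j, name in enumerate(b_names):
                draws[name][kept] = zeta[j]
            if b_dim and spec.family in ("zip0", "zip1"):
                draws["p"][kept] = expit(zeta[0])
            draws["loglik"][kept] = lik.ll
            if gamma_store is not None:
                gamma_store[kept] = x[:n]
            ll_o_store[kept] = lik.ll_o
            if ll_z_store is not None:
                ll_z_store[kept] = lik.ll_z
            kept += 1

    rates = {kkey: (acc[kkey] / tries[kkey] if tries[kkey] else np.nan) for kkey in acc}
    return PosteriorSamples(
        draws=draws,
        gamma=gamma_store,
        ll_o=ll_o_store,
        ll_z=ll_z_store,
        spec=spec,
        config=cfg,
        accept_rates=rates,
    )


# ---------------------------------------------------------------------------
# summaries and diagnostics


def posterior_summary(samples: PosteriorSamples, params=None) -> pd.DataFrame:
    """Posterior mean, sd and central 95% credible interval per parameter.

    Summaries are computed on the stored draws directly, so transformed
    parameters (e.g. ``inv_tau_gamma``) are summarized on their own scale.
    """
    if samples.n_draws == 0:
        raise ValueError("empty chain: nothing to summarize")
    names = params if params is not None else sorted(samples.draws)
    rows = []
    for name in names:
        v = samples.draws[name]
        rows.append(
            {
                "param": name,
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                "q2.5": float(np.quantile(v, 0.025)),
                "q97.5": float(np.quantile(v, 0.975)),
            }
        )
    return pd.DataFrame(rows).set_index("param")


def diagnostics(samples: PosteriorSamples, params=None) -> pd.DataFrame:
    """Split-R-hat and effective sample size per scalar parameter.

    Flags parameters with R-hat > 1.05 or ESS < 200.
    """
    import arviz as az

    names = params if params is not None else sorted(samples.draws)
    rows = []
    for name in names:
        v = samples.draws[name]
        if np.allclose(v, v[0]):
            ess, rhat = float(v.size), 1.0
        else:
            ess = float(az.ess(v[None, :]))
            rhat = _split_rhat(v)
        rows.append(
            {
                "param": name,
                "ess": ess,
                "rhat": rhat,
                "flag": bool(rhat > 1.05 or ess < 200),
            }
        )
    return pd.DataFrame(rows).set_index("param")
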