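"""Model assembly: linear predictors, the misaligned joint response, and the
full log-posterior.

Latent spatial structure comes in two flavours:

* **BYM** — gamma_i = v_i + u_i with v iid N(0, 1/tau_v) and u an ICAR field
  with precision tau_u * Q; marginally
  Var(gamma) = tau_v^-1 I + tau_u^-1 Q^-.
* **BYM2** — gamma = (1/sqrt(tau_gamma)) (sqrt(1-phi) v + sqrt(phi) u*),
  with u* the *scaled* ICAR effect, so
  Var(gamma) = tau_gamma^-1 ((1-phi) I + phi (Q*)^-); tau_gamma is the
  generalized precision and phi in [0, 1) splits the variance between the
  unstructured and structured parts.

In both cases the likelihood depends on the latent field only through
gamma, so inference and the log-posterior work with gamma marginally; the
sum-to-zero constraint on u / u* lives in the null space of the generalized
inverse (see :meth:`ScaledPrecision.eig_pinv`).

The joint model shares one gamma between a Bernoulli occurrence likelihood
(logit p_i = alpha_z + y_i' omega + beta * gamma_i) and a zero-truncated
Poisson count likelihood (log theta_i = alpha_o + x_i' delta + gamma_i),
with the count missing where no event occurred.  Its two-column response
matrix is misaligned: the first n rows carry z in column 1, the next n rows
carry o in column 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import ScaledPrecision
from .likelihoods import (
    ObservedData,
    bernoulli_loglik,
    inv_logit_link,
    poisson_loglik,
    truncated_poisson_loglik,
    zip0_loglik,
    zip1_loglik,
)
from .priors import (
    FixedEffectPriors,
    GammaPrecisionPrior,
    NormalPrior,
    PCMixingPrior,
    PCPrecisionPrior,
)

__all__ = [
    "FAMILIES",
    "LATENTS",
    "ModelSpec",
    "build_joint_response",
    "extract_joint_response",
    "linear_predictors",
    "latent_logpdf",
    "log_posterior",
]

FAMILIES = ("poisson", "zip0", "zip1", "joint")
LATENTS = ("bym", "bym2")


def build_joint_response(z, o) -> np.ndarray:
    """Misaligned (2n, 2) response matrix for the two-likelihood joint model.

    Rows 0..n-1 carry the occurrence indicators in column 0; rows n..2n-1
    carry the counts in column 1; every other cell is NaN.  The count must
    be missing wherever z = 0 (no event, nothing to count).
    """
    z = np.asarray(z, dtype=float)
    o = np.asarray(o, dtype=float)
    if z.shape != o.shape or z.ndim != 1:
        raise ValueError("z and o must be equal-length vectors")
    bad = np.isfinite(o) & (z == 0)
    if np.any(bad):
        raise ValueError(
            "occurrence/count inconsistency: o present where z = 0 at regions "
            f"{np.flatnonzero(bad).tolist()}"
        )
    n = z.shape[0]
    Y = np.full((2 * n, 2), np.nan)
    Y[:n, 0] = z
    Y[n:, 1] = o
    return Y


def extract_joint_response(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recover (z, o) from a misaligned joint response matrix."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2 or Y.shape[0] % 2:
        raise ValueError("joint response must be a (2n, 2) matrix")
    n = Y.shape[0] // 2
    return Y[:n, 0].copy(), Y[n:, 1].copy()


@dataclass
class ModelSpec:
    """Everything needed to evaluate one model's posterior.

    ``family`` is the observation model; ``latent`` selects BYM or BYM2.
    Priors default to the package's standard choices: PC priors for the
    BYM2 hyperparameters (phi: U=0.5, alpha=2/3; precision: U=1,
    alpha=0.01), Gamma(1, 0.01) for the BYM precisions, and the normal
    fixed-effect priors in :class:`FixedEffectPriors`.
    """

    family: str
    latent: str
    data: ObservedData
    precision: ScaledPrecision
    fixed_priors: FixedEffectPriors = field(default_factory=FixedEffectPriors)
    pc_prec: PCPrecisionPrior = field(default_factory=PCPrecisionPrior)
    pc_phi: PCMixingPrior | None = None
    gamma_prec: GammaPrecisionPrior = field(default_factory=GammaPrecisionPrior)
    zero_prob_prior: NormalPrior = NormalPrior.from_precision(-1.0, 0.2)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.latent not in LATENTS:
            raise ValueError(f"unknown latent model {self.latent!r}; one of {LATENTS}")
        if self.data.n != self.precision.n:
            raise ValueError("data and graph have different numbers of regions")
        if self.family == "joint":
            if self.data.z is None:
                raise ValueError("joint family requires occurrence indicators z")
            build_joint_response(self.data.z, self.data.o)  # validates alignment
        if self.latent == "bym2":
            if not self.precision.is_scaled:
                raise ValueError("BYM2 requires a scaled precision (scale_icar)")
            if self.pc_phi is None:
                self.pc_phi = PCMixingPrior(0.5, 2.0 / 3.0, self.precision)

    @property
    def n(self) -> int:
        return self.data.n

    def joint_response(self) -> np.ndarray:
        if self.family != "joint":
            raise ValueError("joint response only defined for the joint family")
        return build_joint_response(self.data.z, self.data.o)


def linear_predictors(spec: ModelSpec, gamma, fixed: dict):
    """Assemble (log_theta, logit_p) from the shared latent field.

    log theta_i = alpha_o + x_i' delta + gamma_i  (the offset log E_i is
    applied inside the Poisson mean, mean = E_i * theta_i);
    logit p_i = alpha_z + y_i' omega + beta * gamma_i.  The same gamma
    vector enters both predictors.

    For single-likelihood families, logit_p is the scalar logit zero
    probability (``fixed["logit_p"]``) broadcast over regions, or None for
    plain Poisson.
    """
    gamma = np.asarray(gamma, dtype=float)
    n = spec.n
    if gamma.shape != (n,):
        raise ValueError(f"gamma must have shape ({n},), got {gamma.shape}")
    log_theta = fixed.get("alpha_o", 0.0) + gamma
    if spec.data.x is not None:
        delta = np.atleast_1d(np.asarray(fixed["delta"], dtype=float))
        if delta.shape[0] != spec.data.x.shape[1]:
            raise ValueError("delta not conformable with covariate matrix x")
        log_theta = log_theta + spec.data.x @ delta
    if spec.family == "joint":
        logit_p = fixed.get("alpha_z", 0.0) + fixed.get("beta", 1.0) * gamma
        if spec.data.y is not None:
            omega = np.atleast_1d(np.asarray(fixed["omega"], dtype=float))
            if omega.shape[0] != spec.data.y.shape[1]:
                raise ValueError("omega not conformable with covariate matrix y")
            logit_p = logit_p + spec.data.y @ omega
    elif spec.family in ("zip0", "zip1"):
        logit_p = np.full(n, float(fixed["logit_p"]))
    else:
        logit_p = None
    return log_theta, logit_p


def observation_loglik(spec: ModelSpec, log_theta, logit_p):
    """Per-observation log-likelihood vectors (ll_o, ll_z).

    Missing cells contribute exactly zero (their entries are NaN in the
    returned vectors only where the observation itself is missing; callers
    sum with nansum).  ll_z is None for single-likelihood families.
    """
    o, E = spec.data.o, spec.data.E
    theta = np.exp(np.asarray(log_theta, dtype=float))
    obs = np.isfinite(o)
    ll_o = np.full(spec.n, np.nan)
    if spec.family == "poisson":
        ll_o[obs] = poisson_loglik(o[obs], E[obs], theta[obs])
        return ll_o, None
    p = inv_logit_link(logit_p)
    if spec.family == "zip1":
        ll_o[obs] = zip1_loglik(o[obs], E[obs], theta[obs], p[obs])
        return ll_o, None
    if spec.family == "zip0":
        ll_o[obs] = zip0_loglik(o[obs], E[obs], theta[obs], p[obs])
        return ll_o, None
    # joint: Bernoulli occurrence + zero-truncated Poisson where z = 1
    z = spec.data.z
    zobs = np.isfinite(z)
    ll_z = np.full(spec.n, np.nan)
    ll_z[zobs] = bernoulli_loglik(z[zobs], p[zobs])
    cobs = obs & (np.nan_to_num(z) == 1)
    ll_o = np.full(spec.n, np.nan)
    if np.any(cobs):
        ll_o[cobs] = truncated_poisson_loglik(o[cobs], E[cobs], theta[cobs])
    return ll_o, ll_z


def _marginal_cov_eigs(spec: ModelSpec, hyper: dict) -> tuple[np.ndarray, np.ndarray]:
    """Eigenbasis V and eigenvalues of Var(gamma) under the latent model."""
    if spec.latent == "bym2":
        V, s = spec.precision.eig_pinv(scaled=True)
        tau, phi = hyper["tau_gamma"], hyper["phi"]
        if tau <= 0 or not 0 <= phi < 1:
            raise ValueError("tau_gamma must be > 0 and phi in [0, 1)")
        cov = ((1.0 - phi) + phi * s) / tau
    else:
        V, s = spec.precision.eig_pinv(scaled=False)
        tau_v, tau_u = hyper["tau_v"], hyper["tau_u"]
        if tau_v <= 0 or tau_u <= 0:
            raise ValueError("tau_v and tau_u must be positive")
        cov = 1.0 / tau_v + s / tau_u
    return V, cov


def latent_logpdf(spec: ModelSpec, gamma, hyper: dict) -> float:
    """Log-density of gamma under its marginal Gaussian prior.

    BYM2: gamma ~ N(0, tau_gamma^-1 ((1-phi) I + phi (Q*)^-));
    BYM:  gamma ~ N(0, tau_v^-1 I + tau_u^-1 Q^-).
    Both are proper for phi < 1 / tau_v finite; the sum-to-zero constraint
    on the structured part is encoded by the zero pseudo-eigenvalues.
    """
    gamma = np.asarray(gamma, dtype=float)
    V, cov = _marginal_cov_eigs(spec, hyper)
    t = V.T @ gamma
    return float(
        -0.5 * spec.n * np.log(2 * np.pi)
        - 0.5 * np.sum(np.log(cov))
        - 0.5 * np.sum(t * t / cov)
    )


def hyper_logprior(spec: ModelSpec, hyper: dict) -> float:
    """Log prior density of the latent hyperparameters (natural scale)."""
    if spec.latent == "bym2":
        return float(
            spec.pc_prec.logpdf(hyper["tau_gamma"]) + spec.pc_phi.logpdf(hyper["phi"])
        )
    return float(
        spec.gamma_prec.logpdf(hyper["tau_v"]) + spec.gamma_prec.logpdf(hyper["tau_u"])
    )


def fixed_logprior(spec: ModelSpec, fixed: dict) -> float:
    """Log prior of intercepts, covariate effects, beta / zero probability."""
    fp = spec.fixed_priors
    lp = fp.intercept_o.logpdf(fixed.get("alpha_o", 0.0))
    if spec.data.x is not None:
        lp += np.sum(fp.delta.logpdf(np.atleast_1d(fixed["delta"])))
    if spec.family == "joint":
        lp += fp.intercept_z.logpdf(fixed.get("alpha_z", 0.0))
        lp += fp.beta.logpdf(fixed.get("beta", 1.0))
        if spec.data.y is not None:
            lp += np.sum(fp.omega.logpdf(np.atleast_1d(fixed["omega"])))
    elif spec.family in ("zip0", "zip1"):
        lp += spec.zero_prob_prior.logpdf(fixed["logit_p"])
    return float(lp)


def log_posterior(spec: ModelSpec, state: dict) -> float:
    """Unnormalized log-posterior of a full model state.

    ``state`` holds gamma plus the fixed effects and hyperparameters
    appropriate to the family/latent combination (see
    :func:`linear_predictors`, :func:`latent_logpdf`).  Out-of-support
    states return -inf rather than raising.
    """
    gamma = np.asarray(state["gamma"], dtype=float)
    try:
        lp = latent_logpdf(spec, gamma, state)
    except ValueError:
        return -np.inf
    hp = hyper_logprior(spec, state)
    fp = fixed_logprior(spec, state)
    if not np.isfinite(lp + hp + fp):
        return -np.inf
    log_theta, logit_p = linear_predictors(spec, gamma, state)
    ll_o, ll_z = observation_loglik(spec, log_theta, logit_p)
    ll = np.nansum(ll_o) + (np.nansum(ll_z) if ll_z is not None else 0.0)
    return float(ll + lp + hp + fp)
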