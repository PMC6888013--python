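"""Observation models: Poisson, zero-truncated Poisson, ZIP type0/type1, Bernoulli.

All count models are parameterized by a per-region relative risk theta and
expected count E (the offset), so the Poisson mean is E * theta.  The two
zero-inflated families follow the "type" naming of the INLA ecosystem:

* type1 mixes a structural zero (mass 1 - p) with a *full* Poisson (mass p),
  so zeros can arise both structurally and by chance;
* type0 (a hurdle) mixes a structural zero with a *zero-truncated* Poisson,
  so every zero is structural.

Note the mixture orientation: (1 - p) is the structural-zero mass and p
multiplies the count component.  Some software parameterizes the reverse
(p as the zero-inflation probability); convert with p' = 1 - p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "ObservedData",
    "poisson_loglik",
    "truncated_poisson_loglik",
    "zip1_loglik",
    "zip0_loglik",
    "bernoulli_loglik",
    "log_link",
    "inv_log_link",
    "logit_link",
    "inv_logit_link",
]


def _check_counts(o, allow_zero=True):
    o = np.asarray(o, dtype=float)
    finite = np.isfinite(o)
    vals = o[finite]
    if np.any(vals < (0 if allow_zero else 1)) or np.any(vals != np.round(vals)):
        lo = "nonnegative" if allow_zero else "positive"
        raise ValueError(f"counts must be {lo} integers")
    return o


def poisson_loglik(o, E, theta):
    """Log-likelihood of counts o under Poisson with mean E * theta."""
    o = _check_counts(o)
    E = np.asarray(E, dtype=float)
    theta = np.asarray(theta, dtype=float)
    mu = E * theta
    out = o * np.log(mu) - mu - gammaln(o + 1.0)
    return out if np.ndim(out) else float(out)


def _log1m_exp_neg(mu):
    """log(1 - exp(-mu)), stable for both small and large mu."""
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(
            mu > 0.693,
            np.log1p(-np.exp(-np.minimum(mu, 745.0))),
            np.log(-np.expm1(-mu)),
        )


def truncated_poisson_loglik(o, E, theta):
    """Zero-truncated Poisson log-likelihood; counts must be >= 1."""
    o = _check_counts(o, allow_zero=False)
    out = poisson_loglik(o, E, theta) - _log1m_exp_neg(
        np.asarray(E, dtype=float) * np.asarray(theta, dtype=float)
    )
    return out if np.ndim(out) else float(out)


def zip1_loglik(o, E, theta, p):
    """ZIP type1: mass (1-p) on a structural zero plus p on a full Poisson."""
    o = _check_counts(o)
    E = np.asarray(E, dtype=float)
    theta = np.asarray(theta, dtype=float)
    p = np.asarray(p, dtype=float)
    o, E, theta, p = np.broadcast_arrays(o, E, theta, p)
    mu = E * theta
    with np.errstate(divide="ignore"):
        # log[(1-p) + p*exp(-mu)] via logaddexp for stability
        zero_term = np.logaddexp(np.log1p(-p), np.log(p) - mu)
        pois = o * np.log(mu) - mu - gammaln(o + 1.0)
        out = np.where(o == 0, zero_term, np.log(p) + pois)
    return out if np.ndim(out) else float(out)


def zip0_loglik(o, E, theta, p):
    """ZIP type0 (hurdle): mass (1-p) on zero plus p on a truncated Poisson."""
    o = _check_counts(o)
    E = np.asarray(E, dtype=float)
    theta = np.asarray(theta, dtype=float)
    p = np.asarray(p, dtype=float)
    o, E, theta, p = np.broadcast_arrays(o, E, theta, p)
    mu = E * theta
    with np.errstate(divide="ignore"):
        pois = o * np.log(mu) - mu - gammaln(o + 1.0)
        out = np.where(
            o == 0,
            np.log1p(-p),
            np.log(p) + pois - _log1m_exp_neg(mu),
        )
    return out if np.ndim(out) else float(out)


def bernoulli_loglik(z, p):
    """Bernoulli log-likelihood for occurrence indicators z in {0, 1}."""
    z = np.asarray(z, dtype=float)
    finite = np.isfinite(z)
    if np.any(~np.isin(z[finite], (0.0, 1.0))):
        raise ValueError("z must be 0 or 1")
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(z == 1, np.log(p), np.log1p(-p))
    return out if np.ndim(out) else float(out)


def log_link(theta):
    """log(theta); -inf at 0 by contract."""
    with np.errstate(divide="ignore"):
        out = np.log(np.asarray(theta, dtype=float))
    return out if np.ndim(out) else float(out)


def inv_log_link(eta):
    out = np.exp(np.asarray(eta, dtype=float))
    return out if np.ndim(out) else float(out)


def logit_link(p):
    """logit(p) = ln(p / (1-p)); +/-inf at the boundary by contract."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.log(p) - np.log1p(-p)
    return out if np.ndim(out) else float(out)


def inv_logit_link(eta):
    out = expit(np.asarray(eta, dtype=float))
    return out if np.ndim(out) else float(out)


@dataclass
class ObservedData:
    """Per-region observations: counts o, occurrence z, expected counts E.

    Missing values are NaN (serialized as "NA").  In the hurdle/joint
    convention, o is missing exactly where z = 0.  Optional covariate
    matrices x (count side) and y (occurrence side) are (n, k) arrays.
    """

    o: np.ndarray
    E: np.ndarray
    z: np.ndarray | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    region_labels: tuple | None = None

    def __post_init__(self):
        self.o = np.asarray(self.o, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        n = self.o.shape[0]
        if self.E.shape != (n,):
            raise ValueError("E must have one entry per region")
        if np.any(~np.isfinite(self.E)) or np.any(self.E <= 0):
            raise ValueError("expected counts E must be positive and finite")
        _check_counts(self.o)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if self.z.shape != (n,):
                raise ValueError("z must have one entry per region")
            zf = self.z[np.isfinite(self.z)]
            if np.any(~np.isin(zf, (0.0, 1.0))):
                raise ValueError("z must be binary")
        for name in ("x", "y"):
            M = getattr(self, name)
            if M is not None:
                M = np.atleast_2d(np.asarray(M, dtype=float))
                if M.shape[0] != n:
                    raise ValueError(f"covariate matrix {name} must have n rows")
                setattr(self, name, M)

    @property
    def n(self) -> int:
        return self.o.shape[0]
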