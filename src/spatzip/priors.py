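"""Prior densities: PC priors for precision and mixing, Gamma and normal priors.

Penalized-complexity (PC) priors put an exponential density on the distance
d = sqrt(2 * KLD) from a base model.  For a precision tau the base model is
"no random effect" (sigma = 1/sqrt(tau) = 0) and d = sigma, so calibrating
P(sigma > U) = alpha gives rate lambda = -ln(alpha)/U.  For the BYM2 mixing
parameter phi the base model is the purely unstructured field (phi = 0); the
distance depends on the graph through the spectrum of the scaled structured
covariance, and lambda is found numerically from P(phi < U) = alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import ScaledPrecision

__all__ = [
    "pc_prec_lambda",
    "pc_prec_logpdf",
    "pc_phi_distance",
    "pc_phi_lambda",
    "pc_phi_logpdf",
    "PCPrecisionPrior",
    "PCMixingPrior",
    "GammaPrecisionPrior",
    "NormalPrior",
    "FixedEffectPriors",
]

_PHI_GRID_SIZE = 1001
_PHI_MAX = 1.0 - 1e-8


def pc_prec_lambda(U: float, alpha: float) -> float:
    """PC-precision rate lambda = -ln(alpha)/U from P(sigma > U) = alpha."""
    if U <= 0:
        raise ValueError(f"U must be positive, got {U}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return -np.log(alpha) / U


def pc_prec_logpdf(tau, lam: float):
    """Log-density of tau when sigma = tau^(-1/2) is Exponential(lam).

    Returns -inf for tau <= 0 (log-density contract, no exception).
    """
    tau = np.asarray(tau, dtype=float)
    out = np.full(tau.shape, -np.inf)
    ok = tau > 0
    t = tau[ok]
    out[ok] = np.log(lam / 2.0) - 1.5 * np.log(t) - lam / np.sqrt(t)
    return out if out.ndim else float(out)


def _phi_kld_terms(phi, xi: np.ndarray):
    """KLD(phi) = 0.5 * sum_i [phi*(xi_i - 1) - ln(1 - phi + phi*xi_i)].

    xi are the eigenvalues of the generalized inverse of Q* (null
    directions contribute xi = 0, i.e. the term phi*(-1) - ln(1 - phi)).
    """
    phi = np.asarray(phi, dtype=float)[..., None]
    return 0.5 * np.sum(phi * (xi - 1.0) - np.log1p(phi * (xi - 1.0)), axis=-1)


def pc_phi_distance(phi, precision: ScaledPrecision):
    """Distance d(phi) = sqrt(2 * KLD(phi)) from the unstructured base model."""
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0) or np.any(phi_arr >= 1):
        raise ValueError("phi must lie in [0, 1)")
    _, xi = precision.eig_pinv(scaled=True)
    kld = _phi_kld_terms(phi_arr, xi)
    d = np.sqrt(np.maximum(2.0 * kld, 0.0))
    return d if d.ndim else float(d)


@dataclass
class PCMixingPrior:
    """Graph-dependent PC prior for the BYM2 mixing parameter phi.

    The density is a truncated exponential on d(phi) transformed to phi,
    with the distance tabulated on a fixed grid and its derivative taken by
    centered finite differences.  ``lam`` is calibrated so that
    P(phi < U) = alpha.
    """

    U: float
    alpha: float
    precision: ScaledPrecision
    lam: float = field(init=False)
    phi_grid: np.ndarray = field(init=False, repr=False)
    d_grid: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if not 0 < self.U < 1:
            raise ValueError(f"U must be in (0,1), got {self.U}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        grid = np.linspace(0.0, 1.0, _PHI_GRID_SIZE)
        grid[-1] = _PHI_MAX
        self.phi_grid = grid
        self.d_grid = pc_phi_distance(grid, self.precision)
        self.lam = _calibrate_phi_lambda(
            self.U, self.alpha, self.phi_grid, self.d_grid
        )

    @property
    def d_max(self) -> float:
        return float(self.d_grid[-1])

    def distance(self, phi):
        return np.interp(phi, self.phi_grid, self.d_grid)

    def logpdf(self, phi):
        """Log-density of phi; -inf outside [0, phi_max)."""
        phi = np.asarray(phi, dtype=float)
        out = np.full(phi.shape, -np.inf)
        ok = (phi >= 0) & (phi < self.phi_grid[-1])
        if np.any(ok):
            p = phi[ok]
            d = np.interp(p, self.phi_grid, self.d_grid)
            dd = _centered_derivative(p, self.phi_grid, self.d_grid)
            log_norm = -np.log1p(-np.exp(-self.lam * self.d_max))
            out[ok] = (
                np.log(self.lam) - self.lam * d + np.log(dd) + log_norm
            )
        return out if out.ndim else float(out)


def _centered_derivative(phi, grid: np.ndarray, d_grid: np.ndarray):
    """d'(phi): finite difference across the grid cell containing phi.

    This is the centered difference at the cell midpoint and, crucially,
    the exact derivative of the linear interpolant used for d, so the
    change of variables conserves probability mass cell by cell.
    """
    j = np.clip(np.searchsorted(grid, phi, side="right") - 1, 0, len(grid) - 2)
    return (d_grid[j + 1] - d_grid[j]) / (grid[j + 1] - grid[j])


def _calibrate_phi_lambda(
    U: float, alpha: float, phi_grid: np.ndarray, d_grid: np.ndarray
) -> float:
    """Bisection on lambda so that P(phi < U) = alpha under the truncated
    exponential on d; the CDF is available in closed form:
    P(phi < U) = (1 - exp(-lam*d(U))) / (1 - exp(-lam*d_max))."""
    dU = float(np.interp(U, phi_grid, d_grid))
    d_max = float(d_grid[-1])

    def cdf(lam):
        return np.expm1(-lam * dU) / np.expm1(-lam * d_max)

    lo, hi = 1e-6, 1e3
    flo, fhi = cdf(lo) - alpha, cdf(hi) - alpha
    if flo * fhi > 0:
        raise ValueError(
            f"PC-phi calibration failed to bracket: cdf({lo})={flo + alpha:.4g}, "
            f"cdf({hi})={fhi + alpha:.4g}, target {alpha}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = cdf(mid) - alpha
        if abs(fm) < 1e-12 or hi - lo < 1e-6 * max(1.0, mid):
            break
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def pc_phi_lambda(U: float, alpha: float, precision: ScaledPrecision) -> float:
    """Calibrated PC-mixing rate for a given graph."""
    return PCMixingPrior(U, alpha, precision).lam


def pc_phi_logpdf(phi, lam: float, precision: ScaledPrecision):
    """Log-density of phi under the PC-mixing prior with given rate."""
    prior = PCMixingPrior.__new__(PCMixingPrior)
    prior.U, prior.alpha, prior.precision = 0.5, 0.5, precision
    grid = np.linspace(0.0, 1.0, _PHI_GRID_SIZE)
    grid[-1] = _PHI_MAX
    prior.phi_grid = grid
    prior.d_grid = pc_phi_distance(grid, precision)
    prior.lam = lam
    return prior.logpdf(phi)


@dataclass(frozen=True)
class PCPrecisionPrior:
    """PC prior for a precision, calibrated by P(sigma > U) = alpha."""

    U: float = 1.0
    alpha: float = 0.01

    @property
    def lam(self) -> float:
        return pc_prec_lambda(self.U, self.alpha)

    def logpdf(self, tau):
        return pc_prec_logpdf(tau, self.lam)


@dataclass(frozen=True)
class GammaPrecisionPrior:
    """Gamma(shape, rate) prior on a precision (the classic BYM choice)."""

    shape: float = 1.0
    rate: float = 0.01

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("Gamma shape and rate must be positive")

    def logpdf(self, tau):
        from scipy.special import gammaln

        tau = np.asarray(tau, dtype=float)
        out = np.full(tau.shape, -np.inf)
        ok = tau > 0
        t = tau[ok]
        out[ok] = (
            self.shape * np.log(self.rate)
            - gammaln(self.shape)
            + (self.shape - 1.0) * np.log(t)
            - self.rate * t
        )
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class NormalPrior:
    """Univariate normal prior specified by mean and variance."""

    mean: float
    var: float

    def __post_init__(self):
        if self.var <= 0:
            raise ValueError("variance must be positive")

    @classmethod
    def from_precision(cls, mean: float, precision: float) -> "NormalPrior":
        return cls(mean, 1.0 / precision)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = -0.5 * np.log(2 * np.pi * self.var) - 0.5 * (x - self.mean) ** 2 / self.var
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class FixedEffectPriors:
    """Default normal priors for intercepts, covariate effects and beta.

    Count-side intercept and covariate effects are vague (precision 1e-4);
    occurrence-side intercept and effects are centered at -1 with precision
    0.2 (probabilities below one half a priori); the sharing coefficient
    beta is N(1, 10) with 10 read as a *variance* — weakly informative
    around "same spatial pattern in both responses".
    """

    intercept_o: NormalPrior = NormalPrior.from_precision(0.0, 1e-4)
    intercept_z: NormalPrior = NormalPrior.from_precision(-1.0, 0.2)
    delta: NormalPrior = NormalPrior.from_precision(0.0, 1e-4)
    omega: NormalPrior = NormalPrior.from_precision(-1.0, 0.2)
    beta: NormalPrior = NormalPrior(1.0, 10.0)
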