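"""Model comparison: DIC and the CPO-based logarithmic score.

DIC follows the classical Spiegelhalter construction: with deviance
D(state) = -2 log-likelihood, Dbar is the posterior mean deviance, the
effective number of parameters is pD = Dbar - D(posterior-mean state), and
DIC = Dbar + pD.  The conditional predictive ordinate for observation i is
the harmonic-mean estimator CPO_i = 1 / mean(1 / p(obs_i | state)), and the
logarithmic score is the per-observation mean of -ln CPO_i.  Smaller DIC
and LS indicate a better model.

For the two-likelihood joint model, DIC and LS are each the sum of the two
per-likelihood blocks (Bernoulli occurrence + truncated-Poisson counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import PosteriorSamples
from .models import linear_predictors, observation_loglik

__all__ = ["SelectionReport", "dic", "cpo", "log_score", "selection_report"]


@dataclass
class SelectionReport:
    """DIC/LS summary, with the per-likelihood breakdown for joint models."""

    DIC: float
    pD: float
    Dbar: float
    LS: float
    cpo_o: np.ndarray
    cpo_z: np.ndarray | None = None
    blocks: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        row = {"DIC": self.DIC, "pD": self.pD, "Dbar": self.Dbar, "LS": self.LS}
        if self.blocks:
            for bname, b in self.blocks.items():
                for key, val in b.items():
                    row[f"{bname}_{key}"] = val
        return pd.DataFrame([row])


def _plugin_loglik(samples: PosteriorSamples):
    """Per-observation log-likelihoods at the posterior-mean state."""
    spec = samples.spec
    state = samples.posterior_mean_state()
    if "logit_p" in state and "p" in state:
        # plug in the mean probability, consistent with natural-scale means
        from scipy.special import logit

        state["logit_p"] = logit(state["p"])
    if spec.data.x is not None:
        state["delta"] = np.array(
            [state[f"delta_{j}"] for j in range(spec.data.x.shape[1])]
        )
    if spec.family == "joint" and spec.data.y is not None:
        state["omega"] = np.array(
            [state[f"omega_{j}"] for j in range(spec.data.y.shape[1])]
        )
    log_theta, logit_p = linear_predictors(spec, state["gamma"], state)
    return observation_loglik(spec, log_theta, logit_p)


def _block_dic(ll_draws: np.ndarray, ll_hat: np.ndarray):
    """(DIC, pD, Dbar) from per-draw and plug-in per-obs log-likelihoods."""
    per_draw = np.nansum(ll_draws, axis=1)
    if np.any(~np.isfinite(per_draw)):
        nbad = int(np.sum(~np.isfinite(per_draw)))
        raise ValueError(f"non-finite deviance in {nbad} draws")
    dbar = float(np.mean(-2.0 * per_draw))
    dhat = float(-2.0 * np.nansum(ll_hat))
    pd_eff = dbar - dhat
    return dbar + pd_eff, pd_eff, dbar


def dic(samples: PosteriorSamples, spec=None):
    """DIC of a fitted model; joint models sum their two likelihood blocks.

    Returns (DIC, pD, Dbar).
    """
    ll_hat_o, ll_hat_z = _plugin_loglik(samples)
    d_o, p_o, db_o = _block_dic(samples.ll_o, ll_hat_o)
    if samples.ll_z is None:
        return d_o, p_o, db_o
    d_z, p_z, db_z = _block_dic(samples.ll_z, ll_hat_z)
    return d_o + d_z, p_o + p_z, db_o + db_z


def cpo(ll_draws: np.ndarray) -> np.ndarray:
    """Harmonic-mean CPO estimate per observation (NaN where missing).

    CPO_i = [mean_m 1/p(obs_i | state_m)]^-1, computed with log-sum-exp
    stabilization; an observation with a zero-likelihood draw gets CPO 0.
    """
    M, n = ll_draws.shape
    out = np.full(n, np.nan)
    for i in range(n):
        col = ll_draws[:, i]
        if np.all(np.isnan(col)):
            continue
        if np.any(np.isneginf(col)):
            out[i] = 0.0
            continue
        out[i] = float(np.exp(-(logsumexp(-col) - np.log(M))))
    return out


def log_score(cpo_values: np.ndarray) -> float:
    """Mean of -ln CPO_i over the non-missing observations of one block."""
    vals = cpo_values[np.isfinite(cpo_values)]
    if vals.size == 0:
        raise ValueError("no observations with CPO values")
    if np.any(vals <= 0):
        return float("inf")
    return float(np.mean(-np.log(vals)))


def selection_report(samples: PosteriorSamples) -> SelectionReport:
    """Full DIC/CPO/LS report for one fitted model."""
    ll_hat_o, ll_hat_z = _plugin_loglik(samples)
    d_o, p_o, db_o = _block_dic(samples.ll_o, ll_hat_o)
    cpo_o = cpo(samples.ll_o)
    ls_o = log_score(cpo_o)
    if samples.ll_z is None:
        return SelectionReport(
            DIC=d_o, pD=p_o, Dbar=db_o, LS=ls_o, cpo_o=cpo_o
        )
    d_z, p_z, db_z = _block_dic(samples.ll_z, ll_hat_z)
    cpo_z = cpo(samples.ll_z)
    ls_z = log_score(cpo_z)
    blocks = {
        "count": {"DIC": d_o, "pD": p_o, "LS": ls_o},
        "occurrence": {"DIC": d_z, "pD": p_z, "LS": ls_z},
    }
    return SelectionReport(
        DIC=d_o + d_z,
        pD=p_o + p_z,
        Dbar=db_o + db_z,
        LS=ls_o + ls_z,
        cpo_o=cpo_o,
        cpo_z=cpo_z,
        blocks=blocks,
    )
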