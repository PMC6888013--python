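# Methods

## Model

Counts with many zero regions are modeled through one of four observation
families over $n$ regions with expected counts $E_i$ and relative risks
$\theta_i$ (Poisson mean $E_i\theta_i$):

| family | likelihood |
|---|---|
| `poisson` | $o_i \sim \mathrm{Pois}(E_i\theta_i)$ |
| `zip1` | $(1-p_i) I(o_i{=}0) + p_i \mathrm{Pois}(o_i; E_i\theta_i)$ |
| `zip0` | $(1-p_i) I(o_i{=}0) + p_i \mathrm{TruncPois}(o_i; E_i\theta_i)$ |
| `joint` | $z_i \sim \mathrm{Bern}(p_i)$ and $o_i \mid z_i{=}1 \sim \mathrm{TruncPois}(E_i\theta_i)$ |

In the mixtures, $(1-p)$ is the structural-zero mass and $p$ multiplies the
count component; software that parameterizes the reverse converts by
$p' = 1-p$. In the joint family, $o_i$ is missing wherever $z_i = 0$ — the
response is the misaligned $(2n \times 2)$ matrix with the occurrence block
above the count block — and the two linear predictors share one latent
field:

$\log\theta_i = \alpha_O + x_i^T\delta + \gamma_i$,
$\mathrm{logit}\,p_i = \alpha_z + y_i^T\omega + \beta\gamma_i$.

The sharing coefficient $\beta$ is implemented as exact reuse of the same
$\gamma$ vector with one scalar multiplier sampled as a parameter. For the
single-likelihood ZIP families, $p$ is a scalar zero-probability
hyperparameter on the logit scale.

### Latent spatial structure

The ICAR precision is the graph Laplacian $Q = D - A$; the BYM2 structured
effect uses $Q^* = cQ$ with $c$ the geometric mean of the constrained
marginal variances of the generalized inverse, computed and applied **per
connected component**, so that hyperpriors transfer across graphs.
Isolated regions are rejected (a region without neighbors has no
structured effect to scale). Two latent models:

* BYM: $\gamma = v + u$,
  $\mathrm{Var}(\gamma) = \tau_v^{-1} I + \tau_u^{-1} Q^-$,
  $\tau_v, \tau_u \sim \mathrm{Gamma}(1, 0.01)$.
* BYM2: $\gamma = \tau_\gamma^{-1/2}(\sqrt{1-\varphi}\,v + \sqrt{\varphi}\,u^*)$,
  $\mathrm{Var}(\gamma) = \tau_\gamma^{-1}((1-\varphi) I + \varphi (Q^*)^-)$.

All computations use the *marginal* law of $\gamma$: the generalized
inverses are diagonal in the (hyperparameter-independent) eigenbasis of
$Q^*$ (or $Q$), with the sum-to-zero constraint on $u$/$u^*$ encoded by
zero pseudo-eigenvalues, i.e. no variance in each component's constant
direction beyond what $v$ contributes. $v$ is unconstrained; the overall
level is absorbed by the intercepts, with no extra centering of $\gamma$.
The offset enters the Poisson mean as $E_i\theta_i$, not as a covariate.

### Priors

* PC precision prior (BYM2): $\sigma = \tau^{-1/2} \sim \mathrm{Exp}(\lambda)$
  with $\lambda = -\ln(\alpha)/U$; defaults $U = 1$, $\alpha = 0.01$.
* PC mixing prior: exponential on the distance
  $d(\varphi) = \sqrt{2\,\mathrm{KLD}(\varphi)}$,
  $\mathrm{KLD} = \tfrac12\sum_i[\varphi(\xi_i - 1) - \ln(1 - \varphi + \varphi\xi_i)]$
  over the eigenvalues $\xi_i$ of $(Q^*)^-$, *including* the null
  eigenvalue (term $-\varphi - \ln(1-\varphi)$), so $d \to \infty$ as
  $\varphi \to 1$; a guard rejects $\varphi \ge 1 - 10^{-8}$. The distance
  is tabulated on 1001 equispaced $\varphi$ points with linear
  interpolation; the density uses the interpolant's own per-cell slope (the
  centered difference at the cell midpoint) so that the change of variables
  conserves probability mass — a node-centered difference scheme was tried
  first and misnormalized the density by ~1% because the steep region near
  $\varphi = 1$ concentrates mass. $\lambda$ is calibrated by bisection on
  $[10^{-6}, 10^3]$ from the closed-form truncated-exponential CDF so that
  $P(\varphi < U) = \alpha$; defaults $U = 0.5$, $\alpha = 2/3$.
* Fixed effects: $\alpha_O, \delta \sim N(0, \text{prec } 10^{-4})$;
  $\alpha_z, \omega \sim N(-1, \text{prec } 0.2)$; $\beta \sim N(1, 10)$
  with 10 read as a **variance** (weakly informative; the recovery results
  are insensitive to the precision-10 reading, which was checked directly).
  The scalar ZIP zero-probability gets $N(-1, \text{prec } 0.2)$ on the
  logit scale.

## Posterior computation

A blocked adaptive MCMC on the marginalized state
$(\gamma, \alpha_O, \delta \mid \text{rest})$:

1. **Gaussian block** $x = (\gamma, \alpha_O, \delta)$: independence
   proposal $N(\hat x, \hat P^{-1})$ with $\hat x$ the conditional mode
   (damped Newton with step halving, warm-started, tolerance $10^{-8}$) and
   $\hat P$ the prior precision plus the clamped negative likelihood
   curvature at the mode; Metropolis-corrected. For count data this is
   close to the exact full conditional (acceptance ~0.65–0.9), so the
   block mixes almost like i.i.d. sampling. Two refreshes per iteration.
2. **Hyperparameters** on internal scales ($\ln\tau$, $\mathrm{logit}\,\varphi$,
   with Jacobians): a 2-d adaptive random walk (empirical-covariance
   proposal, Robbins–Monro scale targeting acceptance 0.35) proposed
   *jointly with a fresh Gaussian-block draw* from the mode proposal under
   the proposed hyperparameters. Joint proposing removes the strong
   coupling between the precision and the field scale that freezes
   single-site hyper updates.
3. **Remaining fixed effects** ($\alpha_z, \beta, \omega$, or the ZIP
   zero-probability): small adaptive random walk; an accepted move
   re-centers the Gaussian-block proposal, which conditions on them.

Initialization: $\alpha_O = \ln(\sum o / \sum E)$ over observed cells,
$\alpha_z = \mathrm{logit}(\bar z)$, $\beta = 1$, $\varphi = 0.5$,
$\tau = 1$, $\gamma$ at its conditional mode; all overridable. Every
stochastic step draws from a single seeded generator, so runs are
bit-reproducible. Hyperparameters can be pinned (`fixed_hyper`) for
validation against numeric integration.

Default run length is 2500 iterations with 500 burn-in; the simulation
study and the acceptance script use 750/250. These are far shorter than a
single-site sampler would need because the mode-centred proposal yields
effective sample sizes of roughly 0.2–0.5 per iteration for the
hyperparameters; tripling the run length moves the reported posterior
means by less than 0.01, which was checked on the study scenarios.
Summaries (mean, sd, central 95% interval) are computed on the stored
draws, so transformed parameters such as $1/\tau_\gamma$ are averaged on
their own scale. Diagnostics report split-$\hat R$ (halved-chain formula)
and ESS, flagging $\hat R > 1.05$ or ESS < 200.

## Model comparison

$D = -2\log L$; $\bar D$ averages over draws; $p_D = \bar D - D(\text{posterior
mean state})$ with the plug-in evaluated at natural-scale means (mean
$\gamma$, mean probabilities); $\mathrm{DIC} = \bar D + p_D$. CPO uses the
harmonic-mean identity $\mathrm{CPO}_i = [\mathrm{mean}_m\, 1/p(o_i \mid
\text{state}_m)]^{-1}$ with log-sum-exp stabilization; a zero-likelihood
draw yields $\mathrm{CPO}_i = 0$ and an infinite score. The logarithmic
score is the **mean** of $-\ln \mathrm{CPO}_i$ within one likelihood — a
per-observation quantity of order 1–3, against DIC which scales with $n$ —
and the joint model reports the sum of its two block means (the
alternative, pooling all $2n$ CPOs into one mean, would halve the value;
the block-sum convention is what makes single and joint models comparable
by addition).

## Simulated data

`generate_dataset` draws, per replicate (seeded by `(seed, replicate)`):

* risk surface $\gamma$ — zeros (constant risk); i.i.d. $N(0, 0.5)$
  (unstructured, $1/\tau_\gamma = 0.5$, $\varphi = 0$); or
  $\sqrt{0.5}\,u^*$ with $u^*$ a scaled-ICAR draw (structured,
  $1/\tau_\gamma = 0.5$, $\varphi = 1$);
* occurrence $z_i \sim \mathrm{Bern}(p_i)$,
  $\mathrm{logit}\,p_i = \mathrm{logit}(1-P) + \beta_{\text{true}}\gamma_i$
  with $\beta_{\text{true}} = 1$ and $P$ the target zero proportion
  (0.50 / 0.70 in the study grid);
* counts — type0/joint: zero-truncated Poisson with mean
  $E\,e^{\gamma_i}$ where $z_i = 1$ (exact inverse-CDF draws), missing
  otherwise; type1: the full-Poisson mixture with the same shared-$\gamma$
  $p_i$, so all fitted families face the same generating process per zero
  type.

The default graph is a 19×19 rook lattice (361 regions) — a programmatic
stand-in with the approximate size of the real administrative maps these
models are used on; any graph file can be substituted. What the generator
does **not** emulate: realistic population-driven variation in $E_i$ (it
uses a constant $E$ per scenario, as in the study grid), covariate effects,
boundary irregularity of real maps, and reporting artifacts; passing
recovery tests therefore demonstrates correctness of the machinery under
the stated generating process, not robustness to real-data violations of
it.

A fresh $\gamma$ surface is drawn per replicate. Replicate-averaged
posterior means then centre near the generating truths; with a single
fixed surface per scenario (an alternative design used in earlier
simulation work of this kind) the averages would instead centre on that
surface's realized variance and structure, which can deviate noticeably
from the nominal truths.

## Problem sizes and numerical choices

The study and acceptance runs use 20 replicates per scenario, 750 MCMC
iterations (250 burn-in) per fit, on the 361-region lattice — the package's
desk-scale defaults; `Scenario.n_replicates` and the sampler configuration
scale these up directly. Dense eigendecomposition of $Q^*$ (done once per
graph and cached) backs the scaling constant, the PC-mixing distance, prior
evaluations and constrained sampling; this targets the package's intended
scale of at most a few thousand regions. Newton curvature is clamped to be
positive semi-definite (the ZIP1 zero-cell curvature can change sign) plus
a $10^{-8}$ ridge; predictors are clipped at $|\eta| \le 300$ before
exponentiation; $\ln(1 - e^{-\mu})$ switches between `log(-expm1(-mu))`
and `log1p(-exp(-mu))` at $\mu = \ln 2$. Truncated-Poisson log-likelihood
curvature uses series expansions below $\mu = 10^{-6}$.

## Known limitations

* The MCMC replaces the INLA-style nested Laplace approximation that is
  commonly used for these models; posterior targets are identical but
  reported SDs carry Monte Carlo error.
* $\varphi$ estimates on small or weakly connected graphs are prior-driven
  (as expected; the constant-risk scenario is the designed illustration).
* CPO uses the harmonic-mean estimator, which has high variance when the
  posterior is diffuse; WAIC/PSIS-LOO are deliberately out of scope.
* Disconnected graphs are supported (per-component scaling and
  constraints), but isolated single regions are rejected rather than
  modeled.
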