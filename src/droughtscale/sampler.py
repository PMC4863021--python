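"""Gibbs-within-Metropolis sampler for the hierarchical beta regression.

Each sweep cycles three blocks, mirroring the fitting algorithm:

1. Metropolis–Hastings random-walk updates of the per-observation latent
   mean (on the logit scale) and dispersion (on the log scale);
2. Gibbs draws from the exact normal/gamma full conditionals of the linear
   hierarchy — regression coefficients, wetland random effects, precisions;
3. Metropolis–Hastings random-walk updates of the three discrete
   timescales (era-specific SPEI timescales on the 1–120 grid, shared SPI
   timescale on 1–3), with edge-reflected symmetric integer proposals.

Auxiliary moves are interleaved for mixing: global Metropolis "ridge"
moves coupling the latent fields (see :func:`mh_update_global`) and
partially collapsed updates of the random-effect precisions (see
:func:`update_effect_precision_collapsed`); each targets the same
posterior.

Multiple chains with overdispersed starts are run with independent seeded
generators; draws are recorded after burn-in at a fixed thinning interval
and convergence is checked with the Gelman–Rubin potential scale reduction
factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .exceptions import InvalidInputError
from .model import (
    ModelData,
    ModelState,
    Priors,
    build_design_matrix,
    beta_logpdf,
)

logger = logging.getLogger(__name__)

#: guard against numerically degenerate latents (expit saturates near ±37)
LATENT_BOUND = 30.0

#: column order of the scalar draw matrix
SCALAR_NAMES = (
    "beta_intercept", "beta_era", "beta_spei", "beta_spi",
    "beta_spei_era", "beta_spei_spi", "beta_spei_spi_era",
    "beta_phi",
    "tau_gamma", "tau_delta", "tau_epsilon", "tau_zeta",
    "t_spei_hist", "t_spei_cont", "t_spi",
)

TIMESCALE_NAMES = ("t_spei_hist", "t_spei_cont", "t_spi")


@dataclass
class SamplerConfig:
    """Run-length and proposal settings.

    Defaults follow the full analysis protocol (3 chains, 10,000 burn-in,
    100,000 kept iterations thinned to every 100th); reduced-scale studies
    override them. ``update_*`` flags freeze individual blocks, which the
    verification suite uses to isolate conditionals.
    """

    n_chains: int = 3
    burn_in: int = 10_000
    iterations: int = 100_000
    thin: int = 100
    step_l: float = 0.3            # logit-scale RW step for latent mean
    step_m: float = 0.3            # log-scale RW step for latent dispersion
    window_spei: int = 12          # half-width of SPEI timescale proposal window
    window_spi: int = 1
    init_jitter_sd: float = 0.5    # overdispersion of chain starts
    adapt: bool = False            # burn-in-only step adaptation toward 0.44
    update_latent: bool = True
    update_linear: bool = True
    update_precisions: bool = True
    update_timescales: bool = True

    def __post_init__(self):
        if min(self.n_chains, self.thin) < 1 or self.burn_in < 0 or self.iterations < 0:
            raise InvalidInputError("chain counts, thinning and iterations must be positive")
        if self.step_l <= 0 or self.step_m <= 0:
            raise InvalidInputError("step sizes must be > 0")
        if self.window_spei < 1 or self.window_spi < 1:
            raise InvalidInputError("proposal windows must be >= 1")


def _beta_loglik_latent(y, log_y, log_1my, l, m):
    """Per-observation beta log density in the latent parameterization.

    Exploits a + b = phi to skip one gammaln call; -inf outside the latent
    guard bound so extreme proposals are rejected.
    """
    mu = expit(l)
    phi = np.exp(m)
    a = mu * phi
    b = phi - a
    out = gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1.0) * log_y + (b - 1.0) * log_1my
    bad = (np.abs(l) > LATENT_BOUND) | (np.abs(m) > LATENT_BOUND)
    if bad.any():
        out = np.where(bad, -np.inf, out)
    return out


def mh_update_latent_mu(state, mdata, X, rng, step, lp_beta=None):
    """Random-walk M-H update of every latent logit-mean l_ij (in place).

    Target per observation: beta likelihood × Normal(l | x'beta + gamma,
    1/tau_delta). Returns (acceptance fraction, updated cached beta
    log-likelihood vector).
    """
    log_y = np.log(mdata.y)
    log_1my = np.log1p(-mdata.y)
    if lp_beta is None:
        lp_beta = _beta_loglik_latent(mdata.y, log_y, log_1my, state.l, state.m)
    pred = X @ state.beta_mu + state.gamma[mdata.wetland_idx]
    l_prop = state.l + step * rng.standard_normal(mdata.n_obs)
    lp_prop = _beta_loglik_latent(mdata.y, log_y, log_1my, l_prop, state.m)
    delta = (
        lp_prop - lp_beta
        - 0.5 * state.tau_delta * ((l_prop - pred) ** 2 - (state.l - pred) ** 2)
    )
    accept = np.log(rng.random(mdata.n_obs)) < delta
    state.l = np.where(accept, l_prop, state.l)
    lp_beta = np.where(accept, lp_prop, lp_beta)
    return float(accept.mean()), lp_beta


def mh_update_latent_phi(state, mdata, rng, step, lp_beta=None):
    """Random-walk M-H update of every latent log-dispersion m_ij (in place).

    Mirror of :func:`mh_update_latent_mu` on the log scale with prior
    Normal(m | beta_phi + eps, 1/tau_zeta).
    """
    log_y = np.log(mdata.y)
    log_1my = np.log1p(-mdata.y)
    if lp_beta is None:
        lp_beta = _beta_loglik_latent(mdata.y, log_y, log_1my, state.l, state.m)
    pred = state.beta_phi + state.epsilon[mdata.wetland_idx]
    m_prop = state.m + step * rng.standard_normal(mdata.n_obs)
    lp_prop = _beta_loglik_latent(mdata.y, log_y, log_1my, state.l, m_prop)
    delta = (
        lp_prop - lp_beta
        - 0.5 * state.tau_zeta * ((m_prop - pred) ** 2 - (state.m - pred) ** 2)
    )
    accept = np.log(rng.random(mdata.n_obs)) < delta
    state.m = np.where(accept, m_prop, state.m)
    lp_beta = np.where(accept, lp_prop, lp_beta)
    return float(accept.mean()), lp_beta


def gibbs_update_linear(state, mdata, X, priors, rng, random_effects=True):
    """Exact Gibbs draws of beta_mu, gamma, beta_phi, epsilon (in place).

    Given the latents, both sides are conjugate normal-linear models:
    beta_mu | . is multivariate normal with precision
    (tau_delta X'X + P0) and each gamma_i | . normal with precision
    (tau_gamma + n_i tau_delta); beta_phi and epsilon mirror them on the
    log-dispersion scale with (tau_zeta, tau_epsilon).
    """
    widx = mdata.wetland_idx
    n_i = np.bincount(widx, minlength=mdata.n_wetlands).astype(float)

    # mean-side coefficients
    resp = state.l - state.gamma[widx]
    prec = state.tau_delta * (X.T @ X) + np.diag(priors.beta_precision)
    rhs = state.tau_delta * (X.T @ resp) + priors.beta_precision * priors.beta_mean
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    state.beta_mu = mean + np.linalg.solve(chol.T, rng.standard_normal(7))

    if random_effects:
        # wetland mean effects
        resid = state.l - X @ state.beta_mu
        prec_g = state.tau_gamma + n_i * state.tau_delta
        mean_g = state.tau_delta * np.bincount(widx, weights=resid, minlength=mdata.n_wetlands) / prec_g
        state.gamma = mean_g + rng.standard_normal(mdata.n_wetlands) / np.sqrt(prec_g)

    # dispersion intercept
    resp_m = state.m - state.epsilon[widx]
    prec_p = priors.phi_precision + mdata.n_obs * state.tau_zeta
    mean_p = (state.tau_zeta * resp_m.sum() + priors.phi_precision * priors.phi_mean) / prec_p
    state.beta_phi = mean_p + rng.standard_normal() / np.sqrt(prec_p)

    if random_effects:
        # wetland dispersion effects
        resid_m = state.m - state.beta_phi
        prec_e = state.tau_epsilon + n_i * state.tau_zeta
        mean_e = state.tau_zeta * np.bincount(widx, weights=resid_m, minlength=mdata.n_wetlands) / prec_e
        state.epsilon = mean_e + rng.standard_normal(mdata.n_wetlands) / np.sqrt(prec_e)


def gibbs_update_precisions(state, mdata, X, priors, rng):
    """Exact gamma full-conditional draws of the four precisions (in place).

    tau_gamma ~ Gamma(a + I/2, b + sum gamma^2 / 2) and analogously for
    tau_delta (residuals), tau_epsilon, tau_zeta; rate parameterization.
    """
    a, b = priors.tau_shape, priors.tau_rate
    I, N = mdata.n_wetlands, mdata.n_obs
    delta = state.delta(X, mdata)
    zeta = state.zeta(mdata)
    state.tau_gamma = rng.gamma(a + I / 2.0, 1.0 / (b + 0.5 * np.sum(state.gamma ** 2)))
    state.tau_delta = rng.gamma(a + N / 2.0, 1.0 / (b + 0.5 * np.sum(delta ** 2)))
    state.tau_epsilon = rng.gamma(a + I / 2.0, 1.0 / (b + 0.5 * np.sum(state.epsilon ** 2)))
    state.tau_zeta = rng.gamma(a + N / 2.0, 1.0 / (b + 0.5 * np.sum(zeta ** 2)))


def mh_update_global(state, mdata, X, priors, rng, step=0.1, lp_beta=None):
    """Global ridge moves coupling the latent fields (in place).

    The centered parameterization mixes slowly along the trade-off between
    observation-level beta noise (phi) and logit-scale residual noise
    (delta): single-site random walks must move thousands of latents
    coherently. Three joint Metropolis moves traverse that ridge directly,
    each a valid M-H step on the same posterior:

    * shift — add one normal increment to every m_ij and to beta_phi
      (residuals zeta unchanged; only the beta likelihood and the flat
      beta_phi prior move);
    * scale-delta — rescale every mean residual, l' = pred + c (l − pred)
      with log c normal; Jacobian c^N enters the acceptance ratio;
    * scale-zeta — the analogous rescaling of the dispersion residuals;
    * scale-gamma / scale-epsilon — rescale the wetland random-effect
      vectors with the latents held fixed (the residuals absorb the
      change), traversing the random-effect-variance trade-off without
      touching the beta likelihood.

    Returns (acceptance flags, updated cached beta log-likelihood).
    """
    log_y = np.log(mdata.y)
    log_1my = np.log1p(-mdata.y)
    if lp_beta is None:
        lp_beta = _beta_loglik_latent(mdata.y, log_y, log_1my, state.l, state.m)
    acc = {}
    n = mdata.n_obs

    # dispersion shift
    eps = step * rng.standard_normal()
    m_new = state.m + eps
    lp_new = _beta_loglik_latent(mdata.y, log_y, log_1my, state.l, m_new)
    d_prior = -0.5 * priors.phi_precision * (
        (state.beta_phi + eps - priors.phi_mean) ** 2
        - (state.beta_phi - priors.phi_mean) ** 2
    )
    delta_lp = np.sum(lp_new) - np.sum(lp_beta) + d_prior
    if np.log(rng.random()) < delta_lp:
        state.m = m_new
        state.beta_phi += eps
        lp_beta = lp_new
        acc["shift"] = True
    else:
        acc["shift"] = False

    # mean-residual rescale
    c = np.exp(step * rng.standard_normal())
    pred = X @ state.beta_mu + state.gamma[mdata.wetland_idx]
    resid = state.l - pred
    l_new = pred + c * resid
    lp_new = _beta_loglik_latent(mdata.y, log_y, log_1my, l_new, state.m)
    delta_lp = (
        np.sum(lp_new) - np.sum(lp_beta)
        - 0.5 * state.tau_delta * (c ** 2 - 1.0) * np.sum(resid ** 2)
        + n * np.log(c)
    )
    if np.log(rng.random()) < delta_lp:
        state.l = l_new
        lp_beta = lp_new
        acc["scale_delta"] = True
    else:
        acc["scale_delta"] = False

    # dispersion-residual rescale
    c = np.exp(step * rng.standard_normal())
    pred_m = state.beta_phi + state.epsilon[mdata.wetland_idx]
    resid_m = state.m - pred_m
    m_new = pred_m + c * resid_m
    lp_new = _beta_loglik_latent(mdata.y, log_y, log_1my, state.l, m_new)
    delta_lp = (
        np.sum(lp_new) - np.sum(lp_beta)
        - 0.5 * state.tau_zeta * (c ** 2 - 1.0) * np.sum(resid_m ** 2)
        + n * np.log(c)
    )
    if np.log(rng.random()) < delta_lp:
        state.m = m_new
        lp_beta = lp_new
        acc["scale_zeta"] = True
    else:
        acc["scale_zeta"] = False

    # random-effect rescales: latents fixed, so only normal terms move
    widx = mdata.wetland_idx
    n_w = mdata.n_wetlands
    for name, eff, tau_eff, pred_fixed, tau_resid in (
        ("scale_gamma", state.gamma, state.tau_gamma,
         X @ state.beta_mu, state.tau_delta),
        ("scale_epsilon", state.epsilon, state.tau_epsilon,
         np.full(n, state.beta_phi), state.tau_zeta),
    ):
        c = np.exp(step * rng.standard_normal())
        latent = state.l if name == "scale_gamma" else state.m
        resid_cur = latent - pred_fixed - eff[widx]
        resid_new = latent - pred_fixed - c * eff[widx]
        delta_lp = (
            -0.5 * tau_resid * (np.sum(resid_new ** 2) - np.sum(resid_cur ** 2))
            - 0.5 * tau_eff * (c ** 2 - 1.0) * np.sum(eff ** 2)
            + n_w * np.log(c)
        )
        if np.log(rng.random()) < delta_lp:
            if name == "scale_gamma":
                state.gamma = c * eff
            else:
                state.epsilon = c * eff
            acc[name] = True
        else:
            acc[name] = False
    return acc, lp_beta


def update_effect_precision_collapsed(state, mdata, X, priors, rng, step=0.6):
    """Blocked update of (tau_gamma, gamma) and (tau_epsilon, epsilon).

    The plain Gibbs pair self-traps: once a random-effect vector shrinks to
    ~0 its precision explodes, which pins the vector at 0. This update
    samples each precision by M-H from its conditional with the effect
    vector integrated out analytically (per wetland, the residual mean is
    normal with variance 1/(n_i tau_resid) + 1/tau_effect), then redraws
    the effect vector from its exact conditional — a partially collapsed
    Gibbs step targeting the same posterior.
    """
    widx = mdata.wetland_idx
    n_i = np.bincount(widx, minlength=mdata.n_wetlands).astype(float)
    a, b = priors.tau_shape, priors.tau_rate

    def collapsed_logpost(tau_eff, r_mean, tau_resid):
        v = 1.0 / (n_i * tau_resid) + 1.0 / tau_eff
        return float(
            -0.5 * np.sum(np.log(v) + r_mean ** 2 / v)
            + a * np.log(tau_eff) - b * tau_eff
        )

    for which in ("gamma", "epsilon"):
        if which == "gamma":
            resid = state.l - X @ state.beta_mu
            tau_resid, tau_eff = state.tau_delta, state.tau_gamma
        else:
            resid = state.m - state.beta_phi
            tau_resid, tau_eff = state.tau_zeta, state.tau_epsilon
        r_mean = np.bincount(widx, weights=resid, minlength=mdata.n_wetlands) / n_i
        prop = float(np.exp(np.log(tau_eff) + step * rng.standard_normal()))
        # log-normal random walk: the Jacobian contributes log(prop/cur)
        delta_lp = (
            collapsed_logpost(prop, r_mean, tau_resid)
            - collapsed_logpost(tau_eff, r_mean, tau_resid)
            + np.log(prop) - np.log(tau_eff)
        )
        if np.log(rng.random()) < delta_lp:
            tau_eff = prop
        # exact conditional redraw of the effect vector
        prec = tau_eff + n_i * tau_resid
        mean = tau_resid * n_i * r_mean / prec
        draw = mean + rng.standard_normal(mdata.n_wetlands) / np.sqrt(prec)
        if which == "gamma":
            state.tau_gamma = tau_eff
            state.gamma = draw
        else:
            state.tau_epsilon = tau_eff
            state.epsilon = draw


def propose_reflected(t: int, lo: int, hi: int, window: int, rng) -> int:
    """Symmetric integer random-walk proposal reflected at half-integer
    grid edges (lo−0.5 and hi+0.5), preserving proposal symmetry."""
    d = 0
    while d == 0:
        d = int(rng.integers(-window, window + 1))
    t_new = t + d
    while t_new < lo or t_new > hi:
        if t_new < lo:
            t_new = 2 * lo - 1 - t_new
        if t_new > hi:
            t_new = 2 * hi + 1 - t_new
    return t_new


def mh_update_timescales(state, mdata, X, priors, rng,
                         window_spei: int = 12, window_spi: int = 1):
    """M-H updates of t_spei_hist, t_spei_cont, t_spi in turn (in place).

    Changing a timescale only moves the latent-mean normal term: with the
    residuals recomputed against the proposed design matrix, the
    acceptance ratio is exp(-tau_delta/2 * (SS_new − SS_cur)) times the
    (unit, uniform-prior) prior ratio. Returns (current design matrix,
    acceptance flags by parameter).
    """
    widx = mdata.wetland_idx
    accepts = {}

    def ss(Xm):
        r = state.l - Xm @ state.beta_mu - state.gamma[widx]
        return np.sum(r ** 2)

    ss_cur = ss(X)
    lo_spei, hi_spei = min(mdata.spei_scales), max(mdata.spei_scales)
    lo_spi, hi_spi = min(mdata.spi_scales), max(mdata.spi_scales)
    for name in TIMESCALE_NAMES:
        if name == "t_spi":
            cur = state.t_spi
            prop = propose_reflected(cur, lo_spi, hi_spi, window_spi, rng)
            cand = (state.t_hist, state.t_cont, prop)
        elif name == "t_spei_hist":
            cur = state.t_hist
            prop = propose_reflected(cur, lo_spei, hi_spei, window_spei, rng)
            cand = (prop, state.t_cont, state.t_spi)
        else:
            cur = state.t_cont
            prop = propose_reflected(cur, lo_spei, hi_spei, window_spei, rng)
            cand = (state.t_hist, prop, state.t_spi)
        X_new = build_design_matrix(mdata, *cand)
        ss_new = ss(X_new)
        delta = -0.5 * state.tau_delta * (ss_new - ss_cur)
        if np.log(rng.random()) < delta:
            state.t_hist, state.t_cont, state.t_spi = cand
            X, ss_cur = X_new, ss_new
            accepts[name] = True
        else:
            accepts[name] = False
    return X, accepts


def initialize_state(mdata: ModelData, priors: Priors, config: SamplerConfig, rng) -> ModelState:
    """Overdispersed chain start.

    Timescales start at their grid midpoints; beta_mu comes from ordinary
    least squares of logit(y) on the midpoint design plus seed-specific
    jitter; random effects start at zero, the latent means at the data
    (l = logit y, so the residual precision's first update sees realistic
    residuals), the latent dispersions at a moment estimate, and
    precisions at 1.
    """
    t_mid = mdata.spei_scales[len(mdata.spei_scales) // 2]
    t_spi_mid = mdata.spi_scales[len(mdata.spi_scales) // 2]
    X = build_design_matrix(mdata, t_mid, t_mid, t_spi_mid)
    # winsorize for the OLS start and latent init: under small dispersion
    # the beta tail reaches y ~ 1e-300, where logit(y) is numerically wild
    ly = np.clip(logit(mdata.y), -12.0, 12.0)
    beta, *_ = np.linalg.lstsq(X, ly, rcond=None)
    beta = beta + config.init_jitter_sd * rng.standard_normal(7)
    mu_hat = expit(np.clip(X @ beta, -LATENT_BOUND + 1, LATENT_BOUND - 1))
    v = max(np.var(mdata.y - mu_hat), 1e-4)
    mbar = float(np.mean(mu_hat))
    phi0 = max(mbar * (1 - mbar) / v - 1.0, 2.0)
    beta_phi = np.log(phi0) + config.init_jitter_sd * rng.standard_normal()
    state = ModelState(
        beta_mu=beta,
        beta_phi=float(beta_phi),
        gamma=np.zeros(mdata.n_wetlands),
        epsilon=np.zeros(mdata.n_wetlands),
        l=ly,
        m=np.full(mdata.n_obs, beta_phi),
        tau_gamma=1.0, tau_delta=1.0, tau_epsilon=1.0, tau_zeta=1.0,
        t_hist=t_mid, t_cont=t_mid, t_spi=t_spi_mid,
    )
    lp = np.sum(beta_logpdf(mdata.y, state.mu(), state.phi()))
    if not np.isfinite(lp):
        raise InvalidInputError("non-finite beta likelihood at initialization (latent l/m)")
    return state


def _record(state: ModelState) -> np.ndarray:
    return np.concatenate([
        state.beta_mu,
        [state.beta_phi, state.tau_gamma, state.tau_delta,
         state.tau_epsilon, state.tau_zeta,
         state.t_hist, state.t_cont, state.t_spi],
    ])


def run_chain(mdata: ModelData, priors: Priors, config: SamplerConfig, seed) -> dict:
    """Run one chain; deterministic given the seed.

    Returns a dict with ``scalars`` (n_draws × len(SCALAR_NAMES)),
    ``gamma``/``epsilon`` (n_draws × I) and per-block acceptance rates.
    """
    rng = np.random.default_rng(seed)
    state = initialize_state(mdata, priors, config, rng)
    X = build_design_matrix(mdata, state.t_hist, state.t_cont, state.t_spi)
    n_draws = config.iterations // config.thin
    scalars = np.empty((n_draws, len(SCALAR_NAMES)))
    gamma_draws = np.empty((n_draws, mdata.n_wetlands))
    eps_draws = np.empty((n_draws, mdata.n_wetlands))
    lp_beta = None
    acc = {"latent_mu": 0.0, "latent_phi": 0.0, "global": 0.0,
           "t_spei_hist": 0, "t_spei_cont": 0, "t_spi": 0}
    step_l, step_m = config.step_l, config.step_m
    n_sweeps = config.burn_in + config.iterations
    acc_window = {"mu": [], "phi": []}
    out_idx = 0
    for sweep in range(n_sweeps):
        if config.update_latent:
            a_mu, lp_beta = mh_update_latent_mu(state, mdata, X, rng, step_l, lp_beta)
            a_phi, lp_beta = mh_update_latent_phi(state, mdata, rng, step_m, lp_beta)
            acc["latent_mu"] += a_mu
            acc["latent_phi"] += a_phi
            if config.adapt and sweep < config.burn_in:
                acc_window["mu"].append(a_mu)
                acc_window["phi"].append(a_phi)
                if len(acc_window["mu"]) == 100:
                    step_l *= float(np.exp(np.mean(acc_window["mu"]) - 0.44))
                    step_m *= float(np.exp(np.mean(acc_window["phi"]) - 0.44))
                    acc_window = {"mu": [], "phi": []}
            g_acc, lp_beta = mh_update_global(state, mdata, X, priors, rng,
                                              lp_beta=lp_beta)
            acc["global"] += np.mean(list(g_acc.values()))
        if config.update_linear:
            gibbs_update_linear(state, mdata, X, priors, rng)
        if config.update_precisions:
            gibbs_update_precisions(state, mdata, X, priors, rng)
            if config.update_linear:
                update_effect_precision_collapsed(state, mdata, X, priors, rng)
        if config.update_timescales:
            X, t_acc = mh_update_timescales(
                state, mdata, X, priors, rng, config.window_spei, config.window_spi
            )
            for k, v in t_acc.items():
                acc[k] += int(v)
        post = sweep - config.burn_in
        if post >= 0 and (post + 1) % config.thin == 0 and out_idx < n_draws:
            scalars[out_idx] = _record(state)
            gamma_draws[out_idx] = state.gamma
            eps_draws[out_idx] = state.epsilon
            out_idx += 1
    rates = {k: v / max(n_sweeps, 1) for k, v in acc.items()}
    logger.info("chain seed=%s acceptance rates: %s", seed,
                {k: round(v, 3) for k, v in rates.items()})
    return {
        "scalars": scalars[:out_idx],
        "gamma": gamma_draws[:out_idx],
        "epsilon": eps_draws[:out_idx],
        "acceptance": rates,
        "final_steps": (step_l, step_m),
    }


@dataclass
class PosteriorSamples:
    """Thinned multi-chain draws.

    ``scalars[c, d, p]`` indexes chain c, draw d, parameter
    ``SCALAR_NAMES[p]``; wetland random effects are stored alongside for
    conditional prediction.
    """

    scalars: np.ndarray            # (C, D, P)
    gamma: np.ndarray              # (C, D, I)
    epsilon: np.ndarray            # (C, D, I)
    wetland_ids: list
    acceptance: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.scalars.shape[0]

    @property
    def n_draws(self) -> int:
        return self.scalars.shape[1]

    def chains(self, name: str) -> np.ndarray:
        """Per-chain draw matrix (C, D) of one scalar parameter."""
        return self.scalars[:, :, SCALAR_NAMES.index(name)]

    def combined(self, name: str) -> np.ndarray:
        """Chains pooled into one flat draw vector."""
        return self.chains(name).reshape(-1)

    def combined_effects(self, which: str) -> np.ndarray:
        arr = self.gamma if which == "gamma" else self.epsilon
        return arr.reshape(-1, arr.shape[2])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.scalars[c], columns=list(SCALAR_NAMES))
            df.insert(0, "iteration", np.arange(1, self.n_draws + 1))
            df.insert(0, "chain", c + 1)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def run_chains(mdata: ModelData, priors: Priors, config: SamplerConfig, seed: int) -> PosteriorSamples:
    """Run ``config.n_chains`` chains with independent generators spawned
    from one seed; deterministic given (seed, config)."""
    seqs = np.random.SeedSequence(seed).spawn(config.n_chains)
    results = [run_chain(mdata, priors, config, s) for s in seqs]
    return PosteriorSamples(
        scalars=np.stack([r["scalars"] for r in results]),
        gamma=np.stack([r["gamma"] for r in results]),
        epsilon=np.stack([r["epsilon"] for r in results]),
        wetland_ids=list(mdata.wetland_ids),
        acceptance=[r["acceptance"] for r in results],
    )


def gelman_rubin_array(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor for one parameter.

    ``chains`` is (n_chains, n_draws). With B the between-chain and W the
    within-chain variance, returns sqrt(((n−1)/n · W + B/n) / W); identical
    chains give B = 0 and hence a value ≤ 1.
    """
    c, n = chains.shape
    if c < 2:
        raise InvalidInputError("Gelman-Rubin requires at least 2 chains")
    if n < 10:
        raise InvalidInputError("Gelman-Rubin requires at least 10 draws per chain")
    means = chains.mean(axis=1)
    w = float(np.mean(chains.var(axis=1, ddof=1)))
    b = n * float(np.var(means, ddof=1))
    if w == 0.0:
        return 1.0
    v_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(v_hat / w))


def gelman_rubin(samples: PosteriorSamples) -> pd.Series:
    """R-hat per parameter (timescales included via their numeric values)."""
    vals = {name: gelman_rubin_array(samples.chains(name)) for name in SCALAR_NAMES}
    return pd.Series(vals, name="rhat")
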