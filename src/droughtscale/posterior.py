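"""Posterior summaries and derived quantities.

Covers the downstream analysis of a fitted model: parameter summary tables
(mean, SE, 95% quantile interval), posterior-predictive R² in marginal
(fixed-effects-only) and conditional (with estimated wetland effects)
modes, the posterior-weighted climate index (every candidate timescale's
index averaged with its posterior probability), era-by-region comparisons
of that index, and population-level predictions of the proportion of a
basin covered with water, with credible bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .climate import IndexBank
from .exceptions import InvalidInputError
from .model import ModelData, build_design_matrix
from .sampler import SCALAR_NAMES, PosteriorSamples


def summarize(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-parameter posterior mean, SE (posterior SD) and 2.5%/97.5%
    quantiles, chains pooled."""
    if samples.n_draws == 0:
        raise InvalidInputError("cannot summarize empty posterior samples")
    rows = []
    for name in SCALAR_NAMES:
        draws = samples.combined(name)
        rows.append({
            "parameter": name,
            "mean": float(np.mean(draws)),
            "se": float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
            "q2.5": float(np.quantile(draws, 0.025)),
            "q97.5": float(np.quantile(draws, 0.975)),
        })
    return pd.DataFrame(rows)


def _draw_table(samples: PosteriorSamples):
    """Pooled draws as (n_total, P) plus pooled random-effect matrices."""
    P = samples.scalars.shape[2]
    return (
        samples.scalars.reshape(-1, P),
        samples.combined_effects("gamma"),
        samples.combined_effects("epsilon"),
    )


def predictive_r2(
    samples: PosteriorSamples,
    mdata: ModelData,
    mode: str,
    seed: int = 0,
    max_draws: int | None = 200,
) -> float:
    """Posterior-predictive coefficient of determination.

    For each stored draw, a replicate dataset y* is simulated from the beta
    likelihood and the squared Pearson correlation between y* and the
    observations is averaged over draws. ``marginal`` redraws the wetland
    effects from their precision-implied normals (fixed effects only);
    ``conditional`` keeps the stored wetland effects. Residual terms are
    redrawn from their precisions in both modes.
    """
    if mode not in ("marginal", "conditional"):
        raise InvalidInputError(f"mode must be 'marginal' or 'conditional', got {mode!r}")
    scalars, gammas, epsilons = _draw_table(samples)
    n_total = scalars.shape[0]
    if n_total == 0:
        raise InvalidInputError("empty posterior samples")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_total)
    if max_draws is not None and n_total > max_draws:
        idx = rng.choice(n_total, size=max_draws, replace=False)
    widx = mdata.wetland_idx
    name_pos = {n: p for p, n in enumerate(SCALAR_NAMES)}
    r2s = []
    for d in idx:
        row = scalars[d]
        beta = row[:7]
        beta_phi = row[name_pos["beta_phi"]]
        tau_g, tau_d = row[name_pos["tau_gamma"]], row[name_pos["tau_delta"]]
        tau_e, tau_z = row[name_pos["tau_epsilon"]], row[name_pos["tau_zeta"]]
        X = build_design_matrix(
            mdata,
            int(row[name_pos["t_spei_hist"]]),
            int(row[name_pos["t_spei_cont"]]),
            int(row[name_pos["t_spi"]]),
        )
        if mode == "marginal":
            g = rng.standard_normal(mdata.n_wetlands) / np.sqrt(tau_g)
            e = rng.standard_normal(mdata.n_wetlands) / np.sqrt(tau_e)
        else:
            g, e = gammas[d], epsilons[d]
        delta = rng.standard_normal(mdata.n_obs) / np.sqrt(tau_d)
        zeta = rng.standard_normal(mdata.n_obs) / np.sqrt(tau_z)
        mu = expit(X @ beta + g[widx] + delta)
        phi = np.exp(beta_phi + e[widx] + zeta)
        y_sim = rng.beta(mu * phi, (1.0 - mu) * phi)
        r = np.corrcoef(y_sim, mdata.y)[0, 1]
        r2s.append(0.0 if not np.isfinite(r) else r * r)
    return float(np.mean(r2s))


@dataclass
class WeightedIndexSeries:
    """Posterior-weighted SPEI: every candidate timescale's index summed
    with its posterior weight, per site-month."""

    frame: pd.DataFrame            # columns site_id, year, month, value (NaN = undefined)
    weights: pd.Series             # indexed by timescale, sums to 1


def weighted_index(bank: IndexBank, t_draws) -> WeightedIndexSeries:
    """Weight each SPEI column by the posterior relative frequency of its
    timescale in ``t_draws`` and sum.

    A month's weighted value is defined only where every positively
    weighted column is defined; earlier months are NaN.
    """
    t_draws = np.asarray(t_draws).astype(int)
    if t_draws.size == 0:
        raise InvalidInputError("no timescale draws supplied")
    bad = ~np.isin(t_draws, bank.spei_scales)
    if bad.any():
        raise InvalidInputError(f"draws outside timescale grid: {np.unique(t_draws[bad])}")
    scales = np.asarray(bank.spei_scales)
    counts = np.array([(t_draws == k).sum() for k in scales], dtype=float)
    w = counts / counts.sum()
    pos = np.flatnonzero(w > 0)
    frames = []
    for site_id, tbl in bank.sites.items():
        cols = tbl.spei[:, pos]
        defined = np.all(np.isfinite(cols), axis=1)
        vals = np.full(len(tbl.years), np.nan)
        vals[defined] = cols[defined] @ w[pos]
        frames.append(pd.DataFrame({
            "site_id": site_id, "year": tbl.years, "month": tbl.months, "value": vals,
        }))
    return WeightedIndexSeries(
        frame=pd.concat(frames, ignore_index=True),
        weights=pd.Series(w, index=scales, name="weight"),
    )


def compare_index_by_group(
    weighted: WeightedIndexSeries,
    site_region: dict,
    hist_max_year: int = 1969,
    cont_min_year: int = 2003,
    month: int | None = None,
) -> pd.DataFrame:
    """Mean weighted index per era × region cell with normal 95% intervals.

    Eras are defined by year cutoffs (historical ≤ ``hist_max_year``,
    contemporary ≥ ``cont_min_year``); sites map to regions through
    ``site_region``. Restricting to one calendar ``month`` mirrors using
    the observation month.
    """
    df = weighted.frame.dropna(subset=["value"]).copy()
    if month is not None:
        df = df[df["month"] == month]
    unknown = set(df["site_id"]) - set(site_region)
    if unknown:
        raise InvalidInputError(f"sites without a region label: {sorted(unknown)}")
    df["region"] = df["site_id"].map(site_region)
    df["era"] = np.where(
        df["year"] <= hist_max_year, 0, np.where(df["year"] >= cont_min_year, 1, -1)
    )
    df = df[df["era"] >= 0]
    rows = []
    for region in sorted(set(site_region.values())):
        for era in (0, 1):
            cell = df[(df["region"] == region) & (df["era"] == era)]["value"]
            if cell.empty:
                raise InvalidInputError(f"empty era×region cell: era={era}, region={region!r}")
            mean = float(cell.mean())
            se = float(cell.std(ddof=1) / np.sqrt(len(cell))) if len(cell) > 1 else 0.0
            rows.append({
                "region": region, "era": era, "n": len(cell), "mean": mean,
                "lo95": mean - 1.96 * se, "hi95": mean + 1.96 * se,
            })
    return pd.DataFrame(rows)


def predict_proportion(
    samples: PosteriorSamples,
    index_by_year: pd.DataFrame,
    era: int,
    spi_value: float = 0.0,
    integrate_random_effects: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Population-level predicted proportion of basin covered with water.

    ``index_by_year`` has columns year, value (the posterior-weighted SPEI
    for the era being predicted). SPI is held fixed (by default at 0, its
    reference mean). For each year and each stored draw the mean response
    mu = inverse-logit(x'beta) is evaluated with random effects at zero —
    or, when ``integrate_random_effects``, with wetland and residual terms
    redrawn from their precisions — and summarized by the pointwise mean
    and 2.5%/97.5% quantiles.
    """
    if era not in (0, 1):
        raise InvalidInputError(f"era must be 0 or 1, got {era}")
    scalars, _, _ = _draw_table(samples)
    if scalars.shape[0] == 0:
        raise InvalidInputError("empty posterior samples")
    name_pos = {n: p for p, n in enumerate(SCALAR_NAMES)}
    betas = scalars[:, :7]
    rng = np.random.default_rng(seed)
    rows = []
    for _, (year, value) in index_by_year[["year", "value"]].iterrows():
        if not np.isfinite(value):
            continue
        x = np.array([
            1.0, era, value, spi_value,
            value * era, value * spi_value, value * spi_value * era,
        ])
        eta = betas @ x
        if integrate_random_effects:
            tau_g = scalars[:, name_pos["tau_gamma"]]
            tau_d = scalars[:, name_pos["tau_delta"]]
            eta = eta + rng.standard_normal(len(eta)) / np.sqrt(tau_g)
            eta = eta + rng.standard_normal(len(eta)) / np.sqrt(tau_d)
        mu = expit(eta)
        rows.append({
            "year": int(year), "mean": float(np.mean(mu)),
            "q2.5": float(np.quantile(mu, 0.025)),
            "q97.5": float(np.quantile(mu, 0.975)),
        })
    return pd.DataFrame(rows)
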