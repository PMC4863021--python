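"""Standardized drought indices at candidate timescales.

This module turns monthly site climate (precipitation, min/max temperature)
into a bank of standardized drought indices:

* SPEI — the z-score of the k-month sum of the climatic water balance
  D = precipitation − potential evapotranspiration, standardized per
  calendar month through a three-parameter log-logistic distribution fitted
  by unbiased probability-weighted moments (PWM);
* SPI — the z-score of the k-month precipitation sum, standardized per
  calendar month through a two-parameter gamma distribution (maximum
  likelihood) with a point mass at zero.

Potential evapotranspiration uses the temperature-based Hargreaves
equation with FAO-56 extraterrestrial radiation. The bank holds one column
per candidate timescale (by default 1–120 months for SPEI, 1–3 for SPI) so
that a sampler can treat the timescale itself as an unknown parameter and
look covariate values up by (site, year, month, timescale).
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gamma as gamma_fn

from .exceptions import FittingError, InvalidInputError

logger = logging.getLogger(__name__)

#: z-scores are clipped to this magnitude for numerical safety; it is far
#: outside the range any 117-year monthly record can produce.
Z_CLIP = 6.0

#: minimum number of reference values per calendar month for a fit
MIN_REFERENCE_VALUES = 20

SPEI_SCALES_DEFAULT = tuple(range(1, 121))
SPI_SCALES_DEFAULT = tuple(range(1, 4))

CLIMATE_COLUMNS = ["site_id", "year", "month", "precip_mm", "tmin_c", "tmax_c", "latitude"]

# FAO-56 constants
_SOLAR_CONSTANT = 0.0820       # MJ m-2 min-1
_MJ_TO_MM = 0.408              # evaporation equivalent of 1 MJ m-2 day-1


@lru_cache(maxsize=4096)
def mean_extraterrestrial_radiation(latitude: float, year: int, month: int) -> float:
    """Month-mean daily extraterrestrial radiation Ra in mm/day equivalent.

    Averages the FAO-56 daily Ra over the actual (leap-aware) days of the
    month at the given latitude.
    """
    if not -90.0 <= latitude <= 90.0:
        raise InvalidInputError(f"latitude {latitude} outside [-90, 90]")
    ndays = calendar.monthrange(year, month)[1]
    first = sum(calendar.monthrange(year, m)[1] for m in range(1, month)) + 1
    j = np.arange(first, first + ndays)          # day of year
    phi = np.deg2rad(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    dec = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    x = np.clip(-np.tan(phi) * np.tan(dec), -1.0, 1.0)
    ws = np.arccos(x)
    ra = (24.0 * 60.0 / np.pi) * _SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.sin(ws)
    )
    return float(np.mean(ra)) * _MJ_TO_MM


def hargreaves_pet(tmin: float, tmax: float, latitude: float, year: int, month: int) -> float:
    """Monthly potential evapotranspiration (mm) from the Hargreaves equation.

    PET_daily = 0.0023 * Ra * (Tmean + 17.8) * sqrt(Tmax - Tmin), with Ra the
    month-mean extraterrestrial radiation in mm/day and Tmean = (Tmin+Tmax)/2,
    scaled by the number of days in the month. A nonpositive (Tmean + 17.8)
    (deep winter cold) is clamped to zero PET with a warning.
    """
    if tmax < tmin:
        raise InvalidInputError(f"tmax ({tmax}) < tmin ({tmin})")
    if abs(latitude) >= 66.5:
        raise InvalidInputError(f"latitude {latitude} within polar circles is unsupported")
    ra = mean_extraterrestrial_radiation(float(latitude), int(year), int(month))
    tmean = 0.5 * (tmin + tmax)
    factor = tmean + 17.8
    if factor < 0.0:
        logger.warning(
            "Hargreaves: Tmean + 17.8 = %.2f < 0 for %d-%02d; PET clamped to 0",
            factor, year, month,
        )
        return 0.0
    ndays = calendar.monthrange(int(year), int(month))[1]
    return 0.0023 * ra * factor * np.sqrt(tmax - tmin) * ndays


def validate_climate(climate: pd.DataFrame) -> pd.DataFrame:
    """Check schema and gap-free monthly ordering; return sorted copy."""
    missing = [c for c in CLIMATE_COLUMNS if c not in climate.columns]
    if missing:
        raise InvalidInputError(f"climate table missing columns: {missing}")
    out = climate.sort_values(["site_id", "year", "month"]).reset_index(drop=True)
    if (out["tmax_c"] < out["tmin_c"]).any():
        bad = out.loc[out["tmax_c"] < out["tmin_c"], ["site_id", "year", "month"]]
        raise InvalidInputError(f"tmax < tmin at rows:\n{bad.head()}")
    if (out["precip_mm"] < 0).any():
        raise InvalidInputError("negative precipitation values present")
    for site, grp in out.groupby("site_id", sort=False):
        seq = grp["year"].to_numpy() * 12 + grp["month"].to_numpy() - 1
        gaps = np.flatnonzero(np.diff(seq) != 1)
        if gaps.size:
            miss = [
                f"{(seq[g] + d) // 12}-{(seq[g] + d) % 12 + 1:02d}"
                for g in gaps[:5]
                for d in range(1, int(seq[g + 1] - seq[g]))
            ]
            raise InvalidInputError(f"site {site!r}: gaps in monthly series, missing {miss[:12]}")
    return out


def water_balance(climate: pd.DataFrame) -> pd.DataFrame:
    """Monthly climatic water balance D = precipitation − Hargreaves PET.

    Returns a frame with columns site_id, year, month, pet_mm, d_mm in the
    same (sorted, gap-free) ordering as the validated input.
    """
    clim = validate_climate(climate)
    pet = np.array([
        hargreaves_pet(r.tmin_c, r.tmax_c, r.latitude, r.year, r.month)
        for r in clim.itertuples()
    ])
    out = clim[["site_id", "year", "month"]].copy()
    out["pet_mm"] = pet
    out["d_mm"] = clim["precip_mm"].to_numpy() - pet
    return out


def aggregate_uniform(values: np.ndarray, k: int) -> np.ndarray:
    """Backward-looking k-month rectangular sum.

    Output at position m is the unweighted sum of values[m-k+1 .. m]; the
    first k−1 positions, where the window is incomplete, are NaN.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if not 1 <= k <= n:
        raise InvalidInputError(f"timescale k={k} outside [1, {n}]")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out = np.full(n, np.nan)
    out[k - 1:] = csum[k:] - csum[:n - k + 1]
    return out


def _pwm(x: np.ndarray) -> tuple[float, float, float]:
    """First three unbiased probability-weighted moments w_s = E[X (1-F)^s].

    Ascending order statistics x_(1..n) enter w_s with weight
    C(n-i, s) / C(n-1, s), the unbiased estimator of the (1-F)-weighted
    moment used by the log-logistic drought-index recipe.
    """
    x = np.sort(x)
    n = x.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    w0 = x.mean()
    w1 = np.sum((n - i) / (n - 1) * x) / n
    w2 = np.sum((n - i) * (n - i - 1) / ((n - 1) * (n - 2)) * x) / n
    return w0, w1, w2


def fit_loglogistic_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Fit a three-parameter log-logistic by unbiased PWMs.

    Returns (alpha, beta, gamma) = (scale, shape, location) such that
    F(v) = [1 + (alpha / (v − gamma))**beta]**(-1).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise FittingError("need at least 3 values for a PWM fit")
    if np.ptp(x) == 0.0:
        raise FittingError("degenerate (constant) values; log-logistic fit undefined")
    b0, b1, b2 = _pwm(x)
    denom = 6.0 * b1 - b0 - 6.0 * b2
    if denom == 0.0:
        raise FittingError("PWM combination degenerate; cannot solve for shape")
    beta = (2.0 * b1 - b0) / denom
    if beta <= 1.0:
        raise FittingError(f"log-logistic shape {beta:.3f} <= 1; moments undefined")
    g1g2 = gamma_fn(1.0 + 1.0 / beta) * gamma_fn(1.0 - 1.0 / beta)
    alpha = (b0 - 2.0 * b1) * beta / g1g2
    if alpha <= 0.0:
        raise FittingError(f"log-logistic scale {alpha:.3f} <= 0")
    gamma = b0 - alpha * g1g2
    return alpha, beta, gamma


def loglogistic_cdf(x: np.ndarray, alpha: float, beta: float, gamma: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > gamma
    out[pos] = 1.0 / (1.0 + (alpha / (x[pos] - gamma)) ** beta)
    return out


def _to_z(prob: np.ndarray) -> np.ndarray:
    lo, hi = stats.norm.cdf(-Z_CLIP), stats.norm.cdf(Z_CLIP)
    return stats.norm.ppf(np.clip(prob, lo, hi))


def standardize_loglogistic(
    aggregated: np.ndarray,
    months: np.ndarray,
    reference_mask: np.ndarray | None = None,
) -> np.ndarray:
    """SPEI standardization of an aggregated water-balance series.

    For each calendar month separately, a three-parameter log-logistic is
    fitted by unbiased PWMs to the defined reference-period values; every
    defined value is mapped to its cumulative probability and then to a
    standard-normal quantile (clipped to ±6). NaN entries (incomplete
    aggregation windows) stay NaN.
    """
    aggregated = np.asarray(aggregated, dtype=float)
    months = np.asarray(months)
    if reference_mask is None:
        reference_mask = np.ones_like(aggregated, dtype=bool)
    z = np.full_like(aggregated, np.nan)
    defined = np.isfinite(aggregated)
    for cm in np.unique(months):
        sel = defined & (months == cm)
        if not sel.any():
            continue
        ref = aggregated[sel & reference_mask]
        if ref.shape[0] < MIN_REFERENCE_VALUES:
            raise FittingError(
                f"calendar month {cm}: only {ref.shape[0]} reference values "
                f"(need >= {MIN_REFERENCE_VALUES})"
            )
        if np.ptp(ref) == 0.0:
            raise FittingError(f"calendar month {cm}: constant reference values")
        # The log-logistic is right-skewed (shape = 1/L-skewness must
        # exceed 1); months whose aggregated values are left-skewed are
        # standardized through the mirrored sample, flipping z back.
        w0, w1, w2 = _pwm(ref)
        tau3 = (w0 - 6.0 * w1 + 6.0 * w2) / (w0 - 2.0 * w1)
        if abs(tau3) < 1e-12:
            raise FittingError(f"calendar month {cm}: zero L-skewness, fit degenerate")
        if tau3 < 0:
            alpha, beta, gamma = fit_loglogistic_pwm(-ref)
            prob = 1.0 - loglogistic_cdf(-aggregated[sel], alpha, beta, gamma)
        else:
            alpha, beta, gamma = fit_loglogistic_pwm(ref)
            prob = loglogistic_cdf(aggregated[sel], alpha, beta, gamma)
        z[sel] = _to_z(prob)
    return z


def standardize_gamma(
    aggregated: np.ndarray,
    months: np.ndarray,
    reference_mask: np.ndarray | None = None,
) -> np.ndarray:
    """SPI standardization of aggregated precipitation.

    Per calendar month: a two-parameter gamma is fitted by maximum
    likelihood to the positive reference values; zeros contribute a point
    mass q = (#zeros / n) so that H(x) = q + (1−q)·G(x), mapped to a
    standard-normal quantile.
    """
    aggregated = np.asarray(aggregated, dtype=float)
    months = np.asarray(months)
    if np.nanmin(aggregated) < 0:
        raise InvalidInputError("aggregated precipitation must be nonnegative")
    if reference_mask is None:
        reference_mask = np.ones_like(aggregated, dtype=bool)
    z = np.full_like(aggregated, np.nan)
    defined = np.isfinite(aggregated)
    for cm in np.unique(months):
        sel = defined & (months == cm)
        if not sel.any():
            continue
        ref = aggregated[sel & reference_mask]
        if ref.shape[0] < MIN_REFERENCE_VALUES:
            raise FittingError(
                f"calendar month {cm}: only {ref.shape[0]} reference values "
                f"(need >= {MIN_REFERENCE_VALUES})"
            )
        pos = ref[ref > 0]
        if pos.shape[0] == 0:
            raise FittingError(f"calendar month {cm}: all reference values are zero")
        if np.ptp(pos) == 0.0 and pos.shape[0] > 1:
            raise FittingError(f"calendar month {cm}: constant positive reference values")
        q = 1.0 - pos.shape[0] / ref.shape[0]
        shape, _, scale = stats.gamma.fit(pos, floc=0.0)
        x = aggregated[sel]
        h = np.where(x > 0, q + (1.0 - q) * stats.gamma.cdf(x, shape, scale=scale), q)
        z[sel] = _to_z(h)
    return z


@dataclass
class SiteIndexTable:
    """Per-site block of the index bank (aligned month rows)."""

    years: np.ndarray
    months: np.ndarray
    spei: np.ndarray          # (n_months, n_spei_scales), NaN where undefined
    spi: np.ndarray           # (n_months, n_spi_scales)
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._pos = {
            (int(y), int(m)): i
            for i, (y, m) in enumerate(zip(self.years, self.months))
        }

    def row(self, year: int, month: int) -> int:
        key = (int(year), int(month))
        if key not in self._pos:
            raise InvalidInputError(f"no bank entry for {year}-{month:02d}")
        return self._pos[key]


@dataclass
class IndexBank:
    """Precomputed SPEI/SPI values for every candidate timescale.

    ``sites[site_id]`` holds a :class:`SiteIndexTable`; column ``j`` of its
    ``spei`` matrix is the SPEI at timescale ``spei_scales[j]`` (likewise
    for SPI). Entries inside the first k−1 months of the record, where a
    k-month window is incomplete, are NaN.
    """

    sites: dict
    spei_scales: tuple
    spi_scales: tuple
    reference_period: tuple

    def spei_value(self, site_id, year: int, month: int, k: int) -> float:
        tbl = self._site(site_id)
        v = tbl.spei[tbl.row(year, month), self.spei_scales.index(k)]
        if not np.isfinite(v):
            raise InvalidInputError(
                f"SPEI undefined at site {site_id!r} {year}-{month:02d} timescale {k}"
            )
        return float(v)

    def spi_value(self, site_id, year: int, month: int, k: int) -> float:
        tbl = self._site(site_id)
        v = tbl.spi[tbl.row(year, month), self.spi_scales.index(k)]
        if not np.isfinite(v):
            raise InvalidInputError(
                f"SPI undefined at site {site_id!r} {year}-{month:02d} timescale {k}"
            )
        return float(v)

    def _site(self, site_id) -> SiteIndexTable:
        if site_id not in self.sites:
            raise InvalidInputError(f"site {site_id!r} not in index bank")
        return self.sites[site_id]

    def to_frame(self) -> pd.DataFrame:
        """Long-to-wide export: one row per site-month, NaN for undefined."""
        frames = []
        for site_id, tbl in self.sites.items():
            df = pd.DataFrame({"site_id": site_id, "year": tbl.years, "month": tbl.months})
            for j, k in enumerate(self.spei_scales):
                df[f"spei_k{k:03d}"] = tbl.spei[:, j]
            for j, k in enumerate(self.spi_scales):
                df[f"spi_k{k}"] = tbl.spi[:, j]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def required_years(max_scale: int) -> int:
    """Minimum whole years so the largest timescale has enough reference
    values for every calendar month."""
    return int(np.ceil(max_scale / 12.0)) + MIN_REFERENCE_VALUES


def build_index_bank(
    climate: pd.DataFrame,
    spei_scales=SPEI_SCALES_DEFAULT,
    spi_scales=SPI_SCALES_DEFAULT,
    reference_period: tuple | None = None,
) -> IndexBank:
    """Compute the full candidate-index bank for every site.

    ``reference_period`` is an inclusive (start_year, end_year) range used
    for distribution fitting; by default the full record is the reference,
    so every index column has per-calendar-month mean ≈ 0 and SD ≈ 1 over
    the whole series.
    """
    spei_scales = tuple(int(k) for k in spei_scales)
    spi_scales = tuple(int(k) for k in spi_scales)
    wb = water_balance(climate)
    clim = validate_climate(climate)
    max_scale = max(spei_scales + spi_scales)
    sites = {}
    for site_id, grp in wb.groupby("site_id", sort=False):
        years = grp["year"].to_numpy()
        months = grp["month"].to_numpy()
        n_years = len(np.unique(years))
        if n_years < required_years(max_scale):
            raise InvalidInputError(
                f"site {site_id!r}: {n_years} years of record; timescale "
                f"{max_scale} needs at least {required_years(max_scale)}"
            )
        if reference_period is None:
            ref_mask = np.ones(len(grp), dtype=bool)
            ref_years = (int(years.min()), int(years.max()))
        else:
            ref_mask = (years >= reference_period[0]) & (years <= reference_period[1])
            ref_years = (int(reference_period[0]), int(reference_period[1]))
        d = grp["d_mm"].to_numpy()
        p = clim.loc[clim["site_id"] == site_id, "precip_mm"].to_numpy()
        spei = np.column_stack([
            standardize_loglogistic(aggregate_uniform(d, k), months, ref_mask)
            for k in spei_scales
        ])
        spi = np.column_stack([
            standardize_gamma(aggregate_uniform(p, k), months, ref_mask)
            for k in spi_scales
        ])
        sites[site_id] = SiteIndexTable(years=years, months=months, spei=spei, spi=spi)
    return IndexBank(
        sites=sites,
        spei_scales=spei_scales,
        spi_scales=spi_scales,
        reference_period=ref_years,
    )
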