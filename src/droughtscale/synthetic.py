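"""Seeded synthetic climate and wetland observations with known truth.

The generator emulates the study system — northern-prairie monthly climate
(1895–2011 by default) and repeated proportion-full observations of
closed-basin wetlands in a historical (pre-1970) and a contemporary
(post-2003) era — from the same hierarchical beta-regression model the
sampler fits, with every generating parameter recorded. Default parameter
values (e.g. beta_spei = 0.68, historical SPEI timescale 84 months,
contemporary 64 months) are realistic study-scale magnitudes, so recovery
experiments run under realistic signal-to-noise.

Climate is site-level: monthly precipitation from a per-calendar-month
gamma distribution with an optional dry-month zero probability, and
min/max temperature from seasonal sinusoids plus AR(1) noise with the
diurnal range kept positive. Spatial correlation between sites is not
modelled.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .climate import IndexBank, required_years
from .exceptions import InvalidInputError
from .model import build_design_matrix, prepare_model_data

# Seasonal shape loosely matching North Dakota PRISM climatology:
# wet early summer, dry cold winter.
PRECIP_MEAN_MM = (12.0, 11.0, 22.0, 35.0, 60.0, 85.0, 70.0, 55.0, 45.0, 30.0, 15.0, 12.0)
PRECIP_SHAPE = (1.6, 1.6, 1.8, 2.0, 2.5, 3.0, 2.8, 2.5, 2.2, 2.0, 1.8, 1.6)
PRECIP_ZERO_PROB = (0.06, 0.06, 0.02, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.01, 0.04, 0.06)

TMEAN_ANNUAL_C = 4.5          # annual mean temperature
TMEAN_AMPLITUDE_C = 16.0      # seasonal half-range
DIURNAL_RANGE_C = 12.0        # mean tmax - tmin
TEMP_NOISE_SD = 2.0
TEMP_NOISE_AR1 = 0.6
RANGE_NOISE_SD = 1.0
MIN_DIURNAL_RANGE = 0.5


@dataclass
class GeneratingTruth:
    """All generating parameters: the model state scalars plus climate
    settings. Defaults are realistic study-scale magnitudes."""

    beta_mu: np.ndarray = field(
        default_factory=lambda: np.array([-0.62, 0.65, 0.68, -0.02, -0.32, 0.0, 0.0])
    )
    beta_phi: float = 3.65
    tau_gamma: float = 19.7
    tau_delta: float = 0.51
    tau_epsilon: float = 0.20
    tau_zeta: float = 0.51
    t_hist: int = 84
    t_cont: int = 64
    t_spi: int = 2
    n_sites: int = 20
    year_start: int = 1895
    year_end: int = 2011
    latitude: float = 47.0

    def __post_init__(self):
        self.beta_mu = np.asarray(self.beta_mu, dtype=float)
        if self.beta_mu.shape != (7,):
            raise InvalidInputError("beta_mu must have length 7")
        for name in ("tau_gamma", "tau_delta", "tau_epsilon", "tau_zeta"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_mu"] = [float(v) for v in self.beta_mu]
        return d


def simulate_climate(truth: GeneratingTruth, seed: int,
                     max_timescale: int | None = None) -> pd.DataFrame:
    """Monthly site climate, deterministic given the seed.

    When ``max_timescale`` is given, the year span is checked to cover that
    largest candidate timescale plus enough reference years for the
    per-calendar-month fits.
    """
    n_years = truth.year_end - truth.year_start + 1
    if max_timescale is not None and n_years < required_years(max_timescale):
        raise InvalidInputError(
            f"{n_years} years of climate is too short; timescale {max_timescale} "
            f"needs at least {required_years(max_timescale)} years"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(truth.n_sites):
        site_id = f"site{s + 1:02d}"
        lat = truth.latitude + 0.2 * (s - truth.n_sites / 2.0)
        noise = 0.0
        for year in range(truth.year_start, truth.year_end + 1):
            for month in range(1, 13):
                cm = month - 1
                if rng.random() < PRECIP_ZERO_PROB[cm]:
                    precip = 0.0
                else:
                    shape = PRECIP_SHAPE[cm]
                    precip = rng.gamma(shape, PRECIP_MEAN_MM[cm] / shape)
                season = TMEAN_ANNUAL_C - TMEAN_AMPLITUDE_C * np.cos(
                    2.0 * np.pi * (month - 1) / 12.0
                )
                noise = TEMP_NOISE_AR1 * noise + np.sqrt(
                    1.0 - TEMP_NOISE_AR1 ** 2
                ) * TEMP_NOISE_SD * rng.standard_normal()
                tmean = season + noise
                half_range = 0.5 * max(
                    DIURNAL_RANGE_C + RANGE_NOISE_SD * rng.standard_normal(),
                    MIN_DIURNAL_RANGE,
                )
                rows.append((site_id, year, month, precip,
                             tmean - half_range, tmean + half_range, lat))
    return pd.DataFrame(
        rows, columns=["site_id", "year", "month", "precip_mm", "tmin_c", "tmax_c", "latitude"]
    )


def era_year_windows(
    truth: GeneratingTruth, years_per_era=None
) -> tuple[list[int], list[int]]:
    """Observation years per era.

    By default mirrors the study design: a 32-year historical window ending
    in 1969 and a 7-year contemporary window starting in 2003. An integer
    gives symmetric windows; a (hist, cont) pair sets each explicitly.
    """
    if years_per_era is None:
        hist_n, cont_n = 32, 7
    elif np.isscalar(years_per_era):
        hist_n = cont_n = int(years_per_era)
    else:
        hist_n, cont_n = (int(v) for v in years_per_era)
    hist = list(range(1970 - hist_n, 1970))
    cont = list(range(2003, 2003 + cont_n))
    if hist[0] < truth.year_start or cont[-1] > truth.year_end:
        raise InvalidInputError(
            f"era windows {hist[0]}-{hist[-1]} / {cont[0]}-{cont[-1]} exceed the "
            f"climate record {truth.year_start}-{truth.year_end}"
        )
    return hist, cont


def simulate_observations(
    truth: GeneratingTruth,
    bank: IndexBank,
    n_wetlands: int = 147,
    years_per_era=None,
    month: int = 8,
    seed: int = 0,
    basin_range_ha: tuple = (0.5, 750.0),
    return_latents: bool = False,
):
    """Simulate the wetland observation table from the generative model.

    Wetlands are assigned round-robin to the bank's sites; for every
    wetland-year, the design row is built at the TRUE timescales, random
    effects and residuals are drawn from their precision-implied normals,
    and y comes from the beta likelihood. Returns (observation frame with
    area/basin columns, generating-truth record for recovery scoring).
    """
    rng = np.random.default_rng(seed)
    hist_years, cont_years = era_year_windows(truth, years_per_era)
    site_ids = list(bank.sites)
    wetland_ids = [f"w{i + 1:03d}" for i in range(n_wetlands)]
    wet_site = {w: site_ids[i % len(site_ids)] for i, w in enumerate(wetland_ids)}
    basins = np.exp(rng.uniform(np.log(basin_range_ha[0]), np.log(basin_range_ha[1]),
                                n_wetlands))
    gamma = rng.standard_normal(n_wetlands) / np.sqrt(truth.tau_gamma)
    epsilon = rng.standard_normal(n_wetlands) / np.sqrt(truth.tau_epsilon)

    skeleton = []
    for i, w in enumerate(wetland_ids):
        for era, years in ((0, hist_years), (1, cont_years)):
            for year in years:
                skeleton.append((w, wet_site[w], year, era, basins[i]))
    obs = pd.DataFrame(skeleton,
                       columns=["wetland_id", "site_id", "year", "era", "basin_ha"])
    # placeholder areas let prepare_model_data assemble the covariate bank rows
    obs["area_ha"] = obs["basin_ha"] * 0.5
    mdata = prepare_model_data(obs, bank, month=month)
    X = build_design_matrix(mdata, truth.t_hist, truth.t_cont, truth.t_spi)
    widx = mdata.wetland_idx
    delta = rng.standard_normal(mdata.n_obs) / np.sqrt(truth.tau_delta)
    zeta = rng.standard_normal(mdata.n_obs) / np.sqrt(truth.tau_zeta)
    mu = expit(X @ truth.beta_mu + gamma[widx] + delta)
    phi = np.exp(truth.beta_phi + epsilon[widx] + zeta)
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    obs = obs.copy()
    obs["area_ha"] = y * obs["basin_ha"].to_numpy()
    obs = obs[["wetland_id", "site_id", "year", "era", "area_ha", "basin_ha"]]
    truth_record = truth.to_dict()
    truth_record.update({
        "n_wetlands": n_wetlands,
        "hist_years": [hist_years[0], hist_years[-1]],
        "cont_years": [cont_years[0], cont_years[-1]],
        "month": month,
        "seed": int(seed),
        "gamma_sd_realized": float(np.std(gamma)),
    })
    if return_latents:
        latents = {"mu": mu, "phi": phi, "gamma": gamma, "epsilon": epsilon,
                   "delta": delta, "zeta": zeta, "y": y}
        return obs, truth_record, latents
    return obs, truth_record
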