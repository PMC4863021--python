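"""Hierarchical beta-regression model for wetland proportion-full data.

The response y_ij (observed water surface area of wetland i in year j as a
proportion of its basin area, clamped strictly inside (0,1)) is modelled as

    y_ij ~ Beta(mu_ij * phi_ij, (1 - mu_ij) * phi_ij)

with a logit model for the mean and a log model for the dispersion:

    logit(mu_ij) = x_ij' beta_mu + gamma_i + delta_ij
    log(phi_ij)  = beta_phi       + eps_i   + zeta_ij

gamma_i / eps_i are wetland random effects and delta_ij / zeta_ij residual
errors, all mean-zero normal with precisions tau_gamma, tau_delta,
tau_epsilon, tau_zeta. The design row x_ij contains an intercept, an era
indicator (0 historical, 1 contemporary), SPEI, SPI, SPEI×era, SPEI×SPI and
SPEI×SPI×era — where the SPEI covariate is read from the index bank at an
*era-specific* timescale (t_hist or t_cont, 1..120 months) and SPI at a
shared timescale t_spi (1..3 months). The three timescales are unknown
discrete parameters with uniform priors over their grids.

This module holds the probability model as pure functions — densities,
design-matrix construction, the unnormalized log posterior — consumed by
the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .climate import IndexBank
from .exceptions import InvalidInputError

#: the fixed column order of the mean-model design matrix
DESIGN_COLUMNS = (
    "intercept",
    "era",
    "spei",
    "spi",
    "spei_era",
    "spei_spi",
    "spei_spi_era",
)

CLAMP_HI = 0.99999
CLAMP_LO = 1.0 - CLAMP_HI

OBSERVATION_COLUMNS = ["wetland_id", "site_id", "year", "era", "area_ha", "basin_ha"]


def clamp_proportion(area_ha: float, basin_ha: float) -> float:
    """Proportion of basin covered with water, clamped into (0, 1).

    Digitization error can make the raw ratio exceed 1, and dry basins give
    0; those are recoded to 0.99999 and 0.00001 so the beta likelihood is
    defined.
    """
    if basin_ha <= 0:
        raise InvalidInputError(f"basin_ha must be positive, got {basin_ha}")
    r = area_ha / basin_ha
    if r >= 1.0:
        return CLAMP_HI
    if r <= 0.0:
        return CLAMP_LO
    return r


def clamp_dataset(obs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Add the clamped response column ``y``; return (frame, #clamped)."""
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise InvalidInputError(f"observation table missing columns: {missing}")
    if not obs["era"].isin([0, 1]).all():
        raise InvalidInputError("era must be 0 (historical) or 1 (contemporary)")
    out = obs.copy()
    out["y"] = [clamp_proportion(a, b) for a, b in zip(out["area_ha"], out["basin_ha"])]
    raw = out["area_ha"].to_numpy() / out["basin_ha"].to_numpy()
    n_clamped = int(np.sum((raw >= 1.0) | (raw <= 0.0)))
    return out, n_clamped


def beta_logpdf(y, mu, phi):
    """Log density of Beta(mu*phi, (1-mu)*phi) at y, vectorized.

    All arguments must be strictly interior (y, mu in (0,1), phi > 0);
    boundary responses must be clamped upstream.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise InvalidInputError("y must lie strictly inside (0, 1); clamp first")
    if np.any(mu <= 0) or np.any(mu >= 1) or np.any(phi <= 0):
        raise InvalidInputError("require mu in (0,1) and phi > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        gammaln(a + b) - gammaln(a) - gammaln(b)
        + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y)
    )


def normal_logpdf_prec(x, mean, prec):
    """Normal log density parameterized by precision (inverse variance)."""
    x = np.asarray(x, dtype=float)
    return 0.5 * (np.log(prec) - np.log(2.0 * np.pi)) - 0.5 * prec * (x - mean) ** 2


@dataclass
class Priors:
    """Hyperparameters: diffuse normals on regression coefficients, diffuse
    gammas on precisions, uniform categorical over each timescale grid."""

    beta_mean: np.ndarray = field(default_factory=lambda: np.zeros(7))
    beta_precision: np.ndarray = field(default_factory=lambda: np.full(7, 1e-6))
    phi_mean: float = 0.0
    phi_precision: float = 1e-6
    tau_shape: float = 0.001
    tau_rate: float = 0.001

    def __post_init__(self):
        self.beta_mean = np.asarray(self.beta_mean, dtype=float)
        self.beta_precision = np.asarray(self.beta_precision, dtype=float)
        if self.beta_mean.shape != (7,) or self.beta_precision.shape != (7,):
            raise InvalidInputError("beta prior vectors must have length 7")
        if (
            np.any(self.beta_precision <= 0)
            or self.phi_precision <= 0
            or self.tau_shape <= 0
            or self.tau_rate <= 0
        ):
            raise InvalidInputError("prior precisions and gamma hyperparameters must be > 0")


@dataclass
class ModelData:
    """Observations joined to the index bank, laid out for fast sampling.

    ``spei_all[n, j]`` is the SPEI covariate of observation n at timescale
    ``spei_scales[j]`` (and likewise ``spi_all``), so rebuilding the design
    matrix for a proposed timescale is pure indexing.
    """

    y: np.ndarray                  # (N,) clamped response
    era: np.ndarray                # (N,) 0/1
    wetland_idx: np.ndarray        # (N,) 0..I-1
    wetland_ids: list              # (I,)
    year: np.ndarray               # (N,)
    spei_all: np.ndarray           # (N, n_spei_scales)
    spi_all: np.ndarray            # (N, n_spi_scales)
    spei_scales: tuple
    spi_scales: tuple

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_wetlands(self) -> int:
        return len(self.wetland_ids)


def prepare_model_data(obs: pd.DataFrame, bank: IndexBank, month: int = 8) -> ModelData:
    """Join clamped observations to the index bank at (year, ``month``).

    The photography month within each observation year is a configuration
    choice (default August). Any observation whose index is undefined at
    some candidate timescale is rejected with an explicit error rather
    than imputed.
    """
    obs_c, _ = clamp_dataset(obs)
    wetland_ids = sorted(obs_c["wetland_id"].unique().tolist())
    wmap = {w: i for i, w in enumerate(wetland_ids)}
    n = len(obs_c)
    spei_all = np.empty((n, len(bank.spei_scales)))
    spi_all = np.empty((n, len(bank.spi_scales)))
    for pos, r in enumerate(obs_c.itertuples()):
        tbl = bank._site(r.site_id)
        row = tbl.row(int(r.year), month)
        spei_all[pos] = tbl.spei[row]
        spi_all[pos] = tbl.spi[row]
        if not np.all(np.isfinite(spei_all[pos])) or not np.all(np.isfinite(spi_all[pos])):
            raise InvalidInputError(
                f"wetland {r.wetland_id!r} year {r.year}: index undefined at some "
                f"candidate timescale for month {month}"
            )
    return ModelData(
        y=obs_c["y"].to_numpy(),
        era=obs_c["era"].to_numpy().astype(int),
        wetland_idx=np.array([wmap[w] for w in obs_c["wetland_id"]]),
        wetland_ids=wetland_ids,
        year=obs_c["year"].to_numpy().astype(int),
        spei_all=spei_all,
        spi_all=spi_all,
        spei_scales=bank.spei_scales,
        spi_scales=bank.spi_scales,
    )


def build_design_matrix(
    mdata: ModelData, t_hist: int, t_cont: int, t_spi: int
) -> np.ndarray:
    """The 7-column design matrix at the given timescales.

    Historical rows (era 0) read SPEI at t_hist, contemporary rows at
    t_cont; SPI uses the shared t_spi. All interaction columns inherit the
    era-specific SPEI value.
    """
    jh = mdata.spei_scales.index(int(t_hist))
    jc = mdata.spei_scales.index(int(t_cont))
    js = mdata.spi_scales.index(int(t_spi))
    era = mdata.era.astype(float)
    spei = np.where(mdata.era == 0, mdata.spei_all[:, jh], mdata.spei_all[:, jc])
    spi = mdata.spi_all[:, js]
    return np.column_stack([
        np.ones(mdata.n_obs),
        era,
        spei,
        spi,
        spei * era,
        spei * spi,
        spei * spi * era,
    ])


@dataclass
class ModelState:
    """One complete draw of all unknowns.

    The per-observation latents are stored as ``l = logit(mu)`` and
    ``m = log(phi)``; the residuals delta and zeta are implicit
    (delta = l − X·beta_mu − gamma, zeta = m − beta_phi − eps).
    """

    beta_mu: np.ndarray            # (7,)
    beta_phi: float
    gamma: np.ndarray              # (I,)
    epsilon: np.ndarray            # (I,)
    l: np.ndarray                  # (N,) logit(mu)
    m: np.ndarray                  # (N,) log(phi)
    tau_gamma: float
    tau_delta: float
    tau_epsilon: float
    tau_zeta: float
    t_hist: int
    t_cont: int
    t_spi: int

    def copy(self) -> "ModelState":
        return ModelState(
            beta_mu=self.beta_mu.copy(), beta_phi=self.beta_phi,
            gamma=self.gamma.copy(), epsilon=self.epsilon.copy(),
            l=self.l.copy(), m=self.m.copy(),
            tau_gamma=self.tau_gamma, tau_delta=self.tau_delta,
            tau_epsilon=self.tau_epsilon, tau_zeta=self.tau_zeta,
            t_hist=self.t_hist, t_cont=self.t_cont, t_spi=self.t_spi,
        )

    def validate(self, mdata: ModelData) -> None:
        for name in ("tau_gamma", "tau_delta", "tau_epsilon", "tau_zeta"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.t_hist not in mdata.spei_scales or self.t_cont not in mdata.spei_scales:
            raise InvalidInputError("SPEI timescale outside grid")
        if self.t_spi not in mdata.spi_scales:
            raise InvalidInputError("SPI timescale outside grid")
        if not (np.all(np.isfinite(self.l)) and np.all(np.isfinite(self.m))):
            raise InvalidInputError("latent l/m must be finite")

    def mu(self) -> np.ndarray:
        return expit(self.l)

    def phi(self) -> np.ndarray:
        return np.exp(self.m)

    def delta(self, X: np.ndarray, mdata: ModelData) -> np.ndarray:
        return self.l - X @ self.beta_mu - self.gamma[mdata.wetland_idx]

    def zeta(self, mdata: ModelData) -> np.ndarray:
        return self.m - self.beta_phi - self.epsilon[mdata.wetland_idx]


def gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def log_joint(state: ModelState, mdata: ModelData, priors: Priors) -> float:
    """Unnormalized log posterior density (likelihood × priors).

    Sum of the beta log-likelihood, the normal densities of the implicit
    residuals and random effects at their precisions, the normal priors on
    the regression coefficients, the gamma priors on the precisions, and
    the (constant) uniform log prior mass of the three timescales.
    """
    state.validate(mdata)
    X = build_design_matrix(mdata, state.t_hist, state.t_cont, state.t_spi)
    out = float(np.sum(beta_logpdf(mdata.y, state.mu(), state.phi())))
    out += float(np.sum(normal_logpdf_prec(state.delta(X, mdata), 0.0, state.tau_delta)))
    out += float(np.sum(normal_logpdf_prec(state.zeta(mdata), 0.0, state.tau_zeta)))
    out += float(np.sum(normal_logpdf_prec(state.gamma, 0.0, state.tau_gamma)))
    out += float(np.sum(normal_logpdf_prec(state.epsilon, 0.0, state.tau_epsilon)))
    out += float(np.sum(normal_logpdf_prec(state.beta_mu, priors.beta_mean, priors.beta_precision)))
    out += float(normal_logpdf_prec(state.beta_phi, priors.phi_mean, priors.phi_precision))
    for tau in (state.tau_gamma, state.tau_delta, state.tau_epsilon, state.tau_zeta):
        out += gamma_logpdf(tau, priors.tau_shape, priors.tau_rate)
    out += -2.0 * np.log(len(mdata.spei_scales)) - np.log(len(mdata.spi_scales))
    return out


__all__ = [
    "DESIGN_COLUMNS", "CLAMP_HI", "CLAMP_LO", "OBSERVATION_COLUMNS",
    "clamp_proportion", "clamp_dataset", "beta_logpdf", "normal_logpdf_prec",
    "Priors", "ModelData", "prepare_model_data", "build_design_matrix",
    "ModelState", "log_joint", "logit", "expit",
]
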