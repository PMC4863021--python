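"""Plain-text readers and writers for every pipeline artifact.

All files are comma-delimited text with ``NA`` as the missing marker:
climate series, wetland observation tables, the precomputed index bank,
posterior draw files (scalars wide, random effects long) and summary
tables. Writers and readers round-trip: reading a written file restores
the in-memory object.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .climate import CLIMATE_COLUMNS, IndexBank, SiteIndexTable
from .exceptions import InvalidInputError
from .model import OBSERVATION_COLUMNS
from .sampler import SCALAR_NAMES, PosteriorSamples, SamplerConfig

NA = "NA"


def read_climate(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA])
    missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing climate columns {missing}")
    return df


def write_climate(df: pd.DataFrame, path) -> None:
    df[CLIMATE_COLUMNS].to_csv(path, index=False, na_rep=NA)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA])
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing observation columns {missing}")
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    df[OBSERVATION_COLUMNS].to_csv(path, index=False, na_rep=NA)


def write_bank(bank: IndexBank, path) -> None:
    df = bank.to_frame()
    df.attrs = {}
    header = f"# reference_period={bank.reference_period[0]}-{bank.reference_period[1]}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, na_rep=NA, float_format="%.6f")


def read_bank(path) -> IndexBank:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# reference_period="):
            raise InvalidInputError(f"{path}: missing reference-period header")
        ref = tuple(int(v) for v in first.strip().split("=")[1].split("-"))
        df = pd.read_csv(fh, na_values=[NA])
    spei_scales = tuple(
        int(c.split("spei_k")[1]) for c in df.columns if c.startswith("spei_k")
    )
    spi_scales = tuple(
        int(c.split("spi_k")[1]) for c in df.columns if c.startswith("spi_k")
    )
    sites = {}
    for site_id, grp in df.groupby("site_id", sort=False):
        sites[site_id] = SiteIndexTable(
            years=grp["year"].to_numpy(),
            months=grp["month"].to_numpy(),
            spei=grp[[f"spei_k{k:03d}" for k in spei_scales]].to_numpy(),
            spi=grp[[f"spi_k{k}" for k in spi_scales]].to_numpy(),
        )
    return IndexBank(sites=sites, spei_scales=spei_scales, spi_scales=spi_scales,
                     reference_period=ref)


def write_draws(samples: PosteriorSamples, scalar_path, effects_path=None) -> None:
    samples.to_frame().to_csv(scalar_path, index=False, na_rep=NA)
    if effects_path is not None:
        rows = []
        for c in range(samples.n_chains):
            for which, arr in (("gamma", samples.gamma), ("epsilon", samples.epsilon)):
                df = pd.DataFrame(arr[c], columns=samples.wetland_ids)
                df.insert(0, "iteration", np.arange(1, samples.n_draws + 1))
                df.insert(0, "effect", which)
                df.insert(0, "chain", c + 1)
                rows.append(df.melt(
                    id_vars=["chain", "effect", "iteration"],
                    var_name="wetland_id", value_name="value",
                ))
        pd.concat(rows, ignore_index=True).to_csv(effects_path, index=False, na_rep=NA)


def read_draws(scalar_path, effects_path=None) -> PosteriorSamples:
    df = pd.read_csv(scalar_path, na_values=[NA])
    chains = sorted(df["chain"].unique())
    scalars = np.stack([
        df[df["chain"] == c].sort_values("iteration")[list(SCALAR_NAMES)].to_numpy()
        for c in chains
    ])
    n_draws = scalars.shape[1]
    if effects_path is not None:
        eff = pd.read_csv(effects_path, na_values=[NA])
        wetland_ids = sorted(eff["wetland_id"].unique())
        gamma = np.empty((len(chains), n_draws, len(wetland_ids)))
        epsilon = np.empty_like(gamma)
        for ci, c in enumerate(chains):
            for which, arr in (("gamma", gamma), ("epsilon", epsilon)):
                sub = eff[(eff["chain"] == c) & (eff["effect"] == which)]
                arr[ci] = sub.pivot(index="iteration", columns="wetland_id",
                                    values="value")[wetland_ids].to_numpy()
    else:
        wetland_ids = []
        gamma = np.zeros((len(chains), n_draws, 0))
        epsilon = np.zeros_like(gamma)
    return PosteriorSamples(scalars=scalars, gamma=gamma, epsilon=epsilon,
                            wetland_ids=wetland_ids)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep=NA, float_format="%.6g")


def write_truth(truth_record: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_record, fh, indent=2, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from one YAML file."""

    paths: dict = field(default_factory=dict)
    seed: int = 0
    month: int = 8                     # calendar month joining observations to the bank
    hist_max_year: int = 1969
    cont_min_year: int = 2003
    spei_max: int = 120
    spi_max: int = 3
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    priors: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 1 <= self.month <= 12:
            raise InvalidInputError(f"month {self.month} outside 1..12")
        if self.hist_max_year >= self.cont_min_year:
            raise InvalidInputError("era year cutoffs overlap")

    def path(self, key: str) -> Path:
        if key not in self.paths:
            raise InvalidInputError(f"config has no path for {key!r}")
        return Path(self.paths[key])

    def config_hash(self) -> str:
        blob = {
            "paths": dict(self.paths), "seed": self.seed, "month": self.month,
            "hist_max_year": self.hist_max_year, "cont_min_year": self.cont_min_year,
            "spei_max": self.spei_max, "spi_max": self.spi_max,
            "sampler": vars(self.sampler), "priors": dict(self.priors),
            "synthetic": dict(self.synthetic),
        }
        return hashlib.sha256(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sampler = SamplerConfig(**raw.get("sampler", {}))
    known = {"paths", "seed", "month", "hist_max_year", "cont_min_year",
             "spei_max", "spi_max", "priors", "synthetic"}
    unknown = set(raw) - known - {"sampler"}
    if unknown:
        raise InvalidInputError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs = {k: raw[k] for k in known if k in raw}
    return RunConfig(sampler=sampler, **kwargs)
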