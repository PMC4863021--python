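"""Generate the fixed synthetic series behind the index-engine fixtures.

Run from the repository root:

    python tests/fixtures/gen_oracle_input.py

Writes ``index_oracle_input.csv`` (a 54-year synthetic monthly water-balance
and precipitation record, fixed seed). The companion ``make_reference.R``
turns it into ``index_oracle_expected.csv`` with an independent base-R
implementation of the SPEI (log-logistic / unbiased-PWM) and SPI (gamma ML
with zero mass) standardization recipes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

HERE = Path(__file__).parent


def main() -> None:
    rng = np.random.default_rng(20160328)
    years = np.repeat(np.arange(1950, 2004), 12)
    months = np.tile(np.arange(1, 13), 54)
    seasonal = 20.0 + 45.0 * np.sin(2.0 * np.pi * (months - 4) / 12.0)
    # water balance: seasonal mean, right-skewed gamma noise re-centred
    noise = rng.gamma(4.0, 12.0, size=len(years)) - 48.0
    d = seasonal - 35.0 + noise
    # precipitation: gamma with occasional winter zeros
    shape = np.where(np.isin(months, (12, 1, 2)), 1.4, 2.5)
    mean = 15.0 + 40.0 * np.clip(np.sin(2.0 * np.pi * (months - 4) / 12.0), -0.3, 1.0)
    precip = rng.gamma(shape, mean / shape)
    dry = (np.isin(months, (12, 1, 2))) & (rng.random(len(years)) < 0.08)
    precip[dry] = 0.0
    out = pd.DataFrame({
        "year": years, "month": months,
        "d_mm": np.round(d, 4), "precip_mm": np.round(precip, 4),
    })
    out.to_csv(HERE / "index_oracle_input.csv", index=False)


if __name__ == "__main__":
    main()
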