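"""Published average expectancies at age 60 used as worked-example inputs.

The bundled table holds sex-specific average state expectancies at age 60
(with 95% intervals and shares of total life expectancy) from an
incidence-based multistate analysis of three harmonized aging surveys: the
Costa Rican Study on Longevity and Healthy Aging, the Mexican Health and
Aging Study, and the Health and Retirement Study.  The state rows (no
disease, one disease, disability-free and disabling multimorbidity) are
inputs for worked examples: the package's aggregation and inequality
functions recompute the multimorbidity-free, multimorbid and total
expectancies and the sex gaps from them.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

STATE_ROWS = ("none", "one", "dfmm", "dmm")


def load_published_expectancies() -> pd.DataFrame:
    """Long table: country, sex, quantity, expectancy, CI bounds, share of LE."""
    path = files("mmle.data").joinpath("published_expectancies.csv")
    with path.open("r") as fh:
        return pd.read_csv(fh)


def state_expectancies(table: pd.DataFrame, country: str, sex: str) -> np.ndarray:
    """Four state expectancies (none, one, dfmm, dmm) for one stratum."""
    sub = table[(table["country"] == country) & (table["sex"] == sex)]
    out = []
    for q in STATE_ROWS:
        row = sub[sub["quantity"] == q]
        if row.empty:
            raise KeyError(f"no published value for {country}/{sex}/{q}")
        out.append(float(row["expectancy"].iloc[0]))
    return np.array(out)


def published_value(
    table: pd.DataFrame, country: str, sex: str, quantity: str, column: str = "expectancy"
) -> float:
    sub = table[
        (table["country"] == country)
        & (table["sex"] == sex)
        & (table["quantity"] == quantity)
    ]
    if sub.empty:
        raise KeyError(f"no published value for {country}/{sex}/{quantity}")
    return float(sub[column].iloc[0])
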