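"""Published stratum-level descriptives from the pooled 2001/2003 MEPS adult cohort.

The MEPS micro-data cannot ship with the package, but the published stratum
table (one row per diagnosis-count stratum k = 0..8: size, mean age, percent
male, mean EQ-5D and SF-6D, and the normalized severity-weighted diagnosis
count) is itself sufficient input for the unadjusted model fits and the
Pearson correlation row. It therefore doubles as a reference fixture: the
pipeline's aggregate stage is bypassed and the fit/selection machinery is run
directly on the printed stratum means, reproducing the published unadjusted
regression results.

Also included, as fixture defaults only (they are estimates from the MEPS
micro-data, not reproducible from the table): the published age-sex reference
equations for both instruments, and the published model coefficients and fit
statistics for the two unadjusted analyses used as reference values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adjust import ReferenceModel
from .models import StratumSeries
from .strata import StratumSummary

# One row per stratum k: n, mean (sd) age, % male, mean (sd) EQ-5D, mean (sd)
# SF-6D, mean normalized severity-weighted diagnosis count. Utility means are
# printed at 3 dp, ages/percents at 1 dp.
_STRATUM_ROWS = [
    # k,   n,   age,  sd,  male%, eq5d, sd,  sf6d, sd,  nswnod
    (0, 7089, 36.9, 13.5, 56.9, 0.948, 0.1, 0.862, 0.1, 0.000),
    (1, 7384, 39.4, 14.6, 52.9, 0.921, 0.1, 0.835, 0.1, 1.000),
    (2, 6194, 42.4, 16.0, 50.2, 0.893, 0.1, 0.811, 0.1, 2.029),
    (3, 4936, 45.3, 16.9, 43.7, 0.867, 0.2, 0.791, 0.1, 3.095),
    (4, 3624, 48.9, 17.0, 39.6, 0.838, 0.2, 0.769, 0.1, 4.182),
    (5, 2813, 51.6, 17.4, 36.7, 0.817, 0.2, 0.748, 0.1, 5.292),
    (6, 2093, 53.4, 17.6, 35.0, 0.785, 0.2, 0.723, 0.2, 6.435),
    (7, 1540, 55.6, 17.3, 33.4, 0.773, 0.2, 0.712, 0.1, 7.543),
    (8, 1212, 58.2, 16.8, 31.5, 0.742, 0.2, 0.686, 0.2, 8.713),
]

#: Denominator of the percent columns: all persons meeting the inclusion criteria.
VALID_N = 39_817

#: Published Pearson row: correlation of k with each column of stratum means.
PUBLISHED_PEARSON = {
    "age": 0.997,
    "male": -0.979,
    "eq5d": -0.998,
    "sf6d": -0.998,
    "nswnod": 1.000,
}

#: Published unadjusted model results (analysis number -> model -> statistics).
PUBLISHED_FITS = {
    1: {  # EQ-5D, unadjusted
        "A": {"alpha": 0.9464, "beta": -0.0261, "adj_r2": 0.9972, "rmse": 0.0029, "l1o_rmsr": 0.0051},
        "B": {"alpha": 0.9486, "beta": -0.0287, "beta2": 0.0004, "adj_r2": 0.9983, "rmse": 0.0021, "l1o_rmsr": 0.0042},
        "C": {"alpha": 0.9488, "beta": 0.9700, "adj_r2": 0.9983, "rmse": 0.0021, "l1o_rmsr": 0.0037},
        "rmsd_ac": 0.0020,
    },
    5: {  # SF-6D, unadjusted
        "A": {"alpha": 0.8582, "beta": -0.0220, "adj_r2": 0.9957, "rmse": 0.0030, "l1o_rmsr": 0.0049},
        "B": {"alpha": 0.8609, "beta": -0.0251, "beta2": 0.0005, "adj_r2": 0.9981, "rmse": 0.0019, "l1o_rmsr": 0.0041},
        "C": {"alpha": 0.8600, "beta": 0.9723, "adj_r2": 0.9980, "rmse": 0.0020, "l1o_rmsr": 0.0033},
        "rmsd_ac": 0.0016,
    },
}

#: Published age-sex reference equations (MEPS estimates; fixture defaults only).
REFERENCE_EQ5D = ReferenceModel(
    instrument="eq5d",
    params={"const": 0.9697, "age": -0.0007, "sex": 0.0085},
    pvalues={"const": 0.0, "age": 0.0, "sex": 0.0},
    n_fit=7089,
)
REFERENCE_SF6D = ReferenceModel(
    instrument="sf6d",
    params={"const": 0.8487, "sex": 0.0237},
    pvalues={"const": 0.0, "sex": 0.0},
    dropped={"age": 0.06},  # age left out at p > 0.05; exact p not published
    n_fit=7089,
)


def published_stratum_table() -> pd.DataFrame:
    """The published stratum descriptives as a DataFrame indexed by k."""
    frame = pd.DataFrame(
        _STRATUM_ROWS,
        columns=[
            "k", "n", "mean_age", "sd_age", "pct_male",
            "mean_eq5d", "sd_eq5d", "mean_sf6d", "sd_sf6d", "mean_nswnod",
        ],
    ).set_index("k")
    return frame


def published_summaries() -> list[StratumSummary]:
    """The published table as StratumSummary objects (percent columns derived)."""
    table = published_stratum_table()
    summaries = []
    cum = 0
    for k, row in table.iterrows():
        cum += int(row["n"])
        summaries.append(
            StratumSummary(
                k=int(k),
                n=int(row["n"]),
                pct_of_valid=100.0 * row["n"] / VALID_N,
                cumulative_n=cum,
                cumulative_pct=100.0 * cum / VALID_N,
                mean_age=row["mean_age"],
                sd_age=row["sd_age"],
                pct_male=row["pct_male"],
                mean_eq5d=row["mean_eq5d"],
                sd_eq5d=row["sd_eq5d"],
                mean_sf6d=row["mean_sf6d"],
                sd_sf6d=row["sd_sf6d"],
                mean_nswnod=row["mean_nswnod"],
            )
        )
    return summaries


def published_series(instrument: str) -> StratumSeries:
    """The fit input (k, mean utility, stratum size) from the published table."""
    table = published_stratum_table()
    return StratumSeries(
        x=table.index.to_numpy(dtype=float),
        y=table[f"mean_{instrument}"].to_numpy(dtype=float),
        w=table["n"].to_numpy(dtype=float),
        instrument=instrument,
        label=f"{instrument}/published-strata",
    )
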