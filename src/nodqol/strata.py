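"""Stratification by diagnosis count and stratum-level descriptive statistics.

Persons are partitioned into strata :math:`P_k` of equal (possibly
severity-weighted, rounded) diagnosis count. Only a contiguous prefix
``k = 0, 1, 2, ...`` of strata meeting a minimum-size threshold (default 1000
persons, chosen for robust mean-utility estimates) is retained; retention stops
at the first stratum below the threshold and the discarded fraction is logged.

Per-stratum descriptives mirror a conventional cohort table: n, percent of the
valid cohort, cumulative counts, mean (SD) age, percent male, mean (SD) utility
per instrument, and -- in severity-adjusted runs -- the mean severity-weighted
diagnosis count. A final Pearson row correlates the stratum label k with each
column of stratum means (unweighted, across strata, not across persons).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort
from .exceptions import ConfigurationError, InsufficientDataError, UndefinedCorrelationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Stratum:
    """A group of persons sharing one diagnosis-count label ``k``."""

    k: int
    member_ids: tuple
    n: int


@dataclass
class StratumSummary:
    """Descriptive statistics for one stratum (one row of the cohort table)."""

    k: int
    n: int
    pct_of_valid: float
    cumulative_n: int
    cumulative_pct: float
    mean_age: float
    sd_age: float
    pct_male: float
    mean_eq5d: float
    sd_eq5d: float
    mean_sf6d: float
    sd_sf6d: float
    mean_nswnod: float | None = None


@dataclass
class CorrelationRow:
    """Pearson correlations of the stratum label k with each column of means.

    A coefficient is None when the column is constant across strata (the
    correlation is undefined) or the column was not computed.
    """

    r_age: float | None
    r_male: float | None
    r_eq5d: float | None
    r_sf6d: float | None
    r_nswnod: float | None = None


def pearson(x, y) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two equal-length 1-d vectors")
    if len(x) < 2:
        raise InsufficientDataError("pearson requires at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


def build_strata(nod_map: pd.Series, min_size: int = 1000) -> list[Stratum]:
    """Partition persons by diagnosis-count label, keeping a contiguous prefix.

    Strata ``k = 0, 1, 2, ...`` are retained while their size is at least
    ``min_size``; retention stops at the first k that fails (so the retained
    labels form a contiguous run starting at 0, suitable as a regressor).

    Raises
    ------
    ConfigurationError
        If the k=0 stratum is already below the threshold.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    counts = nod_map.value_counts()
    strata: list[Stratum] = []
    k = 0
    while counts.get(k, 0) >= min_size:
        members = nod_map.index[nod_map == k]
        strata.append(Stratum(k=k, member_ids=tuple(members), n=len(members)))
        k += 1
    if not strata:
        raise ConfigurationError(
            f"stratum k=0 has {counts.get(0, 0)} persons, below min_size={min_size}; "
            "lower the threshold"
        )
    retained = sum(s.n for s in strata)
    discarded_pct = 100.0 * (len(nod_map) - retained) / len(nod_map)
    logger.info(
        "retained %d strata (k=0..%d), %d persons; %.1f%% of persons discarded",
        len(strata),
        strata[-1].k,
        retained,
        discarded_pct,
    )
    return strata


def discarded_fraction(strata: list[Stratum], nod_map: pd.Series) -> float:
    """Percent of persons in ``nod_map`` not covered by the retained strata."""
    retained = sum(s.n for s in strata)
    return 100.0 * (len(nod_map) - retained) / len(nod_map)


def _mean_sd(values: pd.Series) -> tuple[float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def summarize_strata(
    cohort: Cohort,
    strata: list[Stratum],
    swnod_map: pd.Series | None = None,
) -> list[StratumSummary]:
    """Compute per-stratum descriptives with unweighted arithmetic means.

    Percentages use the full included cohort (``cohort.n_persons``) as the
    denominator, so the cumulative percent of the last retained stratum plus the
    discarded percent totals 100.
    """
    if not strata:
        raise InsufficientDataError("no strata to summarize")
    denominator = cohort.n_persons
    summaries: list[StratumSummary] = []
    cum_n = 0
    for stratum in strata:
        members = cohort.persons.loc[list(stratum.member_ids)]
        cum_n += stratum.n
        mean_age, sd_age = _mean_sd(members["age"])
        mean_eq, sd_eq = _mean_sd(members["eq5d"])
        mean_sf, sd_sf = _mean_sd(members["sf6d"])
        mean_nsw = None
        if swnod_map is not None:
            mean_nsw = float(swnod_map.reindex(members.index).mean())
        summaries.append(
            StratumSummary(
                k=stratum.k,
                n=stratum.n,
                pct_of_valid=100.0 * stratum.n / denominator,
                cumulative_n=cum_n,
                cumulative_pct=100.0 * cum_n / denominator,
                mean_age=mean_age,
                sd_age=sd_age,
                pct_male=100.0 * float(members["sex"].mean()),
                mean_eq5d=mean_eq,
                sd_eq5d=sd_eq,
                mean_sf6d=mean_sf,
                sd_sf6d=sd_sf,
                mean_nswnod=mean_nsw,
            )
        )
    return summaries


def _safe_pearson(k: np.ndarray, column) -> float | None:
    values = np.asarray(column, dtype=float)
    if np.any(np.isnan(values)):
        return None
    try:
        return pearson(k, values)
    except UndefinedCorrelationError:
        return None


def correlation_row(summaries: list[StratumSummary]) -> CorrelationRow:
    """Unweighted Pearson correlation of stratum labels against each mean column.

    Computed across strata (one point per stratum), never across persons; this
    is the conventional footer row of a stratified cohort table.
    """
    if len(summaries) < 3:
        raise InsufficientDataError("correlation row requires at least 3 strata")
    k = np.array([s.k for s in summaries], dtype=float)
    nsw = [s.mean_nswnod for s in summaries]
    return CorrelationRow(
        r_age=_safe_pearson(k, [s.mean_age for s in summaries]),
        r_male=_safe_pearson(k, [s.pct_male for s in summaries]),
        r_eq5d=_safe_pearson(k, [s.mean_eq5d for s in summaries]),
        r_sf6d=_safe_pearson(k, [s.mean_sf6d for s in summaries]),
        r_nswnod=None if any(v is None for v in nsw) else _safe_pearson(k, nsw),
    )


def summaries_to_frame(
    summaries: list[StratumSummary], correlation: CorrelationRow | None = None
) -> pd.DataFrame:
    """Tabulate summaries (and optionally the Pearson row) as a DataFrame."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "k": s.k,
                "n": s.n,
                "pct": s.pct_of_valid,
                "cumulative_n": s.cumulative_n,
                "cumulative_pct": s.cumulative_pct,
                "mean_age": s.mean_age,
                "sd_age": s.sd_age,
                "pct_male": s.pct_male,
                "mean_eq5d": s.mean_eq5d,
                "sd_eq5d": s.sd_eq5d,
                "mean_sf6d": s.mean_sf6d,
                "sd_sf6d": s.sd_sf6d,
                "mean_nswnod": math.nan if s.mean_nswnod is None else s.mean_nswnod,
            }
        )
    frame = pd.DataFrame(rows)
    if correlation is not None:
        frame = pd.concat(
            [
                frame,
                pd.DataFrame(
                    [
                        {
                            "k": "pearson_r",
                            "mean_age": correlation.r_age,
                            "pct_male": correlation.r_male,
                            "mean_eq5d": correlation.r_eq5d,
                            "mean_sf6d": correlation.r_sf6d,
                            "mean_nswnod": correlation.r_nswnod,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return frame
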