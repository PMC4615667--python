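"""Weighted fits of the additive, quadratic, and multiplicative models.

Mean utility per stratum is modelled as a function of the diagnosis count k:

* Model A (additive):        HRQoL = alpha + beta * k
* Model B (quadratic):       HRQoL = alpha + beta * k + beta2 * k**2
* Model C (multiplicative):  HRQoL = alpha * beta**k,
  fitted as ln(HRQoL) = alpha' + beta' * k and back-transformed.

All fits are weighted least squares with the stratum sizes as weights, so
large strata dominate exactly as they do in the person-level means. Model
comparison statistics:

* adjusted R**2 and RMSE, both on the original utility scale (Model C's fitted
  values are back-transformed before computing them);
* the leave-one-out RMS residual (L1O-RMSR): each stratum is deleted in turn,
  the model refitted on the rest (same weights), and the deleted stratum's
  mean predicted; the default aggregation is the plain RMS of the nine
  delete-one residuals (refits weighted, aggregation unweighted -- the
  convention that reproduces published values on the reference fixture), with
  a size-weighted variant available;
* the RMSD between Models A and C: the size-weighted Euclidean distance
  between the two models' fitted vectors, measuring how far apart the two
  functional forms are relative to how far each sits from the data.

``run_analysis`` chains the full pipeline (adjust -> count/SWNoD -> stratify ->
aggregate -> fit) for one instrument under one of four adjustment
specifications (none; age+sex; age, sex and relaxed severity; age, sex and
strict severity), i.e. one of the eight instrument x adjustment analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import adjust as adj
from .cohort import Cohort, count_diagnoses
from .exceptions import DomainError, InsufficientDataError
from .strata import Stratum, StratumSummary, build_strata, summarize_strata

logger = logging.getLogger(__name__)

#: The eight analyses: number -> (instrument, adjustment).
ANALYSES = {
    1: ("eq5d", "none"),
    2: ("eq5d", "age_sex"),
    3: ("eq5d", "severity_relaxed"),
    4: ("eq5d", "severity_strict"),
    5: ("sf6d", "none"),
    6: ("sf6d", "age_sex"),
    7: ("sf6d", "severity_relaxed"),
    8: ("sf6d", "severity_strict"),
}

ADJUSTMENTS = ("none", "age_sex", "severity_relaxed", "severity_strict")


@dataclass
class StratumSeries:
    """Aggregated inputs to the model fits: one point per stratum."""

    x: np.ndarray  # stratum labels k
    y: np.ndarray  # stratum mean utilities
    w: np.ndarray  # stratum sizes
    instrument: str = ""
    label: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.w)):
            raise ValueError("x, y, w must have equal lengths")
        if np.any(self.w <= 0):
            raise ValueError("stratum weights must be positive")
        if len(np.unique(self.x)) != len(self.x):
            raise ValueError("duplicate stratum labels")


@dataclass
class FitResult:
    """One fitted model and its comparison statistics (one results-table row)."""

    model_id: str  # "A", "B" or "C"
    alpha: float
    beta: float
    beta2: float | None = None
    p_beta2: float | None = None
    p_beta: float | None = None
    adj_r2: float = float("nan")
    rmse: float = float("nan")
    l1o_rmsr: float = float("nan")
    fitted: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class AnalysisResult:
    """The three fits plus the A-C distance for one analysis."""

    series: StratumSeries
    fit_a: FitResult
    fit_b: FitResult
    fit_c: FitResult
    rmsd_ac: float
    info: dict = field(default_factory=dict)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    return sm.WLS(y, X, weights=w).fit()


def weighted_rmse(fitted, observed, w) -> float:
    """Size-weighted root-mean-squared error, sqrt(sum w e^2 / sum w)."""
    fitted = np.asarray(fitted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(fitted) == len(observed) == len(w)):
        raise ValueError("length mismatch")
    return float(np.sqrt(np.sum(w * (fitted - observed) ** 2) / np.sum(w)))


def adjusted_r2(fit: FitResult, series: StratumSeries, n_params: int) -> float:
    """Weighted adjusted R**2 on the original utility scale.

    R**2 uses weighted sums of squares about the weighted mean of y;
    ``n_params`` counts predictors excluding the intercept.
    """
    n = len(series.y)
    if n <= n_params + 1:
        raise InsufficientDataError("adjusted R^2 undefined: n <= p + 1")
    w = series.w
    ybar = np.sum(w * series.y) / np.sum(w)
    ss_res = np.sum(w * (series.y - fit.fitted) ** 2)
    ss_tot = np.sum(w * (series.y - ybar) ** 2)
    if ss_tot == 0:
        # constant observed means: any intercept model fits perfectly
        return 1.0 if np.isclose(ss_res, 0.0) else float("nan")
    r2 = 1.0 - ss_res / ss_tot
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1))


def _design(x: np.ndarray, model_id: str) -> np.ndarray:
    if model_id in ("A", "C"):
        return np.column_stack([np.ones_like(x), x])
    if model_id == "B":
        return np.column_stack([np.ones_like(x), x, x**2])
    raise ValueError(f"unknown model id {model_id!r}")


def _predict(model_id: str, params: np.ndarray, x: np.ndarray) -> np.ndarray:
    fitted_lin = _design(x, model_id) @ params
    return np.exp(fitted_lin) if model_id == "C" else fitted_lin


def _fit_params(model_id: str, x, y, w):
    target = np.log(y) if model_id == "C" else y
    return _wls(_design(x, model_id), target, w)


def l1o_rmsr(model_id: str, series: StratumSeries, aggregate: str = "unweighted") -> float:
    """Leave-one-out RMS residual: delete each stratum, refit, predict it back.

    Refits keep the remaining strata's size weights. ``aggregate`` chooses the
    RMS over the delete-one residuals: ``"unweighted"`` (default) or
    ``"weighted"`` by stratum size.
    """
    n_params = 3 if model_id == "B" else 2
    n = len(series.y)
    if n < n_params + 2:
        raise InsufficientDataError(
            f"leave-one-out for model {model_id} needs >= {n_params + 2} strata, got {n}"
        )
    residuals = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        res = _fit_params(model_id, series.x[mask], series.y[mask], series.w[mask])
        pred = _predict(model_id, np.asarray(res.params), series.x[i : i + 1])[0]
        residuals[i] = series.y[i] - pred
    if aggregate == "unweighted":
        return float(np.sqrt(np.mean(residuals**2)))
    if aggregate == "weighted":
        return float(np.sqrt(np.sum(series.w * residuals**2) / np.sum(series.w)))
    raise ValueError(f"unknown aggregate mode {aggregate!r}")


def fit_model_a(series: StratumSeries, l1o_aggregate: str = "unweighted") -> FitResult:
    """Additive model: weighted least squares of y on (1, k)."""
    if len(series.y) < 3:
        raise InsufficientDataError("Model A needs >= 3 strata")
    res = _fit_params("A", series.x, series.y, series.w)
    fitted = _predict("A", np.asarray(res.params), series.x)
    fit = FitResult(
        model_id="A",
        alpha=float(res.params[0]),
        beta=float(res.params[1]),
        p_beta=float(res.pvalues[1]),
        fitted=fitted,
    )
    fit.rmse = weighted_rmse(fitted, series.y, series.w)
    fit.adj_r2 = adjusted_r2(fit, series, n_params=1)
    fit.l1o_rmsr = l1o_rmsr("A", series, aggregate=l1o_aggregate)
    return fit


def fit_model_b(series: StratumSeries, l1o_aggregate: str = "unweighted") -> FitResult:
    """Quadratic model: WLS of y on (1, k, k**2); p_beta2 tests the quadratic term.

    Model A is nested in B, so a non-significant quadratic coefficient flags
    over-specification of B relative to A.
    """
    if len(series.y) < 4:
        raise InsufficientDataError("Model B needs >= 4 strata")
    res = _fit_params("B", series.x, series.y, series.w)
    fitted = _predict("B", np.asarray(res.params), series.x)
    fit = FitResult(
        model_id="B",
        alpha=float(res.params[0]),
        beta=float(res.params[1]),
        beta2=float(res.params[2]),
        p_beta=float(res.pvalues[1]),
        p_beta2=float(res.pvalues[2]),
        fitted=fitted,
    )
    fit.rmse = weighted_rmse(fitted, series.y, series.w)
    fit.adj_r2 = adjusted_r2(fit, series, n_params=2)
    fit.l1o_rmsr = l1o_rmsr("B", series, aggregate=l1o_aggregate)
    return fit


def fit_model_c(series: StratumSeries, l1o_aggregate: str = "unweighted") -> FitResult:
    """Multiplicative model: WLS of ln(y) on (1, k), back-transformed.

    Reported alpha and beta are exp of the log-scale coefficients, so fitted
    values are alpha * beta**k exactly; all fit statistics are computed on the
    original utility scale from the back-transformed fitted values (no
    retransformation bias correction is applied).
    """
    if len(series.y) < 3:
        raise InsufficientDataError("Model C needs >= 3 strata")
    if np.any(series.y <= 0):
        bad = series.x[series.y <= 0]
        raise DomainError(f"Model C requires positive means; offending strata k={bad}")
    res = _fit_params("C", series.x, series.y, series.w)
    fitted = _predict("C", np.asarray(res.params), series.x)
    fit = FitResult(
        model_id="C",
        alpha=float(np.exp(res.params[0])),
        beta=float(np.exp(res.params[1])),
        p_beta=float(res.pvalues[1]),
        fitted=fitted,
    )
    fit.rmse = weighted_rmse(fitted, series.y, series.w)
    fit.adj_r2 = adjusted_r2(fit, series, n_params=1)
    fit.l1o_rmsr = l1o_rmsr("C", series, aggregate=l1o_aggregate)
    return fit


def rmsd_between(fit_a: FitResult, fit_c: FitResult, w) -> float:
    """Size-weighted Euclidean distance between two models' fitted vectors."""
    if len(fit_a.fitted) != len(fit_c.fitted):
        raise ValueError("fitted vectors are on different stratum grids")
    return weighted_rmse(fit_a.fitted, fit_c.fitted, w)


def series_from_summaries(
    summaries: list[StratumSummary], instrument: str, label: str = ""
) -> StratumSeries:
    """Build the fit input (k, mean utility, size) from stratum summaries."""
    column = {"eq5d": "mean_eq5d", "sf6d": "mean_sf6d"}[instrument]
    return StratumSeries(
        x=np.array([s.k for s in summaries], dtype=float),
        y=np.array([getattr(s, column) for s in summaries], dtype=float),
        w=np.array([s.n for s in summaries], dtype=float),
        instrument=instrument,
        label=label,
    )


def fit_all(series: StratumSeries, l1o_aggregate: str = "unweighted") -> AnalysisResult:
    """Fit Models A, B, C to one series and compute the A-C distance."""
    fit_a = fit_model_a(series, l1o_aggregate)
    fit_b = fit_model_b(series, l1o_aggregate)
    fit_c = fit_model_c(series, l1o_aggregate)
    return AnalysisResult(
        series=series,
        fit_a=fit_a,
        fit_b=fit_b,
        fit_c=fit_c,
        rmsd_ac=rmsd_between(fit_a, fit_c, series.w),
    )


def _stratum_mean_series(
    utilities: pd.Series, strata: list[Stratum], instrument: str, label: str
) -> StratumSeries:
    x, y, w = [], [], []
    for stratum in strata:
        values = utilities.loc[list(stratum.member_ids)]
        x.append(stratum.k)
        y.append(float(values.mean()))
        w.append(stratum.n)
    return StratumSeries(x=x, y=y, w=w, instrument=instrument, label=label)


def run_analysis(
    cohort: Cohort,
    instrument: str,
    adjustment: str,
    min_stratum_size: int = 1000,
    drop_alpha: float = 0.05,
    rounding: str = "half_away",
    use_adjusted_for_weights: bool = True,
    truncate_negative: bool = False,
    l1o_aggregate: str = "unweighted",
) -> AnalysisResult:
    """Run one instrument x adjustment analysis end to end on an included cohort.

    The stage chain is: (fit reference model and adjust, if requested) ->
    count NoD or SWNoD -> stratify with the size threshold -> aggregate stratum
    means -> fit Models A/B/C -> comparison statistics.
    """
    if instrument not in ("eq5d", "sf6d"):
        raise ValueError(f"unknown instrument {instrument!r}")
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjustment!r}; one of {ADJUSTMENTS}")
    label = f"{instrument}/{adjustment}"
    info: dict = {"instrument": instrument, "adjustment": adjustment}

    nod = count_diagnoses(cohort)

    if adjustment == "none":
        strata = build_strata(nod, min_size=min_stratum_size)
        utilities = cohort.persons[instrument].astype(float)
        series = _stratum_mean_series(utilities, strata, instrument, label)
        info["summaries"] = summarize_strata(cohort, strata)
    else:
        zero_persons = cohort.persons.loc[nod.index[nod == 0]]
        reference = adj.fit_reference_model(zero_persons, instrument, drop_alpha=drop_alpha)
        adjusted = adj.age_sex_adjust(cohort, reference)
        info["reference_model"] = reference
        if adjustment == "age_sex":
            strata = build_strata(nod, min_size=min_stratum_size)
            series = _stratum_mean_series(adjusted.adjusted, strata, instrument, label)
        else:
            min_n = 1 if adjustment == "severity_relaxed" else 10
            table = adj.compute_severity_weights(
                adjusted,
                min_n=min_n,
                use_adjusted=use_adjusted_for_weights,
                truncate_negative=truncate_negative,
            )
            swnod, excluded = adj.compute_swnod(adjusted, table)
            strata = adj.restratify(swnod, min_size=min_stratum_size, rounding=rounding)
            series = _stratum_mean_series(adjusted.adjusted, strata, instrument, label)
            info["weight_table"] = table
            info["n_weighable_codes"] = len(table.weights)
            info["retained_pct"] = 100.0 * len(swnod) / cohort.n_persons
            info["reclassified_pct"] = adj.fraction_reclassified(
                nod, swnod, rounding=rounding
            )
            info["swnod"] = swnod

    result = fit_all(series, l1o_aggregate=l1o_aggregate)
    result.info.update(info)
    return result


def run_analyses(
    cohort: Cohort, numbers: list[int] | None = None, **kwargs
) -> dict[int, AnalysisResult]:
    """Run a subset (default: all eight) of the instrument x adjustment analyses."""
    numbers = sorted(numbers or ANALYSES)
    results = {}
    for number in numbers:
        instrument, adjustment = ANALYSES[number]
        logger.info("running analysis %d (%s, %s)", number, instrument, adjustment)
        results[number] = run_analysis(cohort, instrument, adjustment, **kwargs)
    return results
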