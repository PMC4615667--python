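"""Age/sex reference adjustment and severity-weighted diagnosis counts.

Stratum membership confounds with demographics (older, more often female with
more diagnoses) and with diagnosis severity. This module implements the three
adjustments applied before model fitting:

1. **Reference model** -- an OLS fit of utility on age and sex within the
   zero-diagnosis stratum, with backward elimination of covariates whose
   p-value exceeds ``drop_alpha``.
2. **Age/sex adjustment** -- each person's utility is shifted by the difference
   between the reference prediction at a fixed anchor (by default the mean age
   and male fraction of the zero-diagnosis stratum) and the prediction at the
   person's own age and sex. A person at the anchor is unchanged, and the
   adjustment is a pure location shift within each (age, sex) cell.
3. **Severity weights** -- for each code D, the decrement is the mean adjusted
   utility of the zero-diagnosis stratum minus the mean adjusted utility of the
   *sole-diagnosis* persons for D (exactly one non-V record, with that code).
   Weights are decrements normalized so that the person-weighted mean weight
   over all sole-diagnosis individuals with weighable codes is exactly 1; the
   severity-weighted number of diagnoses (SWNoD) then sums weights over a
   person's non-V records with multiplicity, and averages 1.000 in the NoD=1
   stratum by construction. "Relaxed" weights require at least one
   sole-diagnosis observation per code, "strict" weights at least 10; persons
   carrying any non-weighable code are excluded from severity-adjusted runs.

Weights are instrument-specific: EQ-5D-based SWNoD uses EQ-5D decrements, and
likewise for SF-6D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort, count_diagnoses
from .exceptions import EmptyWeightTableError, InsufficientDataError
from .strata import Stratum, build_strata

logger = logging.getLogger(__name__)

COVARIATES = ("age", "sex")


@dataclass
class ReferenceModel:
    """Fitted age-sex baseline utility model on the zero-diagnosis stratum.

    ``params`` holds the retained coefficients (always ``const``, plus ``age``
    and/or ``sex``); ``dropped`` maps eliminated covariates to the p-value that
    triggered their removal.
    """

    instrument: str
    params: dict[str, float]
    pvalues: dict[str, float]
    dropped: dict[str, float] = field(default_factory=dict)
    n_fit: int = 0

    @property
    def intercept(self) -> float:
        return self.params["const"]

    @property
    def age_coef(self) -> float | None:
        return self.params.get("age")

    @property
    def sex_coef(self) -> float | None:
        return self.params.get("sex")


@dataclass
class SeverityWeightTable:
    """Normalized per-code severity weights for one instrument and criterion."""

    instrument: str
    criterion: str
    min_n: int
    weights: pd.Series  # index: code, values: normalized weight
    n_sole: pd.Series  # sole-diagnosis count per weighable code
    decrements: pd.Series  # raw utility decrements per weighable code
    normalizer: float  # person-weighted mean decrement used to normalize

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": self.weights.index,
                "n_sole": self.n_sole.values,
                "decrement": self.decrements.values,
                "weight": self.weights.values,
            }
        )


@dataclass
class AdjustedCohort:
    """A cohort with age/sex-adjusted utilities for one instrument."""

    cohort: Cohort
    instrument: str
    adjusted: pd.Series  # adjusted utility per person
    anchor: tuple[float, float]  # (age, male fraction) the adjustment is shifted to
    reference: ReferenceModel
    nod: pd.Series
    swnod: pd.Series | None = None
    excluded_unweighable: frozenset = frozenset()


def fit_reference_model(
    zero_stratum_persons: pd.DataFrame,
    instrument: str,
    drop_alpha: float = 0.05,
) -> ReferenceModel:
    """OLS of utility on age and sex with backward covariate elimination.

    Covariates with p > ``drop_alpha`` are removed one at a time (largest p
    first) and the model is refitted; the intercept is always retained.
    """
    if len(zero_stratum_persons) < 30:
        raise InsufficientDataError(
            f"reference model needs >= 30 persons, got {len(zero_stratum_persons)}"
        )
    data = zero_stratum_persons[["age", "sex", instrument]].dropna()
    y = data[instrument].astype(float)
    covariates = list(COVARIATES)
    dropped: dict[str, float] = {}
    while True:
        X = sm.add_constant(data[covariates].astype(float)) if covariates else pd.DataFrame(
            {"const": np.ones(len(data))}, index=data.index
        )
        res = sm.OLS(y, X).fit()
        pvals = {c: float(res.pvalues[c]) for c in covariates}
        worst = max(pvals, key=pvals.get) if pvals else None
        if worst is not None and pvals[worst] > drop_alpha:
            dropped[worst] = pvals[worst]
            covariates.remove(worst)
            logger.info(
                "reference model (%s): dropping %s (p=%.4f > %.2f)",
                instrument,
                worst,
                dropped[worst],
                drop_alpha,
            )
            continue
        break
    params = {name: float(res.params[name]) for name in res.params.index}
    pvalues = {name: float(res.pvalues[name]) for name in res.pvalues.index}
    return ReferenceModel(
        instrument=instrument,
        params=params,
        pvalues=pvalues,
        dropped=dropped,
        n_fit=len(data),
    )


def predict_reference(model: ReferenceModel, age, sex):
    """Predicted baseline utility at the given age and sex (dropped terms omitted)."""
    pred = model.intercept + np.zeros_like(np.asarray(age, dtype=float))
    if model.age_coef is not None:
        pred = pred + model.age_coef * np.asarray(age, dtype=float)
    if model.sex_coef is not None:
        pred = pred + model.sex_coef * np.asarray(sex, dtype=float)
    if np.ndim(age) == 0 and np.ndim(sex) == 0:
        return float(pred)
    return pred


def age_sex_adjust(
    cohort: Cohort,
    model: ReferenceModel,
    anchor: tuple[float, float] | None = None,
) -> AdjustedCohort:
    """Shift utilities to a common demographic anchor.

    ``adjusted = observed + [predict(anchor) - predict(person)]``. With no
    anchor given, the anchor is the mean age and male fraction of the
    zero-diagnosis stratum, so the adjusted scale stays comparable to the raw
    zero-diagnosis baseline.
    """
    nod = count_diagnoses(cohort)
    if anchor is None:
        zero = cohort.persons.loc[nod.index[nod == 0]]
        if len(zero) == 0:
            raise InsufficientDataError("no zero-diagnosis persons to anchor on")
        anchor = (float(zero["age"].mean()), float(zero["sex"].mean()))
    persons = cohort.persons
    shift = predict_reference(model, anchor[0], anchor[1]) - predict_reference(
        model, persons["age"].to_numpy(), persons["sex"].to_numpy()
    )
    adjusted = persons[model.instrument].astype(float) + shift
    adjusted.name = f"adjusted_{model.instrument}"
    return AdjustedCohort(
        cohort=cohort,
        instrument=model.instrument,
        adjusted=adjusted,
        anchor=anchor,
        reference=model,
        nod=nod,
    )


def _non_v_records(cohort: Cohort) -> pd.DataFrame:
    diag = cohort.diagnoses
    if len(diag) == 0:
        return diag
    return diag[~diag["code"].str.strip().str.upper().str.startswith("V")]


def compute_severity_weights(
    adjusted: AdjustedCohort,
    min_n: int = 1,
    use_adjusted: bool = True,
    truncate_negative: bool = False,
) -> SeverityWeightTable:
    """Estimate normalized per-code severity weights from sole-diagnosis persons.

    ``min_n = 1`` gives the relaxed criterion, ``min_n = 10`` the strict one.
    A negative decrement (sole-diagnosis mean above the zero-diagnosis
    baseline) yields a negative weight, kept as computed unless
    ``truncate_negative`` clips it to zero (the table is then renormalized so
    the mean-1 invariant still holds).
    """
    utilities = (
        adjusted.adjusted
        if use_adjusted
        else adjusted.cohort.persons[adjusted.instrument].astype(float)
    )
    nod = adjusted.nod
    zero_ids = nod.index[nod == 0]
    if len(zero_ids) == 0:
        raise InsufficientDataError("no zero-diagnosis persons: baseline undefined")
    baseline = float(utilities.loc[zero_ids].mean())

    records = _non_v_records(adjusted.cohort)
    sole_ids = nod.index[nod == 1]
    sole_records = records[records["person_id"].isin(sole_ids)]
    if len(sole_records) == 0:
        raise EmptyWeightTableError("no sole-diagnosis persons in cohort")
    sole = pd.DataFrame(
        {
            "code": sole_records["code"].to_numpy(),
            "utility": utilities.loc[sole_records["person_id"]].to_numpy(),
        }
    )
    grouped = sole.groupby("code")["utility"].agg(["size", "mean"])
    weighable = grouped[grouped["size"] >= min_n]
    if len(weighable) == 0:
        raise EmptyWeightTableError(f"no code has >= {min_n} sole-diagnosis persons")
    decrements = baseline - weighable["mean"]
    n_sole = weighable["size"].astype(int)
    normalizer = float(np.sum(n_sole * decrements) / n_sole.sum())
    if normalizer == 0:
        raise EmptyWeightTableError("mean sole-diagnosis decrement is zero; weights undefined")
    weights = decrements / normalizer
    if (weights < 0).any():
        logger.warning(
            "%d codes have negative severity weights (sole-diagnosis mean above baseline)",
            int((weights < 0).sum()),
        )
    if truncate_negative:
        weights = weights.clip(lower=0.0)
        # renormalize to preserve the mean-1 invariant after clipping
        weights = weights / float(np.sum(n_sole * weights) / n_sole.sum())
    criterion = {1: "relaxed", 10: "strict"}.get(min_n, f"min_n={min_n}")
    logger.info(
        "severity weights (%s, %s): %d weighable codes of %d seen as sole diagnosis",
        adjusted.instrument,
        criterion,
        len(weights),
        len(grouped),
    )
    return SeverityWeightTable(
        instrument=adjusted.instrument,
        criterion=criterion,
        min_n=min_n,
        weights=weights.rename("weight"),
        n_sole=n_sole.rename("n_sole"),
        decrements=decrements.rename("decrement"),
        normalizer=normalizer,
    )


def compute_swnod(
    adjusted: AdjustedCohort, table: SeverityWeightTable
) -> tuple[pd.Series, frozenset]:
    """Severity-weighted number of diagnoses per person.

    SWNoD sums the weight of each non-V record (with multiplicity). Persons
    carrying any non-V record whose code is not in the weight table are
    excluded and returned as the second element; zero-diagnosis persons get 0.
    """
    if len(table.weights) == 0:
        raise EmptyWeightTableError("empty severity weight table")
    records = _non_v_records(adjusted.cohort)
    persons = adjusted.cohort.persons.index
    unweighable_mask = ~records["code"].isin(table.weights.index)
    excluded = frozenset(records.loc[unweighable_mask, "person_id"].unique())
    retained = persons[~persons.isin(excluded)]
    kept_records = records[records["person_id"].isin(retained)]
    sums = (
        kept_records["code"].map(table.weights).groupby(kept_records["person_id"]).sum()
        if len(kept_records)
        else pd.Series(dtype=float)
    )
    swnod = sums.reindex(retained, fill_value=0.0).astype(float)
    swnod.name = "swnod"
    logger.info(
        "SWNoD (%s, %s): retained %d of %d persons (%.2f%%)",
        table.instrument,
        table.criterion,
        len(retained),
        len(persons),
        100.0 * len(retained) / len(persons),
    )
    return swnod, excluded


def round_swnod(swnod: pd.Series, rounding: str = "half_away") -> pd.Series:
    """Round SWNoD to a non-negative integer stratum label.

    ``half_away`` rounds halves away from zero (2.5 -> 3); ``half_even`` is
    banker's rounding. Negative sums (possible with negative weights) clip to 0.
    """
    values = swnod.to_numpy(dtype=float)
    if rounding == "half_away":
        labels = np.sign(values) * np.floor(np.abs(values) + 0.5)
    elif rounding == "half_even":
        labels = np.rint(values)
    else:
        raise ValueError(f"unknown rounding mode: {rounding!r}")
    return pd.Series(
        np.clip(labels, 0, None).astype(np.int64), index=swnod.index, name="swnod_k"
    )


def restratify(
    swnod_map: pd.Series, min_size: int = 1000, rounding: str = "half_away"
) -> list[Stratum]:
    """Stratify by rounded SWNoD with the same threshold/contiguity rules as NoD."""
    return build_strata(round_swnod(swnod_map, rounding), min_size=min_size)


def fraction_reclassified(
    nod_map: pd.Series, swnod_map: pd.Series, rounding: str = "half_away"
) -> float:
    """Percent of retained persons whose rounded SWNoD differs from their NoD."""
    labels = round_swnod(swnod_map, rounding)
    common = labels.index.intersection(nod_map.index)
    if len(common) == 0:
        raise InsufficientDataError("no persons common to NoD and SWNoD maps")
    return 100.0 * float((labels.loc[common] != nod_map.loc[common]).mean())
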