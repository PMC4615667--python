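import numpy as np
import pandas as pd
import pytest

from nodqol import (
    Cohort,
    age_sex_adjust,
    compute_severity_weights,
    compute_swnod,
    count_diagnoses,
    fit_reference_model,
    fraction_reclassified,
    predict_reference,
    restratify,
)
from nodqol.adjust import ReferenceModel, round_swnod
from nodqol.exceptions import EmptyWeightTableError, InsufficientDataError
from nodqol.fixtures import REFERENCE_EQ5D, REFERENCE_SF6D


def _persons(n, rng, age_coef=-0.0007, sex_coef=0.0085, noise=0.1, intercept=0.95):
    age = rng.integers(18, 86, n)
    sex = rng.integers(0, 2, n)
    y = intercept + age_coef * age + sex_coef * sex + rng.normal(0, noise, n)
    return pd.DataFrame(
        {"age": age, "sex": sex, "eq5d": y, "sf6d": y},
        index=pd.Index([f"p{i}" for i in range(n)], name="person_id"),
    )


class TestReferenceModel:
    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(42)
        persons = _persons(10_000, rng)
        model = fit_reference_model(persons, "eq5d")
        # tolerances are ~3 standard errors for this design
        assert model.intercept == pytest.approx(0.95, abs=0.01)
        assert model.age_coef == pytest.approx(-0.0007, abs=1.6e-4)
        assert model.sex_coef == pytest.approx(0.0085, abs=0.006)
        assert model.dropped == {}
        assert model.n_fit == 10_000

    def test_drops_null_covariate(self):
        rng = np.random.default_rng(8)
        persons = _persons(5_000, rng, age_coef=0.0)  # age carries no signal
        model = fit_reference_model(persons, "eq5d")
        assert model.age_coef is None
        assert "age" in model.dropped and model.dropped["age"] > 0.05
        assert model.sex_coef is not None

    def test_too_few_persons(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InsufficientDataError):
            fit_reference_model(_persons(10, rng), "eq5d")


class TestPredictReference:
    def test_intercept_at_origin(self):
        assert predict_reference(REFERENCE_EQ5D, 0, 0) == pytest.approx(0.9697)

    def test_arithmetic_with_dropped_age(self):
        # SF-6D reference has no age term: 0.8487 + 0.0237 for a 50-year-old man
        assert predict_reference(REFERENCE_SF6D, 50, 1) == pytest.approx(0.8724)

    def test_intercept_only_model_is_constant(self):
        model = ReferenceModel("eq5d", params={"const": 0.9}, pvalues={"const": 0.0})
        assert predict_reference(model, 80, 1) == predict_reference(model, 18, 0) == 0.9


class TestAgeSexAdjust:
    def test_anchor_fixed_point_and_age_shift(self, tiny_cohort):
        adjusted = age_sex_adjust(tiny_cohort, REFERENCE_EQ5D, anchor=(30.0, 1.0))
        # p0 sits exactly at the anchor
        assert adjusted.adjusted["p0"] == pytest.approx(tiny_cohort.persons.loc["p0", "eq5d"])
        # p2 is 30 years older, same sex: compensated upward by 0.0007 * 30
        assert adjusted.adjusted["p2"] == pytest.approx(
            tiny_cohort.persons.loc["p2", "eq5d"] + 0.0007 * 30
        )

    def test_intercept_only_model_changes_nothing(self, tiny_cohort):
        model = ReferenceModel("eq5d", params={"const": 0.9}, pvalues={"const": 0.0})
        adjusted = age_sex_adjust(tiny_cohort, model)
        pd.testing.assert_series_equal(
            adjusted.adjusted,
            tiny_cohort.persons["eq5d"].astype(float),
            check_names=False,
        )

    def test_default_anchor_is_zero_stratum_mean(self, tiny_cohort):
        adjusted = age_sex_adjust(tiny_cohort, REFERENCE_EQ5D)
        zero = tiny_cohort.persons.loc[["p3", "p4", "p5"]]  # NoD == 0 persons
        assert adjusted.anchor == (zero["age"].mean(), zero["sex"].mean())

    def test_preserves_rank_within_age_sex_cell(self, sim_additive):
        cohort, _ = sim_additive
        nod = count_diagnoses(cohort)
        model = fit_reference_model(cohort.persons.loc[nod == 0], "eq5d")
        adjusted = age_sex_adjust(cohort, model)
        cell = cohort.persons[(cohort.persons["age"] == 45) & (cohort.persons["sex"] == 1)]
        raw_order = cell["eq5d"].rank()
        adj_order = adjusted.adjusted.loc[cell.index].rank()
        pd.testing.assert_series_equal(raw_order, adj_order, check_names=False)


def _sole_cohort():
    """P0 baseline at utility 1.0 plus sole-diagnosis groups with known decrements.

    Code 100: 12 persons at 0.90 (decrement 0.10); code 200: 10 at 0.80
    (decrement 0.20); code 300: 4 at 0.95 (decrement 0.05, below the strict
    threshold). One extra person has code 100 twice, so they are not
    sole-diagnosis; another's only extra record is a V-code, so they are.
    """
    rows, diag = [], []
    idx = 0

    def add(n, utility, codes):
        nonlocal idx
        for _ in range(n):
            pid = f"s{idx}"
            rows.append((pid, 40, 1, utility, utility))
            for code in codes:
                diag.append((pid, code))
            idx += 1

    add(20, 1.00, [])  # zero-diagnosis baseline
    add(12, 0.90, ["100"])
    add(10, 0.80, ["200"])
    add(4, 0.95, ["300"])
    add(1, 0.70, ["100", "100"])  # multiplicity: not sole
    add(1, 0.88, ["100", "V70"])  # V-code ignored: still sole for 100
    persons = pd.DataFrame(
        rows, columns=["person_id", "age", "sex", "eq5d", "sf6d"]
    ).set_index("person_id")
    return Cohort(persons=persons, diagnoses=pd.DataFrame(diag, columns=["person_id", "code"]))


def _adjusted(cohort, instrument="eq5d"):
    model = ReferenceModel(instrument, params={"const": 1.0}, pvalues={"const": 0.0})
    return age_sex_adjust(cohort, model)


class TestSeverityWeights:
    def test_hand_computed_normalization(self):
        adjusted = _adjusted(_sole_cohort())
        table = compute_severity_weights(adjusted, min_n=1)
        # sole-diagnosis sets: 100 -> 13 persons (12 @0.90 + 1 @0.88), 200 -> 10,
        # 300 -> 4; baseline is the P0 mean 1.0
        d100 = 1.0 - (12 * 0.90 + 0.88) / 13
        dbar = (13 * d100 + 10 * 0.20 + 4 * 0.05) / 27
        assert table.n_sole.to_dict() == {"100": 13, "200": 10, "300": 4}
        assert table.weights["200"] == pytest.approx(0.20 / dbar)
        assert table.normalizer == pytest.approx(dbar)
        # person-weighted mean weight over sole-diagnosis individuals is 1
        assert np.sum(table.n_sole * table.weights) / table.n_sole.sum() == pytest.approx(
            1.0, abs=1e-9
        )

    def test_strict_subset_of_relaxed(self):
        adjusted = _adjusted(_sole_cohort())
        relaxed = compute_severity_weights(adjusted, min_n=1)
        strict = compute_severity_weights(adjusted, min_n=10)
        assert set(strict.weights.index) == {"100", "200"}
        assert set(strict.weights.index) <= set(relaxed.weights.index)

    def test_equal_decrements_give_unit_weights(self, sim_exact):
        cohort, truth = sim_exact
        adjusted = _adjusted(cohort, "eq5d")
        table = compute_severity_weights(adjusted, min_n=1)
        assert np.allclose(table.weights, 1.0)

    def test_no_weighable_code_errors(self):
        adjusted = _adjusted(_sole_cohort())
        with pytest.raises(EmptyWeightTableError):
            compute_severity_weights(adjusted, min_n=100)

    def test_proportional_to_true_decrements(self):
        # many sole-diagnosis persons per code, low noise: the estimated raw
        # decrements should track the construction values closely
        rng = np.random.default_rng(9)
        codes = {"101": 0.02, "202": 0.05, "303": 0.10}
        rows, diag = [], []
        for i in range(600):
            rows.append((f"z{i}", 40, 1, 1.0 + rng.normal(0, 0.05), 0.8))
        for j, (code, dec) in enumerate(codes.items()):
            for i in range(400):
                pid = f"c{j}_{i}"
                rows.append((pid, 40, 1, 1.0 - dec + rng.normal(0, 0.05), 0.8))
                diag.append((pid, code))
        persons = pd.DataFrame(
            rows, columns=["person_id", "age", "sex", "eq5d", "sf6d"]
        ).set_index("person_id")
        cohort = Cohort(persons=persons, diagnoses=pd.DataFrame(diag, columns=["person_id", "code"]))
        table = compute_severity_weights(_adjusted(cohort), min_n=200)
        for code, dec in codes.items():
            assert table.decrements[code] == pytest.approx(dec, abs=0.01)


class TestSwnod:
    def test_multiplicity_sum_and_exclusion(self):
        cohort = _sole_cohort()
        adjusted = _adjusted(cohort)
        strict = compute_severity_weights(adjusted, min_n=10)
        swnod, excluded = compute_swnod(adjusted, strict)
        w100 = strict.weights["100"]
        # the double-100 person sums the weight twice
        assert swnod["s46"] == pytest.approx(2 * w100)
        # code 300 is not strictly weighable: its carriers are excluded
        assert len(excluded) == 4
        assert swnod["s0"] == 0.0  # zero-diagnosis person

    def test_mean_swnod_is_one_in_sole_stratum(self):
        cohort = _sole_cohort()
        adjusted = _adjusted(cohort)
        table = compute_severity_weights(adjusted, min_n=1)
        swnod, _ = compute_swnod(adjusted, table)
        nod = count_diagnoses(cohort)
        sole = swnod.index[nod.loc[swnod.index] == 1]
        assert swnod.loc[sole].mean() == pytest.approx(1.0, abs=1e-9)


class TestRestratify:
    @pytest.mark.parametrize(
        "value,mode,label",
        [(2.5, "half_away", 3), (2.4999, "half_away", 2), (2.5, "half_even", 2),
         (-0.4, "half_away", 0)],
    )
    def test_rounding(self, value, mode, label):
        series = pd.Series([value], index=["x"])
        assert round_swnod(series, mode).iloc[0] == label

    def test_unit_weights_reproduce_nod_strata(self, sim_exact):
        cohort, _ = sim_exact
        adjusted = _adjusted(cohort)
        table = compute_severity_weights(adjusted, min_n=1)
        swnod, excluded = compute_swnod(adjusted, table)
        assert not excluded
        nod = count_diagnoses(cohort)
        pd.testing.assert_series_equal(
            round_swnod(swnod), nod, check_names=False, check_dtype=False
        )
        assert fraction_reclassified(nod, swnod) == 0.0
        strata = restratify(swnod, min_size=200)
        from nodqol import build_strata

        expected = build_strata(nod, min_size=200)
        assert [(s.k, s.n) for s in strata] == [(s.k, s.n) for s in expected]

    def test_fraction_reclassified_matches_recount(self, sim_additive):
        cohort, _ = sim_additive
        nod = count_diagnoses(cohort)
        model = fit_reference_model(cohort.persons.loc[nod == 0], "eq5d")
        adjusted = age_sex_adjust(cohort, model)
        table = compute_severity_weights(adjusted, min_n=10)
        swnod, _ = compute_swnod(adjusted, table)
        pct = fraction_reclassified(nod, swnod)
        labels = round_swnod(swnod)
        manual = 100.0 * np.mean(
            [labels[p] != nod[p] for p in labels.index]
        )
        assert pct == pytest.approx(manual)
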