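"""Synthetic MEPS-like cohorts with known ground truth.

The generator emulates the structural features of the pooled 2001/2003 MEPS
adult extract that the pipeline is built around, with an explicit, recoverable
data-generating process:

* a catalog of distinct 3-digit diagnosis codes, a configurable fraction of
  which are V-codes whose records must never carry morbidity signal;
* per-person diagnosis counts from a negative-binomial distribution (mean
  ~3.3, long right tail reaching past 20 diagnoses, most mass at 0-8), with
  codes drawn with replacement so repeated (person, code) rows occur as they
  do under 3-digit truncation;
* ages 18-85 skewing older with more diagnoses (a linear coupling of expected
  age to the diagnosis count) and a male share declining with the count;
* per-code true utility decrements of heterogeneous severity (gamma, mean
  0.025 by default), and expected utility under an additive or multiplicative
  ground truth with additive age and sex effects;
* observed utilities drawn around the expected value from a Beta distribution
  rescaled to the instrument's [floor, ceiling] range, which gives bounded,
  left-skewed indices with a realistic mass near the ceiling while keeping the
  mean of the observed utility equal to the generative expectation (so stratum
  means estimate the ground truth the models are judged against). A
  Gaussian-noise-then-clamp variant is available via ``noise_kind``; note that
  censoring at the ceiling biases stratum means toward the floor and
  attenuates fitted slopes, so it is not the default.

Every stage draws from an independent, seed-derived random stream, so e.g.
switching V-code records off regenerates bit-identical utilities.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .cohort import Cohort
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator (defaults = study conditions)."""

    n_persons: int = 50_000
    seed: int = 0
    # diagnosis catalog
    catalog_size: int = 200
    v_code_fraction: float = 0.10
    v_record_rate: float = 0.3  # Poisson mean of V-coded records per person
    # per-code true decrements: gamma(shape, mean/shape); shape=0 -> all equal to mean
    decrement_mean: float = 0.025
    decrement_shape: float = 2.0
    sf6d_decrement_scale: float = 0.85  # SF-6D decrements relative to EQ-5D's
    # per-person diagnosis counts: negative binomial (size r, mean)
    nod_mean: float = 3.3
    nod_dispersion: float = 1.0
    # code prevalence ~ 1/rank**exponent (0 -> uniform); real ICD-9 prevalence
    # is heavy-tailed, which is what separates the relaxed and strict criteria
    code_zipf_exponent: float = 1.0
    # ground truth for expected utility
    generative_form: str = "additive"  # or "multiplicative"
    baseline_eq5d: float = 0.95
    baseline_sf6d: float = 0.86
    age_effect: float = -0.0007  # utility per year, both instruments
    sex_effect: float = 0.0085  # utility for male=1, both instruments
    # observation noise
    noise_sd: float = 0.15
    noise_kind: str = "beta"  # or "gaussian_clamped"
    # demographics
    age_mean: float = 37.0
    age_sd: float = 13.0
    age_min: int = 18
    age_max: int = 85
    age_nod_coupling: float = 2.6  # expected years of age per diagnosis
    under18_fraction: float = 0.0
    male_fraction: float = 0.455
    sex_nod_coupling: float = 0.13  # decline in log-odds of male per diagnosis
    missing_fraction: float = 0.0  # per-instrument missingness, to exercise inclusion
    # instrument ranges
    ceiling: float = 1.0
    floor_eq5d: float = -0.11
    floor_sf6d: float = 0.30

    def validate(self) -> None:
        if self.n_persons < 1 or self.catalog_size < 1:
            raise ConfigurationError("n_persons and catalog_size must be >= 1")
        for name in ("v_code_fraction", "male_fraction", "under18_fraction", "missing_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.floor_eq5d >= self.ceiling or self.floor_sf6d >= self.ceiling:
            raise ConfigurationError("floor must be below ceiling")
        if self.generative_form not in ("additive", "multiplicative"):
            raise ConfigurationError(f"unknown generative_form {self.generative_form!r}")
        if self.noise_kind not in ("beta", "gaussian_clamped"):
            raise ConfigurationError(f"unknown noise_kind {self.noise_kind!r}")


@dataclass
class GroundTruth:
    """What the generator actually used: reproducible from (config, seed)."""

    config: SimulationConfig
    catalog: pd.DataFrame  # code, is_v, decrement_eq5d, decrement_sf6d
    expected: pd.DataFrame  # per-person expected eq5d/sf6d (pre-noise)
    true_nod: pd.Series  # per-person count of non-V records

    @property
    def mean_decrement(self) -> dict[str, float]:
        """Prevalence-weighted mean true decrement (the additive truth slope)."""
        non_v = self.catalog[~self.catalog["is_v"]]
        p = non_v["prevalence"].to_numpy()
        return {
            "eq5d": float(np.sum(p * non_v["decrement_eq5d"].to_numpy())),
            "sf6d": float(np.sum(p * non_v["decrement_sf6d"].to_numpy())),
        }

    @property
    def mean_survival_factor(self) -> dict[str, float]:
        """Prevalence-weighted mean of (1 - decrement) (the multiplicative truth ratio)."""
        non_v = self.catalog[~self.catalog["is_v"]]
        p = non_v["prevalence"].to_numpy()
        return {
            "eq5d": float(np.sum(p * (1.0 - non_v["decrement_eq5d"].to_numpy()))),
            "sf6d": float(np.sum(p * (1.0 - non_v["decrement_sf6d"].to_numpy()))),
        }


def _stream(seed: int, stage: int) -> np.random.Generator:
    # independent per-stage streams so optional stages never shift the others
    return np.random.default_rng([seed, stage])


def generate_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic code catalog with true per-instrument decrements.

    V-codes are included (per ``v_code_fraction``) and carry drawn decrements
    like any code, but the cohort generator never lets them touch utilities.
    """
    config.validate()
    rng = _stream(config.seed, 0)
    n_v = int(round(config.catalog_size * config.v_code_fraction))
    n_num = config.catalog_size - n_v
    numeric = rng.choice(np.arange(1, 1000), size=n_num, replace=False)
    codes = [f"{c:03d}" for c in numeric]
    is_v = [False] * n_num
    if n_v > 0:
        vcodes = rng.choice(np.arange(1, 92), size=min(n_v, 91), replace=False)
        codes += [f"V{c:02d}" for c in vcodes]
        is_v += [True] * len(vcodes)
    if config.decrement_shape > 0:
        dec = rng.gamma(
            config.decrement_shape,
            config.decrement_mean / config.decrement_shape,
            size=len(codes),
        )
    else:
        dec = np.full(len(codes), config.decrement_mean)
    # sampling probability of each non-V code ~ 1/rank**a; V-codes get 0 here
    # (their record rate is governed separately by v_record_rate)
    n_real = n_num
    ranks = np.arange(1, n_real + 1, dtype=float)
    raw = ranks ** -config.code_zipf_exponent
    prevalence = np.concatenate([raw / raw.sum(), np.zeros(len(codes) - n_real)])
    return pd.DataFrame(
        {
            "code": codes,
            "is_v": is_v,
            "prevalence": prevalence,
            "decrement_eq5d": dec,
            "decrement_sf6d": config.sf6d_decrement_scale * dec,
        }
    ).set_index("code")


def _beta_noise(rng: np.random.Generator, mean, sd, floor, ceiling):
    """Draw from Beta rescaled to [floor, ceiling] with the given mean and sd."""
    span = ceiling - floor
    m = (np.asarray(mean, dtype=float) - floor) / span
    m = np.clip(m, 1e-9, 1.0 - 1e-9)
    s = sd / span
    s_max = np.sqrt(m * (1.0 - m))
    s_eff = np.minimum(s, 0.98 * s_max)
    nu = m * (1.0 - m) / np.square(s_eff) - 1.0
    draws = rng.beta(m * nu, (1.0 - m) * nu)
    return floor + span * draws


def _observe(rng, mu, sd, floor, ceiling, kind):
    mu = np.clip(mu, floor, ceiling)
    if sd == 0:
        return mu
    if kind == "beta":
        return _beta_noise(rng, mu, sd, floor, ceiling)
    return np.clip(mu + rng.normal(0.0, sd, size=len(mu)), floor, ceiling)


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a synthetic cohort and its ground truth, bit-reproducibly."""
    config.validate()
    catalog = generate_catalog(config)
    non_v = catalog[~catalog["is_v"]]
    n = config.n_persons
    person_ids = pd.Index([f"p{i:06d}" for i in range(n)], name="person_id")

    # diagnosis counts (true NoD), ages coupled to counts, sex coupled to counts
    rng_nod = _stream(config.seed, 1)
    p_nb = config.nod_dispersion / (config.nod_dispersion + config.nod_mean)
    nod = rng_nod.negative_binomial(config.nod_dispersion, p_nb, size=n)

    rng_demo = _stream(config.seed, 2)
    age = np.round(
        rng_demo.normal(config.age_mean, config.age_sd, size=n)
        + config.age_nod_coupling * nod
    )
    age = np.clip(age, config.age_min, config.age_max).astype(int)
    if config.under18_fraction > 0:
        minors = rng_demo.random(n) < config.under18_fraction
        age[minors] = rng_demo.integers(5, config.age_min, size=int(minors.sum()))
    p_male = expit(logit(config.male_fraction) - config.sex_nod_coupling * (nod - config.nod_mean))
    sex = (rng_demo.random(n) < p_male).astype(int)

    # morbidity records: codes drawn i.i.d. with replacement from the non-V catalog
    rng_codes = _stream(config.seed, 3)
    code_idx = rng_codes.choice(
        len(non_v), size=int(nod.sum()), p=non_v["prevalence"].to_numpy()
    )
    record_person = np.repeat(np.arange(n), nod)
    diagnoses = pd.DataFrame(
        {
            "person_id": person_ids.to_numpy()[record_person],
            "code": non_v.index.to_numpy()[code_idx],
        }
    )

    # expected utility per instrument from the generative form
    dec_sum = {}
    log_surv = {}
    for inst in ("eq5d", "sf6d"):
        d = non_v[f"decrement_{inst}"].to_numpy()[code_idx]
        dec_sum[inst] = np.bincount(record_person, weights=d, minlength=n)
        log_surv[inst] = np.bincount(record_person, weights=np.log1p(-d), minlength=n)

    age_term = config.age_effect * (age - age.mean())
    sex_term = config.sex_effect * sex
    expected = {}
    for inst, baseline in (("eq5d", config.baseline_eq5d), ("sf6d", config.baseline_sf6d)):
        if config.generative_form == "additive":
            mu = baseline - dec_sum[inst] + age_term + sex_term
        else:
            mu = baseline * np.exp(log_surv[inst]) + age_term + sex_term
        floor = config.floor_eq5d if inst == "eq5d" else config.floor_sf6d
        expected[inst] = np.clip(mu, floor, config.ceiling)

    # observed utilities (independent noise per instrument)
    rng_noise_eq = _stream(config.seed, 4)
    rng_noise_sf = _stream(config.seed, 5)
    eq5d = _observe(
        rng_noise_eq, expected["eq5d"], config.noise_sd, config.floor_eq5d,
        config.ceiling, config.noise_kind,
    )
    sf6d = _observe(
        rng_noise_sf, expected["sf6d"], config.noise_sd, config.floor_sf6d,
        config.ceiling, config.noise_kind,
    )

    if config.missing_fraction > 0:
        rng_missing = _stream(config.seed, 6)
        eq5d = np.where(rng_missing.random(n) < config.missing_fraction, np.nan, eq5d)
        sf6d = np.where(rng_missing.random(n) < config.missing_fraction, np.nan, sf6d)

    # V-coded service-contact records: appended last, from their own stream,
    # so they can never perturb the utilities above
    v_catalog = catalog[catalog["is_v"]]
    if len(v_catalog) > 0 and config.v_record_rate > 0:
        rng_v = _stream(config.seed, 7)
        v_counts = rng_v.poisson(config.v_record_rate, size=n)
        v_idx = rng_v.integers(0, len(v_catalog), size=int(v_counts.sum()))
        v_records = pd.DataFrame(
            {
                "person_id": person_ids.to_numpy()[np.repeat(np.arange(n), v_counts)],
                "code": v_catalog.index.to_numpy()[v_idx],
            }
        )
        diagnoses = pd.concat([diagnoses, v_records], ignore_index=True)

    persons = pd.DataFrame(
        {"age": age, "sex": sex, "eq5d": eq5d, "sf6d": sf6d}, index=person_ids
    )
    cohort = Cohort(
        persons=persons,
        diagnoses=diagnoses,
        label=f"synthetic({config.generative_form}, seed={config.seed})",
    )
    truth = GroundTruth(
        config=config,
        catalog=catalog,
        expected=pd.DataFrame(expected, index=person_ids),
        true_nod=pd.Series(nod, index=person_ids, name="true_nod"),
    )
    logger.info(
        "generated %d persons, %d diagnosis records (%s truth)",
        n,
        len(diagnoses),
        config.generative_form,
    )
    return cohort, truth


def write_cohort(
    cohort: Cohort, truth: GroundTruth | None, out_dir: str | Path
) -> dict[str, Path]:
    """Write persons/conditions tables (CSV) plus a ground-truth YAML sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "persons": out_dir / "persons.csv",
        "conditions": out_dir / "conditions.csv",
    }
    cohort.persons.reset_index().to_csv(paths["persons"], index=False)
    cohort.diagnoses.rename(columns={"code": "icd9"}).to_csv(paths["conditions"], index=False)
    if truth is not None:
        paths["truth"] = out_dir / "truth.yaml"
        sidecar = {
            "config": asdict(truth.config),
            "mean_decrement": truth.mean_decrement,
            "mean_survival_factor": truth.mean_survival_factor,
            "catalog": {
                code: {
                    "is_v": bool(row["is_v"]),
                    "decrement_eq5d": float(row["decrement_eq5d"]),
                    "decrement_sf6d": float(row["decrement_sf6d"]),
                }
                for code, row in truth.catalog.iterrows()
            },
        }
        paths["truth"].write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return paths
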