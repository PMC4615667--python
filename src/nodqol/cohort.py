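"""Person/condition tables, inclusion criteria, and diagnosis counting.

The cohort layer turns two delimited text files -- a person table (one row per
respondent with age, sex, and pre-scored EQ-5D and SF-6D utility indices) and a
conditions table (one row per registered occurrence of a 3-character truncated
ICD-9-CM code) -- into a :class:`Cohort`, applies the adult/valid-utilities
inclusion criteria, and computes the number-of-diagnoses (NoD) variable.

Conventions baked in here and relied on downstream:

* Diagnosis codes are *text*, never integers: ``"001"`` and ``"1"`` are distinct
  and V-codes (``"V01"``-``"V91"``) are legal values. Leading zeros matter.
* Repeated ``(person, code)`` rows are meaningful -- 3-digit truncation collapses
  distinct underlying diagnoses onto the same code, so occurrences are counted
  with multiplicity.
* V-codes record health-service contacts rather than morbidity and are omitted
  from every diagnosis count.
* Sex is coded male = 1, female = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

logger = logging.getLogger(__name__)

#: Default column names expected in the input files; override via ``column_map``.
DEFAULT_COLUMNS = {
    "person_id": "person_id",
    "age": "age",
    "sex": "sex",
    "eq5d": "eq5d",
    "sf6d": "sf6d",
    "icd9": "icd9",
}

#: Extra strings treated as missing values on top of pandas defaults.
NA_MARKERS = ["NA", "."]

INSTRUMENTS = ("eq5d", "sf6d")


@dataclass
class Cohort:
    """A joined person/conditions dataset.

    Attributes
    ----------
    persons
        DataFrame indexed by person id with columns ``age`` (years), ``sex``
        (male=1), ``eq5d`` and ``sf6d`` (utility indices, NaN when missing).
    diagnoses
        DataFrame with columns ``person_id`` and ``code`` (3-character text),
        one row per registered occurrence.
    label
        Free-text provenance tag carried through reports.
    """

    persons: pd.DataFrame
    diagnoses: pd.DataFrame
    label: str = ""

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_diagnosis_records(self) -> int:
        return len(self.diagnoses)

    def subset(self, person_ids) -> "Cohort":
        """Restrict to the given persons, dropping their absent diagnosis rows."""
        persons = self.persons.loc[self.persons.index.isin(person_ids)]
        diagnoses = self.diagnoses[self.diagnoses["person_id"].isin(persons.index)]
        return replace(self, persons=persons, diagnoses=diagnoses.reset_index(drop=True))


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    # sep=None sniffs comma vs tab from the header line
    return pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        na_values=NA_MARKERS,
        dtype=str,
        skipinitialspace=True,
    )


def _require(frame: pd.DataFrame, names: dict[str, str], keys: list[str], origin: str) -> None:
    for key in keys:
        if names[key] not in frame.columns:
            raise SchemaError(
                f"{origin}: required column {names[key]!r} (role {key!r}) not found; "
                f"available: {list(frame.columns)}"
            )


def read_cohort(
    persons_path: str | Path,
    conditions_path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
    label: str | None = None,
) -> Cohort:
    """Read the person and conditions tables and join them into a :class:`Cohort`.

    Both files are delimited text (comma by default, tab accepted) with a header
    row; empty fields, ``NA`` and ``.`` are treated as missing. Condition rows
    whose person id matches no person ("orphans") are dropped with a logged
    count, as are rows with an empty code.
    """
    names = {**DEFAULT_COLUMNS, **(column_map or {})}

    raw_persons = _read_table(persons_path, sep)
    _require(raw_persons, names, ["person_id", "age", "sex", "eq5d", "sf6d"], str(persons_path))
    persons = pd.DataFrame(
        {
            "age": pd.to_numeric(raw_persons[names["age"]], errors="coerce").to_numpy(),
            "sex": pd.to_numeric(raw_persons[names["sex"]], errors="coerce").to_numpy(),
            "eq5d": pd.to_numeric(raw_persons[names["eq5d"]], errors="coerce").to_numpy(),
            "sf6d": pd.to_numeric(raw_persons[names["sf6d"]], errors="coerce").to_numpy(),
        },
        index=pd.Index(raw_persons[names["person_id"]].astype(str).str.strip(), name="person_id"),
    )

    raw_cond = _read_table(conditions_path, sep)
    if len(raw_cond) > 0:
        _require(raw_cond, names, ["person_id", "icd9"], str(conditions_path))
        diagnoses = pd.DataFrame(
            {
                "person_id": raw_cond[names["person_id"]].astype(str).str.strip(),
                "code": raw_cond[names["icd9"]].astype(str).str.strip(),
            }
        )
        empty = diagnoses["code"].isin(["", "nan"]) | raw_cond[names["icd9"]].isna()
        if empty.any():
            logger.warning("dropping %d condition rows with empty codes", int(empty.sum()))
            diagnoses = diagnoses[~empty]
        orphan = ~diagnoses["person_id"].isin(persons.index)
        if orphan.any():
            logger.warning(
                "dropping %d orphan condition rows (person id not in person table)",
                int(orphan.sum()),
            )
            diagnoses = diagnoses[~orphan]
        diagnoses = diagnoses.reset_index(drop=True)
    else:
        diagnoses = pd.DataFrame({"person_id": pd.Series(dtype=str), "code": pd.Series(dtype=str)})

    logger.info(
        "read cohort: %d persons, %d diagnosis records", len(persons), len(diagnoses)
    )
    return Cohort(persons=persons, diagnoses=diagnoses, label=label or str(persons_path))


def apply_inclusion(cohort: Cohort, min_age: int = 18) -> Cohort:
    """Retain adults (``age >= min_age``) with valid data for *both* instruments.

    Diagnosis records of excluded persons are removed. Idempotent; may return an
    empty cohort.
    """
    if min_age < 0:
        raise ValueError("min_age must be non-negative")
    persons = cohort.persons
    keep = (
        (persons["age"] >= min_age)
        & persons["eq5d"].notna()
        & persons["sf6d"].notna()
    )
    excluded = int((~keep).sum())
    if excluded:
        logger.info(
            "inclusion: excluded %d of %d persons (age < %d or missing utility)",
            excluded,
            len(persons),
            min_age,
        )
    return cohort.subset(persons.index[keep])


def is_vcode(code: str) -> bool:
    """True iff the (whitespace-stripped) code starts with ``V`` or ``v``.

    V-codes are ICD-9 supplementary classification codes for non-disease
    health-service contacts and are excluded from diagnosis counts.
    """
    code = code.strip()
    if not code:
        raise ValueError("empty diagnosis code")
    return code[0] in ("V", "v")


def count_diagnoses(cohort: Cohort) -> pd.Series:
    """Number of diagnoses (NoD) per person: non-V records counted with multiplicity.

    Returns an integer Series over *every* person in the cohort; persons with no
    (non-V) records get 0.
    """
    diag = cohort.diagnoses
    if len(diag) > 0:
        non_v = diag[~diag["code"].str.strip().str.upper().str.startswith("V")]
        counts = non_v.groupby("person_id").size()
    else:
        counts = pd.Series(dtype=np.int64)
    nod = counts.reindex(cohort.persons.index, fill_value=0).astype(np.int64)
    nod.name = "nod"
    return nod
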