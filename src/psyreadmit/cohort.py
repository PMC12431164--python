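"""Cohort construction from raw encounter streams.

Pipeline: merge overlapping inpatient encounters into stays
(:func:`merge_encounters`), attach the 30-day readmission label
(:func:`label_instances`), derive model covariates from billing codes and
demographics (:func:`build_covariates`), and split train/test by patient
identifier (:func:`split_train_test`).  :func:`build_cohort` chains the four
steps.

Conventions (day-granularity closed intervals throughout):

* encounters of one patient whose date intervals intersect — including
  same-day adjacency, i.e. a transfer admitted on the discharge day — are
  unioned into a single stay spanning min(admit) to max(discharge);
* a stay is labeled readmitted iff the patient's next inpatient stay (any
  site, any diagnosis) admits at most 30 days after this stay's discharge
  (inclusive boundary); the last stay of a patient is labeled not readmitted;
* classification instances are the mental-health-related stays; by default a
  stay qualifies if it carries any ICD-10 F-chapter code ("any_f"); the
  stricter mood/psychosis rule (codes F2x/F3x only) is available as "f2f3".
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENCOUNTER_COLUMNS = [
    "patient_id", "site", "admit_date", "discharge_date", "inpatient_flag", "icd_codes",
]

_CODE_RE = re.compile(r"^[A-Za-z]\d{2}")

#: ICD-10 numeric sub-ranges of chapter F defining the four diagnosis flags.
DIAGNOSIS_RANGES = {
    "psychosis": (20, 29),
    "mood": (30, 39),
    "anxiety": (40, 48),
    "sud": (10, 19),
}


def read_encounters(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "icd_codes": str})
    for col in ("admit_date", "discharge_date"):
        df[col] = pd.to_datetime(df[col])
    df["inpatient_flag"] = df["inpatient_flag"].astype(bool)
    df["icd_codes"] = df["icd_codes"].fillna("")
    return df


def read_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    return df


def _split_codes(joined: str) -> list[str]:
    return [c for c in str(joined).split(";") if c]


def merge_encounters(encounters: pd.DataFrame) -> pd.DataFrame:
    """Merge each patient's overlapping inpatient encounters into stays.

    Records with discharge before admit are rejected (count logged).
    Outpatient encounters are excluded from stay creation.  The merged stay
    takes the site of its earliest component and the union of ICD codes.
    """
    df = encounters.copy()
    df["admit_date"] = pd.to_datetime(df["admit_date"])
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])
    bad = df["discharge_date"] < df["admit_date"]
    if bad.any():
        logger.warning("rejected %d encounters with discharge before admit", int(bad.sum()))
        df = df.loc[~bad]
    inpt = df.loc[df["inpatient_flag"].astype(bool)].copy()
    if len(inpt) == 0:
        return pd.DataFrame(
            columns=["patient_id", "site", "admit_date", "discharge_date",
                     "los", "icd_codes", "n_components"]
        )
    inpt = inpt.sort_values(
        ["patient_id", "admit_date", "discharge_date"], kind="mergesort"
    ).reset_index(drop=True)

    grp = inpt.groupby("patient_id", sort=False)
    prev_max_discharge = grp["discharge_date"].cummax().groupby(inpt["patient_id"]).shift(1)
    new_stay = prev_max_discharge.isna() | (inpt["admit_date"] > prev_max_discharge)
    stay_id = new_stay.cumsum()

    def _union_codes(series) -> str:
        codes: set[str] = set()
        for joined in series:
            codes.update(_split_codes(joined))
        return ";".join(sorted(codes))

    merged = (
        inpt.assign(_stay=stay_id)
        .groupby("_stay", sort=True)
        .agg(
            patient_id=("patient_id", "first"),
            site=("site", "first"),  # earliest component (sorted by admit)
            admit_date=("admit_date", "min"),
            discharge_date=("discharge_date", "max"),
            icd_codes=("icd_codes", _union_codes),
            n_components=("icd_codes", "size"),
        )
        .reset_index(drop=True)
    )
    merged["los"] = (merged["discharge_date"] - merged["admit_date"]).dt.days
    return merged[
        ["patient_id", "site", "admit_date", "discharge_date", "los",
         "icd_codes", "n_components"]
    ]


def _is_classification(codes: list[str], inclusion: str) -> bool:
    if inclusion == "any_f":
        return any(c[:1].upper() == "F" for c in codes)
    if inclusion == "f2f3":
        return any(c[:1].upper() == "F" and len(c) > 1 and c[1] in "23" for c in codes)
    raise ValueError(f"unknown inclusion rule {inclusion!r}")


def label_instances(stays: pd.DataFrame, inclusion: str = "any_f") -> pd.DataFrame:
    """Attach the 30-day readmission label and classification membership.

    Label rule: readmitted iff the patient's next inpatient stay admits
    within 30 days (inclusive) of this stay's discharge; a stay with no
    successor is not readmitted.  Exact duplicate stays are dropped with a
    warning.  ``classification_instance`` marks stays eligible as prediction
    units under the ``inclusion`` rule; ``mood_psychosis_related`` flags
    F2x/F3x stays regardless of the rule.
    """
    df = stays.copy()
    n0 = len(df)
    df = df.drop_duplicates(subset=["patient_id", "admit_date", "discharge_date"])
    if len(df) < n0:
        logger.warning("dropped %d duplicate stays", n0 - len(df))
    df = df.sort_values(["patient_id", "admit_date"], kind="mergesort").reset_index(drop=True)
    next_admit = df.groupby("patient_id", sort=False)["admit_date"].shift(-1)
    gap = (next_admit - df["discharge_date"]).dt.days
    df["readmitted"] = gap.le(30).fillna(False).astype(bool)
    code_lists = df["icd_codes"].map(_split_codes)
    df["mood_psychosis_related"] = code_lists.map(
        lambda cs: _is_classification(cs, "f2f3")
    )
    df["classification_instance"] = code_lists.map(
        lambda cs: _is_classification(cs, inclusion)
    )
    return df


def build_covariates(
    instances: pd.DataFrame, demographics: pd.DataFrame
) -> pd.DataFrame:
    """Derive the model covariates for each stay.

    Age at discharge in whole years from the patient's birth date; diagnosis
    flags from ICD-10 code ranges (psychosis F20-F29, mood F30-F39, anxiety
    F40-F48, SUD F10-F19); sex and race from the demographics table.  Code
    strings that do not start with a letter and two digits are ignored (count
    logged).
    """
    df = instances.merge(
        demographics[["patient_id", "birth_date", "sex", "race"]],
        on="patient_id", how="left", validate="many_to_one",
    )
    if df["birth_date"].isna().any():
        missing = df.loc[df["birth_date"].isna(), "patient_id"].unique()
        raise ValueError(f"no demographics for patients: {missing[:5]!r}...")
    d, b = df["discharge_date"], df["birth_date"]
    before_birthday = (d.dt.month < b.dt.month) | (
        (d.dt.month == b.dt.month) & (d.dt.day < b.dt.day)
    )
    df["age"] = (d.dt.year - b.dt.year - before_birthday.astype(int)).astype(int)

    n_unparseable = 0

    def _flags(joined: str) -> tuple[bool, ...]:
        nonlocal n_unparseable
        hits = dict.fromkeys(DIAGNOSIS_RANGES, False)
        for code in _split_codes(joined):
            if not _CODE_RE.match(code):
                n_unparseable += 1
                continue
            if code[0].upper() != "F":
                continue
            num = int(code[1:3])
            for flag, (lo, hi) in DIAGNOSIS_RANGES.items():
                if lo <= num <= hi:
                    hits[flag] = True
        return tuple(hits[f] for f in DIAGNOSIS_RANGES)

    flags = np.array([_flags(j) for j in df["icd_codes"]], dtype=bool).reshape(
        len(df), len(DIAGNOSIS_RANGES)
    )
    for j, flag in enumerate(DIAGNOSIS_RANGES):
        df[flag] = flags[:, j]
    if n_unparseable:
        logger.warning("ignored %d unparseable ICD code strings", n_unparseable)
    return df.drop(columns=["birth_date"])


# ---------------------------------------------------------------------------
# Patient-identifier train/test split
# ---------------------------------------------------------------------------


def _id_digits(patient_id: str) -> str:
    digits = "".join(c for c in str(patient_id) if c.isdigit())
    if len(digits) >= 2:
        return digits
    # stable fallback for identifiers without (enough) decimal digits
    h = hashlib.md5(str(patient_id).encode()).hexdigest()
    return str(int(h, 16) % 100).zfill(2)


def in_test_split(patient_id: str) -> bool:
    """Pure function of the patient identifier giving an expected 1/4 test
    fraction over uniform trailing digits.

    Rule: with d the last digit and e the second-to-last digit of the
    identifier, assign to test iff d in {0, 1}, or d == 2 and e is even.
    A patient therefore lands in the same partition at every site.
    """
    digits = _id_digits(patient_id)
    d, e = int(digits[-1]), int(digits[-2])
    return d in (0, 1) or (d == 2 and e % 2 == 0)


def split_train_test(
    instances: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition instances into (train, test) by patient identifier."""
    if len(instances) == 0:
        return instances.copy(), instances.copy()
    is_test = instances["patient_id"].map(in_test_split).astype(bool)
    return instances.loc[~is_test].copy(), instances.loc[is_test].copy()


@dataclass
class SiteCohort:
    """All classification instances of one site, partitioned train/test."""

    site: str
    train: pd.DataFrame
    test: pd.DataFrame

    @classmethod
    def from_instances(cls, site: str, instances: pd.DataFrame) -> "SiteCohort":
        train, test = split_train_test(instances)
        return cls(site=site, train=train, test=test)


def build_cohort(
    encounters: pd.DataFrame,
    demographics: pd.DataFrame,
    inclusion: str = "any_f",
) -> pd.DataFrame:
    """Raw encounters -> labeled, covariate-complete classification instances."""
    stays = merge_encounters(encounters)
    labeled = label_instances(stays, inclusion=inclusion)
    full = build_covariates(labeled, demographics)
    return full.loc[full["classification_instance"]].reset_index(drop=True)


def site_cohorts(instances: pd.DataFrame) -> list[SiteCohort]:
    """Split a multi-site instance table into per-site cohorts."""
    return [
        SiteCohort.from_instances(site, grp.reset_index(drop=True))
        for site, grp in instances.groupby("site", sort=True)
    ]


def write_instances(instances: pd.DataFrame, path) -> None:
    out = instances.copy()
    for col in ("admit_date", "discharge_date"):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_instances(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in ("admit_date", "discharge_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    for col in ("psychosis", "mood", "anxiety", "sud", "readmitted"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
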