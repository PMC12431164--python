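"""Synthetic multi-site EHR generator.

Produces cohorts with the statistical structure the analysis assumes, in two
forms:

* **instance form** — one row per merged inpatient stay with covariates and a
  binary 30-day readmission label, drawn from per-site marginals and a
  logistic outcome model (:func:`simulate_instances`,
  :func:`simulate_scenario`);
* **raw encounter-stream form** — one row per hospital encounter with admit
  and discharge dates and ICD-10 billing codes, constructed so that the
  cohort builder recovers exactly the instances that generated it
  (:func:`instances_to_encounters`).  A configurable fraction of stays is
  emitted as split/overlapping encounter pairs that must re-merge.

Distributional choices: LOS is log-normal matched to the per-site median and
IQR (truncated to [0, 365], whole days); age is truncated normal on the study
inclusion range [18, 65] with parent parameters solved so the *truncated*
moments match the published mean/SD, rounded to whole years; sex, race and
the four diagnosis flags are categorical/Bernoulli draws.  Covariates are
drawn independently (only marginals are published).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .config import (
    AGE_CENTER,
    AGE_SCALE,
    DIAG_FLAGS,
    LOS_CENTER,
    LOS_SCALE,
    RACE_LEVELS,
    ShiftScenario,
    SiteConfig,
)
from .design import build_design

logger = logging.getLogger(__name__)

#: Fixed entropy for intercept calibration draws, so calibrated defaults are
#: stable across processes.
CALIBRATION_SEED = 904_231

EPOCH = pd.Timestamp("2015-01-01")

# ICD-10 code pools per diagnosis flag (psychosis F20-F29, mood F30-F39,
# anxiety F40-F48, SUD F10-F19).  Instances with none of the four flags get a
# residual psychiatric code outside all four ranges.
_CODE_POOLS = {
    "psychosis": ("F20.9", "F25.0", "F29"),
    "mood": ("F31.9", "F32.9", "F33.1"),
    "anxiety": ("F41.1", "F41.9", "F43.10"),
    "sud": ("F10.20", "F11.20", "F19.10"),
}
_RESIDUAL_CODE = "F60.3"
_FOLLOWUP_CODES = ("J18.9", "I10", "K35.80")
_OUTPATIENT_CODE = "Z00.00"


def stable_site_code(name: str) -> int:
    """Deterministic small integer derived from a site name (for seeding)."""
    return int(hashlib.md5(name.encode()).hexdigest()[:6], 16)


@lru_cache(maxsize=64)
def _truncnorm_parent_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) such that N(mu, sigma) truncated to [lo, hi] has the
    requested mean and SD.  Falls back to (mean, sd) if the solver fails."""

    def resid(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.root(resid, x0=[mean, math.log(sd * 1.2)], tol=1e-10)
    if not sol.success:  # pragma: no cover - defensive
        logger.warning("truncated-normal moment matching failed; using naive params")
        return mean, sd
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def draw_covariates(config: SiteConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` independent covariate rows from the config's marginals."""
    p_male, p_miss = config.sex_male, config.sex_missing
    sex = rng.choice(
        np.array(["female", "male", "missing"]),
        size=n,
        p=[1.0 - p_male - p_miss, p_male, p_miss],
    )
    race = rng.choice(
        np.array(RACE_LEVELS), size=n, p=[config.race_probs[r] for r in RACE_LEVELS]
    )
    lo, hi = config.age_bounds
    mu, sigma = _truncnorm_parent_params(config.age_mean, config.age_sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    age = np.rint(stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng))
    age = np.clip(age, lo, hi).astype(int)
    los = np.exp(math.log(config.los_median) + config.los_sigma * rng.standard_normal(n))
    los = np.minimum(np.rint(los), config.los_max).astype(int)
    cols = {"age": age, "sex": sex, "race": race}
    for flag in DIAG_FLAGS:
        cols[flag] = rng.random(n) < config.diag_rates[flag]
    cols["los"] = los
    return pd.DataFrame(cols)


def linear_predictor(config: SiteConfig, covariates: pd.DataFrame) -> np.ndarray:
    """True-model linear predictor (including any nonlinear terms), without
    the intercept."""
    X = build_design(covariates)
    lp = np.zeros(len(X))
    for name, beta in config.coef.items():
        lp += beta * X[name].to_numpy()
    if config.los_sq_coef or config.los_age_coef:
        zlos = (X["los"].to_numpy() - LOS_CENTER) / LOS_SCALE
        zage = (X["age"].to_numpy() - AGE_CENTER) / AGE_SCALE
        lp += config.los_sq_coef * zlos**2 + config.los_age_coef * zlos * zage
    return lp


def calibrate_intercept(
    config: SiteConfig,
    n_draws: int = 200_000,
    seed: int = CALIBRATION_SEED,
    tol: float = 1e-3,
) -> SiteConfig:
    """Solve for the intercept so that marginal prevalence matches
    ``config.target_prevalence`` on a large fixed covariate sample.

    Bisection (Brent) on the monotone map intercept -> mean predicted
    probability, to within ``tol`` on the prevalence scale.
    """
    if config.target_prevalence is None:
        raise ValueError("target_prevalence must be set to calibrate the intercept")
    rng = np.random.default_rng(np.random.SeedSequence([seed, stable_site_code(config.site_name)]))
    lp = linear_predictor(config, draw_covariates(config, n_draws, rng))
    target = config.target_prevalence

    def gap(b0: float) -> float:
        return float(np.mean(special.expit(b0 + lp))) - target

    b0 = optimize.brentq(gap, -25.0, 25.0, xtol=1e-6)
    achieved = gap(b0) + target
    if abs(achieved - target) > tol:  # pragma: no cover - defensive
        raise RuntimeError("intercept calibration did not reach tolerance")
    return config.with_(intercept=float(b0))


def draw_labels(
    config: SiteConfig, covariates: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli 30-day-readmission labels from the site's outcome model."""
    if config.intercept is None:
        raise ValueError(
            f"site {config.site_name!r} has no intercept; calibrate it first"
        )
    p = special.expit(config.intercept + linear_predictor(config, covariates))
    return rng.random(len(covariates)) < p


def simulate_instances(config: SiteConfig, seed: int) -> pd.DataFrame:
    """Simulate ``config.n_instances`` labeled classification instances.

    Returns one row per instance: ``patient_id`` (unique per instance), site,
    covariates and the boolean ``readmitted`` label.  Fully reproducible
    given ``seed``.
    """
    cfg = config if config.intercept is not None else calibrate_intercept(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, stable_site_code(cfg.site_name)])
    )
    n = cfg.n_instances
    df = draw_covariates(cfg, n, rng)
    df.insert(0, "patient_id", [f"{cfg.site_name}-P{i:07d}" for i in range(n)])
    df.insert(1, "site", cfg.site_name)
    df["readmitted"] = draw_labels(cfg, df, rng)
    return df


def simulate_scenario(scenario: ShiftScenario, seed: int) -> dict[str, pd.DataFrame]:
    """Simulate instance tables for every site of a scenario.

    Cross-site patient overlap: per site, ``overlap_fraction`` of instances
    take their patient identifier from a shared pool.  Demographics (age,
    sex, race) of a shared patient are harmonised to whichever site first
    drew that patient, before labels are drawn, so a shared patient is
    internally consistent across sites.
    """
    site_tables: dict[str, pd.DataFrame] = {}
    rngs: dict[str, np.random.Generator] = {}
    calibrated: dict[str, SiteConfig] = {}
    for cfg in scenario.site_configs:
        cfg = cfg if cfg.intercept is not None else calibrate_intercept(cfg)
        calibrated[cfg.site_name] = cfg
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, stable_site_code(cfg.site_name)])
        )
        rngs[cfg.site_name] = rng
        df = draw_covariates(cfg, cfg.n_instances, rng)
        df.insert(
            0,
            "patient_id",
            [f"{cfg.site_name}-P{i:07d}" for i in range(cfg.n_instances)],
        )
        df.insert(1, "site", cfg.site_name)
        site_tables[cfg.site_name] = df

    n_shared = {
        c.site_name: int(round(c.overlap_fraction * c.n_instances))
        for c in scenario.site_configs
    }
    total_shared = sum(n_shared.values())
    if total_shared > 0:
        pool_size = max(1, math.ceil(total_shared / 2))
        registry: dict[str, tuple] = {}
        for cfg in scenario.site_configs:
            name, k = cfg.site_name, n_shared[cfg.site_name]
            if k == 0:
                continue
            rng, df = rngs[name], site_tables[name]
            rows = rng.choice(cfg.n_instances, size=k, replace=False)
            pool_ids = rng.choice(pool_size, size=k, replace=k > pool_size)
            for row, pid in zip(rows, pool_ids):
                shared_id = f"SH-P{pid:07d}"
                df.iat[row, df.columns.get_loc("patient_id")] = shared_id
                if shared_id in registry:
                    age, sex, race = registry[shared_id]
                    df.iat[row, df.columns.get_loc("age")] = age
                    df.iat[row, df.columns.get_loc("sex")] = sex
                    df.iat[row, df.columns.get_loc("race")] = race
                else:
                    registry[shared_id] = (
                        df.iat[row, df.columns.get_loc("age")],
                        df.iat[row, df.columns.get_loc("sex")],
                        df.iat[row, df.columns.get_loc("race")],
                    )

    for name, df in site_tables.items():
        df["readmitted"] = draw_labels(calibrated[name], df, rngs[name])
    return site_tables


# ---------------------------------------------------------------------------
# Instance -> raw encounter-stream emission
# ---------------------------------------------------------------------------


@dataclass
class EncounterBundle:
    """Raw encounter stream plus the ground truth it encodes.

    ``instances`` is the *realised* instance table: identical to the input
    up to ages recomputed from each patient's single birth date when one
    patient carries several stays.
    """

    encounters: pd.DataFrame
    demographics: pd.DataFrame
    instances: pd.DataFrame


def _age_at(birth: pd.Timestamp, date: pd.Timestamp) -> int:
    return date.year - birth.year - ((date.month, date.day) < (birth.month, birth.day))


def _instance_codes(row, rng: np.random.Generator) -> list[str]:
    codes = [
        str(rng.choice(_CODE_POOLS[flag])) for flag in DIAG_FLAGS if bool(row[flag])
    ]
    return codes or [_RESIDUAL_CODE]


def instances_to_encounters(
    instances: pd.DataFrame,
    config: SiteConfig | None = None,
    seed: int = 0,
    split_fraction: float | None = None,
    outpatient_rate: float = 0.3,
    negative_followup_rate: float = 0.5,
) -> EncounterBundle:
    """Emit a raw encounter stream that the cohort builder merges back into
    exactly the given instances.

    * Each stay spans ``los`` whole days and carries one ICD-10 code per
      diagnosis flag (a residual psychiatric code if no flag is set).
    * ``split_fraction`` of stays are emitted as two overlapping or same-day
      adjacent encounters that must re-merge into one instance.
    * Positive-label stays are followed by a non-psychiatric inpatient
      admission 1-30 days after discharge; negative-label stays by either
      none or one at 31-120 days.  Consecutive stays of one patient are
      spaced by more than 60 days so labels never interact.
    * Outpatient noise visits are interleaved and must be ignored.

    Returns an :class:`EncounterBundle`; encounter rows are shuffled so that
    downstream processing cannot rely on input order.
    """
    if split_fraction is None:
        split_fraction = config.encounter_split_fraction if config is not None else 0.2
    rng = np.random.default_rng(np.random.SeedSequence([seed, 40_517]))
    realized = instances.reset_index(drop=True).copy()
    if len(realized) == 0:
        empty_enc = pd.DataFrame(
            columns=["patient_id", "site", "admit_date", "discharge_date",
                     "inpatient_flag", "icd_codes"]
        )
        empty_dem = pd.DataFrame(columns=["patient_id", "birth_date", "sex", "race"])
        return EncounterBundle(empty_enc, empty_dem, realized)

    realized["admit_date"] = pd.NaT
    realized["discharge_date"] = pd.NaT
    enc_rows: list[tuple] = []
    demo_rows: list[tuple] = []

    def emit(pid, site, admit, discharge, inpatient, codes):
        enc_rows.append((pid, site, admit, discharge, inpatient, ";".join(codes)))

    for pid, idx in realized.groupby("patient_id", sort=True).groups.items():
        idx = list(idx)
        cursor = EPOCH + pd.Timedelta(days=int(rng.integers(0, 365)))
        birth = None
        demo_sex = demo_race = None
        for k, i in enumerate(idx):
            row = realized.loc[i]
            los = int(row["los"])
            admit = cursor
            discharge = admit + pd.Timedelta(days=los)
            if birth is None:
                birth = discharge - pd.DateOffset(years=int(row["age"])) - pd.Timedelta(days=30)
                demo_sex, demo_race = row["sex"], row["race"]
                demo_rows.append((pid, birth, demo_sex, demo_race))
            else:
                w_lo = birth + pd.DateOffset(years=int(row["age"]))
                if discharge < w_lo:
                    admit = w_lo + pd.Timedelta(days=int(rng.integers(0, 60)))
                    discharge = admit + pd.Timedelta(days=los)
                realized.iat[i, realized.columns.get_loc("age")] = _age_at(birth, discharge)
                realized.iat[i, realized.columns.get_loc("sex")] = demo_sex
                realized.iat[i, realized.columns.get_loc("race")] = demo_race
            realized.iat[i, realized.columns.get_loc("admit_date")] = admit
            realized.iat[i, realized.columns.get_loc("discharge_date")] = discharge

            codes = _instance_codes(row, rng)
            site = row["site"]
            if rng.random() < split_fraction:
                if los >= 2:
                    cut = admit + pd.Timedelta(days=int(rng.integers(1, los)))
                    back = int(rng.integers(0, 2))  # 0 = same-day adjacency, 1 = overlap
                    b_admit = max(admit, cut - pd.Timedelta(days=back))
                    emit(pid, site, admit, cut, True, codes)
                    emit(pid, site, b_admit, discharge, True, [codes[0]])
                else:
                    emit(pid, site, admit, discharge, True, codes)
                    emit(pid, site, admit, discharge, True, [codes[0]])
            else:
                emit(pid, site, admit, discharge, True, codes)

            last_end = discharge
            if bool(row["readmitted"]):
                gap = int(rng.integers(1, 31))
                f_admit = discharge + pd.Timedelta(days=gap)
                f_end = f_admit + pd.Timedelta(days=int(rng.integers(1, 6)))
                emit(pid, site, f_admit, f_end, True, [str(rng.choice(_FOLLOWUP_CODES))])
                last_end = f_end
            elif rng.random() < negative_followup_rate:
                gap = int(rng.integers(31, 121))
                f_admit = discharge + pd.Timedelta(days=gap)
                f_end = f_admit + pd.Timedelta(days=int(rng.integers(1, 6)))
                emit(pid, site, f_admit, f_end, True, [str(rng.choice(_FOLLOWUP_CODES))])
                last_end = f_end
            if rng.random() < outpatient_rate:
                visit = last_end + pd.Timedelta(days=int(rng.integers(3, 25)))
                emit(pid, site, visit, visit, False, [_OUTPATIENT_CODE])
                last_end = max(last_end, visit)
            cursor = last_end + pd.Timedelta(days=61 + int(rng.integers(0, 30)))

    encounters = pd.DataFrame(
        enc_rows,
        columns=["patient_id", "site", "admit_date", "discharge_date",
                 "inpatient_flag", "icd_codes"],
    )
    encounters = encounters.iloc[rng.permutation(len(encounters))].reset_index(drop=True)
    demographics = pd.DataFrame(
        demo_rows, columns=["patient_id", "birth_date", "sex", "race"]
    )
    return EncounterBundle(encounters, demographics, realized)


def write_encounters(encounters: pd.DataFrame, path) -> None:
    """UTF-8 CSV, ISO-8601 dates, semicolon-separated ICD codes."""
    out = encounters.copy()
    for col in ("admit_date", "discharge_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_demographics(demographics: pd.DataFrame, path) -> None:
    out = demographics.copy()
    out["birth_date"] = pd.to_datetime(out["birth_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
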