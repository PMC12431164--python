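"""Site-level simulation configuration.

A :class:`SiteConfig` fully specifies one hospital site's synthetic cohort:
marginal covariate distributions (length of stay, legal sex, race, age at
discharge, four psychiatric diagnosis flags), a logistic outcome model on
the log-odds scale, and bookkeeping knobs for cross-site patient overlap and
encounter splitting.  Defaults for the four study sites (MGH, MCL, BWH, FH)
reproduce the published marginal distributions and fitted odds ratios of the
source health-system cohort.

A :class:`ShiftScenario` bundles several SiteConfigs and declares the kind of
cross-site distributional difference they encode: ``none`` (identical sites),
``covariate_shift`` (shared outcome model, different covariate marginals),
``conditional_shift`` (shared marginals, different outcome models), or
``both``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import yaml

RACE_LEVELS = ("White", "Black", "Asian", "Other", "Missing")
SEX_LEVELS = ("female", "male", "missing")
DIAG_FLAGS = ("psychosis", "mood", "anxiety", "sud")

#: Slope names of the outcome model, in the order they are reported.
COEF_NAMES = (
    "age",
    "sex_male",
    "race_Black",
    "race_Asian",
    "race_Other",
    "psychosis",
    "mood",
    "anxiety",
    "sud",
    "los",
)

# Centring/scaling used by the optional nonlinear outcome terms.  Chosen once
# near the pooled medians so the scaled variables are O(1).
LOS_CENTER, LOS_SCALE = 8.0, 10.0
AGE_CENTER, AGE_SCALE = 40.0, 12.0

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class SiteConfig:
    """Generative specification of one site's synthetic cohort."""

    site_name: str
    n_instances: int
    # --- covariate marginals ---
    sex_male: float
    race_probs: dict[str, float]
    age_mean: float
    age_sd: float
    los_median: float
    los_iqr: tuple[float, float]
    diag_rates: dict[str, float]
    sex_missing: float = 0.0
    age_bounds: tuple[float, float] = (18.0, 65.0)
    los_max: float = 365.0
    # --- outcome model (log-odds scale) ---
    coef: dict[str, float] = field(default_factory=dict)
    intercept: float | None = None
    target_prevalence: float | None = None
    #: optional curvature / interaction in the true outcome model, applied to
    #: ((los-8)/10)**2 and ((los-8)/10)*((age-40)/12) respectively.  Both are
    #: zero by default; the fitted models never see these terms.
    los_sq_coef: float = 0.0
    los_age_coef: float = 0.0
    # --- multi-site / encounter-stream knobs ---
    overlap_fraction: float = 0.05
    encounter_split_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_instances <= 0:
            raise ValueError("n_instances must be positive")
        for name, p in [("sex_male", self.sex_male), ("sex_missing", self.sex_missing)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.sex_male + self.sex_missing > 1.0 + _PROB_TOL:
            raise ValueError("sex proportions exceed 1")
        if set(self.race_probs) != set(RACE_LEVELS):
            raise ValueError(f"race_probs must have keys {RACE_LEVELS}")
        total = sum(self.race_probs.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"race proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.race_probs.values()):
            raise ValueError("race proportions must be non-negative")
        for flag in DIAG_FLAGS:
            r = self.diag_rates.get(flag)
            if r is None or not 0.0 <= r <= 1.0:
                raise ValueError(f"diag rate for {flag!r} must lie in [0, 1]")
        q1, q3 = self.los_iqr
        if not (0 <= q1 <= self.los_median <= q3):
            raise ValueError("LOS quartiles must satisfy 0 <= q1 <= median <= q3")
        if self.los_median <= 0:
            raise ValueError("LOS median must be positive")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if not 0.0 <= self.encounter_split_fraction <= 1.0:
            raise ValueError("encounter_split_fraction must lie in [0, 1]")
        unknown = set(self.coef) - set(COEF_NAMES)
        if unknown:
            raise ValueError(f"unknown outcome coefficients: {sorted(unknown)}")

    # frozen dataclass: offer an explicit copy-with-changes helper
    def with_(self, **changes) -> "SiteConfig":
        return replace(self, **changes)

    @property
    def los_sigma(self) -> float:
        """Log-normal sigma implied by the IQR ratio (z_{0.75} = 0.67449)."""
        q1, q3 = self.los_iqr
        return math.log(q3 / q1) / (2.0 * 0.6744897501960817)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["los_iqr"] = list(self.los_iqr)
        d["age_bounds"] = list(self.age_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SiteConfig":
        d = dict(d)
        if "los_iqr" in d:
            d["los_iqr"] = tuple(d["los_iqr"])
        if "age_bounds" in d:
            d["age_bounds"] = tuple(d["age_bounds"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Published per-site summaries (counts, so percentages are exact) and fitted
# odds ratios of the four-site study cohort.
# ---------------------------------------------------------------------------

#: Per-site marginal summaries.  Counts are used rather than rounded
#: percentages so that simulated proportions reproduce the printed one-decimal
#: percentages exactly.
SITE_MARGINALS: dict[str, dict] = {
    "BWH": dict(
        n=1406,
        los_median=5.0, los_iqr=(3.0, 9.0),
        sex_counts=dict(female=803, male=603, missing=0),
        race_counts=dict(White=841, Black=321, Asian=11, Other=148, Missing=85),
        age_mean=41.4, age_sd=12.6,
        diag_counts=dict(psychosis=294, mood=1255, anxiety=300, sud=591),
        prevalence=0.329,
    ),
    "FH": dict(
        n=1053,
        los_median=8.0, los_iqr=(6.0, 14.0),
        sex_counts=dict(female=461, male=592, missing=0),
        race_counts=dict(White=627, Black=230, Asian=11, Other=141, Missing=44),
        age_mean=41.4, age_sd=13.2,
        diag_counts=dict(psychosis=404, mood=823, anxiety=213, sud=477),
        prevalence=0.211,
    ),
    "MCL": dict(
        n=29845,
        los_median=8.0, los_iqr=(5.0, 14.0),
        sex_counts=dict(female=16340, male=13496, missing=9),
        race_counts=dict(White=24341, Black=1522, Asian=690, Other=981, Missing=2311),
        age_mean=34.9, age_sd=11.4,
        diag_counts=dict(psychosis=6609, mood=22443, anxiety=10951, sud=14121),
        prevalence=0.283,
    ),
    "MGH": dict(
        n=18772,
        los_median=6.0, los_iqr=(2.0, 12.0),
        sex_counts=dict(female=8985, male=9786, missing=1),
        race_counts=dict(White=15164, Black=1567, Asian=310, Other=1166, Missing=565),
        age_mean=45.7, age_sd=12.1,
        diag_counts=dict(psychosis=4317, mood=16830, anxiety=5599, sud=8394),
        prevalence=0.433,
    ),
}

#: Fitted odds ratios of the site-specific logistic readmission models
#: (race reference level: White).
SITE_ODDS_RATIOS: dict[str, dict[str, float]] = {
    "MGH": dict(age=1.001, sex_male=1.400, race_Black=0.952, race_Asian=0.785,
                race_Other=0.765, psychosis=0.493, mood=0.598, anxiety=0.631,
                sud=0.403, los=0.981),
    "MCL": dict(age=1.002, sex_male=1.104, race_Black=0.930, race_Asian=1.065,
                race_Other=0.941, psychosis=0.93, mood=1.025, anxiety=1.095,
                sud=0.627, los=1.000),
    "BWH": dict(age=0.987, sex_male=1.144, race_Black=1.232, race_Asian=1.509,
                race_Other=1.316, psychosis=1.047, mood=1.026, anxiety=0.773,
                sud=1.084, los=1.013),
    "FH": dict(age=0.999, sex_male=1.012, race_Black=1.105, race_Asian=1.839,
               race_Other=0.921, psychosis=1.394, mood=1.123, anxiety=1.307,
               sud=1.006, los=1.010),
}

SITE_NAMES = ("MGH", "MCL", "BWH", "FH")


def _marginals_to_config_fields(site_name: str, m: dict) -> dict:
    sex_total = sum(m["sex_counts"].values())
    race_total = sum(m["race_counts"].values())
    return dict(
        site_name=site_name,
        n_instances=m["n"],
        sex_male=m["sex_counts"]["male"] / sex_total,
        sex_missing=m["sex_counts"]["missing"] / sex_total,
        race_probs={k: v / race_total for k, v in m["race_counts"].items()},
        age_mean=m["age_mean"],
        age_sd=m["age_sd"],
        los_median=m["los_median"],
        los_iqr=m["los_iqr"],
        diag_rates={k: v / m["n"] for k, v in m["diag_counts"].items()},
        target_prevalence=m["prevalence"],
    )


def site_defaults(site_name: str, calibrate: bool = True) -> SiteConfig:
    """Default :class:`SiteConfig` for one of the four study sites.

    Marginals reproduce the published per-site summaries; the outcome slopes
    are the natural logs of the published odds ratios.  With
    ``calibrate=True`` (default) the intercept is solved by root finding so
    that the marginal simulated prevalence matches the published outcome mean.
    """
    if site_name not in SITE_MARGINALS:
        raise ValueError(
            f"unknown site {site_name!r}; expected one of {sorted(SITE_MARGINALS)}"
        )
    fields_ = _marginals_to_config_fields(site_name, SITE_MARGINALS[site_name])
    fields_["coef"] = {k: math.log(v) for k, v in SITE_ODDS_RATIOS[site_name].items()}
    cfg = SiteConfig(**fields_)
    if calibrate:
        from .synthetic import calibrate_intercept  # local import: avoid cycle

        cfg = calibrate_intercept(cfg)
    return cfg


SCENARIO_KINDS = ("none", "covariate_shift", "conditional_shift", "both")


@dataclass(frozen=True)
class ShiftScenario:
    """A named collection of site configs with a declared kind of shift."""

    scenario_kind: str
    site_configs: tuple[SiteConfig, ...]

    def __post_init__(self) -> None:
        if self.scenario_kind not in SCENARIO_KINDS:
            raise ValueError(f"scenario_kind must be one of {SCENARIO_KINDS}")
        if len({c.site_name for c in self.site_configs}) != len(self.site_configs):
            raise ValueError("site names must be unique")
        if self.scenario_kind in ("none", "covariate_shift"):
            cs = [c.coef for c in self.site_configs]
            ic = [(c.intercept, c.los_sq_coef, c.los_age_coef) for c in self.site_configs]
            if any(c != cs[0] for c in cs) or any(i != ic[0] for i in ic):
                raise ValueError(
                    f"{self.scenario_kind} requires identical outcome models across sites"
                )
        if self.scenario_kind == "none":
            ref = self.site_configs[0]
            for c in self.site_configs[1:]:
                if replace(c, site_name=ref.site_name, n_instances=ref.n_instances) != ref:
                    raise ValueError("scenario 'none' requires identical SiteConfigs up to n")

    @property
    def sites(self) -> list[str]:
        return [c.site_name for c in self.site_configs]

    def to_dict(self) -> dict:
        return {
            "scenario_kind": self.scenario_kind,
            "site_configs": [c.to_dict() for c in self.site_configs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShiftScenario":
        return cls(
            scenario_kind=d["scenario_kind"],
            site_configs=tuple(SiteConfig.from_dict(c) for c in d["site_configs"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ShiftScenario":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def four_site_scenario(n_overrides: dict[str, int] | None = None) -> ShiftScenario:
    """The default four-site study scenario (marginals and outcome models both
    differ across sites, as in the real cohort)."""
    configs = []
    for name in SITE_NAMES:
        cfg = site_defaults(name)
        if n_overrides and name in n_overrides:
            cfg = cfg.with_(n_instances=n_overrides[name])
        configs.append(cfg)
    return ShiftScenario("both", tuple(configs))


def covariate_shift_pair(n_per_site: int = 20_000) -> ShiftScenario:
    """Two sites sharing one conditional outcome model but with a strongly
    shifted age marginal.

    The shared conditional contains a LOS x age interaction, so a main-effects
    logistic model fitted at the source is misspecified; the source-optimal
    and target-optimal linear LOS coefficients differ in sign, which is the
    regime where importance weighting visibly repairs cross-site performance.
    """
    base = dict(
        sex_male=0.5,
        race_probs=dict(White=0.6, Black=0.2, Asian=0.05, Other=0.1, Missing=0.05),
        los_median=7.0, los_iqr=(4.36, 11.24),  # log-normal sigma ~= 0.70
        diag_rates=dict(psychosis=0.25, mood=0.80, anxiety=0.25, sud=0.45),
        coef={"los": 0.01, "age": 0.02 / AGE_SCALE},
        intercept=-0.9,
        los_age_coef=1.2,
        age_sd=10.0,
        overlap_fraction=0.0,
    )
    src = SiteConfig(site_name="SRC", n_instances=n_per_site, age_mean=30.0, **base)
    tgt = SiteConfig(site_name="TGT", n_instances=n_per_site, age_mean=52.0, **base)
    return ShiftScenario("covariate_shift", (src, tgt))


def conditional_shift_pair(n_per_site: int = 20_000) -> ShiftScenario:
    """Two sites with identical covariate marginals but opposite-sign LOS
    effects in the outcome model, taking the two discordant published
    per-day odds ratios (0.981 at MGH vs 1.013 at BWH)."""
    fields_ = _marginals_to_config_fields("MGH", SITE_MARGINALS["MGH"])
    fields_["n_instances"] = n_per_site
    fields_["overlap_fraction"] = 0.0
    coef = {k: math.log(v) for k, v in SITE_ODDS_RATIOS["MGH"].items()}
    neg = dict(fields_, site_name="LOSNEG", coef=dict(coef, los=math.log(0.981)))
    pos = dict(fields_, site_name="LOSPOS", coef=dict(coef, los=math.log(1.013)))
    a = SiteConfig(**neg)
    b = SiteConfig(**pos)
    from .synthetic import calibrate_intercept

    return ShiftScenario(
        "conditional_shift",
        (calibrate_intercept(a), calibrate_intercept(b)),
    )
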