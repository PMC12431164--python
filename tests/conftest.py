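import numpy as np
import pandas as pd
import pytest

from psyreadmit import SiteConfig, site_defaults, simulate_instances


@pytest.fixture(scope="session")
def fh_config():
    return site_defaults("FH")


@pytest.fixture(scope="session")
def fh_instances(fh_config):
    """2,000 FH-like instances, fixed seed, shared across tests."""
    return simulate_instances(fh_config.with_(n_instances=2000), seed=101)


@pytest.fixture(scope="session")
def plain_config():
    """A neutral single-site config with a null outcome model."""
    return SiteConfig(
        site_name="PLAIN",
        n_instances=1000,
        sex_male=0.5,
        race_probs=dict(White=0.6, Black=0.2, Asian=0.05, Other=0.1, Missing=0.05),
        age_mean=40.0,
        age_sd=12.0,
        los_median=7.0,
        los_iqr=(4.0, 12.0),
        diag_rates=dict(psychosis=0.25, mood=0.8, anxiety=0.25, sud=0.45),
        coef={},
        intercept=0.0,
        overlap_fraction=0.0,
    )


def random_instance_table(n, rng, prevalence=0.5):
    """Covariate table with random labels, for fitting-machinery tests."""
    cfg = SiteConfig(
        site_name="RAND",
        n_instances=n,
        sex_male=0.5,
        race_probs=dict(White=0.55, Black=0.2, Asian=0.1, Other=0.1, Missing=0.05),
        age_mean=40.0,
        age_sd=12.0,
        los_median=6.0,
        los_iqr=(3.0, 11.0),
        diag_rates=dict(psychosis=0.3, mood=0.6, anxiety=0.3, sud=0.4),
        coef={},
        intercept=0.0,
    )
    from psyreadmit.synthetic import draw_covariates

    df = draw_covariates(cfg, n, rng)
    df.insert(0, "patient_id", [f"R-P{i:06d}" for i in range(n)])
    df.insert(1, "site", "RAND")
    df["readmitted"] = rng.random(n) < prevalence
    if df["readmitted"].nunique() < 2:  # pragma: no cover
        df.loc[df.index[0], "readmitted"] = True
        df.loc[df.index[1], "readmitted"] = False
    return df
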