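"""Shared predictor schema for all fitted models.

Every model in the package (site-specific outcome models and the IPW
site-membership discriminator) uses the same main-effects design: age at
discharge and LOS as untransformed numerics, legal sex and the four diagnosis
flags as binary indicators, and race as a four-level categorical with White
as the reference.  Rows with missing legal sex are dropped from modelling;
missing race is folded into "Other" (the descriptive tables still report it
separately).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import COEF_NAMES

logger = logging.getLogger(__name__)

#: Design columns, in reporting order.
DESIGN_COLUMNS = list(COEF_NAMES)

#: Original variables -> design columns, used to permute a categorical
#: predictor as one unit in permutation importance.
VARIABLE_GROUPS: dict[str, list[str]] = {
    "age": ["age"],
    "sex": ["sex_male"],
    "race": ["race_Black", "race_Asian", "race_Other"],
    "psychosis": ["psychosis"],
    "mood": ["mood"],
    "anxiety": ["anxiety"],
    "sud": ["sud"],
    "los": ["los"],
}

_REQUIRED = ["age", "sex", "race", "psychosis", "mood", "anxiety", "sud", "los"]


def modeling_frame(data: pd.DataFrame) -> pd.DataFrame:
    """Rows eligible for modelling (drops missing legal sex, with a log note)."""
    missing = data["sex"] == "missing"
    n_miss = int(missing.sum())
    if n_miss:
        logger.info("dropping %d rows with missing legal sex from modelling", n_miss)
    return data.loc[~missing]

def build_design(data: pd.DataFrame) -> pd.DataFrame:
    """Main-effects design matrix (no intercept column) from an instance table.

    Raises ``KeyError`` naming the first missing column on schema mismatch.
    """
    for col in _REQUIRED:
        if col not in data.columns:
            raise KeyError(f"instance table is missing required column {col!r}")
    race = data["race"].where(data["race"] != "Missing", "Other")
    X = pd.DataFrame(
        {
            "age": data["age"].astype(float),
            "sex_male": (data["sex"] == "male").astype(float),
            "race_Black": (race == "Black").astype(float),
            "race_Asian": (race == "Asian").astype(float),
            "race_Other": (race == "Other").astype(float),
            "psychosis": data["psychosis"].astype(float),
            "mood": data["mood"].astype(float),
            "anxiety": data["anxiety"].astype(float),
            "sud": data["sud"].astype(float),
            "los": data["los"].astype(float),
        },
        index=data.index,
    )
    return X


def labels_vector(data: pd.DataFrame) -> np.ndarray:
    """Binary outcome vector (1 = readmitted within 30 days)."""
    y = data["readmitted"]
    if y.isna().any():
        raise ValueError("instance table contains unlabeled rows")
    return y.astype(int).to_numpy()
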