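"""Inverse-probability-weighting adjustment for covariate shift.

To transport a model from source site s to target site s', the two sites'
covariate tables are stacked (outcome excluded) and a main-effects logistic
discriminator estimates p(x) = Pr(site = s' | X = x).  Each source training
row i then receives the density-ratio weight

    w_i = p(x_i) / (1 - p(x_i)),

which up-weights source patients whose covariate profiles are common at the
target.  Training the source model on these weighted rows targets the
expected loss under the target covariate distribution; when the only
cross-site difference is in the covariate marginals (covariate shift) this
aligns the transported model with the target-optimal one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import SiteCohort
from .design import build_design, modeling_frame
from .transport import CrossSiteMatrix, cross_site_matrix

logger = logging.getLogger(__name__)

PROB_CLIP = 1e-6
#: |log-odds coefficient| beyond which the discriminator is treated as
#: (quasi-)separated between sites.
_SEPARATION_COEF = 15.0


@dataclass
class MembershipResults:
    """Fitted site-membership discriminator Pr(site = target | X)."""

    params: pd.Series
    bse: pd.Series
    converged: bool
    separation_flagged: bool
    n_source: int
    n_target: int
    columns: list

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(build_design(data), has_constant="add")[self.params.index]
        lp = X.to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-lp))


class SiteMembershipModel:
    """Main-effects logistic discriminator between two sites' covariates."""

    def __init__(self, source_data: pd.DataFrame, target_data: pd.DataFrame):
        if len(source_data) == 0 or len(target_data) == 0:
            raise ValueError("both covariate tables must be non-empty")
        self.source_data = source_data
        self.target_data = target_data

    def fit(self) -> MembershipResults:
        Xs = build_design(self.source_data)
        Xt = build_design(self.target_data)
        X = sm.add_constant(pd.concat([Xs, Xt], ignore_index=True), has_constant="add")
        y = np.r_[np.zeros(len(Xs)), np.ones(len(Xt))]
        # degenerate (constant) columns carry no membership information;
        # excluded from the fit to keep it identifiable
        keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
        res = sm.GLM(y, X[keep], family=sm.families.Binomial()).fit(maxiter=200)
        params = pd.Series(res.params, index=keep)
        slopes = params.drop("const")
        separation = bool((slopes.abs() > _SEPARATION_COEF).any()) or not res.converged
        if separation:
            logger.warning(
                "site-membership discriminator near-separated (max |coef|=%.2f); "
                "weights will be clipped", float(slopes.abs().max()),
            )
        return MembershipResults(
            params=params,
            bse=pd.Series(res.bse, index=keep),
            converged=bool(res.converged),
            separation_flagged=separation,
            n_source=len(Xs),
            n_target=len(Xt),
            columns=keep,
        )


@dataclass
class WeightVector:
    """Importance weights for the source training rows."""

    values: np.ndarray
    separation_flagged: bool = False

    @property
    def effective_sample_size(self) -> float:
        return float(self.values.sum() ** 2 / np.sum(self.values**2))

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())


def compute_ipw_weights(
    model: MembershipResults,
    source_data: pd.DataFrame,
    clip: float = PROB_CLIP,
    truncate_percentile: float | None = None,
    normalize: bool = False,
) -> WeightVector:
    """Density-ratio weights w_i = p_i / (1 - p_i) for the source rows.

    Membership probabilities are clipped to [clip, 1-clip] so weights stay
    finite under separation.  ``truncate_percentile`` optionally caps weights
    at that percentile (stabilisation; off by default).  ``normalize`` scales
    the weights to mean 1.
    """
    p = np.clip(model.predict_proba(source_data), clip, 1.0 - clip)
    w = p / (1.0 - p)
    if truncate_percentile is not None:
        w = np.minimum(w, np.percentile(w, truncate_percentile))
    if normalize:
        w = w / w.mean()
    return WeightVector(values=w, separation_flagged=model.separation_flagged)


def pairwise_ipw_weights(
    cohorts: list[SiteCohort],
    clip: float = PROB_CLIP,
    truncate_percentile: float | None = None,
) -> dict[tuple[str, str], WeightVector]:
    """IPW weights for every ordered (source, target) pair of cohorts.

    Weights are computed from the *training* partitions only (target test
    rows never influence training) and once per pair; every source training
    row receives a weight aligned positionally with ``modeling_frame(train)``.
    """
    out: dict[tuple[str, str], WeightVector] = {}
    trains = {c.site: modeling_frame(c.train) for c in cohorts}
    for source in cohorts:
        for target in cohorts:
            if source.site == target.site:
                continue
            model = SiteMembershipModel(trains[source.site], trains[target.site]).fit()
            out[(source.site, target.site)] = compute_ipw_weights(
                model, trains[source.site], clip=clip,
                truncate_percentile=truncate_percentile,
            )
    return out


@dataclass
class AdjustedMatrices:
    """IPW-adjusted cross-site matrix and its deltas against the unadjusted one."""

    adjusted: CrossSiteMatrix
    unadjusted: CrossSiteMatrix
    weight_summaries: dict[tuple[str, str], dict]

    def delta_frame(self, metric: str = "auc") -> pd.DataFrame:
        return self.adjusted.metric_frame(metric) - self.unadjusted.metric_frame(metric)


def adjusted_cross_site_matrix(
    cohorts: list[SiteCohort],
    model_kind: str = "logistic",
    n_sub: int | None = None,
    n_reps: int = 100,
    seed: int = 0,
    forest_params: dict | None = None,
    unadjusted: CrossSiteMatrix | None = None,
    truncate_percentile: float | None = None,
) -> AdjustedMatrices:
    """Rerun the cross-site protocol with IPW-weighted training.

    For each ordered (source, target) pair with source != target, weights are
    estimated from source-training vs target-training covariates and the
    same subsampled replication protocol is run with weighted fits (same seed
    stream as the unadjusted run, so subsamples match cell for cell).  The
    diagonal stays unweighted.  Cells with a separation-flagged discriminator
    are annotated in ``weight_summaries``.
    """
    weight_vectors = pairwise_ipw_weights(
        cohorts, truncate_percentile=truncate_percentile
    )
    weights = {pair: wv.values for pair, wv in weight_vectors.items()}
    if unadjusted is None:
        unadjusted = cross_site_matrix(
            cohorts, model_kind=model_kind, n_sub=n_sub, n_reps=n_reps,
            seed=seed, forest_params=forest_params,
        )
    adjusted = cross_site_matrix(
        cohorts, model_kind=model_kind, n_sub=unadjusted.n_sub,
        n_reps=n_reps, seed=seed, forest_params=forest_params, weights=weights,
    )
    summaries = {
        pair: {
            "min": wv.min,
            "max": wv.max,
            "effective_sample_size": wv.effective_sample_size,
            "separation_flagged": wv.separation_flagged,
        }
        for pair, wv in weight_vectors.items()
    }
    return AdjustedMatrices(
        adjusted=adjusted, unadjusted=unadjusted, weight_summaries=summaries
    )
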