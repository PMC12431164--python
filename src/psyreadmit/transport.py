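"""In-site and cross-site evaluation under the subsampled replication protocol.

For each source site, a model is trained on a subsample of the source
training split matched to the smallest training size among all sites, then
scored on every site's test split; the subsample is redrawn ``n_reps`` times
and metrics are averaged across replications.  The diagonal of the resulting
source x target matrix is the in-site performance, the off-diagonal the
cross-site (transportability) performance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SiteCohort
from .design import modeling_frame
from .metrics import MetricResult, compute_auc, optimal_threshold_f1
from .models import ReadmissionForest, ReadmissionLogit
from .synthetic import stable_site_code

logger = logging.getLogger(__name__)

MODEL_KINDS = ("logistic", "forest")
_MAX_REDRAWS = 10


def _fit_model(train: pd.DataFrame, model_kind: str, weights, seed: int,
               forest_params: dict | None):
    if model_kind == "logistic":
        return ReadmissionLogit(train, weights=weights).fit()
    if model_kind == "forest":
        params = dict(forest_params or {})
        return ReadmissionForest(train, weights=weights, seed=seed, **params).fit()
    raise ValueError(f"model_kind must be one of {MODEL_KINDS}")


def replicate_train_eval(
    source: SiteCohort,
    targets: list[SiteCohort],
    model_kind: str = "logistic",
    n_sub: int | None = None,
    n_reps: int = 100,
    seed: int = 0,
    weights: dict[str, np.ndarray] | np.ndarray | None = None,
    forest_params: dict | None = None,
) -> dict[str, MetricResult]:
    """Subsampled-replication evaluation of one source against many targets.

    Per replication r, ``n_sub`` training rows are drawn without replacement
    (seeded by (seed, source, r)), a model is fitted (optionally with
    per-row weights aligned to ``source.train``), and AUC and
    optimal-threshold F1 are recorded on every target's test split.
    Replications whose subsample contains one outcome class are redrawn (up
    to 10 times, logged) and skipped if still degenerate.  When ``n_sub``
    equals the full training size the replications would be identical, so
    ``n_reps`` collapses to 1.
    """
    train = modeling_frame(source.train).reset_index(drop=True)
    n_train = len(train)
    if n_sub is None:
        n_sub = n_train
    if n_sub > n_train:
        raise ValueError(f"n_sub={n_sub} exceeds training size {n_train} at {source.site}")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if isinstance(weights, np.ndarray):
        weights = {t.site: weights for t in targets}
    if n_sub == n_train and n_reps > 1:
        logger.info(
            "%s: subsample equals full training size; collapsing %d replications to 1",
            source.site, n_reps,
        )
        n_reps = 1

    per_target: dict[str, list[tuple[float, float, float]]] = {t.site: [] for t in targets}
    test_frames = {t.site: modeling_frame(t.test) for t in targets}
    y = train["readmitted"].astype(int).to_numpy()
    for r in range(n_reps):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, stable_site_code(source.site), r])
        )
        idx = None
        for attempt in range(_MAX_REDRAWS + 1):
            cand = (
                np.arange(n_train)
                if n_sub == n_train
                else rng.choice(n_train, size=n_sub, replace=False)
            )
            if y[cand].min() != y[cand].max():
                idx = cand
                break
            logger.warning("%s rep %d: one-class subsample, redrawing (%d)",
                           source.site, r, attempt + 1)
        if idx is None:
            logger.warning("%s rep %d skipped after %d redraws", source.site, r, _MAX_REDRAWS)
            continue
        sub = train.iloc[idx]
        model_seed = int(rng.integers(0, 2**31 - 1))
        fits: dict[str, object] = {}
        for t in targets:
            w = None
            if weights is not None and t.site in weights and weights[t.site] is not None:
                w = np.asarray(weights[t.site], dtype=float)[idx]
            # one shared fit per replication for all unweighted targets;
            # separate fits only where per-target weights differ
            key = "__unweighted__" if w is None else t.site
            if key not in fits:
                fits[key] = _fit_model(
                    sub, model_kind, w, seed=model_seed, forest_params=forest_params
                )
            fit = fits[key]
            test = test_frames[t.site]
            scores = fit.predict(test)
            labels = test["readmitted"].astype(int).to_numpy()
            auc = compute_auc(scores, labels)
            thr, f1 = optimal_threshold_f1(scores, labels)
            per_target[t.site].append((auc, f1, thr))

    out = {}
    for site, rows in per_target.items():
        arr = np.array(rows, dtype=float).reshape(-1, 3)
        out[site] = MetricResult(aucs=arr[:, 0], f1s=arr[:, 1], thresholds=arr[:, 2])
    return out


@dataclass
class CrossSiteMatrix:
    """Source x target grid of :class:`MetricResult` for one model kind."""

    sites: list[str]
    model_kind: str
    n_sub: int
    n_reps: int
    cells: dict[tuple[str, str], MetricResult] = field(default_factory=dict)

    def metric_frame(self, metric: str = "auc") -> pd.DataFrame:
        """Square DataFrame of mean metric values (rows = source sites)."""
        data = {
            t: [getattr(self.cells[(s, t)], metric) for s in self.sites]
            for t in self.sites
        }
        return pd.DataFrame(data, index=pd.Index(self.sites, name="source"))

    def to_long(self) -> pd.DataFrame:
        rows = []
        for (s, t), m in sorted(self.cells.items()):
            for metric in ("auc", "f1"):
                rows.append(
                    (s, t, self.model_kind, metric, getattr(m, metric),
                     getattr(m, metric + "_sd"), m.n_reps)
                )
        return pd.DataFrame(
            rows, columns=["source", "target", "model", "metric", "mean", "sd", "n_reps"]
        )

    def to_json(self, path) -> None:
        payload = {
            "sites": self.sites,
            "model_kind": self.model_kind,
            "n_sub": self.n_sub,
            "n_reps": self.n_reps,
            "cells": {
                f"{s}->{t}": {
                    "auc": m.auc, "f1": m.f1,
                    "aucs": m.aucs.tolist(), "f1s": m.f1s.tolist(),
                    "thresholds": m.thresholds.tolist(),
                }
                for (s, t), m in sorted(self.cells.items())
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CrossSiteMatrix":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        cells = {}
        for key, c in d["cells"].items():
            s, t = key.split("->")
            cells[(s, t)] = MetricResult(
                aucs=np.array(c["aucs"]), f1s=np.array(c["f1s"]),
                thresholds=np.array(c["thresholds"]),
            )
        return cls(sites=d["sites"], model_kind=d["model_kind"],
                   n_sub=d["n_sub"], n_reps=d["n_reps"], cells=cells)


def cross_site_matrix(
    cohorts: list[SiteCohort],
    model_kind: str = "logistic",
    n_sub: int | None = None,
    n_reps: int = 100,
    seed: int = 0,
    forest_params: dict | None = None,
    weights: dict[tuple[str, str], np.ndarray] | None = None,
) -> CrossSiteMatrix:
    """Fill every source x target cell via :func:`replicate_train_eval`.

    ``n_sub`` defaults to the minimum training size over sites.  Optional
    ``weights`` maps (source, target) pairs to per-row training weights.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 site cohorts")
    if n_sub is None:
        n_sub = min(len(modeling_frame(c.train)) for c in cohorts)
    sites = [c.site for c in cohorts]
    matrix = CrossSiteMatrix(sites=sites, model_kind=model_kind, n_sub=n_sub, n_reps=n_reps)
    for source in cohorts:
        w = None
        if weights is not None:
            w = {
                t.site: weights.get((source.site, t.site))
                for t in cohorts
            }
        results = replicate_train_eval(
            source, cohorts, model_kind=model_kind, n_sub=n_sub,
            n_reps=n_reps, seed=seed, weights=w, forest_params=forest_params,
        )
        for t_site, metric in results.items():
            matrix.cells[(source.site, t_site)] = metric
    return matrix


class TransportabilityExperiment:
    """Model-object wrapper around the full cross-site protocol.

    ``fit()`` runs the subsampled replication protocol for every ordered
    source/target pair and returns a results object carrying the
    :class:`CrossSiteMatrix`.
    """

    def __init__(
        self,
        cohorts: list[SiteCohort],
        model_kind: str = "logistic",
        n_sub: int | None = None,
        n_reps: int = 100,
        seed: int = 0,
        forest_params: dict | None = None,
    ):
        self.cohorts = cohorts
        self.model_kind = model_kind
        self.n_sub = n_sub
        self.n_reps = n_reps
        self.seed = seed
        self.forest_params = forest_params

    def fit(self) -> "TransportabilityResults":
        matrix = cross_site_matrix(
            self.cohorts, self.model_kind, self.n_sub, self.n_reps,
            self.seed, self.forest_params,
        )
        return TransportabilityResults(matrix=matrix)


@dataclass
class TransportabilityResults:
    matrix: CrossSiteMatrix

    def summary(self, display_threshold: float = 0.6) -> str:
        from .report import render_matrix

        return render_matrix(self.matrix, display_threshold=display_threshold)
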