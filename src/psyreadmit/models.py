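"""Site-specific prediction models.

Two algorithms, both over the shared main-effects predictor schema
(:mod:`psyreadmit.design`):

* :class:`ReadmissionLogit` — logistic regression with Wald inference
  reported on the odds-ratio scale, fitted by (optionally weighted) maximum
  likelihood through statsmodels GLM;
* :class:`ReadmissionForest` — a bagged ensemble of classification trees
  with weighted bootstrap resampling, out-of-bag (OOB) accuracy, and OOB
  permutation feature importance.

Both follow the statsmodels convention: the model object holds the data, and
``fit()`` returns a results object carrying estimates, diagnostics and a
``summary()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.tree import DecisionTreeClassifier
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .design import DESIGN_COLUMNS, VARIABLE_GROUPS, build_design, labels_vector

logger = logging.getLogger(__name__)


def _validate_inputs(y: np.ndarray, weights: np.ndarray | None) -> None:
    if y.min() == y.max():
        raise ValueError("labels contain a single class; cannot fit")
    if weights is not None:
        if len(weights) != len(y):
            raise ValueError("weights must have the same length as labels")
        if np.any(np.asarray(weights) < 0):
            raise ValueError("weights must be non-negative")


class ReadmissionLogit:
    """Main-effects logistic readmission model for one site.

    Parameters
    ----------
    data : instance table with covariate columns and a boolean ``readmitted``
        label; rows with missing legal sex are dropped.
    weights : optional per-row non-negative weights entering the likelihood
        multiplicatively (used by the covariate-shift adjustment).
    """

    def __init__(self, data: pd.DataFrame, weights: np.ndarray | None = None):
        from .design import modeling_frame

        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if len(weights) != len(data):
                raise ValueError("weights must align with data rows")
            weights = pd.Series(weights, index=data.index)
        data = modeling_frame(data)
        self.data = data
        exog = sm.add_constant(build_design(data), has_constant="add")
        # constant predictor columns (e.g. a race level absent from a small
        # subsample) are dropped to keep the fit identifiable; prediction
        # simply ignores them
        keep = [c for c in exog.columns if c == "const" or exog[c].nunique() > 1]
        self.exog = exog[keep]
        self.endog = labels_vector(data)
        self.weights = None if weights is None else weights.loc[data.index].to_numpy()
        _validate_inputs(self.endog, self.weights)

    def fit(self) -> "LogisticResults":
        kwargs = {}
        if self.weights is not None and not np.all(self.weights == self.weights[0]):
            kwargs["freq_weights"] = self.weights
        model = sm.GLM(self.endog, self.exog, family=sm.families.Binomial(), **kwargs)
        separation = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(maxiter=200)
        for w in caught:
            if issubclass(w.category, PerfectSeparationWarning):
                separation = True
        if separation:
            logger.warning("perfect separation detected; coefficients unreliable")
        return LogisticResults(
            params=pd.Series(res.params, index=self.exog.columns),
            bse=pd.Series(res.bse, index=self.exog.columns),
            pvalues=pd.Series(res.pvalues, index=self.exog.columns),
            cov=res.cov_params(),
            converged=bool(res.converged),
            separation=separation,
            nobs=int(res.nobs),
            _sm_results=res,
        )


@dataclass
class LogisticResults:
    """Fitted logistic model: coefficients on the log-odds scale with Wald
    standard errors, 95% CIs and two-sided p-values."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    converged: bool
    separation: bool
    nobs: int
    _sm_results: object = field(repr=False, default=None)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params.drop("const"))

    def odds_ratio_table(self) -> pd.DataFrame:
        """Reporting table: predictor, OR, 95% CI bounds, p-value."""
        ci = np.exp(self.conf_int().drop(index="const"))
        return pd.DataFrame(
            {
                "predictor": self.odds_ratios.index,
                "odds_ratio": self.odds_ratios.to_numpy(),
                "ci_low": ci["lower"].to_numpy(),
                "ci_high": ci["upper"].to_numpy(),
                "p_value": self.pvalues.drop("const").to_numpy(),
            }
        )

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predicted readmission probabilities (inverse-logit of the linear
        predictor); raises ``KeyError`` naming any missing column."""
        X = sm.add_constant(build_design(data), has_constant="add")
        X = X[self.params.index]  # enforce schema/order
        lp = X.to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-lp))

    def summary(self) -> str:
        lines = [
            f"Logistic readmission model  (n={self.nobs}, converged={self.converged}"
            + (", PERFECT SEPARATION" if self.separation else "")
            + ")",
            f"{'predictor':<12}{'OR':>8}{'CI low':>9}{'CI high':>9}{'p':>9}",
        ]
        for _, r in self.odds_ratio_table().iterrows():
            lines.append(
                f"{r.predictor:<12}{r.odds_ratio:>8.3f}{r.ci_low:>9.3f}"
                f"{r.ci_high:>9.3f}{r.p_value:>9.3g}"
            )
        return "\n".join(lines)


class ReadmissionForest:
    """Bagged classification-tree ensemble with weighted bootstrap.

    Each of ``n_trees`` trees is grown on a bootstrap sample of size n drawn
    with replacement with probability proportional to the sample weights
    (uniform when no weights are given); out-of-bag rows of each tree are
    tracked for the OOB accuracy estimate and permutation importance.
    Defaults: 500 trees, sqrt(p) candidate variables per split, unlimited
    depth, minimum node size 5.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        weights: np.ndarray | None = None,
        n_trees: int = 500,
        max_features: str | int = "sqrt",
        min_samples_leaf: int = 5,
        seed: int = 0,
    ):
        from .design import modeling_frame

        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if len(weights) != len(data):
                raise ValueError("weights must align with data rows")
            weights = pd.Series(weights, index=data.index)
        data = modeling_frame(data)
        if len(data) < 10:
            raise ValueError("need at least 10 rows for an out-of-bag estimate")
        self.data = data
        self.X = build_design(data)
        self.y = labels_vector(data)
        self.weights = None if weights is None else weights.loc[data.index].to_numpy()
        _validate_inputs(self.y, self.weights)
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed

    def fit(self) -> "ForestResults":
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 61_403]))
        n = len(self.y)
        Xm = self.X.to_numpy()
        p = None
        if self.weights is not None and not np.all(self.weights == self.weights[0]):
            total = self.weights.sum()
            if total <= 0:
                raise ValueError("weights sum to zero")
            p = self.weights / total
        elif self.weights is not None and self.weights[0] <= 0:
            raise ValueError("weights sum to zero")
        trees, oob_sets = [], []
        votes = np.zeros(n)
        counts = np.zeros(n, dtype=int)
        for _ in range(self.n_trees):
            idx = rng.choice(n, size=n, replace=True, p=p)
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(Xm[idx], self.y[idx])
            oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
            if len(oob):
                votes[oob] += tree.predict(Xm[oob])
                counts[oob] += 1
            trees.append(tree)
            oob_sets.append(oob)
        has_oob = counts > 0
        oob_pred = (votes[has_oob] / counts[has_oob]) >= 0.5
        oob_accuracy = float(np.mean(oob_pred == self.y[has_oob].astype(bool)))
        return ForestResults(
            trees=trees,
            oob_sets=oob_sets,
            X=self.X,
            y=self.y,
            oob_accuracy=oob_accuracy,
            hyperparameters={
                "n_trees": self.n_trees,
                "max_features": self.max_features,
                "min_samples_leaf": self.min_samples_leaf,
                "seed": self.seed,
            },
        )


@dataclass
class ForestResults:
    """Fitted tree ensemble with OOB bookkeeping."""

    trees: list
    oob_sets: list
    X: pd.DataFrame
    y: np.ndarray
    oob_accuracy: float
    hyperparameters: dict

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Score = fraction of trees voting for readmission."""
        X = build_design(data)[self.X.columns].to_numpy()
        votes = np.zeros(len(X))
        for tree in self.trees:
            votes += tree.predict(X)
        return votes / len(self.trees)

    def _oob_accuracy_for(self, Xm: np.ndarray) -> float:
        n = len(self.y)
        votes = np.zeros(n)
        counts = np.zeros(n, dtype=int)
        for tree, oob in zip(self.trees, self.oob_sets):
            if len(oob):
                votes[oob] += tree.predict(Xm[oob])
                counts[oob] += 1
        has = counts > 0
        pred = (votes[has] / counts[has]) >= 0.5
        return float(np.mean(pred == self.y[has].astype(bool)))

    def permutation_importance(
        self, n_permutations: int = 10, seed: int = 0
    ) -> pd.DataFrame:
        """OOB permutation importance per original variable.

        For each predictor, importance = baseline OOB accuracy minus the
        mean OOB accuracy over ``n_permutations`` independent permutations of
        that variable's column(s) (a categorical predictor's dummy columns
        are permuted as one unit).  Values below ~0.01 in magnitude are
        negligible; above ~0.1, substantial.
        """
        rng = np.random.default_rng(np.random.SeedSequence([seed, 88_109]))
        Xm = self.X.to_numpy()
        n = len(Xm)
        col_index = {c: j for j, c in enumerate(self.X.columns)}
        rows = []
        for variable, cols in VARIABLE_GROUPS.items():
            js = [col_index[c] for c in cols if c in col_index]
            if not js:
                raise KeyError(f"predictor {variable!r} not in the fitted schema")
            accs = []
            for _ in range(n_permutations):
                perm = rng.permutation(n)
                Xp = Xm.copy()
                Xp[:, js] = Xm[perm][:, js]
                accs.append(self._oob_accuracy_for(Xp))
            rows.append((variable, self.oob_accuracy - float(np.mean(accs))))
        return pd.DataFrame(rows, columns=["predictor", "importance"])

    def summary(self) -> str:
        hp = self.hyperparameters
        return (
            f"Readmission forest: {hp['n_trees']} trees, "
            f"max_features={hp['max_features']}, "
            f"min_samples_leaf={hp['min_samples_leaf']}, "
            f"OOB accuracy={self.oob_accuracy:.3f}"
        )
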