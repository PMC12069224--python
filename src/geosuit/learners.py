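"""The learner roster for presence / pseudo-absence modelling.

Twelve roster slots mirror the usual ensemble-platform line-up: GLM, GAM,
MARS, FDA, RF, MAXENT, GBM, CTA, ANN, SRE, RFD, XGBOOST. Each slot is backed
by a concrete estimator with fixed, documented hyperparameters (no automatic
tuning):

- GLM            unpenalized logistic regression
- GAM            cubic-spline basis expansion + logistic regression
- MARS           piecewise-linear (degree-1 spline) basis + logistic regression
- FDA            linear discriminant analysis
- CTA            single decision tree
- RF             random forest
- RFD            random forest with class-balanced bootstrap weighting
- GBM            gradient-boosted trees (scikit-learn)
- XGBOOST        gradient-boosted trees (xgboost)
- ANN            one-hidden-layer perceptron
- MAXENT         L2-penalized logistic regression on linear + quadratic +
                 pairwise-product features (a penalized-logit stand-in keeping
                 the roster slot; it is not a MaxEnt implementation)
- SRE            surface range envelope: presence-only per-variable quantile
                 box, predicting {0, 1}

Every fit is deterministic given its seed; every fitted learner exposes
``predict_proba(DataFrame) -> array of P(presence)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = ["ROSTER", "FittedLearner", "fit_learner", "sre_predict", "SurfaceRangeEnvelope"]

# roster order as conventionally listed
ROSTER = (
    "GLM", "GAM", "MARS", "FDA", "RF", "MAXENT",
    "GBM", "CTA", "ANN", "SRE", "RFD", "XGBOOST",
)


class SurfaceRangeEnvelope:
    """Rectilinear presence-only envelope on per-variable quantiles.

    Predicts 1 iff every variable lies within [q, 1-q] quantile bounds of the
    training presences; participates in ensembles as a {0,1} probability.
    """

    def __init__(self, quantile: float = 0.025):
        if not 0 <= quantile < 0.5:
            raise ValueError("envelope quantile must be in [0, 0.5)")
        self.quantile = quantile
        self.bounds_: dict[str, tuple[float, float]] = {}

    def fit(self, X: pd.DataFrame, y) -> "SurfaceRangeEnvelope":
        pres = X[np.asarray(y) == 1]
        if pres.empty:
            raise ValueError("SRE needs at least one presence")
        lo = pres.quantile(self.quantile)
        hi = pres.quantile(1 - self.quantile)
        self.bounds_ = {c: (float(lo[c]), float(hi[c])) for c in X.columns}
        return self

    def predict_proba_presence(self, X: pd.DataFrame) -> np.ndarray:
        return sre_predict(self.bounds_, X)


def sre_predict(envelope: dict, x) -> np.ndarray:
    """1 iff every variable lies within its [lo, hi] envelope bounds.

    ``x`` may be a DataFrame (rows scored vectorwise) or a single mapping/row.
    """
    if isinstance(x, pd.DataFrame):
        ok = np.ones(len(x), dtype=bool)
        for var, (lo, hi) in envelope.items():
            if var not in x.columns:
                raise KeyError(f"variable {var!r} missing from envelope input")
            v = x[var].to_numpy()
            ok &= (v >= lo) & (v <= hi)
        return ok.astype(float)
    row = x
    for var, (lo, hi) in envelope.items():
        if var not in row:
            raise KeyError(f"variable {var!r} missing from envelope input")
        if not (lo <= row[var] <= hi):
            return np.float64(0.0)
    return np.float64(1.0)


def _build(kind: str, seed: int, n_features: int):
    # spline knot count kept small so tiny folds stay well-posed
    if kind == "GLM":
        return make_pipeline(StandardScaler(), LogisticRegression(penalty=None, max_iter=2000))
    if kind == "GAM":
        return make_pipeline(
            StandardScaler(),
            SplineTransformer(n_knots=4, degree=3),
            LogisticRegression(C=1.0, max_iter=2000),
        )
    if kind == "MARS":
        return make_pipeline(
            StandardScaler(),
            SplineTransformer(n_knots=5, degree=1),
            LogisticRegression(C=1.0, max_iter=2000),
        )
    if kind == "FDA":
        return LinearDiscriminantAnalysis()
    if kind == "MAXENT":
        return make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=2, include_bias=False),
            LogisticRegression(penalty="l2", C=1.0, max_iter=3000),
        )
    if kind == "CTA":
        return DecisionTreeClassifier(min_samples_leaf=5, random_state=seed)
    if kind == "RF":
        return RandomForestClassifier(n_estimators=100, min_samples_leaf=2, random_state=seed)
    if kind == "RFD":
        return RandomForestClassifier(
            n_estimators=100, min_samples_leaf=2,
            class_weight="balanced_subsample", random_state=seed,
        )
    if kind == "GBM":
        return GradientBoostingClassifier(n_estimators=100, max_depth=3, random_state=seed)
    if kind == "XGBOOST":
        return XGBClassifier(
            n_estimators=100, max_depth=4, learning_rate=0.1,
            n_jobs=1, random_state=seed, verbosity=0, eval_metric="logloss",
        )
    if kind == "ANN":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(16,), max_iter=600, random_state=seed),
        )
    raise ValueError(f"unknown learner id {kind!r}")


@dataclass
class FittedLearner:
    kind: str
    model: object
    columns: tuple

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """P(presence) per row; columns are re-ordered to match training."""
        X = X[list(self.columns)]
        if isinstance(self.model, SurfaceRangeEnvelope):
            return self.model.predict_proba_presence(X)
        p = self.model.predict_proba(X.to_numpy(dtype=float))
        classes = list(self.model.classes_) if hasattr(self.model, "classes_") else [0, 1]
        return p[:, classes.index(1)]


def fit_learner(kind: str, X: pd.DataFrame, y, seed: int) -> FittedLearner:
    """Fit one roster learner on a presence(1)/pseudo-absence(0) design table."""
    y = np.asarray(y, dtype=int)
    if kind not in ROSTER:
        raise ValueError(f"unknown learner id {kind!r}")
    if len(np.unique(y)) < 2 and kind != "SRE":
        raise ValueError("degenerate single-class training data")
    if kind == "SRE":
        model = SurfaceRangeEnvelope().fit(X, y)
    else:
        model = _build(kind, seed, X.shape[1])
        with warnings.catch_warnings():
            # small folds may stop the MLP before formal convergence; that is
            # part of the fixed-budget configuration, not an error
            warnings.simplefilter("ignore")
            model.fit(X.to_numpy(dtype=float), y)
    return FittedLearner(kind=kind, model=model, columns=tuple(X.columns))
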