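"""Ensemble suitability modelling: folds, evaluation, gating, mapping.

The workflow follows standard ensemble-platform practice for presence /
pseudo-absence data: draw background points, make repeated stratified 80/20
splits with k-fold cross-validation inside the training portion, evaluate
every roster learner by rank-based AUC and threshold-optimized TSS
(sensitivity + specificity - 1), keep only learners passing strict AUC and
TSS gates, combine survivors by a weighted mean (weights proportional to the
gating metric), and render the ensemble probability as an integer 0-1000
suitability raster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .grids import CovariateStack, GridSpec
from .learners import ROSTER, FittedLearner, fit_learner

__all__ = [
    "EvaluationResult",
    "EnsembleModel",
    "SuitabilityMap",
    "GateFailureError",
    "generate_pseudoabsences",
    "build_training_table",
    "make_folds",
    "auc_score",
    "confusion_rates",
    "evaluate",
    "cross_validate_roster",
    "build_ensemble",
    "predict_map",
    "variable_importance",
    "response_curve",
    "fit_sdm",
]

log = logging.getLogger(__name__)


class GateFailureError(RuntimeError):
    """No candidate learner passed the AUC/TSS gate."""

    def __init__(self, metrics: pd.DataFrame, gate):
        self.metrics = metrics
        super().__init__(
            f"no learner passed the gate AUC>{gate[0]}, TSS>{gate[1]};"
            f" candidate metrics:\n{metrics.to_string()}"
        )


@dataclass(frozen=True)
class EvaluationResult:
    sensitivity: float
    specificity: float
    tss: float
    auc: float
    threshold: float


@dataclass(frozen=True)
class SuitabilityMap:
    """Integer 0-1000 suitability per cell; nodata outside the mask."""

    grid: GridSpec
    values: np.ndarray  # int array, shape = grid.shape
    nodata: int = -1

    def probabilities(self) -> np.ndarray:
        """Back to [0, 1] floats with NaN outside the mask."""
        p = self.values.astype(float) / 1000.0
        p[self.values == self.nodata] = np.nan
        return p


# ---------------------------------------------------------------------------
# background points and design tables


def generate_pseudoabsences(
    stack: CovariateStack,
    presences: pd.DataFrame,
    n: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw n background cells uniformly, excluding cells holding a presence."""
    rng = np.random.default_rng(seed)
    grid = stack.grid
    pi, pj = grid.cell_of(presences["lon"].to_numpy(), presences["lat"].to_numpy())
    presence_cells = set((pi * grid.n_cols + pj).tolist())
    candidates = np.array(
        [c for c in np.flatnonzero(stack.mask.ravel()) if c not in presence_cells]
    )
    if n > candidates.size:
        raise ValueError(f"requested {n} pseudo-absences but only {candidates.size} free cells")
    chosen = rng.choice(candidates, size=n, replace=False)
    i, j = np.divmod(chosen, grid.n_cols)
    lon, lat = grid.cell_center(i, j)
    return pd.DataFrame({"species": "pseudo-absence", "lon": lon, "lat": lat,
                         "source": "background"})


def build_training_table(
    stack: CovariateStack,
    presences: pd.DataFrame,
    absences: pd.DataFrame,
    variables: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariate values at presence and background cells -> (features, labels)."""
    variables = variables or stack.names
    xp = stack.values_at(presences["lon"].to_numpy(), presences["lat"].to_numpy(), variables)
    xa = stack.values_at(absences["lon"].to_numpy(), absences["lat"].to_numpy(), variables)
    X = pd.concat([xp, xa], ignore_index=True)
    y = np.concatenate([np.ones(len(xp), dtype=int), np.zeros(len(xa), dtype=int)])
    keep = ~X.isna().any(axis=1).to_numpy()
    if (~keep).sum():
        log.warning("dropped %d training row(s) outside the valid grid", int((~keep).sum()))
    return X[keep].reset_index(drop=True), y[keep]


# ---------------------------------------------------------------------------
# folds


def make_folds(labels, k: int = 10, repetitions: int = 10, holdout: float = 0.2, seed: int = 0):
    """Repeated stratified 80/20 splits with stratified k-fold CV inside training.

    Returns a list (one entry per repetition) of dicts with ``train_idx``,
    ``test_idx`` and ``cv_folds`` (list of (fit_idx, val_idx) into the full
    row range). Every row of the training portion validates exactly once per
    repetition.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k-fold CV needs k >= 2")
    if not 0 < holdout < 1:
        raise ValueError("holdout must be in (0, 1)")
    counts = np.bincount(y, minlength=2)
    if min(counts) * (1 - holdout) < k:
        raise ValueError(f"a class with {min(counts)} members cannot support k={k} folds")
    rng = np.random.default_rng(seed)
    reps = []
    idx = np.arange(y.size)
    for _ in range(repetitions):
        rep_seed = int(rng.integers(2**31 - 1))
        train_idx, test_idx = train_test_split(
            idx, test_size=holdout, stratify=y, random_state=rep_seed
        )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        cv = [
            (train_idx[fit], train_idx[val])
            for fit, val in skf.split(train_idx, y[train_idx])
        ]
        reps.append({"train_idx": train_idx, "test_idx": test_idx, "cv_folds": cv})
    return reps


# ---------------------------------------------------------------------------
# evaluation


def auc_score(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formulation with midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def confusion_rates(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) predicting presence iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    sens = float(pred[y == 1].mean())
    spec = float((~pred)[y == 0].mean())
    return sens, spec


def evaluate(scores, labels) -> EvaluationResult:
    """Rank AUC plus the TSS-optimal threshold over all distinct score values.

    The threshold maximizing sensitivity + specificity - 1 is retained (ties
    broken to the smallest threshold) along with the rates achieved there.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for evaluation")
    auc = auc_score(scores, y)
    best = (-np.inf, np.inf)  # (tss, threshold)
    for t in np.unique(scores):
        sens, spec = confusion_rates(scores, y, t)
        tss = sens + spec - 1
        if tss > best[0] + 1e-15 or (abs(tss - best[0]) <= 1e-15 and t < best[1]):
            best = (tss, t)
    sens, spec = confusion_rates(scores, y, best[1])
    return EvaluationResult(
        sensitivity=sens, specificity=spec, tss=sens + spec - 1,
        auc=auc, threshold=float(best[1]),
    )


def cross_validate_roster(
    X: pd.DataFrame,
    y,
    folds,
    roster=ROSTER,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit/evaluate every roster learner on every repetition x CV fold.

    Returns a tidy frame (learner, repetition, fold, sensitivity, specificity,
    tss, auc, threshold).
    """
    y = np.asarray(y, dtype=int)
    rows = []
    for kind in roster:
        for r, rep in enumerate(folds):
            for f, (fit_idx, val_idx) in enumerate(rep["cv_folds"]):
                learner = fit_learner(kind, X.iloc[fit_idx], y[fit_idx],
                                      seed=seed + 1000 * r + f)
                ev = evaluate(learner.predict_proba(X.iloc[val_idx]), y[val_idx])
                rows.append({
                    "learner": kind, "repetition": r, "fold": f,
                    "sensitivity": ev.sensitivity, "specificity": ev.specificity,
                    "tss": ev.tss, "auc": ev.auc, "threshold": ev.threshold,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ensemble


class EnsembleModel:
    """Gate survivors combined by a weighted mean of predicted probabilities."""

    def __init__(self, members, gate=(0.9, 0.8), weight_metric: str = "TSS"):
        if not members:
            raise ValueError("ensemble needs at least one member")
        total = float(sum(w for _, _, w in members))
        if total <= 0:
            raise ValueError("member weights must be positive")
        self.members = [(k, m, w / total) for k, m, w in members]
        self.gate = gate
        self.weight_metric = weight_metric

    @property
    def weights(self) -> dict[str, float]:
        return {k: w for k, _, w in self.members}

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(X))
        for _, model, w in self.members:
            out += w * np.asarray(model.predict_proba(X), dtype=float)
        return out


def build_ensemble(
    candidates,
    gate: tuple[float, float] = (0.9, 0.8),
    weight_metric: str = "TSS",
) -> EnsembleModel:
    """Keep candidates with AUC and TSS strictly above the gate; weight by metric.

    ``candidates`` is a list of (FittedLearner, EvaluationResult). Raises
    :class:`GateFailureError` (listing every candidate's metrics) if nothing
    survives.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    if weight_metric.upper() not in ("TSS", "AUC"):
        raise ValueError("weight_metric must be 'TSS' or 'AUC'")
    auc_min, tss_min = gate
    survivors = []
    for learner, ev in candidates:
        if ev.auc > auc_min and ev.tss > tss_min:
            w = ev.tss if weight_metric.upper() == "TSS" else ev.auc
            survivors.append((learner.kind, learner, max(w, 0.0)))
    if not survivors:
        metrics = pd.DataFrame(
            [{"learner": l.kind, "auc": ev.auc, "tss": ev.tss} for l, ev in candidates]
        )
        raise GateFailureError(metrics, gate)
    return EnsembleModel(survivors, gate=gate, weight_metric=weight_metric)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def predict_map(ens: EnsembleModel, stack: CovariateStack) -> SuitabilityMap:
    """Cellwise ensemble probability rescaled to integers 0-1000 (half away from zero)."""
    needed = {c for _, m, _ in ens.members for c in m.columns}
    missing = needed - set(stack.names)
    if missing:
        raise KeyError(f"stack is missing model variable layer(s): {sorted(missing)}")
    table = stack.table(sorted(needed))
    p = ens.predict_proba(table)
    values = np.full(stack.grid.shape, -1, dtype=int)
    flat = values.ravel()
    flat[table.index.to_numpy()] = _round_half_away(1000 * p).astype(int)
    return SuitabilityMap(grid=stack.grid, values=flat.reshape(stack.grid.shape), nodata=-1)


# ---------------------------------------------------------------------------
# interpretation


def variable_importance(
    model,
    data: pd.DataFrame,
    n_perm: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance: mean over shuffles of 1 - r(pred, pred_shuffled).

    ``model`` is anything with ``predict_proba(DataFrame)``. Scores are clipped
    to [0, 1]; a constant-prediction model scores 0 everywhere (logged).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    base = np.asarray(model.predict_proba(data), dtype=float)
    if np.std(base) == 0:
        log.warning("constant predictions; importance defined as 0 for all variables")
        return pd.Series(0.0, index=data.columns)
    scores = {}
    for col in data.columns:
        vals = []
        for _ in range(n_perm):
            shuffled = data.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            pred = np.asarray(model.predict_proba(shuffled), dtype=float)
            if np.std(pred) == 0:
                vals.append(1.0)
            else:
                vals.append(1.0 - float(np.corrcoef(base, pred)[0, 1]))
        scores[col] = float(np.clip(np.mean(vals), 0.0, 1.0))
    return pd.Series(scores)


def response_curve(model, variable: str, data: pd.DataFrame, n_points: int = 50) -> pd.DataFrame:
    """Evaluation-strip response: sweep one variable, others held at their medians."""
    if variable not in data.columns:
        raise KeyError(f"unknown variable {variable!r}")
    lo = float(data[variable].min())
    hi = float(data[variable].max())
    sweep = np.linspace(lo, hi, n_points)
    strip = pd.DataFrame(
        {c: np.full(n_points, float(data[c].median())) for c in data.columns}
    )
    strip[variable] = sweep
    return pd.DataFrame({"value": sweep, "probability": model.predict_proba(strip)})


# ---------------------------------------------------------------------------
# high-level fit


def fit_sdm(
    X: pd.DataFrame,
    y,
    roster=ROSTER,
    k: int = 10,
    repetitions: int = 10,
    holdout: float = 0.2,
    gate: tuple[float, float] = (0.9, 0.8),
    weight_metric: str = "TSS",
    seed: int = 0,
):
    """Cross-validate the roster, gate on mean metrics, refit survivors.

    Per-learner metrics are means over all repetitions x folds. Survivors are
    refit on the first repetition's 80% training portion; the returned
    ensemble's held-out evaluation uses that repetition's 20% test rows.

    Returns (ensemble, cv_table, mean_metrics, heldout_eval).
    """
    y = np.asarray(labels_arr := np.asarray(y, dtype=int))
    folds = make_folds(labels_arr, k=k, repetitions=repetitions, holdout=holdout, seed=seed)
    cv = cross_validate_roster(X, y, folds, roster=roster, seed=seed)
    mean_metrics = (
        cv.groupby("learner", sort=False)[["sensitivity", "specificity", "tss", "auc"]]
        .mean()
        .reset_index()
    )
    train_idx = folds[0]["train_idx"]
    test_idx = folds[0]["test_idx"]
    candidates = []
    for _, row in mean_metrics.iterrows():
        learner = fit_learner(row["learner"], X.iloc[train_idx], y[train_idx], seed=seed)
        ev = EvaluationResult(
            sensitivity=row["sensitivity"], specificity=row["specificity"],
            tss=row["tss"], auc=row["auc"],
            threshold=float(cv[cv["learner"] == row["learner"]]["threshold"].mean()),
        )
        candidates.append((learner, ev))
    ens = build_ensemble(candidates, gate=gate, weight_metric=weight_metric)
    heldout = evaluate(ens.predict_proba(X.iloc[test_idx]), y[test_idx])
    return ens, cv, mean_metrics, heldout
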