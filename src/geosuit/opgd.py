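"""Optimal-parameters geographical detector.

The geographical detector quantifies spatial stratified heterogeneity: how
much of the variance of a response Y (here, habitat suitability) is explained
by stratifying space on a covariate X. The power of determinant is

    q = 1 - SSW / SST,
    SSW = sum_h sum_{i in h} (y_i - ybar_h)^2,   SST = sum_i (y_i - ybar)^2,

computed throughout via sums of squares, which makes the identity
``N_h * sigma_h^2 = SS_h`` (population-variance convention) exact and avoids
any sample/population ambiguity.

The "optimal parameters" part searches five discretization methods (equal
width, natural/Fisher-Jenks breaks, quantile, geometric-progression widths,
standard-deviation bands) crossed with 3-7 classes and keeps the scheme with
the highest q per covariate. On top of the factor detector come:

- interaction detector: q of the overlay of two stratifications versus the
  individual q's, classified into enhance/weaken/independent types;
- ecological detector: an F-ratio comparing within-stratum sums of squares of
  two stratifications;
- risk detector: per-stratum means with pairwise Welch t-tests and a
  classification of each stratum as elevated / intermediate / decreased
  suitability.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "METHODS",
    "DiscretizationScheme",
    "FactorResult",
    "InteractionResult",
    "EcoResult",
    "RiskResult",
    "discretize",
    "assign_strata",
    "q_statistic",
    "q_significance",
    "evaluate_candidates",
    "optimize_discretization",
    "factor_detector",
    "interaction_detector",
    "classify_interaction",
    "ecological_detector",
    "risk_detector",
    "fisher_jenks_breaks",
]

log = logging.getLogger(__name__)

# search order; also the tie-break order in the discretization search
METHODS = ("equal", "natural", "quantile", "geometric", "sd")

INTERACTION_TYPES = (
    "Enhance-nonlinear", "Enhance-bi", "Independent", "Weaken-uni", "Weaken-nonlinear",
)


@dataclass(frozen=True)
class DiscretizationScheme:
    method: str
    n_classes: int
    breaks: tuple
    achieved_q: float | None = None


@dataclass(frozen=True)
class FactorResult:
    variable: str
    scheme: DiscretizationScheme
    q: float
    p_value: float | None = None


@dataclass(frozen=True)
class InteractionResult:
    pair: tuple
    q1: float
    q2: float
    q12: float
    type: str


@dataclass(frozen=True)
class EcoResult:
    pair: tuple
    F: float
    ssw_x1: float
    ssw_x2: float
    L1: int
    L2: int
    decision: str  # "Y" / "N"


@dataclass(frozen=True)
class RiskResult:
    variable: str
    stratum_means: pd.Series
    stratum_counts: pd.Series
    t_matrix: pd.DataFrame
    significant: pd.DataFrame
    levels: dict = field(default_factory=dict)  # stratum -> elevated/intermediate/decreased
    trend: float = float("nan")


# ---------------------------------------------------------------------------
# discretization


def _equal_breaks(x: np.ndarray, k: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    return np.linspace(lo, hi, k + 1)[1:-1]


def _quantile_breaks(x: np.ndarray, k: int) -> np.ndarray:
    return np.quantile(x, np.arange(1, k) / k)


def _sd_breaks(x: np.ndarray, k: int) -> np.ndarray:
    """Half-sd bands outward from the mean: mean +/- 0.5 sd, +/- 1.5 sd, ...

    For an odd number of interior breaks the mean itself is included. Breaks
    falling outside the data range are clipped away (the class would be empty).
    """
    mu, sd = float(x.mean()), float(x.std())
    n_breaks = k - 1
    offsets: list[float] = [] if n_breaks % 2 == 0 else [0.0]
    j = 0
    while len(offsets) < n_breaks:
        offsets.extend([-(0.5 + j), 0.5 + j])
        j += 1
    breaks = np.sort(mu + sd * np.asarray(offsets[:n_breaks]))
    lo, hi = float(x.min()), float(x.max())
    return breaks[(breaks > lo) & (breaks < hi)]


def _geometric_breaks(x: np.ndarray, k: int, ratio: float = 2.0) -> np.ndarray:
    """Interval widths in geometric progression w, w*r, ..., summing to the range."""
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo
    w0 = span * (ratio - 1) / (ratio**k - 1)
    widths = w0 * ratio ** np.arange(k)
    return lo + np.cumsum(widths)[:-1]


def fisher_jenks_breaks(x: np.ndarray, k: int, max_n: int = 2000) -> np.ndarray:
    """Exact Fisher-Jenks natural breaks (min within-class sum of squares).

    Dynamic program over sorted values, O(k n^2). Inputs longer than ``max_n``
    are reduced to ``max_n`` evenly spaced order statistics before the search
    (the optimum on order statistics is an excellent proxy at that density);
    class boundaries are reported as the maximum value of each class.
    """
    v = np.sort(np.asarray(x, dtype=float))
    if v.size > max_n:
        take = np.unique(np.linspace(0, v.size - 1, max_n).round().astype(int))
        v = v[take]
    n = v.size
    if np.unique(v).size < k:
        raise ValueError(f"need >= {k} distinct values for {k} natural-breaks classes")
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def sse(i: np.ndarray, j: int) -> np.ndarray:
        # within-class SSE of v[i..j] inclusive, vectorized over i
        cnt = j - i + 1
        s = s1[j + 1] - s1[i]
        return (s2[j + 1] - s2[i]) - s * s / cnt

    cost = np.full((k + 1, n), np.inf)
    back = np.zeros((k + 1, n), dtype=int)
    ends = np.arange(n)
    cost[1, :] = (s2[ends + 1] - s1[ends + 1] ** 2 / (ends + 1))
    for c in range(2, k + 1):
        for i in range(c - 1, n):
            starts = np.arange(c - 1, i + 1)
            total = cost[c - 1, starts - 1] + sse(starts, i)
            best = int(np.argmin(total))
            cost[c, i] = total[best]
            back[c, i] = starts[best]
    # recover class boundaries
    breaks = []
    end = n - 1
    for c in range(k, 1, -1):
        start = back[c, end]
        breaks.append(v[start - 1])
        end = start - 1
    return np.array(sorted(breaks))


def discretize(x, method: str, k: int, allow_any_k: bool = False) -> DiscretizationScheme:
    """Compute interior class breaks for one method and class count.

    Classes are half-open bins (-inf, b1], (b1, b2], ...; duplicate breaks are
    collapsed, so the achieved class count can be lower than requested.
    """
    x = np.asarray(x, dtype=float)
    if method not in METHODS:
        raise ValueError(f"unknown discretization method {method!r}")
    if not allow_any_k and not (3 <= k <= 7):
        raise ValueError("class count k must lie in [3, 7] (override with allow_any_k)")
    if np.unique(x).size < k:
        raise ValueError(f"need >= {k} distinct values for k={k}")
    if method == "equal":
        breaks = _equal_breaks(x, k)
    elif method == "quantile":
        breaks = _quantile_breaks(x, k)
    elif method == "sd":
        breaks = _sd_breaks(x, k)
    elif method == "geometric":
        breaks = _geometric_breaks(x, k)
    else:
        breaks = fisher_jenks_breaks(x, k)
    breaks = np.unique(breaks)
    return DiscretizationScheme(method=method, n_classes=len(breaks) + 1,
                                breaks=tuple(float(b) for b in breaks))


def assign_strata(x, breaks) -> np.ndarray:
    """Labels 1..k for half-open bins (-inf,b1], (b1,b2], ...; empty classes collapsed."""
    x = np.asarray(x, dtype=float)
    breaks = np.asarray(breaks, dtype=float)
    if breaks.size and not np.all(np.diff(breaks) > 0):
        raise ValueError("breaks must be strictly ascending")
    labels = np.searchsorted(breaks, x, side="left") + 1
    present = np.unique(labels)
    if present.size < breaks.size + 1:
        log.info("collapsed %d empty class(es)", breaks.size + 1 - present.size)
        relabel = {old: new + 1 for new, old in enumerate(present)}
        labels = np.vectorize(relabel.get)(labels)
    return labels


# ---------------------------------------------------------------------------
# q statistic


def _sums_of_squares(y: np.ndarray, strata: np.ndarray) -> tuple[float, float, int]:
    codes, _ = pd.factorize(strata)
    n = np.bincount(codes).astype(float)
    s = np.bincount(codes, weights=y)
    s2 = np.bincount(codes, weights=y * y)
    ssw = float(np.sum(s2 - s * s / n))
    sst = float(np.sum(y * y) - y.sum() ** 2 / y.size)
    return ssw, sst, len(n)


def q_statistic(y, strata) -> float:
    """q = 1 - SSW/SST: variance fraction explained by the stratification."""
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    if y.size != strata.size:
        raise ValueError("y and strata must align")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ssw, sst, _ = _sums_of_squares(y, strata)
    if sst <= 0:
        raise ValueError("zero total variance: q undefined")
    return float(np.clip(1.0 - ssw / sst, 0.0, 1.0))


def q_significance(y, strata) -> float:
    """p-value of q via its noncentral-F reference distribution.

    With L strata and N observations, F = (N-L)/(L-1) * q/(1-q) is referred to
    a noncentral F(L-1, N-L; lambda) with

        lambda = [ sum_h ybar_h^2 - (sum_h sqrt(N_h) ybar_h)^2 / N ] / sigma^2

    (population variance sigma^2 = SST/N). Under a random stratification
    lambda is near zero and the reference reduces to a central F, so null
    p-values are approximately uniform.
    """
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    codes, _ = pd.factorize(strata)
    L = codes.max() + 1
    N = y.size
    if L < 2:
        raise ValueError("q significance undefined for a single stratum")
    if N - L < 1:
        raise ValueError("too few observations for the reference distribution")
    q = q_statistic(y, strata)
    if q >= 1.0:
        return 0.0
    n_h = np.bincount(codes).astype(float)
    mean_h = np.bincount(codes, weights=y) / n_h
    sigma2 = float(np.var(y))  # population convention, consistent with SS identity
    lam = (np.sum(mean_h**2) - (np.sum(np.sqrt(n_h) * mean_h)) ** 2 / N) / sigma2
    f_val = (N - L) / (L - 1) * q / (1 - q)
    return float(stats.ncf.sf(f_val, L - 1, N - L, max(lam, 0.0)))


# ---------------------------------------------------------------------------
# discretization search


def evaluate_candidates(
    x,
    y,
    methods=METHODS,
    k_range=range(3, 8),
) -> list[DiscretizationScheme]:
    """q for every (method, k) candidate; degenerate candidates logged and skipped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = []
    for method, k in itertools.product(methods, k_range):
        try:
            scheme = discretize(x, method, k, allow_any_k=True)
            strata = assign_strata(x, scheme.breaks)
            if np.unique(strata).size < 2:
                raise ValueError("single occupied class")
            q = q_statistic(y, strata)
        except ValueError as exc:
            log.info("skipping degenerate candidate (%s, k=%d): %s", method, k, exc)
            continue
        out.append(DiscretizationScheme(
            method=method, n_classes=int(np.unique(strata).size),
            breaks=scheme.breaks, achieved_q=q,
        ))
    return out


def optimize_discretization(
    x,
    y,
    methods=METHODS,
    k_range=range(3, 8),
) -> DiscretizationScheme:
    """Best discretization by achieved q; ties -> fewer classes, then method order."""
    candidates = evaluate_candidates(x, y, methods=methods, k_range=k_range)
    if not candidates:
        raise ValueError("all discretization candidates were degenerate")
    method_rank = {m: i for i, m in enumerate(methods)}
    return min(
        candidates,
        key=lambda s: (-s.achieved_q, s.n_classes, method_rank[s.method]),
    )


def factor_detector(
    y,
    x,
    variable: str = "x",
    methods=METHODS,
    k_range=range(3, 8),
    with_significance: bool = False,
) -> FactorResult:
    """Optimal-parameters factor detector for one covariate."""
    scheme = optimize_discretization(x, y, methods=methods, k_range=k_range)
    p = None
    if with_significance:
        p = q_significance(y, assign_strata(x, scheme.breaks))
    return FactorResult(variable=variable, scheme=scheme, q=float(scheme.achieved_q), p_value=p)


# ---------------------------------------------------------------------------
# interaction detector


def _drop_small_strata(y: np.ndarray, strata: np.ndarray, min_stratum: int):
    codes, uniques = pd.factorize(strata)
    counts = np.bincount(codes)
    small = counts < min_stratum
    if small.any():
        keep = ~small[codes]
        log.info("dropped %d stratum(-a) (%d obs) below the minimum size %d",
                 int(small.sum()), int((~keep).sum()), min_stratum)
        return y[keep], strata[keep]
    return y, strata


def classify_interaction(q1: float, q2: float, q12: float, tol: float = 1e-9) -> str:
    """Standard geographical-detector interaction typology.

    Enhance-nonlinear: q12 > q1 + q2; Independent: q12 = q1 + q2 (within tol);
    Enhance-bi: max(q1,q2) < q12 < q1+q2; Weaken-uni: min <= q12 < max;
    Weaken-nonlinear: q12 < min(q1,q2). Boundary values within ``tol`` of a
    threshold resolve to the stronger (enhance-side) category.
    """
    lo, hi = min(q1, q2), max(q1, q2)
    if abs(q12 - (q1 + q2)) <= tol:
        return "Independent"
    if q12 > q1 + q2:
        return "Enhance-nonlinear"
    if q12 > hi - tol:
        return "Enhance-bi"
    if q12 >= lo - tol:
        return "Weaken-uni"
    return "Weaken-nonlinear"


def interaction_detector(
    y,
    strata_a,
    strata_b,
    pair: tuple = ("X1", "X2"),
    min_stratum: int = 10,
    tol: float = 1e-9,
) -> InteractionResult:
    """q of the overlay (cross-classification) of two stratifications vs each alone.

    The minimum-stratum-size rule is applied to each computation independently
    (A, B and the overlay); without dropping, overlay refinement guarantees
    q12 >= max(q1, q2).
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(strata_a)
    b = np.asarray(strata_b)
    if not (y.size == a.size == b.size):
        raise ValueError("y and both strata must align")
    ya, aa = _drop_small_strata(y, a, min_stratum)
    yb, bb = _drop_small_strata(y, b, min_stratum)
    overlay = pd.factorize(pd.Series(zip(a.tolist(), b.tolist())))[0]
    yo, oo = _drop_small_strata(y, overlay, min_stratum)
    q1 = q_statistic(ya, aa)
    q2 = q_statistic(yb, bb)
    q12 = q_statistic(yo, oo)
    return InteractionResult(pair=pair, q1=q1, q2=q2, q12=q12,
                             type=classify_interaction(q1, q2, q12, tol=tol))


# ---------------------------------------------------------------------------
# ecological detector


def ecological_detector(
    y,
    strata_a,
    strata_b,
    alpha: float = 0.05,
    pair: tuple = ("X1", "X2"),
    min_stratum: int = 1,
) -> EcoResult:
    """F-ratio test of whether two stratifications differ in within-stratum SS.

    F = [N1 (N2-1) SSW1] / [N2 (N1-1) SSW2]; the null SSW1 = SSW2 is rejected
    (decision "Y") if F falls above the upper-alpha or below the lower-alpha
    quantile of F(N1-1, N2-1), so either ordering of the pair flags the same
    difference. Zero SSW on one side flags significance outright.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(strata_a)
    b = np.asarray(strata_b)
    ya, aa = _drop_small_strata(y, a, min_stratum)
    yb, bb = _drop_small_strata(y, b, min_stratum)
    ssw1, _, L1 = _sums_of_squares(ya, aa)
    ssw2, _, L2 = _sums_of_squares(yb, bb)
    n1, n2 = ya.size, yb.size
    if ssw2 <= 0 and ssw1 <= 0:
        return EcoResult(pair=pair, F=1.0, ssw_x1=ssw1, ssw_x2=ssw2, L1=L1, L2=L2, decision="N")
    if ssw2 <= 0:
        return EcoResult(pair=pair, F=np.inf, ssw_x1=ssw1, ssw_x2=ssw2, L1=L1, L2=L2, decision="Y")
    f_val = (n1 * (n2 - 1) * ssw1) / (n2 * (n1 - 1) * ssw2)
    upper = stats.f.ppf(1 - alpha, n1 - 1, n2 - 1)
    lower = stats.f.ppf(alpha, n1 - 1, n2 - 1)
    decision = "Y" if (f_val > upper or f_val < lower) else "N"
    return EcoResult(pair=pair, F=float(f_val), ssw_x1=ssw1, ssw_x2=ssw2,
                     L1=L1, L2=L2, decision=decision)


# ---------------------------------------------------------------------------
# risk detector


def _welch(y1: np.ndarray, y2: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and two-sided p with Welch-Satterthwaite dof."""
    n1, n2 = y1.size, y2.size
    v1, v2 = y1.var(ddof=1), y2.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return (0.0, 1.0) if y1.mean() == y2.mean() else (np.inf, 0.0)
    t = (y1.mean() - y2.mean()) / np.sqrt(se2)
    dof = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    return float(t), float(2 * stats.t.sf(abs(t), dof))


def risk_detector(
    y,
    strata,
    alpha: float = 0.05,
    variable: str = "x",
) -> RiskResult:
    """Per-stratum suitability means, pairwise Welch tests and risk levels.

    Strata with fewer than 2 observations are merged into the nearest
    neighbouring stratum (warned). A stratum is *elevated* (resp. *decreased*)
    when its mean is significantly above (below) the pooled mean of all other
    strata by a Welch test at alpha / L (Bonferroni across the L stratum
    tests); otherwise *intermediate*. ``trend`` is the Spearman rank
    correlation between stratum order and stratum mean.
    """
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata).copy()
    labels = np.unique(strata)
    # merge undersized strata into their nearest (by label order) neighbour
    for lab in labels:
        if (strata == lab).sum() < 2:
            others = labels[labels != lab]
            if others.size == 0:
                raise ValueError("cannot merge: only one stratum")
            nearest = others[np.argmin(np.abs(others.astype(float) - float(lab)))]
            log.warning("merged stratum %r (n<2) into %r", lab, nearest)
            strata[strata == lab] = nearest
            labels = np.unique(strata)
    groups = {lab: y[strata == lab] for lab in labels}
    means = pd.Series({lab: g.mean() for lab, g in groups.items()})
    counts = pd.Series({lab: g.size for lab, g in groups.items()})
    L = len(labels)
    t_mat = pd.DataFrame(0.0, index=labels, columns=labels)
    sig = pd.DataFrame(False, index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            t, p = _welch(groups[la], groups[lb])
            t_mat.loc[la, lb] = t
            t_mat.loc[lb, la] = -t
            sig.loc[la, lb] = sig.loc[lb, la] = p < alpha
    levels = {}
    for lab in labels:
        rest = y[strata != lab]
        if rest.size < 2:
            levels[lab] = "intermediate"
            continue
        t, p = _welch(groups[lab], rest)
        if p < alpha / L and t > 0:
            levels[lab] = "elevated"
        elif p < alpha / L and t < 0:
            levels[lab] = "decreased"
        else:
            levels[lab] = "intermediate"
    if L >= 2:
        trend = float(stats.spearmanr(np.arange(L), means.to_numpy()).statistic)
    else:
        trend = float("nan")
    return RiskResult(variable=variable, stratum_means=means, stratum_counts=counts,
                      t_matrix=t_mat, significant=sig, levels=levels, trend=trend)
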