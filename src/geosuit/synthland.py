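"""Synthetic landscapes with known structure.

Every downstream stage (variable screening, the learner ensemble, the
geographical detectors) is exercised against landscapes whose generating
process is fully known: smoothed Gaussian random fields for the covariates,
optionally constructed to hit a target pairwise correlation, and a suitability
surface built on the logit scale from linear terms, one stratified
(step-function) term, one pairwise interaction and Gaussian noise.

Putting the noise on the logit scale keeps the variance decomposition exact:
for a stratified term with between-stratum variance B over cells and
independent residual variance V, the q-statistic of the true strata on
logit(p) converges to B / (B + V) as the grid grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for callers)

from .grids import FAMILIES, CovariateStack, GridSpec

__all__ = [
    "VarSpec",
    "TrueModel",
    "make_stack",
    "blob_mask",
    "step_term",
    "linear_predictor",
    "true_suitability",
    "sample_occurrences",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VarSpec:
    """One synthetic covariate: smoothed noise, optionally correlated to a partner.

    ``smoothness`` is the Gaussian kernel standard deviation in cells (0 gives
    white noise). With a partner, the layer is ``rho * partner + sqrt(1-rho^2) *
    independent`` so its sample correlation with the partner is close to rho.
    """

    name: str
    family: str = "bioclim"
    smoothness: float = 3.0
    partner: str | None = None
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        if self.partner is not None and not (-1.0 < self.rho < 1.0):
            raise ValueError("target correlation must lie in (-1, 1)")


@dataclass(frozen=True)
class TrueModel:
    """Known generating model for the suitability surface (logit scale)."""

    linear_coefs: dict = field(default_factory=dict)
    step_var: str | None = None
    step_breaks: tuple = ()
    step_levels: tuple = ()
    interaction: tuple | None = None  # (var_a, var_b, coefficient)
    intercept: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        breaks = np.asarray(self.step_breaks, dtype=float)
        if breaks.size and not np.all(np.diff(breaks) > 0):
            raise ValueError("step_breaks must be strictly ascending")
        if self.step_var is not None and len(self.step_levels) != len(self.step_breaks) + 1:
            raise ValueError("need len(step_levels) == len(step_breaks) + 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def variables(self) -> list[str]:
        names = list(self.linear_coefs)
        if self.step_var is not None:
            names.append(self.step_var)
        if self.interaction is not None:
            names.extend(self.interaction[:2])
        # stable de-dup
        return list(dict.fromkeys(names))


def _smoothed_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    if smoothness > 0:
        z = gaussian_filter(z, sigma=smoothness, mode="reflect")
    return z


def _standardize(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = values[mask]
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate layer: zero variance over masked-in cells")
    return (values - v.mean()) / sd


def make_stack(
    grid: GridSpec,
    var_specs: Sequence[VarSpec],
    seed: int,
    mask: np.ndarray | None = None,
) -> CovariateStack:
    """Generate a stack of standardized smoothed random fields.

    Layers are standardized to zero mean / unit variance over masked-in cells;
    masked-out cells are set to the grid's nodata value. Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    layers: dict[str, np.ndarray] = {}
    family: dict[str, str] = {}
    for spec in var_specs:
        if spec.name in layers:
            raise ValueError(f"duplicate layer name {spec.name!r}")
        z = _standardize(_smoothed_field(rng, grid.shape, spec.smoothness), mask)
        if spec.partner is not None:
            if spec.partner not in layers:
                raise ValueError(f"unknown correlation partner {spec.partner!r}")
            z = spec.rho * layers[spec.partner] + np.sqrt(1 - spec.rho**2) * z
            z = _standardize(z, mask)
        z = z.copy()
        z[~mask] = grid.nodata_value
        layers[spec.name] = z
        family[spec.name] = spec.family
    return CovariateStack(grid=grid, layers=layers, family=family, mask=mask)


def blob_mask(grid: GridSpec, seed: int, keep_fraction: float = 0.7) -> np.ndarray:
    """A smooth blob-shaped study-area mask keeping roughly ``keep_fraction`` of cells."""
    rng = np.random.default_rng(seed)
    z = gaussian_filter(rng.standard_normal(grid.shape), sigma=max(grid.shape) / 8)
    thresh = np.quantile(z, 1 - keep_fraction)
    return z >= thresh


def step_term(x: np.ndarray, breaks: Sequence[float], levels: Sequence[float]) -> np.ndarray:
    """Evaluate the stratified (step-function) effect of a covariate."""
    idx = np.searchsorted(np.asarray(breaks, dtype=float), x, side="left")
    return np.asarray(levels, dtype=float)[idx]


def linear_predictor(stack: CovariateStack, model: TrueModel) -> np.ndarray:
    """Deterministic part of the logit surface (no noise), full-grid array.

    Masked-out cells are NaN.
    """
    for v in model.variables():
        if v not in stack.layers:
            raise KeyError(f"model variable {v!r} not in stack")
    eta = np.full(stack.grid.shape, np.nan)
    m = stack.mask
    acc = np.full(m.sum(), model.intercept, dtype=float)
    for name, coef in model.linear_coefs.items():
        acc += coef * stack.layers[name][m]
    if model.step_var is not None:
        acc += step_term(stack.layers[model.step_var][m], model.step_breaks, model.step_levels)
    if model.interaction is not None:
        a, b, coef = model.interaction
        acc += coef * stack.layers[a][m] * stack.layers[b][m]
    eta[m] = acc
    return eta


def true_suitability(stack: CovariateStack, model: TrueModel, seed: int) -> np.ndarray:
    """True per-cell suitability probability: logistic(eta + noise).

    Returns a full-grid array with the grid's nodata value outside the mask;
    values on masked-in cells lie strictly in (0, 1).
    """
    rng = np.random.default_rng(seed)
    eta = linear_predictor(stack, model)
    m = stack.mask
    p = np.full(stack.grid.shape, stack.grid.nodata_value, dtype=float)
    noise = model.noise_sd * rng.standard_normal(int(m.sum())) if model.noise_sd > 0 else 0.0
    p[m] = expit(eta[m] + noise)
    return p


def sample_occurrences(
    p_field: np.ndarray,
    stack: CovariateStack,
    n_presence: int,
    seed: int,
    species: str = "synthetic-species",
    source: str = "simulated",
) -> pd.DataFrame:
    """Draw presence cells without replacement with probability proportional to p.

    Emits the cell-centre lon/lat of each drawn cell as an occurrence table
    with columns ``species, lon, lat, source``.
    """
    rng = np.random.default_rng(seed)
    m = stack.mask
    cell_ids = np.flatnonzero(m.ravel())
    if n_presence > cell_ids.size:
        raise ValueError(f"n_presence={n_presence} exceeds {cell_ids.size} masked-in cells")
    w = np.asarray(p_field).ravel()[cell_ids].astype(float)
    if np.any(w < 0):
        raise ValueError("p field must be non-negative")
    if np.count_nonzero(w) < n_presence:
        raise ValueError("fewer cells with positive probability than n_presence")
    chosen = rng.choice(cell_ids, size=n_presence, replace=False, p=w / w.sum())
    i, j = np.divmod(chosen, stack.grid.n_cols)
    lon, lat = stack.grid.cell_center(i, j)
    return pd.DataFrame(
        {"species": species, "lon": lon, "lat": lat, "source": source}
    )
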