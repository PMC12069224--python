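"""Occurrence-record ingestion, cleaning and spatial thinning.

Occurrence tables are plain pandas DataFrames with columns
``species, lon, lat, source`` (lon/lat in decimal degrees). Records are
cleaned (unparseable or out-of-range coordinates dropped, exact coordinate
duplicates collapsed), clipped to the study-area mask, and thinned to at most
one record per grid cell to curb spatial autocorrelation and sampling bias.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import CovariateStack, GridSpec

__all__ = ["load_occurrences", "filter_to_mask", "thin_to_grid"]

log = logging.getLogger(__name__)

COLUMNS = ["species", "lon", "lat", "source"]


def load_occurrences(
    path,
    lon_col: str = "lon",
    lat_col: str = "lat",
    species_col: str = "species",
    source_col: str = "source",
) -> pd.DataFrame:
    """Read an occurrence CSV, dropping bad coordinates and exact duplicates.

    Rows with unparseable/missing coordinates or coordinates outside
    [-180, 180] x [-90, 90] are dropped with a logged count; records sharing
    the exact same (lon, lat) are collapsed to the first. Raises if required
    columns are missing or nothing survives cleaning.
    """
    df = pd.read_csv(path)
    missing = [c for c in (lon_col, lat_col) if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence file missing required column(s): {missing}")
    out = pd.DataFrame(
        {
            "species": df[species_col] if species_col in df.columns else "unknown",
            "lon": pd.to_numeric(df[lon_col], errors="coerce"),
            "lat": pd.to_numeric(df[lat_col], errors="coerce"),
            "source": df[source_col] if source_col in df.columns else "unknown",
        }
    )
    n0 = len(out)
    ok = (
        out["lon"].notna()
        & out["lat"].notna()
        & out["lon"].between(-180, 180)
        & out["lat"].between(-90, 90)
    )
    out = out[ok]
    if n0 - len(out):
        log.warning("dropped %d record(s) with missing/out-of-range coordinates", n0 - len(out))
    n1 = len(out)
    out = out.drop_duplicates(subset=["lon", "lat"], keep="first")
    if n1 - len(out):
        log.info("collapsed %d duplicate coordinate record(s)", n1 - len(out))
    if out.empty:
        raise ValueError("no valid occurrence records after cleaning")
    return out.reset_index(drop=True)


def filter_to_mask(occ: pd.DataFrame, stack: CovariateStack) -> pd.DataFrame:
    """Keep records whose containing cell is on-grid and masked-in."""
    grid = stack.grid
    i, j = grid.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    ok = grid.in_bounds(i, j)
    ii = np.clip(i, 0, grid.n_rows - 1)
    jj = np.clip(j, 0, grid.n_cols - 1)
    ok = ok & stack.mask[ii, jj]
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("boundary filter removed %d record(s)", n_drop)
    out = occ[ok].reset_index(drop=True)
    if out.empty:
        log.warning("no occurrence records remain inside the study area")
    return out


def thin_to_grid(occ: pd.DataFrame, grid: GridSpec, seed: int) -> pd.DataFrame:
    """Retain one record per occupied grid cell, chosen uniformly under ``seed``.

    Output rows are ordered by cell (row-major); the output size equals the
    number of distinct occupied cells, so re-thinning is a no-op.
    """
    rng = np.random.default_rng(seed)
    i, j = grid.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    cell = i * grid.n_cols + j
    keep_rows: list[int] = []
    # iterate cells in sorted order so the choice sequence does not depend on
    # input row order
    groups = pd.Series(np.arange(len(occ))).groupby(cell, sort=True)
    for _, rows in groups:
        members = np.sort(rows.to_numpy())
        keep_rows.append(int(rng.choice(members)))
    return occ.iloc[keep_rows].reset_index(drop=True)
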