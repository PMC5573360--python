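"""Spatial stability and asynchrony statistics over subplot basal areas.

Each 1200 m² plot is tiled into 12 subplots of 10 m × 10 m.  Productivity is
proxied by stem basal area, and the central object is the **subplot
matrix**: species (rows) × subplots (columns) with entry (i, k) the summed
basal area (cm²) of species *i* in subplot *k*, exact zero where a species
has no stem in a subplot.  All columns are present even for empty subplots.

From it we compute, per plot:

* spatial stability ``mu / sigma`` of the subplot totals (the inverse
  coefficient of variation of productivity across subplots; high when
  productivity is evenly spread),
* the dominant species (maximum total basal area; ties broken
  lexicographically) and its own ``mu / sigma`` stability over the
  zero-filled 12-entry row,
* spatial species asynchrony ``1 - sigma^2 / (sum_i sigma_i)^2`` where
  ``sigma^2`` is the variance of subplot totals and ``sigma_i`` the SD of
  each species' zero-filled row: 0 is perfect synchrony, 1 perfect
  compensation among species across space.

Sample (n-1) standard deviations are used throughout.  The statistics are
unitless ratios, so the basal-area unit cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_metrics import basal_area
from .exceptions import DegenerateStatisticError


@dataclass(frozen=True)
class StabilityResult:
    """mu/sigma stability of a set of replicate productivity values."""

    mean: float
    sd: float
    stability: float  # nan when degenerate
    degenerate: bool  # sigma == 0


def subplot_matrix(plot_trees: pd.DataFrame, *, n_subplots: int = 12) -> pd.DataFrame:
    """Species × subplot basal-area matrix for the stems of one plot.

    Rows are species labels (sorted), columns subplot ids ``1..n_subplots``;
    all columns are emitted even when a subplot holds no stems.
    """
    if plot_trees.empty:
        raise DegenerateStatisticError("plot contains no stems")
    df = plot_trees.copy()
    df["_ba"] = basal_area(df["dbh_cm"].to_numpy(dtype=float))
    mat = df.pivot_table(
        index="species", columns="subplot_id", values="_ba", aggfunc="sum", fill_value=0.0
    )
    mat = mat.reindex(columns=range(1, n_subplots + 1), fill_value=0.0)
    mat = mat.sort_index()
    mat.columns.name = "subplot_id"
    return mat.astype(float)


def spatial_stability(values) -> StabilityResult:
    """mu/sigma of per-subplot totals; sample SD; requires >= 3 replicates."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise DegenerateStatisticError(
            "standard deviation requires at least 3 replicate subplot values"
        )
    mu = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        return StabilityResult(mu, 0.0, float("nan"), True)
    return StabilityResult(mu, sd, mu / sd, False)


def _as_array(matrix) -> np.ndarray:
    arr = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise DegenerateStatisticError("subplot matrix must be 2-D and non-empty")
    if np.any(arr < 0):
        raise DegenerateStatisticError("basal areas must be non-negative")
    return arr


def dominant_species(matrix: pd.DataFrame) -> str:
    """Species with maximum total basal area; ties broken lexicographically."""
    sums = matrix.sum(axis=1)
    best = sums.max()
    return str(sorted(sums.index[sums == best])[0])


def dominant_stability(matrix: pd.DataFrame) -> StabilityResult:
    """mu/sigma stability of the dominant species' zero-filled subplot row."""
    row = matrix.loc[dominant_species(matrix)].to_numpy(dtype=float)
    return spatial_stability(row)


def spatial_asynchrony(matrix) -> float:
    """Spatial species asynchrony ``1 - sigma^2 / (sum_i sigma_i)^2``.

    ``sigma^2`` is the sample variance of the column (subplot) totals and
    ``sigma_i`` the sample SD of species *i*'s zero-filled row.  Exactly 0
    for a monoculture (the ratio is identically 1).  A matrix whose rows are
    all constant has denominator 0 and raises
    :class:`DegenerateStatisticError`.  Accepts a DataFrame or ndarray.
    """
    arr = _as_array(matrix)
    if arr.shape[1] < 3:
        raise DegenerateStatisticError("asynchrony requires >= 3 subplots")
    totals = arr.sum(axis=0)
    var_tot = totals.var(ddof=1)
    sd_rows = arr.std(axis=1, ddof=1)
    denom = sd_rows.sum() ** 2
    if denom == 0.0:
        raise DegenerateStatisticError(
            "all species rows constant across subplots: asynchrony undefined"
        )
    value = 1.0 - var_tot / denom
    if value < -1e-9 or value > 1 + 1e-9:
        warnings.warn(f"asynchrony {value} outside [0,1] beyond rounding", stacklevel=2)
    return float(min(max(value, 0.0), 1.0))
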