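"""Plot-level diversity, dominance and trait statistics.

All indices operate on an *abundance vector*: per-species individual counts
within one plot (stem counts, not basal-area shares).  Relative densities
are ``p_i = a_i / sum(a)``.

Statistics
----------
* species richness ``S`` — number of species present,
* Shannon–Wiener index ``H' = -sum p_i ln p_i`` (natural log, nats),
* Berger–Parker dominance ``N_max / N``,
* functional dispersion ``FDis`` for a single trait (species maximum
  height): the abundance-weighted mean absolute distance of species trait
  values to the abundance-weighted trait centroid,
* the species trait itself: the 99th percentile of all measured heights of
  a species, pooled over the whole study, with linear interpolation between
  order statistics.

Missing tree heights are filled by stochastic regression imputation from a
per-species ``height ~ ln(DBH)`` linear fit (global fit as fallback for
sparsely observed species); a deterministic mode suppresses the resampled
residual so tests can pin exact values.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DomainError

#: Minimum believable tree height (breast height), metres. Imputed values
#: are floored here.
HEIGHT_FLOOR_M = 1.3


def basal_area(dbh_cm):
    """Cross-sectional stem area pi*(DBH/2)^2 in cm² (scalar or array)."""
    arr = np.asarray(dbh_cm, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("DBH must be finite and positive")
    out = np.pi * (arr / 2.0) ** 2
    return float(out) if np.isscalar(dbh_cm) or arr.ndim == 0 else out


def _counts(abundances) -> np.ndarray:
    if isinstance(abundances, Mapping):
        vals = np.asarray(list(abundances.values()), dtype=float)
    else:
        vals = np.asarray(pd.Series(abundances), dtype=float)
    if vals.size == 0:
        raise DomainError("empty abundance vector (plot without stems)")
    if np.any(vals < 1):
        raise DomainError("abundance counts must be >= 1 for present species")
    return vals


def species_richness(abundances) -> int:
    """Number of species present (count of entries with a_i >= 1)."""
    return int(_counts(abundances).size)


def shannon_index(abundances) -> float:
    """Shannon–Wiener index H' = -sum p_i ln p_i in nats; 0 for a monoculture."""
    a = _counts(abundances)
    p = a / a.sum()
    return float(-np.sum(p * np.log(p)))


def berger_parker(abundances) -> float:
    """Berger–Parker dominance N_max / N, in (0, 1]; 1 for a monoculture."""
    a = _counts(abundances)
    return float(a.max() / a.sum())


def functional_dispersion(abundances, traits: Mapping[str, float]) -> float:
    """Single-trait functional dispersion.

    ``c = sum(a_i t_i) / sum(a_i)`` is the abundance-weighted trait
    centroid, ``z_i = |t_i - c|`` the species distance to it, and
    ``FDis = sum(a_i z_i) / sum(a_i)``.  Exactly 0 for a monoculture.
    """
    if isinstance(abundances, Mapping):
        series = pd.Series(abundances, dtype=float)
    else:
        series = pd.Series(abundances).astype(float)
    a = _counts(series)
    missing = [sp for sp in series.index if sp not in traits]
    if missing:
        raise DomainError(f"no trait value for species {missing}")
    t = np.asarray([traits[sp] for sp in series.index], dtype=float)
    c = float(np.sum(a * t) / a.sum())
    z = np.abs(t - c)
    return float(np.sum(a * z) / a.sum())


def max_height_per_species(trees: pd.DataFrame) -> pd.Series:
    """Per-species maximum height trait: 99th percentile of measured heights.

    Heights are pooled over the whole study (all plots), and the percentile
    uses linear interpolation between order statistics.  Heights must be
    complete; impute first.
    """
    if trees["height_m"].isna().any():
        raise DomainError("heights contain missing values; run impute_missing_heights first")
    return trees.groupby("species")["height_m"].agg(
        lambda h: float(np.percentile(np.asarray(h, dtype=float), 99))
    )


def impute_missing_heights(
    trees: pd.DataFrame,
    *,
    seed: int | None = 0,
    deterministic: bool = False,
    min_obs_per_species: int = 3,
) -> tuple[pd.DataFrame, int]:
    """Fill missing heights from a height ~ ln(DBH) linear fit.

    Species with at least ``min_obs_per_species`` observed heights get their
    own fit; others fall back to a fit pooled over all species.  The
    prediction receives a residual resampled (with replacement) from the
    fitting set, unless ``deterministic=True``.  Observed heights are never
    modified.  Returns ``(completed copy, number of imputed cells)``.
    """
    out = trees.copy()
    missing = out["height_m"].isna()
    n_missing = int(missing.sum())
    if n_missing == 0:
        return out, 0
    observed = out[~missing]
    if observed.empty:
        raise DomainError("cannot impute: no observed heights at all")
    rng = np.random.default_rng(seed)

    def _fit(df: pd.DataFrame):
        x = np.log(df["dbh_cm"].to_numpy(dtype=float))
        y = df["height_m"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return coef, resid

    global_coef, global_resid = _fit(observed)
    fits: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sp, grp in observed.groupby("species"):
        if len(grp) >= min_obs_per_species:
            fits[sp] = _fit(grp)

    idx = out.index[missing]
    for i in idx:
        sp = out.at[i, "species"]
        coef, resid = fits.get(sp, (global_coef, global_resid))
        pred = coef[0] + coef[1] * np.log(float(out.at[i, "dbh_cm"]))
        if not deterministic:
            pred += float(rng.choice(resid))
        out.at[i, "height_m"] = max(pred, HEIGHT_FLOOR_M)
    return out, n_missing
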