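"""Synthetic forest-census generator with known statistical structure.

Emulates a mountain-forest survey: 43 sites on a ~100 km × 150 km planar
landscape, 3 rectangular 1200 m² plots per site (within 1 km of the site
centre, pairwise >= 100 m apart), each tiled into 12 subplots of
10 m × 10 m; all stems with DBH >= 3 cm are recorded with species, DBH and
height; plot elevations span 25–819 m; per-plot woody richness spans 4–49.

The generator's value is that the diversity–stability relationship is
*known*.  Per plot:

1. species richness is drawn (optionally correlated with elevation, as in
   real mountain gradients), species are sampled from a fixed pool and
   per-species stem counts from a log-series (lognormal optional) — this
   fixes all abundance-based diversity indices before any spatial layout;
2. a latent log-stability target is set as

       eta = eta0 + g * z_elev + s(x, y) * (1 + e * r_elev) * z_H + noise

   where ``z_H`` is the plot's standardised Shannon index, ``z_elev`` its
   standardised elevation, ``r_elev`` its elevation rank in (0, 1],
   ``s(x, y)`` the configured coefficient surface and ``e`` the
   ``elevation_effect`` (relationship strength grows with elevation);
3. stems are scattered over the 12 subplots by a Dirichlet–multinomial
   whose concentration is chosen so the realised spatial stability of
   total basal area tracks ``exp(eta)``: the ``aggregation`` parameter
   (inverse Dirichlet concentration) is the single dial for subplot-level
   clumping — low aggregation spreads stems evenly (high stability), high
   aggregation concentrates them (low stability).

DBH is lognormal truncated below the census threshold; height follows the
allometry ``a * DBH^b`` plus Gaussian noise, floored at breast height
(1.3 m); a small fraction of heights is blanked completely at random.

Coordinates are planar km by default; ``lonlat=True`` emits equivalent
longitude/latitude for the great-circle path of the GWR engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .community_metrics import HEIGHT_FLOOR_M, shannon_index
from .exceptions import DesignError

# Reference point used when emitting lon/lat instead of planar km.
_LON0, _LAT0 = 113.5, 23.2


@dataclass(frozen=True)
class StudyDesign:
    """Survey layout constants."""

    n_sites: int = 43
    plots_per_site: int = 3
    subplots_per_plot: int = 12
    plot_area_m2: float = 1200.0
    subplot_side_m: float = 10.0
    dbh_min_cm: float = 3.0
    elevation_range_m: tuple[float, float] = (25.0, 819.0)
    richness_range: tuple[int, int] = (4, 49)
    extent_km: tuple[float, float] = (100.0, 150.0)

    def __post_init__(self):
        if self.n_sites < 1 or self.plots_per_site < 1:
            raise DesignError("n_sites and plots_per_site must be positive")
        if abs(self.subplots_per_plot * self.subplot_side_m**2 - self.plot_area_m2) > 1e-9:
            raise DesignError("subplots_per_plot * subplot_side^2 must equal plot_area")
        if self.dbh_min_cm <= 0:
            raise DesignError("dbh_min must be positive")
        for lo, hi in (self.elevation_range_m, self.richness_range):
            if lo > hi:
                raise DesignError("range bounds must be ordered low <= high")

    @property
    def n_plots(self) -> int:
        return self.n_sites * self.plots_per_site

    @property
    def total_area_ha(self) -> float:
        return self.n_plots * self.plot_area_m2 / 1e4


@dataclass(frozen=True)
class SyntheticTruth:
    """Hidden parameters of the generator, kept for recovery tests.

    ``coefficient_surface`` maps plot location to the true slope of latent
    log-stability on standardised Shannon diversity; kinds:
    ``constant`` (value), ``gradient`` (value + dx*(x/ex-1/2) + dy*(y/ey-1/2))
    and ``split`` (+value east of mid-extent, -value west).
    """

    coefficient_surface: dict[str, Any] = field(
        default_factory=lambda: {"kind": "constant", "value": -0.35}
    )
    elevation_effect: float = 1.0  # strength growth with elevation rank
    elevation_main: float = -0.3  # direct elevation effect on log-stability
    richness_elevation_corr: float = 0.5
    aggregation: float = 0.5  # inverse Dirichlet concentration (plot default)
    abundance_model: str = "lognormal"  # or "logseries"
    abundance_param: float = 1.0  # lognormal sigma, or log-series p
    # per-plot evenness heterogeneity: the shape parameter is drawn uniformly
    # from this range (set None to pin it at abundance_param); it decouples
    # the Shannon index from richness as in real communities, where evenness
    # varies between stands of equal richness
    abundance_param_range: tuple[float, float] | None = (0.2, 2.5)
    stems_per_plot: float = 200.0  # expected census size of one plot
    species_pool: int = 180
    allometry_a: float = 1.5
    allometry_b: float = 0.66
    allometry_noise_sd: float = 1.0
    dbh_log_mean: float = 2.0  # ln cm
    dbh_log_sd: float = 0.4
    missing_height_fraction: float = 0.0007
    stability_base: float = 0.3  # eta0, log of baseline mu/sigma
    stability_noise_sd: float = 0.25
    seed: int | None = None

    def __post_init__(self):
        if not (0 <= self.missing_height_fraction < 1):
            raise DesignError("missing_height_fraction must be in [0, 1)")
        if self.aggregation < 0:
            raise DesignError("aggregation must be >= 0")


def evaluate_surface(surface: dict[str, Any], x: float, y: float, extent: tuple[float, float]) -> float:
    """True diversity->log-stability slope at planar location (x, y) km."""
    kind = surface.get("kind", "constant")
    if kind == "constant":
        return float(surface["value"])
    if kind == "gradient":
        ex, ey = extent
        return float(
            surface["value"]
            + surface.get("dx", 0.0) * (x / ex - 0.5)
            + surface.get("dy", 0.0) * (y / ey - 0.5)
        )
    if kind == "split":
        return float(surface["value"] if x > extent[0] / 2 else -surface["value"])
    raise DesignError(f"unknown coefficient surface kind {kind!r}")


# ------------------------------------------------------------- landscape
def generate_landscape(
    design: StudyDesign, seed: int | None = None, *, lonlat: bool = False
) -> pd.DataFrame:
    """Site/plot locations and elevations.

    One row per plot: ``plot_id, site_id, x_km, y_km, elevation_m`` (or
    ``longitude, latitude`` when ``lonlat``).  Elevation follows a smooth
    south–north gradient plus site noise, so elevation classes are
    spatially structured, as on a real mountain flank.  Plots of one site
    lie within 1 km of the site centre and >= 100 m apart.
    """
    if design.n_sites < 2:
        raise DesignError("need at least 2 sites for a landscape")
    rng = np.random.default_rng(seed)
    ex, ey = design.extent_km
    lo, hi = design.elevation_range_m
    rows = []
    for s in range(design.n_sites):
        sx, sy = rng.uniform(0, ex), rng.uniform(0, ey)
        enorm = float(np.clip(sy / ey + rng.normal(0, 0.12), 0, 1))
        site_elev = lo + (hi - lo) * enorm
        offsets: list[tuple[float, float]] = []
        for p in range(design.plots_per_site):
            for _ in range(200):
                r = rng.uniform(0.15, 0.9)  # km, within 1 km of centre
                th = rng.uniform(0, 2 * math.pi)
                ox, oy = r * math.cos(th), r * math.sin(th)
                if all(math.hypot(ox - a, oy - b) >= 0.1 for a, b in offsets):
                    break
            else:  # pragma: no cover - probability ~0
                raise DesignError("could not place plots >= 100 m apart")
            offsets.append((ox, oy))
            elev = float(np.clip(site_elev + rng.normal(0, 10.0), lo, hi))
            rows.append(
                {
                    "plot_id": f"S{s + 1:02d}P{p + 1}",
                    "site_id": f"S{s + 1:02d}",
                    "x_km": sx + ox,
                    "y_km": sy + oy,
                    "elevation_m": elev,
                }
            )
    plots = pd.DataFrame(rows)
    if lonlat:
        lat = _LAT0 + plots["y_km"] / 110.574
        lon = _LON0 + plots["x_km"] / (111.320 * np.cos(np.radians(_LAT0)))
        plots = plots.assign(longitude=lon, latitude=lat).drop(columns=["x_km", "y_km"])
        plots.attrs["coordinate_mode"] = "geographic"
    else:
        plots.attrs["coordinate_mode"] = "planar"
    return plots


# ----------------------------------------------------------- plot census
def _draw_abundances(
    rng: np.random.Generator, design: StudyDesign, truth: SyntheticTruth, richness: int
) -> pd.Series:
    """Species labels and per-species stem counts for one plot.

    Total stem count is Poisson around ``stems_per_plot`` regardless of
    richness (stem density in closed-canopy forest is set by space, not by
    how many species share it); richness only controls how the stems are
    divided.  Relative abundances follow a log-series-shaped (default) or
    lognormal composition, and every sampled species keeps at least one
    stem so realised richness equals the draw.
    """
    if richness > truth.species_pool:
        raise DesignError(
            f"richness {richness} infeasible for species pool of {truth.species_pool}"
        )
    pool = [f"sp{i + 1:03d}" for i in range(truth.species_pool)]
    species = rng.choice(pool, size=richness, replace=False)
    shape = truth.abundance_param
    if truth.abundance_param_range is not None:
        shape = rng.uniform(*truth.abundance_param_range)
    if truth.abundance_model == "logseries":
        v = rng.logseries(shape, size=richness).astype(float)
    elif truth.abundance_model == "lognormal":
        v = rng.lognormal(0.0, shape, size=richness)
    else:
        raise DesignError(f"unknown abundance model {truth.abundance_model!r}")
    w = v / v.sum()
    total = max(richness, int(rng.poisson(truth.stems_per_plot)))
    counts = 1 + rng.multinomial(total - richness, w)
    return pd.Series(counts, index=species, dtype=int)


def _scatter_subplots(
    rng: np.random.Generator, n: int, k: int, aggregation: float
) -> np.ndarray:
    """Subplot ids (1..k) for n stems of one species.

    Dirichlet–multinomial with concentration 1/aggregation per subplot;
    aggregation == 0 is the exact uniform limit (deterministic even split).
    """
    if aggregation <= 0:
        counts = np.full(k, n // k, dtype=int)
        counts[: n % k] += 1
    else:
        w = rng.dirichlet(np.full(k, 1.0 / aggregation))
        counts = rng.multinomial(n, w)
    return np.repeat(np.arange(1, k + 1), counts)


def generate_plot_census(
    plot: pd.Series | dict,
    truth: SyntheticTruth,
    design: StudyDesign,
    seed: int | None = None,
    *,
    richness: int | None = None,
    aggregation: float | None = None,
    abundances: pd.Series | None = None,
) -> pd.DataFrame:
    """Stem records for one plot (TreeRecord rows).

    Richness defaults to a uniform draw over the design's richness range;
    ``abundances`` may be supplied to reuse a pre-drawn community (used by
    :func:`generate_study` so diversity is fixed before subplot layout).
    """
    rng = np.random.default_rng(seed)
    plot = dict(plot)
    if abundances is None:
        if richness is None:
            lo, hi = design.richness_range
            richness = int(rng.integers(lo, hi + 1))
        abundances = _draw_abundances(rng, design, truth, richness)
    agg = truth.aggregation if aggregation is None else aggregation
    k = design.subplots_per_plot
    frames = []
    for sp, n in abundances.items():
        n = int(n)
        sub = _scatter_subplots(rng, n, k, agg)
        # lognormal DBH truncated below the census threshold
        dbh = rng.lognormal(truth.dbh_log_mean, truth.dbh_log_sd, size=n)
        while np.any(dbh < design.dbh_min_cm):
            redo = dbh < design.dbh_min_cm
            dbh[redo] = rng.lognormal(truth.dbh_log_mean, truth.dbh_log_sd, size=int(redo.sum()))
        height = truth.allometry_a * dbh**truth.allometry_b + rng.normal(
            0, truth.allometry_noise_sd, size=n
        )
        height = np.maximum(height, HEIGHT_FLOOR_M)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": plot.get("site_id", plot["plot_id"]),
                    "plot_id": plot["plot_id"],
                    "subplot_id": sub,
                    "species": sp,
                    "dbh_cm": np.round(dbh, 1),
                    "height_m": np.round(height, 1),
                }
            )
        )
    trees = pd.concat(frames, ignore_index=True)
    if truth.missing_height_fraction > 0:
        blank = rng.random(len(trees)) < truth.missing_height_fraction
        trees.loc[blank, "height_m"] = np.nan
    return trees


# ------------------------------------------------------------ full study
def generate_study(
    design: StudyDesign = StudyDesign(),
    truth: SyntheticTruth = SyntheticTruth(),
    seed: int | None = None,
    *,
    lonlat: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full synthetic study: ``(trees, plots, truth_table)``.

    ``truth_table`` has one row per plot with the hidden quantities
    (``true_slope`` of latent log-stability on standardised Shannon
    diversity, the latent ``eta``, and the realised ``aggregation``), for
    parameter-recovery tests.
    """
    master = np.random.default_rng(seed if seed is not None else truth.seed)
    land_seed = int(master.integers(2**31))
    plots = generate_landscape(design, land_seed, lonlat=lonlat)
    n = len(plots)
    elev = plots["elevation_m"].to_numpy()
    e_sd = elev.std() or 1.0
    z_elev = (elev - elev.mean()) / e_sd
    r_elev = (pd.Series(elev).rank(method="average") / n).to_numpy()

    # phase 1: communities (richness correlated with elevation)
    lo, hi = design.richness_range
    mu_r, sd_r = (lo + hi) / 2.0, (hi - lo) / 4.0
    rho = truth.richness_elevation_corr
    rich = np.clip(
        np.round(mu_r + sd_r * (rho * z_elev + math.sqrt(max(1 - rho**2, 0)) * master.normal(size=n))),
        lo,
        hi,
    ).astype(int)
    communities = [_draw_abundances(master, design, truth, int(r)) for r in rich]
    h = np.array([shannon_index(c) for c in communities])
    z_h = (h - h.mean()) / (h.std() or 1.0)

    # phase 2: latent stability target -> per-plot aggregation
    if lonlat:
        # recover planar km for surface evaluation
        xs = (plots["longitude"].to_numpy() - _LON0) * (111.320 * math.cos(math.radians(_LAT0)))
        ys = (plots["latitude"].to_numpy() - _LAT0) * 110.574
    else:
        xs, ys = plots["x_km"].to_numpy(), plots["y_km"].to_numpy()
    slope = np.array(
        [
            evaluate_surface(truth.coefficient_surface, x, y, design.extent_km)
            * (1.0 + truth.elevation_effect * r)
            for x, y, r in zip(xs, ys, r_elev)
        ]
    )
    eta = (
        truth.stability_base
        + truth.elevation_main * z_elev
        + slope * z_h
        + truth.stability_noise_sd * master.normal(size=n)
    )
    target = np.exp(eta)
    k = design.subplots_per_plot
    # Solve the per-plot Dirichlet concentration so the expected CV of
    # subplot basal-area totals matches the target.  With n_i stems of
    # species i scattered Dirichlet-multinomially (intra-class correlation
    # rho = 1/(k alpha + 1)) and i.i.d. stem basal areas,
    #   CV^2 = (k-1)/N^2 * (N + rho * sum n_i(n_i-1)) + k * v/m^2 / N ,
    # where v/m^2 = exp(4 dbh_log_sd^2) - 1 is the relative basal-area
    # variance (basal area ~ DBH^2, DBH lognormal).  The second and the
    # rho-free terms are an irreducible sampling floor: targets below it
    # clamp to near-uniform scattering.
    m_ratio = math.exp(4.0 * truth.dbh_log_sd**2) - 1.0
    agg = np.empty(n)
    for i, com in enumerate(communities):
        ni = com.to_numpy(dtype=float)
        N, Q = ni.sum(), float(np.sum(ni * (ni - 1.0)))
        cv2_floor = (k - 1.0) / N + k * m_ratio / N
        need = 1.0 / target[i] ** 2 - cv2_floor
        if Q > 0 and need > 0:
            rho = min(max(need * N**2 / ((k - 1.0) * Q), 1e-9), 0.995)
        else:
            rho = 1e-9
        agg[i] = k * rho / (1.0 - rho)  # aggregation = 1/alpha

    tree_frames = []
    for i, (_, plot) in enumerate(plots.iterrows()):
        ps = int(master.integers(2**31))
        tree_frames.append(
            generate_plot_census(
                plot, truth, design, ps, abundances=communities[i], aggregation=float(agg[i])
            )
        )
    trees = pd.concat(tree_frames, ignore_index=True)
    truth_table = pd.DataFrame(
        {
            "plot_id": plots["plot_id"],
            "richness_drawn": rich,
            "shannon_z": z_h,
            "true_slope": slope,
            "eta": eta,
            "aggregation": agg,
        }
    )
    return trees, plots, truth_table


def truth_to_dict(truth: SyntheticTruth) -> dict:
    """JSON-serialisable form of the hidden generator parameters."""
    return asdict(truth)
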