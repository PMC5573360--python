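"""End-to-end inference: plot summaries, transforms, GWR suite, elevation.

The pipeline mirrors a complete diversity–stability analysis:

1. assemble one summary row per plot (richness, Shannon, functional
   dispersion, Berger–Parker dominance, spatial stability of productivity,
   species asynchrony, dominant-species stability, totals, coordinates,
   elevation and its class);
2. transform model variables (default policy: log10 everything except
   functional dispersion; a screening policy applies Shapiro–Wilk at
   alpha = 0.05 and transforms only rejected variables);
3. fit the GWR model suite — stability/asynchrony/dominance/dominant-
   stability against the three diversity measures, plus stability against
   the three mediators — each with CV-selected adaptive bandwidth, and
   collect AICc / global R² / RSS diagnostics;
4. classify per-plot local-slope signs, test local R² across the four
   elevation classes with Kruskal–Wallis, and re-run the suite after
   controlling for elevation (each response replaced by its OLS residuals
   on elevation in metres).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import census_io, community_metrics as cm, gwr, stability_metrics as sm_
from .exceptions import DegenerateStatisticError, DomainError, SpastabError
from .synthetic_data import StudyDesign, SyntheticTruth, generate_study, truth_to_dict

log = logging.getLogger("spastab")

#: Elevation class upper bounds (m): 1 = up to 200, 2 = 201-400, 3 = 401-600,
#: 4 = above.  Values below the survey floor map to class 1, values above the
#: survey ceiling to class 4 with a warning.
ELEVATION_BREAKS = (200.0, 400.0, 600.0)
ELEVATION_CEILING = 819.0

#: Model variables; all but functional dispersion are log10-transformed under
#: the default transform policy.
MODEL_VARIABLES = (
    "ssfp",
    "asynchrony",
    "berger_parker",
    "dominant_stability",
    "richness",
    "shannon",
    "fdis",
)
NEVER_TRANSFORM = ("fdis",)

#: Default model suite: responses x diversity predictors, plus stability
#: against the three mediators.
DEFAULT_SUITE: tuple[tuple[str, str], ...] = tuple(
    (resp, pred)
    for resp in ("ssfp", "asynchrony", "berger_parker", "dominant_stability")
    for pred in ("richness", "shannon", "fdis")
) + (("ssfp", "asynchrony"), ("ssfp", "berger_parker"), ("ssfp", "dominant_stability"))


def elevation_class(elevation_m) -> int | np.ndarray:
    """Elevation class 1..4 (breaks at 200/400/600 m)."""
    arr = np.asarray(elevation_m, dtype=float)
    if np.any(arr < 0):
        raise DomainError("negative elevation")
    if np.any(arr > ELEVATION_CEILING):
        warnings.warn("elevation above survey ceiling mapped to class 4", stacklevel=2)
    cls = 1 + np.searchsorted(ELEVATION_BREAKS, arr, side="left")
    cls = np.minimum(cls, 4)
    return int(cls) if arr.ndim == 0 else cls.astype(int)


# ------------------------------------------------------------- summaries
def assemble_plot_summaries(
    trees: pd.DataFrame,
    plots: pd.DataFrame,
    *,
    n_subplots: int = 12,
    impute_seed: int | None = 0,
    deterministic_imputation: bool = False,
) -> pd.DataFrame:
    """One row of derived statistics per plot.

    Missing heights are imputed study-wide before the trait table is built.
    Plots whose stability or asynchrony is undefined (zero variance) are
    flagged ``degenerate`` and later excluded from model fitting.
    """
    complete, n_imputed = cm.impute_missing_heights(
        trees, seed=impute_seed, deterministic=deterministic_imputation
    )
    if n_imputed:
        log.info("imputed %d missing heights", n_imputed)
    traits = cm.max_height_per_species(complete).to_dict()
    rows = []
    for plot_id, grp in complete.groupby("plot_id", sort=False):
        counts = grp["species"].value_counts()
        mat = sm_.subplot_matrix(grp, n_subplots=n_subplots)
        totals = mat.sum(axis=0).to_numpy()
        stab = sm_.spatial_stability(totals)
        dom = sm_.dominant_stability(mat)
        degenerate = stab.degenerate or dom.degenerate
        try:
            asyn = sm_.spatial_asynchrony(mat)
        except DegenerateStatisticError:
            asyn, degenerate = np.nan, True
        rows.append(
            {
                "plot_id": plot_id,
                "richness": cm.species_richness(counts),
                "shannon": cm.shannon_index(counts),
                "fdis": cm.functional_dispersion(counts, traits),
                "berger_parker": cm.berger_parker(counts),
                "ssfp": stab.stability,
                "asynchrony": asyn,
                "dominant_species": sm_.dominant_species(mat),
                "dominant_stability": dom.stability,
                "total_basal_area_cm2": float(mat.to_numpy().sum()),
                "n_stems": int(len(grp)),
                "degenerate": bool(degenerate),
            }
        )
    summary = pd.DataFrame(rows).merge(plots, on="plot_id", how="left")
    summary["elevation_class"] = elevation_class(summary["elevation_m"].to_numpy())
    summary.attrs["coordinate_mode"] = plots.attrs.get("coordinate_mode", "planar")
    summary.attrs["n_imputed_heights"] = n_imputed
    return summary


# ------------------------------------------------------------ transforms
def normality_screen_and_transform(
    summary: pd.DataFrame,
    policy: str = "paper",
    variables: Sequence[str] = MODEL_VARIABLES,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[dict]]:
    """Log10-transform model variables in place (on a copy).

    ``policy="paper"`` transforms every listed variable except functional
    dispersion; ``policy="test"`` applies a Shapiro–Wilk screen at ``alpha``
    and transforms only variables that reject normality.  Rows with
    non-positive values of a variable being transformed are dropped with a
    logged warning (a zero cannot be log-transformed).
    Returns ``(transformed copy, decision log)``.
    """
    out = summary.copy()
    decisions: list[dict] = []
    for var in variables:
        if var not in out.columns:
            continue
        if policy == "paper":
            do = var not in NEVER_TRANSFORM
            reason = "default policy" if do else "exempt by policy"
        elif policy == "test":
            vals = out[var].dropna().to_numpy(dtype=float)
            p = scipy.stats.shapiro(vals).pvalue if len(vals) >= 3 else 1.0
            do = p < alpha
            reason = f"shapiro p={p:.4g}"
        else:
            raise DomainError(f"unknown transform policy {policy!r}")
        n_dropped = 0
        if do:
            bad = out[var].notna() & (out[var] <= 0)
            if bad.any():
                n_dropped = int(bad.sum())
                log.warning(
                    "dropping %d plot(s) with non-positive %s before log10: %s",
                    n_dropped, var, list(out.loc[bad, "plot_id"]),
                )
                out = out[~bad]
            out[var] = np.log10(out[var])
        decisions.append(
            {"variable": var, "transformed": bool(do), "reason": reason, "n_dropped": n_dropped}
        )
    out.attrs.update(summary.attrs)
    return out, decisions


# ----------------------------------------------------------- model suite
@dataclass
class ModelResult:
    """Diagnostics of one response ~ predictor GWR model."""

    response: str
    predictor: str
    elevation_controlled: bool
    n: int = 0
    q: float = float("nan")
    aicc: float = float("nan")
    r2: float = float("nan")
    rss: float = float("nan")
    plot_ids: list = field(default_factory=list)
    local_slopes: np.ndarray | None = None
    local_r2: np.ndarray | None = None
    bandwidths: np.ndarray | None = None
    elevation_classes: np.ndarray | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _coords(summary: pd.DataFrame) -> tuple[np.ndarray, str]:
    if {"x_km", "y_km"} <= set(summary.columns):
        return summary[["x_km", "y_km"]].to_numpy(dtype=float), "euclidean"
    if {"longitude", "latitude"} <= set(summary.columns):
        return summary[["longitude", "latitude"]].to_numpy(dtype=float), "haversine"
    raise DomainError("summary lacks coordinate columns")


def fit_model_pair(
    summary: pd.DataFrame,
    response: str,
    predictor: str,
    *,
    elevation_controlled: bool = False,
    q_bounds: tuple[float, float] = (0.02, 1.0),
    selector: str = "cv",
) -> ModelResult:
    """Bandwidth selection plus GWR fit for one response ~ predictor pair."""
    if response == predictor:
        raise DomainError("response and predictor are identical (R²=1 guard)")
    data = summary[~summary["degenerate"]].dropna(subset=[response, predictor])
    coords, mode = _coords(data)
    y = data[response].to_numpy(dtype=float)
    x = data[predictor].to_numpy(dtype=float)
    q_star, _ = gwr.select_bandwidth(
        y, x, coords, mode=mode, q_bounds=q_bounds, criterion=selector
    )
    fit = gwr.fit_gwr(y, x, coords, q_star, mode=mode)
    return ModelResult(
        response=response,
        predictor=predictor,
        elevation_controlled=elevation_controlled,
        n=len(y),
        q=q_star,
        aicc=fit.aicc,
        r2=fit.r2,
        rss=fit.rss,
        plot_ids=list(data["plot_id"]),
        local_slopes=fit.slopes.copy(),
        local_r2=fit.local_r2.copy(),
        bandwidths=fit.bandwidths.copy(),
        elevation_classes=data["elevation_class"].to_numpy(),
    )


def run_model_suite(
    summary: pd.DataFrame,
    specs: Sequence[tuple[str, str]] = DEFAULT_SUITE,
    *,
    elevation_controlled: bool = False,
    q_bounds: tuple[float, float] = (0.02, 1.0),
    selector: str = "cv",
) -> list[ModelResult]:
    """Fit every (response, predictor) pair; a failing model is recorded
    with its error message and does not abort the suite."""
    results = []
    for resp, pred in specs:
        try:
            results.append(
                fit_model_pair(
                    summary, resp, pred,
                    elevation_controlled=elevation_controlled,
                    q_bounds=q_bounds, selector=selector,
                )
            )
        except (SpastabError, np.linalg.LinAlgError) as exc:
            log.warning("model %s ~ %s failed: %s", resp, pred, exc)
            results.append(
                ModelResult(resp, pred, elevation_controlled, error=str(exc))
            )
    return results


def classify_signs(model: ModelResult) -> tuple[int, int]:
    """(negative, positive) counts of per-plot local slopes; an exactly zero
    slope counts as positive with a warning."""
    if not model.ok:
        raise DomainError(f"cannot classify a failed model: {model.error}")
    slopes = model.local_slopes
    if np.any(slopes == 0):
        warnings.warn("zero local slope counted as positive", stacklevel=2)
    neg = int(np.sum(slopes < 0))
    return neg, int(len(slopes) - neg)


@dataclass(frozen=True)
class KWResult:
    """Kruskal–Wallis rank test across groups."""

    h: float
    df: int
    pvalue: float
    group_sizes: tuple[int, ...]


def kruskal_wallis(values, classes) -> KWResult:
    """Tie-corrected Kruskal–Wallis H test of ``values`` across ``classes``.

    All-identical values give H = 0, P = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    labels = np.unique(classes)
    groups = [values[classes == c] for c in labels]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise DomainError("Kruskal-Wallis needs >= 2 non-empty groups")
    sizes = tuple(int(len(g)) for g in groups)
    if np.all(values == values[0]):
        return KWResult(0.0, len(groups) - 1, 1.0, sizes)
    h, p = scipy.stats.kruskal(*groups)
    return KWResult(float(h), len(groups) - 1, float(p), sizes)


def control_for_elevation(
    summary: pd.DataFrame,
    specs: Sequence[tuple[str, str]] = DEFAULT_SUITE,
    *,
    q_bounds: tuple[float, float] = (0.02, 1.0),
    selector: str = "cv",
) -> list[ModelResult]:
    """Re-run the model suite with each response replaced by its OLS
    residuals on elevation (m).  Each response variable gets its own
    residuals; predictors are untouched."""
    controlled = summary.copy()
    for resp in {r for r, _ in specs}:
        mask = controlled[resp].notna() & ~controlled["degenerate"]
        y = controlled.loc[mask, resp].to_numpy(dtype=float)
        e = controlled.loc[mask, "elevation_m"].to_numpy(dtype=float)
        fit = gwr.fit_ols(y, e)
        controlled.loc[mask, resp] = fit.residuals
    controlled.attrs.update(summary.attrs)
    return run_model_suite(
        controlled, specs, elevation_controlled=True, q_bounds=q_bounds, selector=selector
    )


# -------------------------------------------------------------- reporting
def models_to_frame(models: Sequence[ModelResult]) -> pd.DataFrame:
    """Global diagnostics table, one row per model (Table-1 shape)."""
    rows = []
    for m in models:
        neg, pos = classify_signs(m) if m.ok else (np.nan, np.nan)
        rows.append(
            {
                "response": m.response,
                "predictor": m.predictor,
                "elevation_controlled": m.elevation_controlled,
                "n": m.n,
                "q": m.q,
                "aicc": m.aicc,
                "r2": m.r2,
                "rss": m.rss,
                "n_negative": neg,
                "n_positive": pos,
                "error": m.error or "",
            }
        )
    return pd.DataFrame(rows)


def locals_to_frame(models: Sequence[ModelResult]) -> pd.DataFrame:
    """Long per-plot local diagnostics for all fitted models."""
    frames = []
    for m in models:
        if not m.ok:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "response": m.response,
                    "predictor": m.predictor,
                    "elevation_controlled": m.elevation_controlled,
                    "plot_id": m.plot_ids,
                    "local_slope": m.local_slopes,
                    "local_r2": m.local_r2,
                    "bandwidth_km": m.bandwidths,
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def kw_tests_frame(models: Sequence[ModelResult]) -> pd.DataFrame:
    """Kruskal–Wallis of local R² across elevation classes, per model."""
    rows = []
    for m in models:
        if not m.ok:
            continue
        kw = kruskal_wallis(m.local_r2, m.elevation_classes)
        rows.append(
            {
                "response": m.response,
                "predictor": m.predictor,
                "elevation_controlled": m.elevation_controlled,
                "kw_h": kw.h,
                "df": kw.df,
                "pvalue": kw.pvalue,
                "group_sizes": "/".join(map(str, kw.group_sizes)),
            }
        )
    return pd.DataFrame(rows)


def run_full_pipeline(config: dict, seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Run the whole analysis from a config dict and write the report bundle.

    Config keys: ``simulate`` (design/truth overrides) *or* ``input``
    (``trees``/``plots`` file paths), ``transform_policy``, ``models``
    (list of [response, predictor]; default suite if absent), ``gwr``
    (``q_bounds``, ``selector``), ``output_dir``.
    """
    stage = "config"
    try:
        out_dir = Path(config.get("output_dir", "spastab_out"))
        gwr_cfg = config.get("gwr", {})
        q_bounds = tuple(gwr_cfg.get("q_bounds", (0.02, 1.0)))
        selector = gwr_cfg.get("selector", "cv")
        specs = [tuple(m) for m in config.get("models", DEFAULT_SUITE)]

        stage = "census_io"
        if "input" in config:
            trees = census_io.read_tree_census(config["input"]["trees"])
            plots = census_io.read_plot_table(config["input"]["plots"])
            truth_table = None
        else:
            sim = config.get("simulate", {}) or {}
            design = StudyDesign(**sim.get("design", {}))
            truth = SyntheticTruth(**sim.get("truth", {}))
            trees, plots, truth_table = generate_study(design, truth, seed)
        report = census_io.validate_census(trees, plots)
        if not report.ok:
            raise DomainError(f"census validation failed: {report.errors[:5]}")
        log.info("census: %s", report.counts)

        stage = "plot_summaries"
        summary = assemble_plot_summaries(trees, plots, impute_seed=seed)

        stage = "transform"
        transformed, tlog = normality_screen_and_transform(
            summary, policy=config.get("transform_policy", "paper")
        )

        stage = "model_suite"
        raw_models = run_model_suite(transformed, specs, q_bounds=q_bounds, selector=selector)
        stage = "elevation_control"
        ctl_models = control_for_elevation(transformed, specs, q_bounds=q_bounds, selector=selector)

        stage = "report"
        all_models = list(raw_models) + list(ctl_models)
        tables = {
            "plot_summary": summary,
            "model_diagnostics": models_to_frame(all_models),
            "local_diagnostics": locals_to_frame(all_models),
            "kw_tests": kw_tests_frame(raw_models),
            "transform_log": pd.DataFrame(tlog),
        }
        cfg_text = json.dumps(config, sort_keys=True, default=str)
        manifest = {
            "seed": seed,
            "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "stems": report.counts["stems"],
            "plots": report.counts["plots"],
        }
        if truth_table is not None:
            tables["truth_table"] = truth_table
            manifest["truth"] = truth_to_dict(SyntheticTruth(**(config.get("simulate", {}) or {}).get("truth", {})))
        census_io.write_results(tables, out_dir, manifest=manifest)
        return tables
    except (SpastabError, OSError) as exc:
        raise SpastabError(f"pipeline aborted at stage {stage!r}: {exc}") from exc
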