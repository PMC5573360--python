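"""Reading, validating and writing forest-census tables.

The pipeline consumes two delimited text tables:

* a **tree table** with one row per measured stem
  (``site_id, plot_id, subplot_id, species, dbh_cm, height_m``), and
* a **plot table** with one row per plot
  (``plot_id, site_id, x_km, y_km`` *or* ``longitude, latitude``,
  ``elevation_m`` and optional terrain columns).

Header matching is case-insensitive and accepts common synonyms
(``DBH``, ``dbh_cm``, ``height``...).  Blank, ``NA`` and ``n/a`` cells in
the height column become missing values; every other numeric cell must
parse.  CSV is the default dialect, TSV is selected with
``delimiter="\\t"``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DuplicateKeyError, SchemaError

#: Markers interpreted as a missing height measurement.
NA_MARKERS = ["", "na", "n/a", "nan", "null", "NA", "N/A", "NaN", "NULL", "-"]

#: Canonical tree-table column -> accepted header synonyms (lower-case).
TREE_SYNONYMS: dict[str, tuple[str, ...]] = {
    "site_id": ("site_id", "site", "siteid"),
    "plot_id": ("plot_id", "plot", "plotid"),
    "subplot_id": ("subplot_id", "subplot", "quadrat", "subplotid"),
    "species": ("species", "species_name", "sp", "taxon"),
    "dbh_cm": ("dbh_cm", "dbh", "diameter", "diameter_cm", "d"),
    "height_m": ("height_m", "height", "tree_height", "h", "ht_m"),
}

PLOT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "plot_id": ("plot_id", "plot", "plotid"),
    "site_id": ("site_id", "site", "siteid"),
    "x_km": ("x_km", "x"),
    "y_km": ("y_km", "y"),
    "longitude": ("longitude", "lon", "long", "lng"),
    "latitude": ("latitude", "lat"),
    "elevation_m": ("elevation_m", "elevation", "elev", "altitude", "alt"),
    "slope_aspect": ("slope_aspect", "aspect"),
    "slope_steepness": ("slope_steepness", "slope", "steepness"),
}


def _map_headers(
    columns: Sequence[str],
    synonyms: Mapping[str, tuple[str, ...]],
    required: Sequence[str],
    extra_synonyms: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, str]:
    """Map raw headers onto canonical names; raise SchemaError if a required
    field cannot be located."""
    table = {}
    for canon, names in synonyms.items():
        pool = set(names)
        if extra_synonyms and canon in extra_synonyms:
            pool |= {s.lower() for s in extra_synonyms[canon]}
        for raw in columns:
            if raw.strip().lower() in pool:
                table[raw] = canon
                break
    found = set(table.values())
    missing = [c for c in required if c not in found]
    if missing:
        raise SchemaError(
            f"could not locate required column(s) {missing} among headers "
            f"{list(columns)}"
        )
    return table


def read_tree_census(
    path: str | Path,
    *,
    delimiter: str = ",",
    synonyms: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Read a stem-level census table.

    Parameters
    ----------
    path
        Delimited text file with one row per stem.
    delimiter
        Field separator; ``","`` (default) or ``"\\t"``.
    synonyms
        Extra header synonyms, mapping canonical name to a list of accepted
        raw headers (e.g. ``{"dbh_cm": ["DBH_cm"]}``).

    Returns
    -------
    DataFrame with columns ``site_id, plot_id, subplot_id, species, dbh_cm,
    height_m``; missing heights are NaN; row order preserved.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    mapping = _map_headers(
        raw.columns, TREE_SYNONYMS, list(TREE_SYNONYMS), synonyms
    )
    df = raw.rename(columns=mapping)[list(TREE_SYNONYMS)]
    out = pd.DataFrame(
        {
            "site_id": df["site_id"].str.strip(),
            "plot_id": df["plot_id"].str.strip(),
            "species": df["species"].str.strip(),
        }
    )
    out["subplot_id"] = _parse_numeric(df["subplot_id"], "subplot_id", path, integer=True)
    out["dbh_cm"] = _parse_numeric(df["dbh_cm"], "dbh_cm", path)
    out["height_m"] = _parse_numeric(df["height_m"], "height_m", path, allow_na=True)
    return out[["site_id", "plot_id", "subplot_id", "species", "dbh_cm", "height_m"]]


def _parse_numeric(
    col: pd.Series, name: str, path: Path, *, integer: bool = False, allow_na: bool = False
) -> pd.Series:
    cleaned = col.str.strip()
    is_na = cleaned.str.lower().isin([m.lower() for m in NA_MARKERS])
    values = pd.to_numeric(cleaned.where(~is_na), errors="coerce")
    bad = values.isna() & ~is_na
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, plus header line
        raise SchemaError(
            f"{path.name}: unparseable value {cleaned[bad.idxmax()]!r} in column "
            f"{name!r} at file line {row}"
        )
    if is_na.any() and not allow_na:
        row = int(is_na.idxmax()) + 2
        raise SchemaError(f"{path.name}: missing value in column {name!r} at line {row}")
    if integer:
        return values.astype("int64")
    return values.astype(float)


def read_plot_table(
    path: str | Path,
    *,
    delimiter: str = ",",
    synonyms: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Read the plot table.

    Either planar ``x_km/y_km`` or geographic ``longitude/latitude``
    coordinates must be present; the detected convention is recorded in
    ``df.attrs["coordinate_mode"]`` (``"planar"`` or ``"geographic"``).
    Duplicate ``plot_id`` values raise :class:`DuplicateKeyError`.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    mapping = _map_headers(raw.columns, PLOT_SYNONYMS, ["plot_id", "elevation_m"], synonyms)
    df = raw.rename(columns=mapping)
    have = set(df.columns)
    if {"x_km", "y_km"} <= have:
        mode, cx, cy = "planar", "x_km", "y_km"
    elif {"longitude", "latitude"} <= have:
        mode, cx, cy = "geographic", "longitude", "latitude"
    else:
        raise SchemaError(
            f"{path.name}: need either x_km/y_km or longitude/latitude columns"
        )
    out = pd.DataFrame({"plot_id": df["plot_id"].str.strip()})
    out["site_id"] = df["site_id"].str.strip() if "site_id" in have else out["plot_id"]
    out[cx] = _parse_numeric(df[cx], cx, path)
    out[cy] = _parse_numeric(df[cy], cy, path)
    out["elevation_m"] = _parse_numeric(df["elevation_m"], "elevation_m", path)
    for opt in ("slope_aspect", "slope_steepness"):
        if opt in have:
            out[opt] = _parse_numeric(df[opt], opt, path, allow_na=True)
    dup = out["plot_id"].duplicated()
    if dup.any():
        raise DuplicateKeyError(
            f"{path.name}: duplicated plot_id {sorted(out.loc[dup, 'plot_id'].unique())}"
        )
    if not np.isfinite(out[[cx, cy]].to_numpy()).all():
        raise SchemaError(f"{path.name}: non-finite coordinates")
    out.attrs["coordinate_mode"] = mode
    return out


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_census`; empty ``errors`` means accepted."""

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_census(
    trees: pd.DataFrame,
    plots: pd.DataFrame,
    *,
    dbh_threshold: float = 3.0,
    n_subplots: int = 12,
) -> ValidationReport:
    """Check a typed census against the survey protocol.

    Flags stems below the DBH census threshold (default 3 cm), subplot ids
    outside ``1..n_subplots``, non-positive recorded heights, empty species
    labels and stems referencing unknown plots.  The inputs are not modified.
    """
    report = ValidationReport()
    known_plots = set(plots["plot_id"])
    for idx, row in trees.iterrows():
        loc = f"tree row {idx}"
        if row["dbh_cm"] < dbh_threshold:
            report.errors.append((loc, f"dbh {row['dbh_cm']} below threshold {dbh_threshold}"))
        if not (1 <= row["subplot_id"] <= n_subplots):
            report.errors.append((loc, f"subplot_id {row['subplot_id']} outside 1..{n_subplots}"))
        if pd.notna(row["height_m"]) and row["height_m"] <= 0:
            report.errors.append((loc, f"non-positive height {row['height_m']}"))
        if not row["species"]:
            report.errors.append((loc, "empty species label"))
        if row["plot_id"] not in known_plots:
            report.errors.append((loc, f"plot_id {row['plot_id']!r} not in plot table"))
    report.counts = {
        "stems": int(len(trees)),
        "plots": int(len(plots)),
        "species": int(trees["species"].nunique()),
        "missing_heights": int(trees["height_m"].isna().sum()),
    }
    return report


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    manifest: Mapping | None = None,
    float_format: str = "%.12g",
) -> list[Path]:
    """Write each table as ``<name>.csv`` plus a ``manifest.json``.

    Floats are serialized with 12 significant digits so that a write/read
    round trip reproduces the table.  The manifest records whatever the
    caller passes (seed, config) plus a content hash of each file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    hashes: dict[str, str] = {}
    for name, table in tables.items():
        target = out_dir / f"{name}.csv"
        table.to_csv(target, index=False, float_format=float_format)
        hashes[target.name] = hashlib.sha256(target.read_bytes()).hexdigest()
        written.append(target)
    meta = dict(manifest or {})
    meta["files"] = hashes
    target = out_dir / "manifest.json"
    target.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    written.append(target)
    return written
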