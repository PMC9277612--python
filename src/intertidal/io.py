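"""Tabular input/output, schemas, units and shared constants.

Four field tables drive the pipeline:

* **transect** — ordered sampling sites along a shore-normal line, with
  distance from the seaward forest edge (m) and surface elevation relative
  to local mean sea level (cm);
* **quadrats** — molluscan counts per site × season × assemblage ×
  quadrat, with the quadrat area (m²);
* **rset** — rod-surface-elevation-table pin readings (benchmark × date ×
  direction × pin × arm-to-pin distance, mm);
* **markers** — feldspar marker-horizon burial depths (station × date ×
  core × depth, mm).

All elevations are carried in centimetres and all vertical rates in
millimetres per year; the single conversion between the two lives in
:func:`mm_to_cm`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "Constants",
    "TransectProfile",
    "mm_to_cm",
    "decimal_years",
    "slr_grid",
    "read_transect",
    "write_transect",
    "read_quadrats",
    "write_quadrats",
    "read_rset",
    "write_rset",
    "read_markers",
    "write_markers",
    "write_results",
    "load_config",
    "ASSEMBLAGES",
    "SEASONS",
    "DEFAULT_QUADRAT_AREA",
    "QUADRATS_PER_SITE",
]

DAYS_PER_YEAR = 365.25

ASSEMBLAGES = ("arboreal", "epifaunal", "infaunal")
SEASONS = ("spring", "summer", "autumn", "winter")

#: Default quadrat area per assemblage, m² (5×5 m arboreal, 1×1 m epifaunal,
#: 0.25×0.25 m infaunal).
DEFAULT_QUADRAT_AREA = {"arboreal": 25.0, "epifaunal": 1.0, "infaunal": 0.0625}

#: Default number of quadrats per site and season per assemblage.
QUADRATS_PER_SITE = {"arboreal": 3, "epifaunal": 5, "infaunal": 5}

TRANSECT_COLUMNS = ["site_id", "distance_m", "elevation_cm"]
QUADRAT_COLUMNS = [
    "site_id",
    "season",
    "assemblage",
    "species_code",
    "quadrat_id",
    "quadrat_area_m2",
    "count",
]
RSET_COLUMNS = ["benchmark_id", "date", "direction", "pin", "distance_mm"]
MARKER_COLUMNS = ["station_id", "date", "core_id", "depth_mm"]


class SchemaError(ValueError):
    """A table is missing required columns or is otherwise malformed."""


class ValidationError(ValueError):
    """A table parses but violates a domain invariant."""


def mm_to_cm(x):
    """Convert mm (or mm yr⁻¹) to cm (or cm yr⁻¹).

    This is the only place in the package where vertical units change
    scale; rates stay in mm yr⁻¹ everywhere else.
    """
    return np.asarray(x, dtype=float) / 10.0


def decimal_years(dates, origin=None) -> np.ndarray:
    """Elapsed time of each date relative to ``origin`` in decimal years.

    ``origin`` defaults to the earliest date. A year is 365.25 days, which
    absorbs the irregular 3–12 month revisit intervals of the field design.
    """
    d = pd.to_datetime(pd.Series(list(dates)))
    if origin is None:
        origin = d.min()
    else:
        origin = pd.to_datetime(origin)
    return ((d - origin).dt.total_seconds() / (DAYS_PER_YEAR * 86400.0)).to_numpy()


@dataclass(frozen=True)
class Constants:
    """Fixed modelling constants, overridable from a config file.

    e_min_cm is the minimum relative elevation at which mangroves persist;
    the scenario range spans present-day local sea-level rise (2 mm yr⁻¹)
    to the high-end 2100 projection (16 mm yr⁻¹).
    """

    e_min_cm: float = -15.0
    grid_step_cm: float = 25.0
    year_start: int = 2020
    year_end: int = 2100
    slr_min: float = 2.0
    slr_max: float = 16.0
    slr_step: float = 0.25

    @classmethod
    def from_config(cls, cfg: Mapping) -> "Constants":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in cfg:
                kwargs[f.name] = type(f.default)(cfg[f.name])
        return cls(**kwargs)


def slr_grid(constants: Constants | None = None) -> np.ndarray:
    """Inclusive scenario grid of sea-level-rise rates, mm yr⁻¹."""
    c = constants or Constants()
    n = int(round((c.slr_max - c.slr_min) / c.slr_step))
    return c.slr_min + c.slr_step * np.arange(n + 1)


@dataclass(frozen=True)
class TransectProfile:
    """Ordered sampling sites defining the intertidal topography.

    Sites are sorted by distance from the seaward forest edge; distances
    must be strictly increasing (two sites cannot share a position) and at
    least two sites are required so segments exist to interpolate over.
    """

    site_ids: tuple
    distances_m: np.ndarray
    elevations_cm: np.ndarray

    def __post_init__(self):
        ids = tuple(str(s) for s in self.site_ids)
        d = np.asarray(self.distances_m, dtype=float)
        e = np.asarray(self.elevations_cm, dtype=float)
        if len(ids) != d.size or d.size != e.size:
            raise ValidationError("site_ids, distances and elevations must align")
        if d.size < 2:
            raise ValidationError("a transect needs at least 2 sites")
        order = np.argsort(d, kind="stable")
        ids = tuple(ids[i] for i in order)
        d = d[order]
        e = e[order]
        if not np.all(np.isfinite(d)) or not np.all(np.isfinite(e)):
            raise ValidationError("distances and elevations must be finite")
        if np.any(d < 0):
            raise ValidationError("distances must be >= 0")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("duplicate or non-increasing site distances")
        object.__setattr__(self, "site_ids", ids)
        object.__setattr__(self, "distances_m", d)
        object.__setattr__(self, "elevations_cm", e)
        d.setflags(write=False)
        e.setflags(write=False)

    def __len__(self) -> int:
        return len(self.site_ids)

    @property
    def span_m(self) -> float:
        """Distance from the first to the last site."""
        return float(self.distances_m[-1] - self.distances_m[0])

    def elevation_of(self, site_id: str) -> float:
        try:
            i = self.site_ids.index(str(site_id))
        except ValueError:
            raise KeyError(f"unknown site {site_id!r}") from None
        return float(self.elevations_cm[i])

    def with_elevations(self, elevations_cm) -> "TransectProfile":
        """Same geometry, new elevations (e.g. a simulated year-2100 state)."""
        return TransectProfile(self.site_ids, self.distances_m.copy(),
                               np.asarray(elevations_cm, dtype=float))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TransectProfile":
        _require_columns(df, TRANSECT_COLUMNS, "transect")
        return cls(
            tuple(df["site_id"].astype(str)),
            _numeric(df, "distance_m"),
            _numeric(df, "elevation_cm"),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": list(self.site_ids),
                "distance_m": self.distances_m,
                "elevation_cm": self.elevations_cm,
            }
        )


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing columns: {missing}")


def _numeric(df: pd.DataFrame, col: str) -> np.ndarray:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"non-numeric value in column {col!r} at row {row}")
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise SchemaError(f"missing value in column {col!r} at row {row}")
    return out.to_numpy(dtype=float)


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty table: {path}") from None
    return df


def read_transect(path) -> TransectProfile:
    """Read a transect CSV (site_id, distance_m, elevation_cm)."""
    return TransectProfile.from_dataframe(_read_csv(path))


def write_transect(profile: TransectProfile, path) -> None:
    profile.to_dataframe().to_csv(path, index=False)


def validate_quadrats(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, QUADRAT_COLUMNS, "quadrat")
    df = df.copy()
    df["site_id"] = df["site_id"].astype(str)
    df["species_code"] = df["species_code"].astype(str)
    df["quadrat_id"] = df["quadrat_id"].astype(str)
    bad = ~df["assemblage"].isin(ASSEMBLAGES)
    if bad.any():
        labels = sorted(df.loc[bad, "assemblage"].unique())
        raise ValidationError(f"unknown assemblage labels: {labels}")
    area = _numeric(df, "quadrat_area_m2")
    if np.any(area <= 0):
        raise ValidationError("quadrat_area_m2 must be > 0")
    count = _numeric(df, "count")
    if np.any(count < 0) or np.any(count != np.round(count)):
        raise ValidationError("count must be a non-negative integer")
    df["quadrat_area_m2"] = area
    df["count"] = count.astype(int)
    return df


def read_quadrats(path) -> pd.DataFrame:
    """Read and validate a quadrat-count CSV."""
    return validate_quadrats(_read_csv(path))


def write_quadrats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=QUADRAT_COLUMNS)


def read_rset(path) -> pd.DataFrame:
    """Read an RSET pin-reading CSV; dates parsed as ISO-8601."""
    df = _read_csv(path)
    _require_columns(df, RSET_COLUMNS, "rset")
    df = df.copy()
    df["benchmark_id"] = df["benchmark_id"].astype(str)
    df["date"] = pd.to_datetime(df["date"])
    df["direction"] = _numeric(df, "direction").astype(int)
    df["pin"] = _numeric(df, "pin").astype(int)
    df["distance_mm"] = _numeric(df, "distance_mm")
    if not df["direction"].isin(range(1, 5)).all():
        raise ValidationError("direction must be 1..4")
    if not df["pin"].isin(range(1, 10)).all():
        raise ValidationError("pin must be 1..9")
    return df


def write_rset(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=RSET_COLUMNS)


def read_markers(path) -> pd.DataFrame:
    """Read a marker-horizon CSV (burial depth of the feldspar layer)."""
    df = _read_csv(path)
    _require_columns(df, MARKER_COLUMNS, "marker")
    df = df.copy()
    df["station_id"] = df["station_id"].astype(str)
    df["date"] = pd.to_datetime(df["date"])
    df["core_id"] = _numeric(df, "core_id").astype(int)
    df["depth_mm"] = _numeric(df, "depth_mm")
    if np.any(df["depth_mm"].to_numpy() < 0):
        raise ValidationError("depth_mm must be >= 0")
    return df


def write_markers(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=MARKER_COLUMNS)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> list:
    """Write every result table as ``<name>.csv`` under ``out_dir``.

    Column order is whatever the table carries, which each pipeline stage
    fixes deterministically, so re-running with the same inputs produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = out / f"{name}.csv"
        tables[name].to_csv(path, index=False)
        written.append(path)
    return written


def load_config(path) -> dict:
    """Load a YAML (or JSON — YAML is a superset) run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a mapping")
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable hash of a configuration mapping, for run manifests."""
    import hashlib

    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
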