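"""Seeded synthetic versions of the four field tables.

The generators reproduce the statistical structure the analysis assumes —
Gaussian-niche zonation of species densities along the elevation gradient,
linear elevation-change trends at the RSET benchmarks, accretion rates
that decay exponentially with elevation, Poisson (optionally negative
binomial) count noise on quadrat densities — so every downstream stage is
testable without the archived field data.  Everything is a pure function
of (parameters, seed); per-table randomness is derived from one global
seed via fixed stream tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ASSEMBLAGES,
    DEFAULT_QUADRAT_AREA,
    QUADRATS_PER_SITE,
    SEASONS,
    TransectProfile,
    ValidationError,
    decimal_years,
)
from .datasets import ELEVATION_GRID

__all__ = [
    "SpeciesSpec",
    "SyntheticConfig",
    "gen_transect",
    "gen_quadrats",
    "gen_rset_series",
    "gen_marker_series",
    "default_species",
    "default_dates",
    "generate_all",
]

# fixed stream tags: a change here would silently re-randomise fixtures
_STREAM = {"transect": 11, "quadrats": 23, "rset": 37, "marker": 53}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM[stream]]))


@dataclass(frozen=True)
class SpeciesSpec:
    """Gaussian elevation niche of one synthetic species.

    Expected density at elevation E is
    peak_density · exp(−(E − mode)² / (2·width²)), ind. m⁻².
    """

    species_code: str
    assemblage: str
    mode_elevation_cm: float
    niche_width_cm: float
    peak_density: float

    def __post_init__(self):
        if self.assemblage not in ASSEMBLAGES:
            raise ValidationError(f"unknown assemblage {self.assemblage!r}")
        if self.niche_width_cm <= 0:
            raise ValidationError("niche_width must be > 0")
        if self.peak_density < 0:
            raise ValidationError("peak_density must be >= 0")

    def density_at(self, elevation_cm):
        e = np.asarray(elevation_cm, dtype=float)
        z = (e - self.mode_elevation_cm) / self.niche_width_cm
        return self.peak_density * np.exp(-0.5 * z**2)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition defaults for the synthetic tables.

    The feedback-law truth (a_true, b_true) sits at the threshold-
    calibrated field scale; the accretion regression slope/intercept match
    the printed ranges of elevation change (4.76–9.61 mm yr⁻¹) against
    accretion (7.35–24.67 mm yr⁻¹).  Pin readings carry 2.0 mm noise
    (RSET pin reproducibility); recorded core depths, each already a mean
    of three ruler readings, carry 1.5 mm.
    """

    seed: int = 0
    n_species_per_assemblage: int = 4
    a_true: float = 7.72  # mm/yr at mean sea level
    b_true: float = 3.5e-3  # 1/cm
    accretion_slope: float = 0.30  # elev change per unit accretion
    accretion_intercept: float = 2.5  # mm/yr
    pin_noise_sd_mm: float = 2.0
    marker_noise_sd_mm: float = 1.5
    count_dispersion: float | None = None  # None = Poisson


def default_species(config: SyntheticConfig) -> list:
    """Evenly staggered Gaussian niches spanning the sampled gradient.

    Modes run from −15 to 150 cm per assemblage, widths of 25–40 cm
    (one to two grid steps, matching the compact zones of the box plots),
    peaks scaled so arboreal/epifaunal/infaunal specimens arrive in
    realistic proportions for their quadrat areas.
    """
    peak = {"arboreal": 3.0, "epifaunal": 20.0, "infaunal": 40.0}
    out = []
    n = config.n_species_per_assemblage
    for asm in ASSEMBLAGES:
        modes = np.linspace(-15.0, 150.0, n)
        widths = np.linspace(25.0, 40.0, n)
        for i, (m, w) in enumerate(zip(modes, widths), start=1):
            out.append(
                SpeciesSpec(f"{asm[:3]}{i}", asm, float(m), float(w), peak[asm])
            )
    return out


def gen_transect(n_sites: int = 9, elevation_grid=None, seed: int = 0,
                 mean_spacing_m: float = 80.0, dip_prob: float = 0.5) -> TransectProfile:
    """Synthetic transect on the 25-cm elevation lattice.

    Distances accumulate random positive gaps; elevations are grid values
    in ascending order (covering both endpoints when room allows), with a
    chance of one interior dip so the profile can be non-monotone the way
    real forest floors are.
    """
    if n_sites < 2:
        raise ValidationError("need at least 2 sites")
    grid = np.asarray(
        ELEVATION_GRID if elevation_grid is None else elevation_grid, dtype=float
    )
    grid = np.unique(grid)
    rng = _rng(seed, "transect")
    if n_sites <= grid.size:
        if n_sites == grid.size:
            chosen = grid
        else:
            interior = rng.choice(grid.size - 2, size=n_sites - 2, replace=False) + 1
            chosen = np.sort(np.r_[grid[0], grid[np.sort(interior)], grid[-1]])
    else:
        extra = rng.choice(grid[1:-1], size=n_sites - grid.size, replace=True)
        chosen = np.sort(np.r_[grid, extra])
    if n_sites >= 4 and rng.random() < dip_prob:
        i = int(rng.integers(1, n_sites - 2))
        if chosen[i] != chosen[i + 1]:
            chosen[i], chosen[i + 1] = chosen[i + 1], chosen[i]
    gaps = rng.uniform(0.3, 1.7, size=n_sites) * mean_spacing_m
    distances = np.round(np.cumsum(gaps) - gaps[0] + rng.uniform(5, 20), 2)
    ids = tuple(f"S{i + 1}" for i in range(n_sites))
    return TransectProfile(ids, distances, chosen)


def gen_quadrats(profile: TransectProfile, species, seed: int = 0,
                 dispersion: float | None = None) -> pd.DataFrame:
    """Quadrat counts: 4 seasons × (3 arboreal / 5 epifaunal / 5 infaunal)
    quadrats per site, expected count = niche density × quadrat area.

    ``dispersion`` switches Poisson noise to negative binomial with that
    shape parameter (smaller = more overdispersed).  Zero-count rows are
    kept so sampling effort is recoverable from the table itself.
    """
    rng = _rng(seed, "quadrats")
    rows = []
    for sid, elev in zip(profile.site_ids, profile.elevations_cm):
        for season in SEASONS:
            for asm in ASSEMBLAGES:
                area = DEFAULT_QUADRAT_AREA[asm]
                for q in range(1, QUADRATS_PER_SITE[asm] + 1):
                    qid = f"{asm[:3]}-q{q}"
                    for sp in species:
                        if sp.assemblage != asm:
                            continue
                        mu = float(sp.density_at(elev)) * area
                        if mu == 0:
                            count = 0
                        elif dispersion is None:
                            count = int(rng.poisson(mu))
                        else:
                            p = dispersion / (dispersion + mu)
                            count = int(rng.negative_binomial(dispersion, p))
                        rows.append(
                            (sid, season, asm, sp.species_code, qid, area, count)
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "season", "assemblage", "species_code",
            "quadrat_id", "quadrat_area_m2", "count",
        ],
    )


def default_dates(n: int = 8, start: str = "2016-07-15",
                  months_step: int = 6) -> pd.DatetimeIndex:
    """Measurement occasions at regular multi-month intervals."""
    return pd.date_range(start=start, periods=n, freq=pd.DateOffset(months=months_step))


def gen_rset_series(benchmark_elevations, a_true: float, b_true: float,
                    dates, noise_sd_mm: float = 0.0, seed: int = 0,
                    baseline_mm: float = 500.0) -> pd.DataFrame:
    """RSET pin readings for benchmarks rising at a_true·exp(−b_true·E).

    Each benchmark's latent surface rises linearly at its elevation's
    rate; pin distances shrink accordingly around per-pin baseline offsets
    (micro-topography), plus reading noise.
    """
    if a_true <= 0:
        raise ValidationError("a_true must be > 0")
    dates = pd.to_datetime(pd.Index(dates))
    if not dates.is_monotonic_increasing or dates.has_duplicates:
        raise ValidationError("dates must be strictly increasing")
    rng = _rng(seed, "rset")
    t = decimal_years(dates)
    rows = []
    for bench, elev in dict(benchmark_elevations).items():
        rate = a_true * np.exp(-b_true * float(elev))  # mm/yr
        offsets = baseline_mm + rng.normal(0.0, 10.0, size=(4, 9))
        for ti, date in zip(t, dates):
            noise = (
                rng.normal(0.0, noise_sd_mm, size=(4, 9)) if noise_sd_mm > 0
                else np.zeros((4, 9))
            )
            for di in range(4):
                for pi in range(9):
                    rows.append((
                        str(bench), date, di + 1, pi + 1,
                        offsets[di, pi] - rate * ti + noise[di, pi],
                    ))
    return pd.DataFrame(
        rows, columns=["benchmark_id", "date", "direction", "pin", "distance_mm"]
    )


def gen_marker_series(station_elevations, a_true: float, b_true: float,
                      accretion_slope: float, accretion_intercept: float,
                      dates, noise_sd_mm: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Marker-horizon depths consistent with the full calibration chain.

    Accretion at elevation E is (a_true·exp(−b_true·E) − intercept)/slope,
    the inverse of the accretion→elevation-change regression, so running
    the chain (accretion rates → regression → exponential fit) on
    noiseless output recovers (a_true, b_true) exactly.  Depths grow
    linearly from zero at the first date (deployment); three cores per
    occasion, truncated at zero depth.
    """
    if accretion_slope <= 0:
        raise ValidationError("accretion_slope must be > 0")
    dates = pd.to_datetime(pd.Index(dates))
    if not dates.is_monotonic_increasing or dates.has_duplicates:
        raise ValidationError("dates must be strictly increasing")
    rng = _rng(seed, "marker")
    t = decimal_years(dates)
    rows = []
    for station, elev in dict(station_elevations).items():
        rate = a_true * np.exp(-b_true * float(elev))
        acc = (rate - accretion_intercept) / accretion_slope  # mm/yr
        if acc <= 0:
            raise ValidationError(
                f"station {station}: implied accretion {acc:.2f} mm/yr is not positive"
            )
        for ti, date in zip(t, dates):
            for core in (1, 2, 3):
                noise = rng.normal(0.0, noise_sd_mm) if noise_sd_mm > 0 else 0.0
                depth = max(0.0, acc * ti + noise)
                rows.append((str(station), date, core, depth))
    return pd.DataFrame(rows, columns=["station_id", "date", "core_id", "depth_mm"])


def _marker_station_elevations() -> dict:
    """36 marker stations with the surveyed elevation distribution.

    The field campaign deployed marker horizons at every sampling site of
    all six transects; the stations here reuse that elevation multiset so
    the exponential fit sees the same leverage the real study had.
    """
    from .datasets import load_transect, transect_names

    elevs = np.concatenate(
        [load_transect(n).elevations_cm for n in transect_names()]
    )
    return {f"MH-{i + 1}": float(e) for i, e in enumerate(elevs)}


def generate_all(config: SyntheticConfig,
                 profile: TransectProfile | None = None,
                 include_quadrats: bool = True) -> dict:
    """All four tables from one config: the full synthetic study.

    The layout mirrors the field design: 9 RSET benchmarks along the
    simulated transect (paired marker horizons for the accretion
    regression), plus marker horizons at 36 transect sampling sites
    across the elevation gradient for the exponential fit.
    ``include_quadrats=False`` skips the count table (the slow part) for
    callers that only exercise the elevation calibration chain.
    """
    if profile is None:
        profile = gen_transect(seed=config.seed)
    species = default_species(config)
    quadrats = (
        gen_quadrats(profile, species, seed=config.seed,
                     dispersion=config.count_dispersion)
        if include_quadrats else None
    )
    bench_elevs = {f"RSET-{i + 1}": e
                   for i, e in enumerate(profile.elevations_cm)}
    rset = gen_rset_series(
        bench_elevs, config.a_true, config.b_true,
        default_dates(8, "2016-07-15", 6),
        noise_sd_mm=config.pin_noise_sd_mm, seed=config.seed,
    )
    marker_dates = default_dates(6, "2016-07-15", 5)
    bench_markers = gen_marker_series(
        bench_elevs, config.a_true, config.b_true,
        config.accretion_slope, config.accretion_intercept,
        marker_dates, noise_sd_mm=config.marker_noise_sd_mm, seed=config.seed,
    )
    station_elevs = _marker_station_elevations()
    site_markers = gen_marker_series(
        station_elevs, config.a_true, config.b_true,
        config.accretion_slope, config.accretion_intercept,
        default_dates(6, "2017-07-15", 5),
        noise_sd_mm=config.marker_noise_sd_mm, seed=config.seed + 1,
    )
    return {
        "profile": profile,
        "species": species,
        "quadrats": quadrats,
        "rset": rset,
        "benchmark_markers": bench_markers,
        "site_markers": site_markers,
        "benchmark_elevations": bench_elevs,
        "station_elevations": station_elevs,
    }
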