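"""Surface-elevation dynamics: calibration and scenario simulation.

The mechanistic core is an ecogeomorphic feedback law: the lower a patch
of forest floor sits in the tidal frame, the longer it is inundated and
the faster sediment accretes on it.  The rate of surface-elevation change
(mm yr⁻¹) at relative elevation ``E`` (cm above contemporaneous mean sea
level) is modelled as an exponential decay

    rate(E) = a · exp(−b·E)

with ``a`` the rate at mean sea level and ``b`` the decay constant per cm.
Under a sea-level-rise rate ``S`` (mm yr⁻¹), the relative elevation of a
site evolves in annual steps

    E_{t+1} = E_t + rate(E_t)/10 − S/10        (cm)

so each site drifts monotonically toward the equilibrium
``E* = ln(a/S)/b`` where accretion exactly keeps pace with the sea.

Calibration routes:

* from field data — RSET pin-reading trends give elevation-change rates at
  the benchmarks; marker-horizon burial gives accretion rates; a linear
  regression links the two; accretion measured at the transect sites is
  then converted to elevation-change rates, and the exponential law fitted
  to (site elevation, rate) pairs (:class:`SurfaceElevationModel`);
* from two anchor rates (:func:`calibrate_from_thresholds`) — a closed form
  through two (elevation, rate) points;
* from one anchor rate and a known simulated endpoint
  (:func:`calibrate_from_endpoint`) — scalar root-finding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import Constants, TransectProfile, ValidationError, decimal_years, mm_to_cm

__all__ = [
    "LinearFit",
    "SurfaceElevationModel",
    "SurfaceElevationResults",
    "ZoneExtent",
    "fit_rset_trend",
    "accretion_rate",
    "fit_accretion_regression",
    "predict_elev_change",
    "calibrate_from_thresholds",
    "calibrate_from_endpoint",
    "annual_step",
    "zone_extent",
    "zone_width_fraction",
]

READINGS_PER_OCCASION = 36  # 9 pins × 4 directions


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line ``y = slope·x + intercept``."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def _linregress(x, y) -> LinearFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("regressor is constant; singular fit")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=int(x.size),
    )


def fit_rset_trend(rset: pd.DataFrame) -> pd.DataFrame:
    """Per-benchmark surface-elevation-change rate from RSET pin readings.

    For every measurement occasion the elevation change relative to the
    first occasion is the mean over the 36 pin positions of
    (baseline distance − current distance): pins sticking out less mean
    the surface came up.  The rate is the OLS slope of those changes
    against decimal years, in mm yr⁻¹.  Occasions with fewer than 36
    readings are dropped with a warning; at least three complete
    occasions are required per benchmark.

    Returns a DataFrame indexed by benchmark_id with columns
    rate_mm_yr, intercept, r_squared, p_value, stderr, n_occasions.
    """
    rows = {}
    for bench, grp in rset.groupby("benchmark_id", sort=True):
        pivot = grp.pivot_table(
            index="date", columns=["direction", "pin"], values="distance_mm"
        )
        complete = pivot.notna().sum(axis=1) == READINGS_PER_OCCASION
        if (~complete).any():
            dropped = list(pivot.index[~complete].strftime("%Y-%m-%d"))
            warnings.warn(
                f"benchmark {bench}: dropping incomplete occasions {dropped}",
                stacklevel=2,
            )
            pivot = pivot.loc[complete]
        if len(pivot) < 3:
            raise ValidationError(
                f"benchmark {bench}: need >=3 complete occasions, have {len(pivot)}"
            )
        pivot = pivot.sort_index()
        baseline = pivot.iloc[0]
        change = (baseline - pivot).mean(axis=1)  # mm of surface rise
        t = decimal_years(pivot.index)
        fit = _linregress(t, change.to_numpy())
        rows[bench] = {
            "rate_mm_yr": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "p_value": fit.p_value,
            "stderr": fit.stderr,
            "n_occasions": fit.n,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "benchmark_id"
    return out


def accretion_rate(markers: pd.DataFrame, deployment=None) -> pd.DataFrame:
    """Per-station sediment-accretion rate from marker-horizon depths.

    The depth above the feldspar layer, averaged over the three cores of
    an occasion, is regressed on decimal years; the slope is the accretion
    rate in mm yr⁻¹.  ``deployment`` (a date) optionally anchors the
    regression at (deployment, 0 mm) — the layer starts at the surface —
    which lets a single revisit yield a rate.
    """
    rows = {}
    for station, grp in markers.groupby("station_id", sort=True):
        occ = grp.groupby("date")["depth_mm"].mean().sort_index()
        t = decimal_years(occ.index, origin=deployment)
        depth = occ.to_numpy()
        if deployment is not None:
            t = np.concatenate([[0.0], t])
            depth = np.concatenate([[0.0], depth])
        if len(depth) < 2:
            raise ValidationError(
                f"station {station}: need >=2 occasions (or a deployment date)"
            )
        if len(depth) == 2:
            slope = (depth[1] - depth[0]) / (t[1] - t[0])
            rows[station] = {
                "accretion_mm_yr": float(slope),
                "r_squared": 1.0,
                "p_value": np.nan,
                "n_occasions": 2,
            }
        else:
            fit = _linregress(t, depth)
            rows[station] = {
                "accretion_mm_yr": fit.slope,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "n_occasions": fit.n,
            }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "station_id"
    return out


def fit_accretion_regression(accretion_rates, elev_change_rates) -> LinearFit:
    """OLS of elevation-change rate on accretion rate (both mm yr⁻¹).

    Elevation change is slower than raw accretion (shallow subsidence,
    compaction); this line converts accretion measured at unmonumented
    sites into elevation-change rates.  Requires at least three pairs.
    """
    x = np.asarray(accretion_rates, dtype=float)
    y = np.asarray(elev_change_rates, dtype=float)
    if x.size != y.size:
        raise ValidationError("accretion and elevation-change rates must pair up")
    if x.size < 3:
        raise ValidationError("need >=3 paired benchmarks")
    return _linregress(x, y)


def predict_elev_change(fit: LinearFit, accretion_rates) -> np.ndarray:
    """Elevation-change rates (mm yr⁻¹) predicted from accretion rates."""
    return fit.predict(accretion_rates)


def annual_step(elevation_cm, a: float, b: float, slr_mm_yr: float):
    """One year of the feedback dynamics, in cm.

    Accretion is evaluated at the start-of-year relative elevation and the
    year's sea-level rise is subtracted in the same step.
    """
    e = np.asarray(elevation_cm, dtype=float)
    rise = mm_to_cm(a * np.exp(-b * e))
    return e + rise - float(mm_to_cm(slr_mm_yr))


@dataclass(frozen=True)
class ZoneExtent:
    """Horizontal extent of the surviving (elevation ≥ floor) zone."""

    segments: tuple
    total_width_m: float

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def zone_extent(profile: TransectProfile, e_min_cm: float,
                seaward_edge_m: float | None = None) -> ZoneExtent:
    """Portions of the transect at or above the survival floor.

    Elevation is linearly interpolated between adjacent sites along
    distance; disjoint surviving segments are summed.  If
    ``seaward_edge_m`` is given (typically 0.0), the profile is extended
    seaward to that coordinate at the first site's elevation, so the
    reference width runs from the forest edge to the landward-most site.
    """
    x = profile.distances_m
    y = profile.elevations_cm
    if seaward_edge_m is not None:
        if seaward_edge_m > x[0]:
            raise ValidationError("seaward edge must lie seaward of the first site")
        x = np.concatenate([[seaward_edge_m], x])
        y = np.concatenate([[y[0]], y])
    segments = []
    cur_start = None
    for i in range(len(x) - 1):
        x1, x2, y1, y2 = x[i], x[i + 1], y[i], y[i + 1]
        a1, a2 = y1 >= e_min_cm, y2 >= e_min_cm
        if a1 and cur_start is None:
            cur_start = x1
        if a1 and a2:
            continue
        if a1 and not a2:
            xc = x1 + (e_min_cm - y1) * (x2 - x1) / (y2 - y1)
            segments.append((cur_start, xc))
            cur_start = None
        elif not a1 and a2:
            xc = x1 + (e_min_cm - y1) * (x2 - x1) / (y2 - y1)
            cur_start = xc
    if y[-1] >= e_min_cm and cur_start is not None:
        segments.append((cur_start, x[-1]))
    total = float(sum(b - a for a, b in segments))
    return ZoneExtent(tuple((float(a), float(b)) for a, b in segments), total)


def zone_width_fraction(profile_2020: TransectProfile,
                        profile_final: TransectProfile,
                        e_min_cm: float = -15.0) -> float:
    """Final zone width as a fraction of the initial one.

    The initial width is measured from the seaward forest edge (x = 0) to
    the landward-most site; the final width sums the surviving segments
    between sites.
    """
    w0 = zone_extent(profile_2020, e_min_cm, seaward_edge_m=0.0).total_width_m
    if w0 == 0:
        raise ValidationError("initial zone has zero width")
    w1 = zone_extent(profile_final, e_min_cm).total_width_m
    return w1 / w0


class SurfaceElevationModel:
    """Exponential accretion-feedback model, rate(E) = a·exp(−b·E).

    Parameters
    ----------
    elevations_cm : array-like
        Site surface elevations relative to mean sea level, cm.
    rates_mm_yr : array-like
        Surface-elevation-change rates at those sites, mm yr⁻¹.
        Non-positive rates cannot be represented by the law and are
        excluded with a warning at fit time.

    Use :meth:`from_field_data` to run the full measurement-reduction
    chain from raw RSET and marker-horizon tables.
    """

    def __init__(self, elevations_cm, rates_mm_yr):
        self.elevations_cm = np.asarray(elevations_cm, dtype=float)
        self.rates_mm_yr = np.asarray(rates_mm_yr, dtype=float)
        if self.elevations_cm.size != self.rates_mm_yr.size:
            raise ValidationError("elevations and rates must align")

    @classmethod
    def from_field_data(
        cls,
        rset: pd.DataFrame,
        benchmark_markers: pd.DataFrame,
        site_markers: pd.DataFrame,
        site_elevations: pd.Series | dict,
        deployment=None,
    ) -> "SurfaceElevationModel":
        """Build the model from raw field tables.

        1. RSET trends → elevation-change rate per benchmark;
        2. benchmark marker horizons → accretion rate per benchmark;
        3. regress (1) on (2);
        4. transect-site marker horizons → accretion per site, converted
           through the regression to elevation-change rates.

        The fitted accretion regression is attached as
        ``model.accretion_fit`` for diagnostics.
        """
        trend = fit_rset_trend(rset)
        bench_acc = accretion_rate(benchmark_markers, deployment=deployment)
        common = trend.index.intersection(bench_acc.index)
        if len(common) < 3:
            raise ValidationError("need >=3 benchmarks with both RSET and marker data")
        fit = fit_accretion_regression(
            bench_acc.loc[common, "accretion_mm_yr"],
            trend.loc[common, "rate_mm_yr"],
        )
        site_acc = accretion_rate(site_markers, deployment=deployment)
        elev = pd.Series(site_elevations).astype(float)
        missing = site_acc.index.difference(elev.index)
        if len(missing):
            raise ValidationError(f"no elevation for stations: {list(missing)}")
        rates = predict_elev_change(fit, site_acc["accretion_mm_yr"].to_numpy())
        model = cls(elev.loc[site_acc.index].to_numpy(), rates)
        model.accretion_fit = fit
        model.rset_trend = trend
        return model

    @staticmethod
    def _loglinear_start(e, r):
        # exact solution when the data are exactly exponential
        slope, intercept = np.polyfit(e, np.log(r), 1)
        return float(np.exp(intercept)), float(-slope)

    def fit(self) -> "SurfaceElevationResults":
        """Least-squares fit of (a, b), initialised from the log-linear solution."""
        keep = self.rates_mm_yr > 0
        if (~keep).any():
            warnings.warn(
                f"excluding {int((~keep).sum())} non-positive rate(s) from the "
                "exponential fit",
                stacklevel=2,
            )
        e = self.elevations_cm[keep]
        r = self.rates_mm_yr[keep]
        if np.unique(e).size < 3:
            raise ValidationError("need >=3 distinct elevations with positive rates")
        a0, b0 = self._loglinear_start(e, r)
        popt, pcov = optimize.curve_fit(
            lambda x, a, b: a * np.exp(-b * x), e, r, p0=[a0, b0], maxfev=10000
        )
        a, b = (float(p) for p in popt)
        resid = r - a * np.exp(-b * e)
        ss_tot = float(np.sum((r - r.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        bse = tuple(float(s) for s in np.sqrt(np.diag(pcov)))
        return SurfaceElevationResults(
            a=a, b=b, bse=bse, r_squared=r2, nobs=int(e.size),
            method="nonlinear-ls", model=self,
        )


@dataclass
class SurfaceElevationResults:
    """Calibrated feedback law plus everything that hangs off it.

    Attributes
    ----------
    a : float
        Elevation-change rate at mean sea level (E = 0), mm yr⁻¹.
    b : float
        Exponential decay constant, cm⁻¹.
    bse : tuple
        Standard errors of (a, b); NaN for closed-form calibrations.
    """

    a: float
    b: float
    bse: tuple = (np.nan, np.nan)
    r_squared: float = np.nan
    nobs: int = 0
    method: str = "explicit"
    model: SurfaceElevationModel | None = None

    def __post_init__(self):
        if self.a <= 0:
            raise ValidationError("a must be > 0")

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a, self.b])

    # -- rate law ---------------------------------------------------------
    def predict(self, elevation_cm):
        """rate(E) = a·exp(−b·E), mm yr⁻¹."""
        return self.a * np.exp(-self.b * np.asarray(elevation_cm, dtype=float))

    def critical_slr(self, elevation_cm):
        """SLR rate (mm yr⁻¹) at which a site of this elevation just holds.

        Below it the site gains relative elevation by 2100; above it the
        site loses elevation.
        """
        return self.predict(elevation_cm)

    def equilibrium(self, slr_mm_yr: float) -> float:
        """Relative elevation E* = ln(a/S)/b toward which trajectories relax.

        Undefined (NaN) when b = 0: the rate is then elevation-independent
        and nothing balances.
        """
        if self.b == 0:
            return float("nan")
        if slr_mm_yr <= 0:
            raise ValidationError("slr must be > 0")
        return float(np.log(self.a / slr_mm_yr) / self.b)

    # -- simulation -------------------------------------------------------
    def simulate(self, e0_cm, slr_mm_yr: float,
                 year_start: int = 2020, year_end: int = 2100) -> np.ndarray:
        """Annual relative-elevation trajectory; first entry equals ``e0_cm``.

        Returns an array of ``year_end − year_start + 1`` elevations (cm),
        vectorised over ``e0_cm``.
        """
        if year_end <= year_start:
            raise ValidationError("year_end must exceed year_start")
        e = np.asarray(e0_cm, dtype=float)
        out = np.empty((year_end - year_start + 1,) + e.shape)
        out[0] = e
        for i in range(1, out.shape[0]):
            e = annual_step(e, self.a, self.b, slr_mm_yr)
            out[i] = e
        return out

    def trajectory(self, profile: TransectProfile, slr_mm_yr: float,
                   constants: Constants | None = None) -> pd.DataFrame:
        """Long table (site_id, year, elevation_cm) for one scenario."""
        c = constants or Constants()
        traj = self.simulate(profile.elevations_cm, slr_mm_yr,
                             c.year_start, c.year_end)
        years = np.arange(c.year_start, c.year_end + 1)
        frames = []
        for j, sid in enumerate(profile.site_ids):
            frames.append(pd.DataFrame({
                "site_id": sid,
                "slr_mm_yr": slr_mm_yr,
                "year": years,
                "elevation_cm": traj[:, j],
            }))
        return pd.concat(frames, ignore_index=True)

    def simulate_profile(self, profile: TransectProfile, slr_mm_yr: float,
                         constants: Constants | None = None) -> TransectProfile:
        """The transect with each site at its simulated final elevation."""
        c = constants or Constants()
        traj = self.simulate(profile.elevations_cm, slr_mm_yr,
                             c.year_start, c.year_end)
        return profile.with_elevations(traj[-1])

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        se_a = f"   (se {self.bse[0]:.4f})" if np.isfinite(self.bse[0]) else ""
        se_b = f"    (se {self.bse[1]:.6f})" if np.isfinite(self.bse[1]) else ""
        lines = [
            "Surface elevation feedback model  rate(E) = a*exp(-b*E)",
            f"  calibration: {self.method}   n = {self.nobs}",
            f"  a = {self.a:10.4f} mm/yr{se_a}",
            f"  b = {self.b:10.6f} 1/cm{se_b}",
        ]
        if np.isfinite(self.r_squared):
            lines.append(f"  R^2 = {self.r_squared:.4f}")
        lines.append(
            f"  rate at 150 cm: {float(self.predict(150.0)):.2f} mm/yr; "
            f"rate at -15 cm: {float(self.predict(-15.0)):.2f} mm/yr"
        )
        return "\n".join(lines)


def calibrate_from_thresholds(e1_cm: float, s1_mm_yr: float,
                              e2_cm: float, s2_mm_yr: float) -> SurfaceElevationResults:
    """Closed-form calibration through two (elevation, rate) anchors.

    b = ln(s2/s1)/(e1 − e2);  a = s1·exp(b·e1).  Equal rates give b = 0.
    """
    if s1_mm_yr <= 0 or s2_mm_yr <= 0:
        raise ValidationError("anchor rates must be > 0")
    if e1_cm == e2_cm:
        raise ValidationError("anchor elevations must differ")
    b = float(np.log(s2_mm_yr / s1_mm_yr) / (e1_cm - e2_cm))
    a = float(s1_mm_yr * np.exp(b * e1_cm))
    return SurfaceElevationResults(a=a, b=b, nobs=2, method="thresholds")


def calibrate_from_endpoint(
    e_anchor_cm: float,
    s_anchor_mm_yr: float,
    e0_cm: float,
    slr_mm_yr: float,
    endpoint_cm: float,
    year_start: int = 2020,
    year_end: int = 2100,
    b_bracket=(1e-6, 0.05),
) -> SurfaceElevationResults:
    """Calibrate (a, b) from one rate anchor plus one simulated endpoint.

    Given rate(e_anchor) = s_anchor, every candidate b fixes
    a(b) = s_anchor·exp(b·e_anchor); the b for which the annual-step
    trajectory from ``e0_cm`` under ``slr_mm_yr`` lands on ``endpoint_cm``
    is found by bracketed root-finding.
    """
    def final(b):
        a = s_anchor_mm_yr * np.exp(b * e_anchor_cm)
        e = float(e0_cm)
        for _ in range(year_end - year_start):
            e = float(annual_step(e, a, b, slr_mm_yr))
        return e - endpoint_cm

    lo, hi = b_bracket
    if final(lo) * final(hi) > 0:
        raise ValidationError("endpoint not bracketed by the b search interval")
    b = float(optimize.brentq(final, lo, hi, xtol=1e-12))
    a = float(s_anchor_mm_yr * np.exp(b * e_anchor_cm))
    return SurfaceElevationResults(a=a, b=b, nobs=2, method="endpoint")
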