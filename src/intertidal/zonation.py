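"""Molluscan vertical zonation statistics.

From the quadrat counts: per-species mean density on the sampled elevation
grid (seasons and quadrats pooled), standardisation to proportions,
density-weighted elevation moments and percentiles, rank-based comparison
of the species' elevation distributions (Kruskal–Wallis with tie
correction, then pairwise Dunn tests with Holm adjustment and a
compact-letter display), and the quadratic regression of elevation
variance on mean elevation whose vertex marks the mid-shore maximum of
niche spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import TransectProfile, ValidationError

__all__ = [
    "DensityProfile",
    "EmptyNicheError",
    "KwResult",
    "QuadraticFit",
    "density_profiles",
    "standardize",
    "weighted_moments",
    "weighted_percentiles",
    "zonation_summary",
    "individual_elevations",
    "kruskal_wallis",
    "dunn_pairwise",
    "stepdown_groups",
    "quadratic_variance_fit",
    "one_sample_t",
]


class EmptyNicheError(ValidationError):
    """A species' density profile is identically zero."""


@dataclass(frozen=True)
class DensityProfile:
    """Mean density (ind. m⁻²) of one species on the elevation grid."""

    species_code: str
    assemblage: str
    elevations_cm: np.ndarray
    densities: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.elevations_cm, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        if e.size != d.size or e.size == 0:
            raise ValidationError("elevations and densities must align")
        order = np.argsort(e)
        e, d = e[order], d[order]
        if np.any(d < 0):
            raise ValidationError("densities must be >= 0")
        object.__setattr__(self, "elevations_cm", e)
        object.__setattr__(self, "densities", d)


def density_profiles(quadrats: pd.DataFrame,
                     profile: TransectProfile) -> dict:
    """Per-species density profile over elevation, pooling seasons/quadrats.

    The density of a species at an elevation is its total count across all
    quadrats of its assemblage sampled at that elevation (all sites
    sharing the elevation, all seasons), divided by the total sampled
    area.  Sampling effort comes from the full quadrat table, so species
    absent from a quadrat still count its area in the denominator.
    """
    elev = dict(zip(profile.site_ids, profile.elevations_cm))
    missing = set(quadrats["site_id"]) - set(elev)
    if missing:
        raise ValidationError(f"sites without surveyed elevation: {sorted(missing)}")
    q = quadrats.copy()
    q["elevation_cm"] = q["site_id"].map(elev)

    # sampled area per (assemblage, elevation): one row per physical quadrat
    effort = (
        q.drop_duplicates(["site_id", "season", "assemblage", "quadrat_id"])
        .groupby(["assemblage", "elevation_cm"])["quadrat_area_m2"]
        .sum()
    )
    counts = q.groupby(["species_code", "assemblage", "elevation_cm"])["count"].sum()

    out = {}
    for (sp, asm), grp in counts.groupby(level=["species_code", "assemblage"]):
        grid = effort.loc[asm]
        dens = pd.Series(0.0, index=grid.index)
        totals = grp.droplevel(["species_code", "assemblage"])
        dens.loc[totals.index] = totals.to_numpy() / grid.loc[totals.index].to_numpy()
        out[sp] = DensityProfile(sp, asm, dens.index.to_numpy(), dens.to_numpy())
    return out


def standardize(profile: DensityProfile) -> np.ndarray:
    """Densities as proportions of the species total (sum to 1)."""
    total = profile.densities.sum()
    if total <= 0:
        raise EmptyNicheError(
            f"species {profile.species_code}: no individuals anywhere on the grid"
        )
    return profile.densities / total


def weighted_moments(profile: DensityProfile) -> tuple:
    """Density-weighted mean elevation (cm) and variance (cm²)."""
    p = standardize(profile)
    mean = float(np.sum(p * profile.elevations_cm))
    var = float(np.sum(p * (profile.elevations_cm - mean) ** 2))
    return mean, var


def weighted_percentiles(profile: DensityProfile,
                         qs=(10, 25, 50, 75, 90)) -> np.ndarray:
    """Percentiles of the discrete elevation distribution.

    The q-th percentile is the smallest sampled elevation whose cumulative
    proportion reaches q/100, so the outputs are always monotone in q.
    """
    p = standardize(profile)
    cdf = np.cumsum(p)
    out = []
    for q in qs:
        idx = int(np.searchsorted(cdf, q / 100.0 - 1e-12))
        out.append(profile.elevations_cm[min(idx, p.size - 1)])
    return np.asarray(out)


def zonation_summary(profiles: Mapping[str, DensityProfile]) -> pd.DataFrame:
    """Summary table: mean, variance and percentiles per species.

    Species with empty niches (all-zero profiles) are skipped with a
    warning rather than poisoning the table with NaNs.
    """
    rows = []
    for sp in sorted(profiles):
        prof = profiles[sp]
        try:
            mean, var = weighted_moments(prof)
        except EmptyNicheError:
            warnings.warn(f"skipping empty-niche species {sp}", stacklevel=2)
            continue
        p10, p25, p50, p75, p90 = weighted_percentiles(prof)
        rows.append({
            "species_code": sp,
            "assemblage": prof.assemblage,
            "mean_elevation_cm": mean,
            "variance_cm2": var,
            "p10": p10, "p25": p25, "p50": p50, "p75": p75, "p90": p90,
        })
    return pd.DataFrame(rows)


def individual_elevations(quadrats: pd.DataFrame,
                          profile: TransectProfile) -> dict:
    """Per-species array of individual elevations (site elevation × count).

    Reconstructs an individual-level sample for the rank tests: every
    counted individual is assigned the elevation of its site, which
    produces heavy ties — the tie-corrected H statistic is therefore
    essential downstream.
    """
    elev = dict(zip(profile.site_ids, profile.elevations_cm))
    missing = set(quadrats["site_id"]) - set(elev)
    if missing:
        raise ValidationError(f"sites without surveyed elevation: {sorted(missing)}")
    out = {}
    grouped = quadrats.groupby(["species_code", "site_id"])["count"].sum()
    for sp, bysite in grouped.groupby(level="species_code"):
        counts = bysite.droplevel("species_code")
        e = np.repeat([elev[s] for s in counts.index],
                      counts.to_numpy().astype(int))
        if e.size:
            out[sp] = np.sort(e)
    return out


@dataclass(frozen=True)
class KwResult:
    """Kruskal–Wallis outcome, optionally completed with post-hoc letters."""

    h: float
    df: int
    p_value: float
    mean_ranks: dict
    pairwise_p: pd.DataFrame | None = None
    letters: dict | None = None


def kruskal_wallis(groups: Mapping[str, np.ndarray]) -> KwResult:
    """Tie-corrected Kruskal–Wallis test across species elevation samples."""
    names = [k for k in groups if len(np.asarray(groups[k])) > 0]
    if len(names) < 2:
        raise ValidationError("need at least two nonempty groups")
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    ranks = stats.rankdata(pooled)
    mean_ranks, start = {}, 0
    for name, s in zip(names, samples):
        mean_ranks[name] = float(ranks[start:start + s.size].mean())
        start += s.size
    return KwResult(h=float(h), df=len(names) - 1, p_value=float(p),
                    mean_ranks=mean_ranks)


def dunn_pairwise(groups: Mapping[str, np.ndarray],
                  adjust: str = "holm") -> pd.DataFrame:
    """Two-sided Dunn rank tests between all group pairs.

    The z statistic uses the tie-corrected pooled rank variance
    N(N+1)/12 − ΣT/(12(N−1)) with T = t³ − t over tied values; p-values
    are Holm-adjusted across the k(k−1)/2 comparisons (``adjust=None``
    for raw p).
    """
    names = sorted(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    sizes = np.array([s.size for s in samples])
    if np.any(sizes == 0):
        raise ValidationError("empty group in Dunn test")
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, start = [], 0
    for s in samples:
        mean_ranks.append(ranks[start:start + s.size].mean())
        start += s.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var -= tie_term / (12.0 * (n_total - 1))

    pairs, praw = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if var <= 0:  # every observation tied
                praw.append(1.0)
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(
                    var * (1.0 / sizes[i] + 1.0 / sizes[j])
                )
                praw.append(2.0 * stats.norm.sf(abs(z)))
            pairs.append((i, j))

    if adjust == "holm":
        padj = _holm(np.asarray(praw))
    elif adjust is None:
        padj = np.asarray(praw)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    mat = pd.DataFrame(1.0, index=names, columns=names)
    for (i, j), p in zip(pairs, padj):
        mat.iloc[i, j] = mat.iloc[j, i] = float(p)
    return mat


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def stepdown_groups(groups: Mapping[str, np.ndarray],
                    alpha: float = 0.05,
                    kw: KwResult | None = None) -> KwResult:
    """Homogeneous-subset letters from pairwise Dunn tests.

    Species are ordered by ascending mean rank; every maximal window of
    consecutive species that are mutually non-significant (Holm-adjusted
    p ≥ alpha) receives one lowercase letter, so species bridging two
    subsets carry both letters — the lettering style of zonation box
    plots.  Returns the Kruskal–Wallis result completed with the pairwise
    p matrix and the letters.
    """
    if kw is None:
        kw = kruskal_wallis(groups)
    pmat = dunn_pairwise(groups)
    ordered = sorted(kw.mean_ranks, key=kw.mean_ranks.get)
    k = len(ordered)

    windows = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and all(
            pmat.loc[ordered[a], ordered[j + 1]] >= alpha for a in range(i, j + 1)
        ):
            j += 1
        if not windows or windows[-1][1] < j:
            windows.append((i, j))
        i += 1
    letters = {name: "" for name in ordered}
    for w, (lo, hi) in enumerate(windows):
        letter = chr(ord("a") + w)
        for idx in range(lo, hi + 1):
            letters[ordered[idx]] += letter
    return replace(kw, pairwise_p=pmat, letters=letters)


@dataclass(frozen=True)
class QuadraticFit:
    """OLS of variance on mean elevation and its square."""

    beta0: float
    beta1: float
    beta2: float
    vertex_cm: float  # NaN when beta2 == 0
    r_squared: float
    p_value: float  # overall F test
    n: int


def quadratic_variance_fit(mean_elevations, variances) -> QuadraticFit:
    """Quadratic regression of elevation variance on mean elevation.

    Raw (uncentred) polynomial terms; the reported p is the overall-F
    p-value.  The vertex −β1/(2β2) locates the mean elevation of maximum
    niche spread; it is undefined (NaN) for a degenerate β2 = 0.
    """
    m = np.asarray(mean_elevations, dtype=float)
    v = np.asarray(variances, dtype=float)
    if m.size < 4:
        raise ValidationError("need >=4 species for the quadratic fit")
    X = sm.add_constant(np.column_stack([m, m**2]))
    res = sm.OLS(v, X).fit()
    b0, b1, b2 = (float(c) for c in res.params)
    vertex = float("nan") if np.isclose(b2, 0.0) else -b1 / (2.0 * b2)
    r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 0.0
    return QuadraticFit(
        beta0=b0, beta1=b1, beta2=b2, vertex_cm=vertex,
        r_squared=r2, p_value=float(res.f_pvalue), n=int(m.size),
    )


def one_sample_t(rates, mu0: float) -> tuple:
    """Two-sided one-sample t test of a rate sample against ``mu0``.

    Returns (t, p).  A zero-variance sample equal to ``mu0`` gives
    (0, 1); zero variance away from ``mu0`` is degenerate and returns a
    signed infinite t with p = 0 plus a warning.
    """
    x = np.asarray(rates, dtype=float)
    if x.size < 2:
        raise ValidationError("need n >= 2 for a t test")
    if np.ptp(x) == 0:
        if x[0] == mu0:
            return 0.0, 1.0
        warnings.warn("zero-variance sample off the null: degenerate t",
                      stacklevel=2)
        return float(np.sign(x[0] - mu0)) * float("inf"), 0.0
    t, p = stats.ttest_1samp(x, mu0)
    return float(t), float(p)
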