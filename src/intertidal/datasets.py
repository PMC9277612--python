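"""Published field inputs small enough to ship as code.

The Zhenzhu Bay (Guangxi, China) topographic survey placed 36 sampling
sites on six shore-normal transects through the mangrove forest, at 25-cm
elevation intervals between −15 and 150 cm above local mean sea level
(no site at 135 cm — a forest gap at that elevation). Distances are metres
from the seaward forest edge; elevations are cm relative to the 2020 mean
sea level. The SJ transect is the most completely sampled and is the one
the dynamic simulations run on.
"""

from __future__ import annotations

from .io import TransectProfile

_TRANSECTS = {
    "SJ": [
        ("SJ-1", 14.80, -15),
        ("SJ-2", 47.68, 10),
        ("SJ-3", 151.00, 35),
        ("SJ-4", 405.23, 60),
        ("SJ-5", 481.18, 35),
        ("SJ-6", 557.18, 60),
        ("SJ-7", 634.54, 85),
        ("SJ-8", 656.09, 110),
        ("SJ-9", 680.03, 150),
    ],
    "SJD": [
        ("SJD-1", 12.42, -15),
        ("SJD-2", 25.34, 10),
        ("SJD-3", 55.41, 35),
        ("SJD-4", 144.25, 60),
        ("SJD-5", 255.40, 60),
        ("SJD-6", 360.02, 35),
        ("SJD-7", 473.35, 10),
    ],
    "MLJD": [
        ("MLJD-1", 5.37, 10),
        ("MLJD-2", 92.61, 35),
        ("MLJD-3", 160.84, 60),
        ("MLJD-4", 372.88, 60),
        ("MLJD-5", 597.25, 35),
    ],
    "MLJ": [
        ("MLJ-1", 6.71, -15),
        ("MLJ-2", 25.70, 10),
        ("MLJ-3", 129.83, 35),
        ("MLJ-4", 215.12, 60),
        ("MLJ-5", 357.09, 60),
        ("MLJ-6", 386.54, 85),
    ],
    "JD": [
        ("JD-1", 8.74, -15),
        ("JD-2", 24.60, 10),
        ("JD-3", 102.12, 35),
        ("JD-4", 305.75, 60),
        ("JD-5", 582.87, 35),
    ],
    "GM": [
        ("GM-1", 21.68, 35),
        ("GM-2", 209.69, 60),
        ("GM-3", 469.62, 85),
        ("GM-4", 641.94, 110),
    ],
}

#: Elevation sampling lattice, cm: 25-cm steps from −15, the 135-cm level
#: unsampled, top level 150 cm.
ELEVATION_GRID = (-15, 10, 35, 60, 85, 110, 150)

#: Regime boundaries of the published simulations: the accretion-feedback
#: rate at the highest site (150 cm) and at the survival floor (−15 cm),
#: mm yr⁻¹. Sites whose feedback rate falls below the sea-level-rise rate
#: lose relative elevation.
THRESHOLD_HIGH_SITE = (150.0, 4.57)
THRESHOLD_LOW_SITE = (-15.0, 8.14)


def transect_names() -> tuple:
    return tuple(_TRANSECTS)


def load_transect(name: str = "SJ") -> TransectProfile:
    """One of the six surveyed transects as a :class:`TransectProfile`."""
    try:
        rows = _TRANSECTS[name]
    except KeyError:
        raise KeyError(
            f"unknown transect {name!r}; available: {sorted(_TRANSECTS)}"
        ) from None
    ids, dist, elev = zip(*rows)
    return TransectProfile(ids, dist, elev)
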