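"""Diagnostic plots hanging off the model results.

Quick matplotlib views, not publication figures: scenario trajectories,
species density profiles, and the rate–elevation law with its data.
"""

from __future__ import annotations

import numpy as np


def plot_trajectories(results, profile, slr_rates=(2.0, 8.0, 16.0), ax=None):
    """Relative-elevation trajectories of every site, one panel."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    years = np.arange(2020, 2101)
    for s in slr_rates:
        traj = results.simulate(profile.elevations_cm, float(s))
        for j in range(traj.shape[1]):
            ax.plot(years, traj[:, j], lw=0.8,
                    label=f"S={s}" if j == 0 else None)
    ax.axhline(-15.0, color="k", ls=":", lw=0.8)
    ax.set_xlabel("year")
    ax.set_ylabel("relative elevation (cm)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_rate_law(results, ax=None):
    """Fitted rate(E) curve over the calibration data, if any."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    e = np.linspace(-30, 160, 200)
    ax.plot(e, results.predict(e), "C0-")
    if results.model is not None:
        ax.plot(results.model.elevations_cm, results.model.rates_mm_yr, "C1o",
                ms=4)
    ax.set_xlabel("surface elevation (cm)")
    ax.set_ylabel("elevation change (mm/yr)")
    return ax


def plot_density_profiles(profiles, ax=None):
    """Per-species mean density against elevation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for sp in sorted(profiles):
        prof = profiles[sp]
        ax.plot(prof.elevations_cm, prof.densities, marker="o", ms=3,
                lw=0.8, label=sp)
    ax.set_xlabel("elevation (cm)")
    ax.set_ylabel("density (ind./m$^2$)")
    ax.legend(frameon=False, fontsize=7, ncol=2)
    return ax
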