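"""Plotting hooks: position profiles and onset-signature regions."""

from __future__ import annotations

import numpy as np

from hbaccess.explore import RegionSample
from hbaccess.features import PositionProfile, SignaturePoint

__all__ = ["plot_position_profile", "plot_regions"]


def plot_position_profile(profile: PositionProfile, axes=None):
    """Initial loading rate, t_on and fraction active vs AP position."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(12, 3.2), constrained_layout=True)
    ax_rate, ax_ton, ax_frac = axes
    x = profile.positions
    m = profile.active_mask
    ax_rate.errorbar(x[m], profile.init_rate[m], yerr=None if profile.init_rate_sem is None else profile.init_rate_sem[m], fmt="o-")
    ax_rate.set_xlabel("position (%EL)")
    ax_rate.set_ylabel("initial rate (RNAP/min)")
    ax_ton.errorbar(x[m], profile.t_on[m], yerr=None if profile.t_on_sem is None else profile.t_on_sem[m], fmt="o-")
    ax_ton.set_xlabel("position (%EL)")
    ax_ton.set_ylabel(r"$t_{on}$ (min)")
    ax_frac.plot(x, profile.fraction_active, "o-")
    ax_frac.axhline(0.3, ls="--", color="grey", lw=1)
    ax_frac.set_xlabel("position (%EL)")
    ax_frac.set_ylabel("fraction active")
    ax_frac.set_ylim(-0.05, 1.05)
    return axes


def plot_regions(regions: list[RegionSample], points: list[SignaturePoint] = (), ax=None):
    """Attainable (offset, delay) regions per model class with data points."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
    for region in regions:
        valid = region.samples[region.samples["valid"]]
        ax.scatter(valid["offset"], valid["avg_delay"], s=4, alpha=0.3, label=region.model_class)
    for point in points:
        ax.plot(point.offset, point.avg_delay, "k*", ms=10)
        if point.sem_offset > 0 or point.sem_delay > 0:
            ax.add_patch(
                Ellipse(
                    (point.offset, point.avg_delay),
                    2 * point.sem_offset,
                    2 * point.sem_delay,
                    fill=False,
                    color="k",
                )
            )
    ax.set_xlabel(r"$t_{on}$ offset (min)")
    ax.set_ylabel(r"average $t_{on}$ delay (min)")
    ax.legend(fontsize=8)
    return ax
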