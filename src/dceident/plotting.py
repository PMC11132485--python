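"""Figure panels for profiles and compensating traces."""

from __future__ import annotations

import numpy as np

from .profiles import CompensatingProfiles, LikelihoodProfile, chi2_threshold

__all__ = ["plot_profile", "plot_compensating"]

_LEVELS = (0.68, 0.80, 0.95)


def plot_profile(profile: LikelihoodProfile, levels=_LEVELS, ax=None):
    """Profile likelihood with chi-squared threshold lines.

    Returns the matplotlib Axes; log x-scale when the grid is positive.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(profile.grid, profile.pl_values, "k.-", lw=1, ms=4)
    for lev in levels:
        thr = profile.mle_hat + chi2_threshold(lev)
        ax.axhline(thr, ls="--", lw=0.8, label=f"{int(round(lev*100))}%")
    ax.plot([profile.target_hat], [profile.mle_hat], "r*", ms=10)
    if np.all(profile.grid > 0):
        ax.set_xscale("log")
    ax.set_xlabel(profile.target)
    ax.set_ylabel("PL")
    ax.legend(fontsize=8, title="confidence")
    ax.set_title(f"{profile.kind.value}: profile of {profile.target}")
    return ax


def plot_compensating(cp: CompensatingProfiles, ax=None):
    """Compensating co-parameter traces on twin y-axes (rates left,
    fractional volumes right)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax2 = ax.twinx()
    styles = ["-", "--", "-.", ":"]
    for i, (name, trace) in enumerate(cp.traces.items()):
        target_ax = ax if name in ("ktrans", "lam") else ax2
        color = "k" if target_ax is ax else "r"
        target_ax.plot(cp.target_values, trace, color=color, ls=styles[i % 4], label=name)
    ax.set_xlabel(cp.target)
    ax.set_ylabel("rates (1/s)", color="k")
    ax2.set_ylabel("fractional volumes", color="r")
    lines, labels = ax.get_legend_handles_labels()
    l2, lab2 = ax2.get_legend_handles_labels()
    ax.legend(lines + l2, labels + lab2, fontsize=8)
    ax.set_title(f"compensating profiles vs {cp.target}")
    return ax
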