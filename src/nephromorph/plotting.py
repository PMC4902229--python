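"""Diagnostic figures for longitudinal eGFR analyses."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_egfr_trajectories", "plot_stratified_slopes"]


def plot_egfr_trajectories(dataset, ax=None):
    """Spaghetti plot of all eGFR visits with the pooled linear fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for _, grp in dataset.visits.groupby("subject_id"):
        ax.plot(grp["time"], grp["egfr"], color="0.7", lw=0.6, alpha=0.6)
    t = dataset.visits["time"].to_numpy(dtype=float)
    y = dataset.visits["egfr"].to_numpy(dtype=float)
    coef = np.polyfit(t, y, 1)
    xs = np.linspace(0, t.max() if t.max() > 0 else 1, 50)
    ax.plot(xs, np.polyval(coef, xs), color="C3", lw=2,
            label=f"pooled slope {coef[0] * 12:.2f}/yr")
    ax.set_xlabel("months of follow-up")
    ax.set_ylabel("eGFR (mL/min/1.73 m$^2$)")
    ax.legend(frameon=False)
    return ax


def plot_stratified_slopes(dataset, result, ax=None):
    """Linear eGFR fits per stratifier quantile bin.

    ``result`` is a :class:`~nephromorph.longitudinal.StratifiedSlopes`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    fit = result.fit
    names = fit.exog_names
    params = fit.params
    t_max = float(dataset.visits["time"].max())
    xs = np.linspace(0, t_max if t_max > 0 else 1, 50)
    n_strata = len(result.slopes)
    colors = ["C3", "C1", "C0", "C4", "C2", "C5"]
    for b in range(n_strata):
        intercept = params[names.index("intercept")]
        slope = params[names.index("time")]
        if b > 0:
            intercept += params[names.index(f"stratum{b+1}")]
            slope += params[names.index(f"stratum{b+1}:time")]
        label = f"{result.stratifier} Q{b+1} ({slope:+.2f}/mo)"
        ax.plot(xs, intercept + slope * xs, color=colors[b % len(colors)], label=label)
    ax.set_xlabel("months of follow-up")
    ax.set_ylabel("eGFR (mL/min/1.73 m$^2$)")
    ax.legend(frameon=False, fontsize=8)
    return ax
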