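"""Figures for study results: brightness scatters and distribution fits."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["plot_brightness_scatter", "plot_brightness_distributions"]


def plot_brightness_scatter(results, ax=None):
    """Per-telomere brightness scatter by condition with median and IQR bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)
    conditions = results.model.conditions
    for i, cond in enumerate(conditions):
        vals = results.model.data.loc[results.model.data["condition"] == cond, "brightness"].to_numpy()
        x = i + rng.uniform(-0.18, 0.18, size=len(vals))
        ax.scatter(x, vals, s=6, alpha=0.4)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        ax.hlines(med, i - 0.28, i + 0.28, color="red", lw=2)
        ax.vlines(i + 0.28, q1, q3, color="red", lw=1.5)
    ax.set_xticks(range(len(conditions)), conditions)
    ax.set_ylabel("telomere brightness (photon counts)")
    return ax


def plot_brightness_distributions(results, ax=None, bins: int = 40):
    """Brightness histograms per condition with the fitted lognormal density."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    data = results.model.data
    hi = float(data["brightness"].quantile(0.995))
    grid = np.linspace(1e-6, hi, 400)
    for cond in results.model.conditions:
        vals = data.loc[data["condition"] == cond, "brightness"].to_numpy()
        ax.hist(vals, bins=bins, range=(0, hi), density=True, alpha=0.35, label=cond)
        fit = results.lognormal_fits[cond]
        if fit.sigma_log > 0:
            pdf = (
                1.0
                / (grid * fit.sigma_log * math.sqrt(2 * math.pi))
                * np.exp(-((np.log(grid) - fit.mu_log) ** 2) / (2 * fit.sigma_log**2))
            )
            ax.plot(grid, pdf, lw=1.5)
    ax.axvline(results.dark_threshold_counts, color="k", ls="--", lw=1, label="dark threshold")
    ax.set_xlabel("telomere brightness (photon counts)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    return ax
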