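"""Diagnostic and presentation figures (matplotlib, non-interactive)."""

from __future__ import annotations

import numpy as np

HABITAT_COLOURS = {
    "forest": "#1b5e20",
    "woodland": "#66bb6a",
    "open": "#c0a040",
    "aquatic": "#1565c0",
    "human-modified": "#212121",
}


def buffer_r2_profile(model_table, ax=None):
    """Partial R² against buffer radius, one line per metric × predictor."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (metric, predictor), sub in model_table.groupby(["metric", "predictor"]):
        sub = sub.sort_values("buffer_m")
        style = "-" if predictor == "mean_ndvi" else "--"
        ax.plot(sub["buffer_m"], sub["partial_r2"], style, marker="o", label=f"{metric} / {predictor}")
    ax.set_xscale("log")
    ax.set_xlabel("buffer radius (m)")
    ax.set_ylabel("partial $R^2$ of the vegetation term")
    ax.legend(fontsize=7)
    return ax


def ordination_plot(result, habitat_map=None, env_vectors=None, ax=None):
    """Site and species scores, species coloured by habitat preference."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(result.scores[:, 0], result.scores[:, 1], s=12, c="grey", alpha=0.6, label="sites")
    if result.species_scores is not None:
        for name, row in result.species_scores.iterrows():
            colour = HABITAT_COLOURS.get((habitat_map or {}).get(name, ""), "#7b1fa2")
            ax.text(row.iloc[0], row.iloc[1], str(name), fontsize=6, color=colour)
    if env_vectors is not None:
        scale = 0.9 * np.abs(result.scores).max()
        for name, row in env_vectors.iterrows():
            ax.annotate(
                name,
                xy=(row["dir1"] * row["r2"] * scale, row["dir2"] * row["r2"] * scale),
                xytext=(0, 0),
                arrowprops={"arrowstyle": "<-", "color": "firebrick"},
                color="firebrick",
                fontsize=8,
            )
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.set_title(f"stress = {result.stress:.3f}")
    return ax


def predicted_vs_observed(obs, pred, sma=None, ax=None, label=""):
    """Scatter of predictions against held-out observations with the SMA
    line and the 1:1 reference."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    ax.scatter(obs, pred, s=18)
    lims = [min(obs.min(), pred.min()), max(obs.max(), pred.max())]
    ax.plot(lims, lims, "k--", lw=0.8, label="1:1")
    if sma is not None:
        xs = np.linspace(lims[0], lims[1], 50)
        ax.plot(xs, sma["intercept"] + sma["slope"] * xs, "r-", lw=1.2,
                label=f"SMA slope {sma['slope']:.2f}")
    ax.set_xlabel(f"observed {label}")
    ax.set_ylabel(f"predicted {label}")
    ax.legend(fontsize=8)
    return ax
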