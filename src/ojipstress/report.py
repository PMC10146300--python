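"""Figure export: transient overlays, radar (spider) plots, assay bars.

Plot conventions follow the field's temperature-stress reports: low
temperature in blue, the control temperature in black, high temperature
in red; transients on a log10 time axis; JIP parameters on a radar plot
normalized to the control mean; assay bars annotated with significance
stars.  All numerical analysis happens on tables — figures are export
side-effects only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

TREATMENT_COLORS = {"LT": "tab:blue", "MT": "black", "HT": "tab:red"}


def _color(treatment: str) -> str:
    return TREATMENT_COLORS.get(treatment, "tab:gray")


def plot_transients(transients_df: pd.DataFrame, path) -> None:
    """Per-strain overlay of replicate-mean induction curves on log time."""
    strains = sorted(transients_df["strain"].unique())
    fig, axes = plt.subplots(1, len(strains), figsize=(5.2 * len(strains), 4.0), squeeze=False)
    for ax, strain in zip(axes[0], strains):
        sub = transients_df[transients_df["strain"] == strain]
        for treatment in sorted(sub["treatment"].unique()):
            grp = sub[sub["treatment"] == treatment]
            mean = grp.groupby("time_s")["fluorescence"].mean()
            ax.plot(mean.index, mean.values, color=_color(treatment), label=treatment)
        ax.set_xscale("log")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("fluorescence (a.u.)")
        ax.set_title(strain)
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_radar(spider_table: pd.DataFrame, path) -> None:
    """Radar plot of control-normalized JIP parameters, one panel per strain.

    ``spider_table`` is the parameter x condition table from
    ``spider_normalize`` with columns named ``strain-treatment``.
    """
    params = list(spider_table.index)
    angles = np.linspace(0, 2 * np.pi, len(params), endpoint=False)
    strains = sorted({c.rsplit("-", 1)[0] for c in spider_table.columns})
    fig, axes = plt.subplots(
        1, len(strains), figsize=(5.2 * len(strains), 4.6),
        subplot_kw={"projection": "polar"}, squeeze=False,
    )
    for ax, strain in zip(axes[0], strains):
        for col in spider_table.columns:
            s, treatment = col.rsplit("-", 1)
            if s != strain:
                continue
            vals = spider_table[col].to_numpy()
            closed = np.append(vals, vals[0])
            ax.plot(np.append(angles, angles[0]), closed, color=_color(treatment), label=treatment)
        ax.set_xticks(angles)
        ax.set_xticklabels(params, fontsize=7)
        ax.set_title(strain)
        ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_comparison_bars(comparisons: pd.DataFrame, parameters: list[str], path) -> None:
    """Grouped mean +- SD bars with significance stars for chosen parameters."""
    fig, axes = plt.subplots(
        1, len(parameters), figsize=(4.2 * len(parameters), 3.8), squeeze=False
    )
    for ax, parameter in zip(axes[0], parameters):
        sub = comparisons[comparisons["parameter"] == parameter]
        labels, means, sds, stars, colors = [], [], [], [], []
        for strain in sorted(sub["strain"].unique()):
            rows = sub[sub["strain"] == strain]
            first = rows.iloc[0]
            labels.append(f"{strain}\n{first['control_label']}")
            means.append(first["control_mean"])
            sds.append(first["control_sd"])
            stars.append("")
            colors.append(_color(first["control_label"]))
            for _, r in rows.iterrows():
                labels.append(f"{strain}\n{r['treatment_label']}")
                means.append(r["treatment_mean"])
                sds.append(r["treatment_sd"])
                stars.append("" if r["significance"] == "ns" else r["significance"])
                colors.append(_color(r["treatment_label"]))
        x = np.arange(len(labels))
        ax.bar(x, means, yerr=sds, color=colors, capsize=3)
        for xi, m, sd, star in zip(x, means, sds, stars):
            if star:
                ax.text(xi, m + sd, star, ha="center", va="bottom")
        ax.set_xticks(x)
        ax.set_xticklabels(labels, fontsize=7)
        ax.set_title(parameter)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
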