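#!/usr/bin/env python
"""Treatment-vs-control statistics across JIP, NPQ and assay readouts.

Builds the comparison table (mean +- SD, percent change, fold change,
Welch p, significance stars) for every strain x treatment x parameter,
and prints the headline contrasts: the PI_abs and Fv/Fm declines, the
NPQ fold changes and the oxidative-stress increases.
"""

from pathlib import Path

import pandas as pd

from ojipstress.assays import format_percent, read_assays
from ojipstress.compare import compare_conditions, melt_parameters
from ojipstress.quenching import fold_change, format_fold, read_quenching

JIP = Path("results/jip_parameters.csv")
QUENCH = Path("results/synthetic/quenching.csv")
ASSAY = Path("results/synthetic/assays.csv")
OUT = Path("results/comparisons.csv")


def main() -> None:
    long = melt_parameters(pd.read_csv(JIP), read_quenching(QUENCH), read_assays(ASSAY))
    comparisons = compare_conditions(long, "MT")
    comparisons.to_csv(OUT, index=False)
    print(f"{len(comparisons)} comparisons -> {OUT}\n")

    idx = comparisons.set_index(["strain", "treatment_label", "parameter"])
    for strain, treatment, parameter in [
        ("GM", "HT", "PI_abs"), ("WT", "HT", "PI_abs"),
        ("GM", "LT", "PI_abs"), ("WT", "LT", "PI_abs"),
        ("GM", "LT", "FvFm"), ("WT", "LT", "FvFm"),
        ("GM", "HT", "OFR"), ("WT", "HT", "OFR"),
        ("GM", "HT", "MDA"), ("WT", "HT", "MDA"),
    ]:
        row = idx.loc[(strain, treatment, parameter)]
        direction = "decreased" if row["percent_change"] < 0 else "increased"
        print(
            f"{parameter:>7} {strain} {treatment} vs MT: {direction} by "
            f"{abs(format_percent(row['percent_change']))}% "
            f"(p = {row['p_value']:.2g} {row['significance']})"
        )

    npq = idx.xs("NPQ", level="parameter")
    for strain in ("GM", "WT"):
        row = npq.loc[(strain, "HT")]
        print(
            f"    NPQ {strain}: {row['control_mean']:.2f} -> {row['treatment_mean']:.2f} "
            f"under heat ({format_fold(row['fold_change'])}-fold)"
        )
    wt_vs_gm = fold_change(npq.loc[("GM", "HT"), "treatment_mean"],
                           npq.loc[("WT", "HT"), "treatment_mean"])
    print(f"    wild-type HT NPQ is {format_fold(wt_vs_gm)}-fold the mutant's")


if __name__ == "__main__":
    main()
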