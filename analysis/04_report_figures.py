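#!/usr/bin/env python
"""Export the figures: transient overlays, control-normalized radar
plots of the JIP parameters, and mean +- SD bars with significance stars
for the headline readouts."""

from pathlib import Path

import pandas as pd

from ojipstress.jip_test import spider_normalize
from ojipstress.report import plot_comparison_bars, plot_radar, plot_transients

RESULTS = Path("results")
FIGS = RESULTS / "figures"


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    jip = pd.read_csv(RESULTS / "jip_parameters.csv")
    spider = spider_normalize(jip, "MT")
    spider.to_csv(RESULTS / "spider_normalized.csv")
    plot_radar(spider, FIGS / "radar.png")
    plot_transients(pd.read_csv(RESULTS / "synthetic" / "transients.csv"),
                    FIGS / "transients.png")
    comparisons = pd.read_csv(RESULTS / "comparisons.csv")
    plot_comparison_bars(comparisons, ["PI_abs", "FvFm", "NPQ", "OFR", "MDA"],
                         FIGS / "comparison_bars.png")
    print(f"wrote {RESULTS/'spider_normalized.csv'} and 3 figures -> {FIGS}/")


if __name__ == "__main__":
    main()
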