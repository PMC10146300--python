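#!/usr/bin/env python
"""Simulate the two-strain x three-temperature study design.

Generates the synthetic dataset the rest of the analysis consumes: OJIP
transients, dark/light quenching pairs and oxidative-stress assay values
for the green mutant (GM) and wild type (WT) at 8 C (LT), 20 C (MT,
control) and 30 C (HT), three replicate cultures per condition, from the
packaged study-calibrated presets.
"""

from pathlib import Path

from ojipstress.config import PipelineConfig
from ojipstress.synthetic_data import generate_dataset

OUT = Path("results/synthetic")


def main() -> None:
    cfg = PipelineConfig(out_dir=str(OUT))
    OUT.mkdir(parents=True, exist_ok=True)
    transients, quenching, assays = generate_dataset(cfg.presets(), cfg.n_replicates, cfg.seed)
    transients.to_csv(OUT / "transients.csv", index=False)
    quenching.to_csv(OUT / "quenching.csv", index=False)
    assays.to_csv(OUT / "assays.csv", index=False)
    print(
        f"simulated {transients['sample_id'].nunique()} transients "
        f"({len(transients)} rows), {len(quenching)} quenching pairs and "
        f"{len(assays)} assay rows (seed {cfg.seed}) -> {OUT}/"
    )


if __name__ == "__main__":
    main()
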