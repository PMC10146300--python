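# ojipstress

Analysis pipeline for temperature-stress phenotyping of photosynthetic
organisms from fast chlorophyll *a* fluorescence: JIP-test parameter
derivation from OJIP induction transients, non-photochemical quenching
(NPQ), oxidative-stress assay comparisons, and treatment-versus-control
statistics. The motivating system is a two-strain comparison of the red
seaweed *Gracilariopsis lemaneiformis* — a green-pigmented mutant (GM)
versus the wild type (WT) — cultured at 8 °C (LT), 20 °C (MT, control)
and 30 °C (HT), but every stage is generic over strains and treatment
labels.

The package is written for plant/algal stress physiologists who have
induction traces and kit assay readouts and want the standard derived
parameters, the control-relative contrasts, and publication-style
tables and figures — plus a calibrated synthetic-data generator so the
whole pipeline is testable without instrument data.

## The science in brief

A dark-adapted sample exposed to saturating light shows a polyphasic
fluorescence rise through the steps O (20 µs), K (300 µs), J (2 ms),
I (30 ms) and P (the peak, F_m). From the five marker intensities the
JIP test derives, in closed form, the energy-cascade quantities of PSII:

- relative variable fluorescence `V_X = (F_X − F_O)/(F_m − F_O)` for
  X ∈ {K, J, I}, and the OEC-damage indicator
  `W_K = (F_K − F_O)/(F_J − F_O)`;
- the initial slope `M_o = 4(F_K − F_O)/(F_m − F_O)`;
- quantum yields `φ_Po = F_V/F_m = 1 − F_O/F_m`, `Ψ_o = 1 − V_J`,
  `φ_Eo = φ_Po Ψ_o`, `φ_Ro = φ_Po (1 − V_I)`;
- specific fluxes per active reaction centre `TR_o/RC = M_o/V_J`,
  `ABS/RC = (M_o/V_J)/φ_Po`, `ET_o/RC = (M_o/V_J)(1 − V_J)`,
  `DI_o/RC = ABS/RC − TR_o/RC`, and `RC/CS_o = φ_Po (V_J/M_o) · ABS/CS`
  with the standard approximation ABS/CS ≈ F_O;
- the performance index
  `PI_abs = (RC/ABS) · [φ_Po/(1 − φ_Po)] · [Ψ_o/(1 − Ψ_o)]`.

NPQ is computed in the Stern–Volmer form `(F_m − F_m′)/F_m′`. Assay
readouts (OFR, MDA, SOD, POD, CAT) are compared as percent changes of
condition means, and every strain × treatment × parameter contrast gets
a two-sided Welch *t*-test with the usual `*` (p < 0.05) / `**`
(p < 0.01) starring.

The synthetic generator works backwards from JIP targets: given
(φ_Po, PI_abs, W_K, V_I) it solves
`Ψ_o/(1 − Ψ_o) = 4 W_K PI_abs (1 − φ_Po)/φ_Po²` for V_J, places the
five markers, threads a monotone PCHIP interpolant through them in
(log₁₀ t, F), and adds lognormal replicate scatter plus multiplicative
point noise. The packaged presets encode the observed effect sizes of
the motivating study (e.g. PI_abs −16 % in GM vs −37 % in WT under
heat).

## Worked example

The numbered scripts under `analysis/` run the whole study on the
packaged presets (3 replicates per condition, seed 7):

```sh
python analysis/01_simulate.py
python analysis/02_jip_parameters.py
python analysis/03_compare_conditions.py
python analysis/04_report_figures.py
```

which prints, among other lines:

```
simulated 18 transients (2160 rows), 18 quenching pairs and 90 assay rows (seed 7) -> results/synthetic/
JIP parameters for 18/18 samples -> results/jip_parameters.csv
control-condition means: Fv/Fm = 0.606, PI_abs = 0.585
 PI_abs GM HT vs MT: decreased by 18% (p = 0.041 *)
 PI_abs WT HT vs MT: decreased by 44% (p = 0.0063 **)
   FvFm GM LT vs MT: decreased by 20% (p = 0.00054 **)
    NPQ GM: 0.21 -> 0.56 under heat (2.7-fold)
    NPQ WT: 0.40 -> 0.78 under heat (1.9-fold)
```

Read: at three replicates the mutant's performance index drops mildly
under heat (−18 %, just significant) while the wild type's collapses
(−44 %, p < 0.01); cold lowers the mutant's F_V/F_m by 20 %; heat
trebles the mutant's NPQ. These are noisy three-replicate estimates of
the programmed effects (−16 %, −37 %, −22 %, 3.0-fold); at 50
replicates the pipeline recovers each to within ±2 percentage points.
The same pipeline is available as a console tool
(`ojipstress simulate|jip|compare|report`) for external tables in the
documented tidy formats.

Outputs land under `results/`: per-sample `jip_parameters.csv`, the
`comparisons.csv` statistics table, the control-normalized
`spider_normalized.csv`, and figures (transient overlay, radar plot,
bar charts with stars).

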