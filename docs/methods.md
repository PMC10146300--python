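# Methods

## Scope and model

The pipeline treats fast chlorophyll-fluorescence stress phenotyping as
a chain of small, closed-form computations over tidy tables:

1. **Markers.** An OJIP transient is a strictly positive trace on a
   log-spaced time grid covering 20 µs – 1 s. The five canonical
   markers are read at fixed protocol times — F_O at 20 µs, F_K at
   300 µs, F_J at 2 ms, F_I at 30 ms — and F_m is the maximum of the
   trace. Marker times are protocol constants, not configuration: the
   K/J/I steps are defined by PSII electron-transport kinetics, not by
   the instrument.
2. **JIP parameters.** All derived quantities are algebraic in the five
   markers (see README for the formula set). Two conventions deserve
   mention because published formula tables sometimes garble them:
   ABS/RC is computed as (M_o/V_J)/φ_Po — the form consistent with
   φ_Po = TR_o/ABS and with DI_o/RC = ABS/RC − TR_o/RC ≥ 0 — and
   RC/CS_o uses the common approximation ABS/CS ≈ F_O, since no
   instrument cross-section calibration is modelled. All parameters are
   emitted dimensionless except RC/CS_o, which inherits the
   fluorescence unit.
3. **NPQ.** Stern–Volmer, (F_m − F_m′)/F_m′. Induction/relaxation
   kinetics (qP, qL, Y(NO), …) are out of scope.
4. **Statistics.** Group summaries are mean ± sample SD (n − 1).
   Treatment-vs-control contrasts use a two-sided Welch
   unequal-variance *t*-test per comparison, with Welch–Satterthwaite
   degrees of freedom. Welch is chosen over Student because replicate
   groups of three give no power to verify equal variances. No
   multiple-testing correction is applied — this mirrors the
   per-comparison starring convention of the field and is a known
   limitation: with ~21 parameters per contrast, a few stars per table
   are expected under the null.

## Marker extraction details

Instrument grids are log-spaced, so marker lookup interpolates linearly
in (log₁₀ t, F) between the bracketing samples; this makes extraction
exactly invariant under inserting redundant collinear (in log-time)
samples into a monotone trace.

Before lookup the trace is projected onto its least-squares
nondecreasing envelope (isotonic regression over log-time). The
rationale: the OJIP rise is monotone by physics, and the raw trace
maximum is a badly biased estimator of F_m under multiplicative point
noise — with a coefficient of variation of 2 % and ~25 samples per
decade, the maximum over the ~10 near-plateau points overshoots the
plateau by 2.4–3.1 %, and the bias is condition-dependent (flatter
plateaus bias more), which systematically distorts PI_abs contrasts
between conditions. Isotonic projection is the mildest monotone
denoiser: it is the identity on any already-monotone trace (so all
noise-free behaviour is exact to machine precision), requires no
bandwidth choice, and pools exactly the plateau samples that the raw
maximum over-reads. F_m is then the maximum of the projected trace,
which still allows a genuine pre-1 s peak; if that maximum is reached
before 100 ms a warning flags the trace as suspicious.

Degenerate inputs (constant trace, F_J ≤ F_O, φ_Po ∉ (0,1)) raise typed
errors rather than emitting NaN; batch stages catch them per sample,
log the sample id, and continue.

## Synthetic data

The generator encodes *outcomes*, not mechanisms — no PSII kinetic
model is solved. Each strain × treatment condition is specified by
JIP-level targets and inverted in closed form to marker space
(`solve_preset`); a monotone shape-preserving PCHIP interpolant through
the markers in (log₁₀ t, F) provides the curve, with the protocol
marker times embedded exactly in the 120-point log-spaced grid.

Noise has two components, both multiplicative because fluorescence is
positive and instrument noise scales roughly with signal: one lognormal
per-replicate factor (default SD 0.05 on the log scale) modelling
culture-to-culture brightness variation, and i.i.d. Gaussian point
noise (default CV 0.02). Assay values are lognormal around the preset
mean with the mean-preserving parameterization (so ensemble means are
unbiased); quenching pairs share the replicate factor between F_m and
F_m′, so the programmed NPQ survives replicate scatter. All random
streams are keyed on (seed, strain, treatment, replicate), making
datasets reproducible and order-independent.

The packaged presets anchor the control condition at φ_Po = 0.60,
PI_abs = 0.55, W_K = 0.50, V_I = 0.80, F_m = 1250 (absolute levels are
implementer-chosen; only relative changes are meaningful) and apply
per-condition multipliers reproducing the motivating study's printed
effects: PI_abs ×0.84 (GM-HT), ×0.63 (WT-HT), ×0.60 with φ_Po ×0.78
(GM-LT), ×0.76 with φ_Po ×0.86 (WT-LT), F_m ×0.8 under cold; NPQ means
0.19/0.57 (GM, MT/HT) and 0.42/0.73 (WT); OFR ×1.21/×1.62 and MDA
×1.29/×1.80 (GM/WT) under heat, MDA ×1.28/×1.80 under cold. Values the
study reports only directionally (cold NPQ, cold OFR for GM, all
SOD/POD/CAT magnitudes) are marked qualitative in the preset file and
excluded from quantitative validation.

What passing tests show — and what they do not: recovery of programmed
percent changes demonstrates that the measurement chain (simulation →
marker extraction → JIP derivation → ensemble contrast) is unbiased to
within ~1 percentage point under the modelled noise. Real instrument
data additionally contain baseline drift, detector saturation near P,
actinic-intensity miscalibration and genuinely non-monotone artefacts
(e.g. the dip after P), none of which the generator emulates; the
pipeline's robustness to those is untested by design.

## Numerical choices

- Marker-time coverage and container invariants use a 10⁻⁹ relative
  tolerance; JIP identities hold to 10⁻¹² in tests.
- `solve_preset` rejects solutions with V_J outside
  [10⁻⁶, 1 − 10⁻⁶]: beyond that the J-step sinks below any realistic
  noise floor and the marker set is numerically degenerate. It also
  rejects V_I < V_J and W_K > 1 (non-monotone markers).
- When both variances in a Welch test are zero the limit is reported
  (p = 1 for equal means, p = 0 otherwise) instead of NaN.
- Report rounding is half-up (fold changes to one decimal, percents to
  integers) to match how such values are quoted; raw ratios are always
  kept in the tables.
- Generated traces are floored at 10⁻³ × F_O to keep the positivity
  invariant under extreme noise draws.
- CSV numerics are parsed with Python's round-trip `float`, not the
  fast approximate parser, so write→read cycles are bit-identical.

## Problem sizes

The analysis scripts use the study's own design (3 replicates per
condition). Validation of the programmed effect sizes uses 50
replicates per condition — enough to pin ensemble percent changes to
±2 percentage points under the default noise — and the algebraic
identity suites use 10⁴ random marker sets and 10³ random target sets.

## Known limitations

- ABS/CS ≈ F_O is an approximation; studies with instrument-provided
  cross-sections will get different RC/CS_o absolute values (ratios to
  control are unaffected).
- The spider table normalizes each strain to its own control mean;
  cross-strain absolute comparisons should use the raw parameter table.
- No ANOVA/post-hoc family is offered; with more than two treatments
  per strain the per-pair Welch tests are not jointly calibrated.
- The NPQ measurement protocol (actinic intensity, duration) is not
  modelled; presets target NPQ values directly.
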