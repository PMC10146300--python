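# Packaged simulation presets for the two-strain (green mutant GM, wild
# type WT) x three-temperature (LT 8 C, MT 20 C control, HT 30 C) design.
#
# The baseline (MT) marker space is an implementer-chosen anchor — no
# absolute fluorescence values are published for this system — while the
# per-condition multipliers encode the study's reported relative effects:
# PI_abs -16% (GM-HT), -37% (WT-HT), -40% (GM-LT), -24% (WT-LT);
# Fv/Fm -22% (GM-LT), -14% (WT-LT); NPQ 0.19 -> 0.57 (GM) and
# 0.42 -> 0.73 (WT) under heat; OFR +21%/+62% and MDA +29%/+80% (GM/WT)
# under heat, MDA +28%/+80% under cold.
#
# Entries marked "qualitative" have no published magnitude (only a
# direction); their values are plausible placeholders and are excluded
# from any quantitative validation.

baseline:
  phi_po: 0.60      # Fv/Fm at the control temperature
  pi_abs: 0.55      # performance index on absorption basis
  w_k: 0.50         # OEC-damage indicator
  v_i: 0.80         # relative variable fluorescence at the I step
  f_m: 1250.0       # absolute anchor; F_O follows as F_m * (1 - phi_po)

noise:
  noise_cv: 0.02        # multiplicative point noise, coefficient of variation
  replicate_sd: 0.05    # SD of the per-replicate lognormal scale factor
  n_timepoints: 120     # log-spaced acquisition grid, 20 us .. 1 s

conditions:
  GM:
    MT:
      npq: 0.19
      assays: {OFR: 1.0, MDA: 1.0, SOD: 1.0, POD: 1.0, CAT: 1.0}
    HT:
      pi_abs_x: 0.84
      w_k_x: 0.95
      npq: 0.57
      assays: {OFR: 1.21, MDA: 1.29, SOD: 1.5, POD: 1.5, CAT: 1.5}  # SOD/POD/CAT qualitative
    LT:
      phi_po_x: 0.78
      pi_abs_x: 0.60
      w_k_x: 0.95
      f_m_x: 0.8
      npq: 0.10   # qualitative: cold lowers NPQ in both strains
      assays: {OFR: 1.02, MDA: 1.28, SOD: 1.1, POD: 1.0, CAT: 1.0}  # OFR/SOD/POD/CAT qualitative
  WT:
    MT:
      npq: 0.42
      assays: {OFR: 1.0, MDA: 1.0, SOD: 1.0, POD: 1.0, CAT: 1.0}
    HT:
      pi_abs_x: 0.63
      w_k_x: 1.10
      npq: 0.73
      assays: {OFR: 1.62, MDA: 1.80, SOD: 1.2, POD: 1.2, CAT: 1.2}  # SOD/POD/CAT qualitative
    LT:
      phi_po_x: 0.86
      pi_abs_x: 0.76
      w_k_x: 1.10
      f_m_x: 0.8
      npq: 0.20   # qualitative
      assays: {OFR: 1.30, MDA: 1.80, SOD: 1.05, POD: 1.0, CAT: 1.0}  # OFR/SOD/POD/CAT qualitative
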