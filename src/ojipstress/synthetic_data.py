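"""Synthetic OJIP transients, quenching pairs and assay values.

The generator emulates the study design — two strains x three
temperatures x replicate cultures — by working backwards from JIP-test
targets to fluorescence marker space:

1. :func:`solve_preset` inverts the performance-index identity
   ``PI_abs = [phi_Po/(4 W_K)] [phi_Po/(1-phi_Po)] [Psi_o/(1-Psi_o)]``
   to find the electron-transport odds, hence V_J, and places the five
   markers so that a round-trip through the JIP computation reproduces
   the requested (phi_Po, PI_abs, W_K, V_I) exactly.
2. :func:`generate_transient` threads a monotone shape-preserving (PCHIP)
   interpolant through the five marker knots in (log10 t, F) over a
   log-spaced grid, then applies one lognormal per-replicate scale factor
   (culture-to-culture variation) and i.i.d. multiplicative Gaussian
   point noise (instrument noise, roughly proportional to signal).
3. :func:`generate_dataset` emits tidy transient / quenching / assay
   tables for a preset collection.  Quenching pairs are built from the
   condition F_m and the preset NPQ mean; assay values are lognormal
   around the preset analyte means (mean-preserving parameterization).

Randomness is keyed on (seed, strain, treatment, replicate) so datasets
are reproducible and independent of generation order.  The marker times
are embedded exactly in the generated time grid, so with noise switched
off marker extraction recovers the preset markers to machine precision.

No PSII electron-transport kinetics are modelled: presets encode observed
outcomes, not mechanisms.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InfeasibleTargetsError
from .jip_test import compute_jip
from .quenching import QUENCHING_COLUMNS, QuenchingPair, compute_npq
from .assays import ANALYTES, ASSAY_COLUMNS
from .transients import MARKER_TIMES, T_MAX, T_MIN, FluorescenceTransient, MarkerSet

__all__ = [
    "PresetTargets",
    "GeneratorPreset",
    "solve_preset",
    "time_grid",
    "generate_transient",
    "generate_quenching_pair",
    "generate_assays",
    "generate_dataset",
    "load_presets",
    "default_presets",
]


@dataclass(frozen=True)
class PresetTargets:
    """JIP-parameter targets defining one condition's marker space.

    Exactly one of ``f_o`` / ``f_m`` anchors the absolute fluorescence
    scale; the other follows from ``phi_po``.  If both are given the F_O
    anchor wins and F_m is rescaled to F_O / (1 - phi_Po).
    """

    phi_po: float  # target Fv/Fm, in (0, 1)
    pi_abs: float  # target performance index, > 0
    w_k: float  # target OEC-damage indicator, in (0, 1]
    v_i: float  # target I-step relative variable fluorescence, in (0, 1)
    f_o: float | None = None
    f_m: float | None = None

    def __post_init__(self):
        if not 0 < self.phi_po < 1:
            raise InfeasibleTargetsError(f"phi_Po must lie in (0, 1), got {self.phi_po}")
        if not self.pi_abs > 0:
            raise InfeasibleTargetsError(f"PI_abs must be positive, got {self.pi_abs}")
        if not 0 < self.w_k:
            raise InfeasibleTargetsError(f"W_K must be positive, got {self.w_k}")
        if not 0 < self.v_i < 1:
            raise InfeasibleTargetsError(f"V_I must lie in (0, 1), got {self.v_i}")
        if self.f_o is None and self.f_m is None:
            raise InfeasibleTargetsError("one of f_o or f_m must anchor the fluorescence scale")
        for name in ("f_o", "f_m"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InfeasibleTargetsError(f"{name} must be positive, got {v}")


def solve_preset(t: PresetTargets) -> MarkerSet:
    """Closed-form inversion from JIP targets to the five markers.

    Solves ``Psi_o/(1 - Psi_o) = 4 W_K PI_abs (1 - phi_Po) / phi_Po^2``
    for the electron-transport efficiency, sets ``V_J = 1 - Psi_o`` and
    places ``F_K = F_O + W_K V_J (F_m - F_O)``, ``F_J = F_O + V_J (F_m -
    F_O)``, ``F_I = F_O + V_I (F_m - F_O)``.  A round-trip through
    :func:`~ojipstress.jip_test.compute_jip` reproduces the targets.

    Raises :class:`InfeasibleTargetsError` when the solved V_J leaves
    (0, 1) or the markers would not rise monotonically (V_I < V_J).
    """
    odds = 4.0 * t.w_k * t.pi_abs * (1.0 - t.phi_po) / (t.phi_po**2)
    psi_o = odds / (1.0 + odds)
    v_j = 1.0 - psi_o
    # 1e-6 floor: below it F_J - F_O (or F_m - F_J) sinks under any
    # realistic noise floor and the markers are numerically degenerate
    if not 1e-6 < v_j < 1.0 - 1e-6:
        raise InfeasibleTargetsError(
            f"targets (phi_Po={t.phi_po}, PI_abs={t.pi_abs}, W_K={t.w_k}) "
            f"solve to V_J={v_j:g} outside (0, 1)"
        )
    if t.v_i < v_j:
        raise InfeasibleTargetsError(
            f"target V_I={t.v_i:g} below solved V_J={v_j:g}: markers would not rise"
        )
    if t.w_k > 1.0:
        raise InfeasibleTargetsError(f"W_K={t.w_k:g} > 1 would place F_K above F_J")
    if t.f_o is not None:
        f_o = t.f_o
        f_m = f_o / (1.0 - t.phi_po)
    else:
        f_m = t.f_m
        f_o = f_m * (1.0 - t.phi_po)
    fv = f_m - f_o
    return MarkerSet(
        f_o=f_o,
        f_k=f_o + t.w_k * v_j * fv,
        f_j=f_o + v_j * fv,
        f_i=f_o + t.v_i * fv,
        f_m=f_m,
    )


@dataclass(frozen=True)
class GeneratorPreset:
    """Marker-space plus noise description of one strain x treatment."""

    strain: str
    treatment: str
    markers: MarkerSet
    npq_mean: float = 0.0
    assay_means: dict = field(default_factory=dict)
    noise_cv: float = 0.02  # multiplicative point noise CV
    replicate_sd: float = 0.05  # SD of the lognormal per-replicate factor
    n_timepoints: int = 120

    def __post_init__(self):
        if not self.markers.is_monotone():
            raise ConfigurationError(
                f"{self.strain}-{self.treatment}: preset markers must rise monotonically"
            )
        if self.noise_cv < 0 or self.replicate_sd < 0:
            raise ConfigurationError("noise_cv and replicate_sd must be nonnegative")
        if self.npq_mean < 0:
            raise ConfigurationError("npq_mean must be nonnegative")
        if self.n_timepoints < 16:
            raise ConfigurationError("n_timepoints must be at least 16")
        for analyte in self.assay_means:
            if analyte not in ANALYTES:
                raise ConfigurationError(f"unknown analyte {analyte!r} in preset assay means")


def _stream(seed: int, strain: str, treatment: str, replicate: int, channel: str):
    """Independent RNG keyed on the full sample identity."""
    key = [
        int(seed),
        zlib.crc32(strain.encode()),
        zlib.crc32(treatment.encode()),
        int(replicate),
        zlib.crc32(channel.encode()),
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def time_grid(n: int = 120) -> np.ndarray:
    """Log-spaced acquisition grid on [20 us, 1 s] with the protocol marker
    times embedded exactly (nearest grid points are snapped onto them)."""
    g = np.geomspace(T_MIN, T_MAX, n)
    logg = np.log10(g)
    for tm in sorted(MARKER_TIMES.values()):
        if tm in (T_MIN, T_MAX):
            continue
        g[int(np.argmin(np.abs(logg - np.log10(tm))))] = tm
    g = np.sort(g)
    if np.any(np.diff(g) <= 0):
        raise ConfigurationError(f"time grid of {n} points collapses marker times together")
    return g


def _marker_curve(markers: MarkerSet, times: np.ndarray) -> np.ndarray:
    from scipy.interpolate import PchipInterpolator

    knot_t = np.log10([T_MIN, *sorted(MARKER_TIMES.values())[1:], T_MAX])
    knot_f = np.asarray(markers.as_tuple())
    curve = PchipInterpolator(knot_t, knot_f)(np.log10(times))
    # PCHIP through monotone knots is monotone; pin the knots exactly
    for tm, f in zip(10.0**knot_t, knot_f):
        curve[np.argmin(np.abs(times - tm))] = f
    return curve


def generate_transient(
    p: GeneratorPreset, seed: int, replicate: int
) -> FluorescenceTransient:
    """One simulated induction trace, deterministic in (seed, strain,
    treatment, replicate)."""
    times = time_grid(p.n_timepoints)
    clean = _marker_curve(p.markers, times)
    rng = _stream(seed, p.strain, p.treatment, replicate, "transient")
    scale = float(np.exp(rng.normal(0.0, p.replicate_sd))) if p.replicate_sd > 0 else 1.0
    values = clean * scale
    if p.noise_cv > 0:
        values = values * (1.0 + p.noise_cv * rng.standard_normal(values.size))
    values = np.maximum(values, 1e-3 * p.markers.f_o * scale)
    return FluorescenceTransient(
        sample_id=f"{p.strain}-{p.treatment}-r{replicate}",
        strain=p.strain,
        treatment=p.treatment,
        replicate=replicate,
        times=times,
        values=values,
    )


def generate_quenching_pair(p: GeneratorPreset, seed: int, replicate: int) -> QuenchingPair:
    """Dark/light F_m pair whose expected NPQ equals the preset mean.

    The per-replicate lognormal factor is shared by both members of the
    pair (it models culture brightness), so NPQ noise comes only from the
    independent point noise on each reading.
    """
    rng = _stream(seed, p.strain, p.treatment, replicate, "quenching")
    scale = float(np.exp(rng.normal(0.0, p.replicate_sd))) if p.replicate_sd > 0 else 1.0
    fm_dark = p.markers.f_m * scale
    fm_light = fm_dark / (1.0 + p.npq_mean)
    if p.noise_cv > 0:
        fm_dark *= 1.0 + p.noise_cv * float(rng.standard_normal())
        fm_light *= 1.0 + p.noise_cv * float(rng.standard_normal())
    return QuenchingPair(
        sample_id=f"{p.strain}-{p.treatment}-r{replicate}",
        strain=p.strain,
        treatment=p.treatment,
        replicate=replicate,
        fm_dark=fm_dark,
        fm_light=fm_light,
    )


def generate_assays(p: GeneratorPreset, seed: int, replicate: int) -> list[dict]:
    """Lognormal assay readouts with ensemble mean equal to the preset mean
    (CV = noise_cv), one row per analyte."""
    rng = _stream(seed, p.strain, p.treatment, replicate, "assays")
    rows = []
    sigma = float(np.sqrt(np.log1p(p.noise_cv**2)))
    for analyte in ANALYTES:
        if analyte not in p.assay_means:
            continue
        mean = float(p.assay_means[analyte])
        value = mean if sigma == 0 else mean * float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        rows.append(
            {
                "sample_id": f"{p.strain}-{p.treatment}-r{replicate}",
                "strain": p.strain,
                "treatment": p.treatment,
                "replicate": replicate,
                "analyte": analyte,
                "value": value,
                "unit": "a.u.",
            }
        )
    return rows


def generate_dataset(
    presets: list[GeneratorPreset], n_replicates: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full synthetic study: tidy (transients, quenching, assays) tables.

    Returns the long transient table (one row per time point), the
    quenching table (with computed ``npq``) and the assay table.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be at least 1")
    seen = set()
    for p in presets:
        key = (p.strain, p.treatment)
        if key in seen:
            raise ConfigurationError(f"duplicate preset for strain/treatment {key}")
        seen.add(key)

    from .transients import transients_to_frame

    transients = []
    quench_rows = []
    assay_rows = []
    for p in presets:
        for r in range(1, n_replicates + 1):
            transients.append(generate_transient(p, seed, r))
            q = generate_quenching_pair(p, seed, r)
            quench_rows.append(
                {
                    "sample_id": q.sample_id,
                    "strain": q.strain,
                    "treatment": q.treatment,
                    "replicate": q.replicate,
                    "fm_dark": q.fm_dark,
                    "fm_light": q.fm_light,
                    "npq": compute_npq(q),
                }
            )
            assay_rows.extend(generate_assays(p, seed, r))
    trans_df = transients_to_frame(transients)
    quench_df = pd.DataFrame(quench_rows, columns=[*QUENCHING_COLUMNS, "npq"])
    assay_df = pd.DataFrame(assay_rows, columns=ASSAY_COLUMNS)
    return trans_df, quench_df, assay_df


def _build_presets(doc: dict) -> list[GeneratorPreset]:
    base = doc["baseline"]
    noise = doc.get("noise", {})
    presets = []
    for strain, treatments in doc["conditions"].items():
        for treatment, cond in treatments.items():
            cond = cond or {}
            targets = PresetTargets(
                phi_po=base["phi_po"] * cond.get("phi_po_x", 1.0),
                pi_abs=base["pi_abs"] * cond.get("pi_abs_x", 1.0),
                w_k=base["w_k"] * cond.get("w_k_x", 1.0),
                v_i=base["v_i"] * cond.get("v_i_x", 1.0),
                f_m=base["f_m"] * cond.get("f_m_x", 1.0),
            )
            presets.append(
                GeneratorPreset(
                    strain=str(strain),
                    treatment=str(treatment),
                    markers=solve_preset(targets),
                    npq_mean=float(cond.get("npq", 0.0)),
                    assay_means={k: float(v) for k, v in (cond.get("assays") or {}).items()},
                    noise_cv=float(noise.get("noise_cv", 0.02)),
                    replicate_sd=float(noise.get("replicate_sd", 0.05)),
                    n_timepoints=int(noise.get("n_timepoints", 120)),
                )
            )
    return presets


def load_presets(path) -> list[GeneratorPreset]:
    """Load a preset collection from a YAML condition file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "baseline" not in doc or "conditions" not in doc:
        raise ConfigurationError(f"{path}: preset file needs 'baseline' and 'conditions' maps")
    return _build_presets(doc)


def default_presets(
    noise_cv: float | None = None,
    replicate_sd: float | None = None,
    n_timepoints: int | None = None,
) -> list[GeneratorPreset]:
    """The packaged study-calibrated presets (optionally overriding noise)."""
    text = resources.files("ojipstress").joinpath("data/default_presets.yaml").read_text()
    presets = _build_presets(yaml.safe_load(text))
    overrides = {}
    if noise_cv is not None:
        overrides["noise_cv"] = noise_cv
    if replicate_sd is not None:
        overrides["replicate_sd"] = replicate_sd
    if n_timepoints is not None:
        overrides["n_timepoints"] = n_timepoints
    if overrides:
        presets = [replace(p, **overrides) for p in presets]
    return presets
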