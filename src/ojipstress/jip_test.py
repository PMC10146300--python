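"""JIP-test parameter derivation from OJIP fluorescence markers.

Given the five markers (F_O, F_K, F_J, F_I, F_m) of one transient, the
JIP test yields closed-form parameters describing PSII energy absorption,
trapping, electron transport and dissipation.  The conventions used here:

* relative variable fluorescence V_X = (F_X - F_O)/(F_m - F_O)
* W_K = (F_K - F_O)/(F_J - F_O), an indicator of oxygen-evolving-complex
  damage
* Mo = 4 (F_K - F_O)/(F_m - F_O), the approximated initial slope of the
  rise (nominal ms^-1; treated as dimensionless here)
* phi_Po = F_V/F_m = 1 - F_O/F_m, the maximum photochemical quantum
  yield; Psi_o = 1 - V_J; phi_Eo = phi_Po * Psi_o; phi_Ro = phi_Po (1 - V_I)
* specific fluxes per active reaction centre: TRo/RC = Mo/V_J,
  ABS/RC = (Mo/V_J)/phi_Po, ETo/RC = (Mo/V_J)(1 - V_J),
  DIo/RC = ABS/RC - TRo/RC
* RC/CSo = phi_Po (V_J/Mo) * ABS/CS with the standard approximation
  ABS/CS ~= F_O (so RC/CSo carries the fluorescence unit)
* PI_abs = (RC/ABS) * [phi_Po/(1-phi_Po)] * [Psi_o/(1-Psi_o)] with
  RC/ABS = phi_Po V_J / Mo

ABS/RC is implemented as (Mo/V_J)/phi_Po — the standard form satisfying
phi_Po = TRo/ABS and DIo/RC >= 0.  Degenerate markers raise a typed error
instead of silently propagating NaN, so batch runs can skip and report the
failing sample.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import DegenerateTransientError, NormalizationError, SampleError
from .transients import FluorescenceTransient, MarkerSet, extract_markers

__all__ = ["JIPResult", "PARAMETER_ORDER", "compute_jip", "batch_jip", "spider_normalize"]

#: Output/report order of the derived parameters.
PARAMETER_ORDER = [
    "V_J",
    "V_I",
    "V_K",
    "W_K",
    "Mo",
    "FvFm",
    "Phi_Eo",
    "Phi_Ro",
    "Psi_o",
    "ABS_RC",
    "ETo_RC",
    "TRo_RC",
    "DIo_RC",
    "RC_CSo",
    "PI_abs",
]


@dataclass(frozen=True)
class JIPResult:
    """All derived JIP-test parameters for one sample."""

    V_J: float
    V_I: float
    V_K: float
    W_K: float
    Mo: float
    FvFm: float  # = phi_Po
    Phi_Eo: float
    Phi_Ro: float
    Psi_o: float
    ABS_RC: float
    ETo_RC: float
    TRo_RC: float
    DIo_RC: float
    RC_CSo: float
    PI_abs: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_jip(m: MarkerSet) -> JIPResult:
    """Derive the full JIP-test parameter set from one marker set.

    Raises :class:`DegenerateTransientError` when F_m <= F_O, F_J <= F_O
    or the implied quantum yield phi_Po leaves (0, 1), i.e. whenever a
    denominator of the parameter formulas vanishes.
    """
    f_o, f_k, f_j, f_i, f_m = m.as_tuple()
    fv = f_m - f_o
    if fv <= 0:
        raise DegenerateTransientError(f"F_m={f_m:g} <= F_O={f_o:g}: no variable fluorescence")
    if f_j <= f_o:
        raise DegenerateTransientError(f"F_J={f_j:g} <= F_O={f_o:g}: V_J undefined")
    phi_po = 1.0 - f_o / f_m
    if not 0.0 < phi_po < 1.0:
        raise DegenerateTransientError(f"phi_Po={phi_po:g} outside (0, 1)")

    v_j = (f_j - f_o) / fv
    v_i = (f_i - f_o) / fv
    v_k = (f_k - f_o) / fv
    w_k = (f_k - f_o) / (f_j - f_o)
    mo = 4.0 * (f_k - f_o) / fv
    psi_o = 1.0 - v_j
    if v_j >= 1.0:
        raise DegenerateTransientError(f"V_J={v_j:g} >= 1: electron-transport odds undefined")
    tro_rc = mo / v_j
    abs_rc = tro_rc / phi_po
    eto_rc = tro_rc * psi_o
    dio_rc = abs_rc - tro_rc
    rc_cso = phi_po * (v_j / mo) * f_o  # ABS/CS approximated by F_O
    pi_abs = (phi_po * v_j / mo) * (phi_po / (1.0 - phi_po)) * (psi_o / (1.0 - psi_o))
    return JIPResult(
        V_J=v_j,
        V_I=v_i,
        V_K=v_k,
        W_K=w_k,
        Mo=mo,
        FvFm=phi_po,
        Phi_Eo=phi_po * psi_o,
        Phi_Ro=phi_po * (1.0 - v_i),
        Psi_o=psi_o,
        ABS_RC=abs_rc,
        ETo_RC=eto_rc,
        TRo_RC=tro_rc,
        DIo_RC=dio_rc,
        RC_CSo=rc_cso,
        PI_abs=pi_abs,
    )


def batch_jip(
    transients: list[FluorescenceTransient], log=sys.stderr
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Run marker extraction + JIP derivation over a transient collection.

    Returns a per-sample parameter table (metadata columns followed by the
    parameters in report order) and the list of ``(sample_id, reason)``
    pairs for samples that failed with a degenerate-transient or coverage
    error.  Failures are logged, not raised, so one bad trace does not
    abort a batch.
    """
    rows = []
    failures: list[tuple[str, str]] = []
    for t in transients:
        try:
            res = compute_jip(extract_markers(t))
        except SampleError as exc:
            failures.append((t.sample_id, str(exc)))
            if log is not None:
                print(f"skipping {t.sample_id}: {exc}", file=log)
            continue
        rows.append(
            {
                "sample_id": t.sample_id,
                "strain": t.strain,
                "treatment": t.treatment,
                "replicate": t.replicate,
                **res.as_dict(),
            }
        )
    columns = ["sample_id", "strain", "treatment", "replicate", *PARAMETER_ORDER]
    df = pd.DataFrame(rows, columns=columns)
    return df, failures


def spider_normalize(
    results: pd.DataFrame,
    control_label: str,
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Control-relative scaling of per-sample parameters for radar plots.

    ``results`` is the per-sample table from :func:`batch_jip` (columns
    ``strain``, ``treatment`` plus parameter columns).  Within each strain,
    every parameter is divided by that strain's control-condition mean, so
    the control maps to exactly 1 and treatments become ratios to it.

    Returns a table indexed by parameter (report order preserved) with one
    column per ``strain-treatment`` condition.
    """
    if parameters is None:
        parameters = [p for p in PARAMETER_ORDER if p in results.columns]
    means = results.groupby(["strain", "treatment"], sort=True)[parameters].mean()
    out = {}
    for (strain, treatment), row in means.iterrows():
        if (strain, control_label) not in means.index:
            raise NormalizationError(f"strain {strain!r} has no control condition {control_label!r}")
        control = means.loc[(strain, control_label)]
        zero = control.index[control == 0]
        if len(zero):
            raise NormalizationError(
                f"control mean of {zero[0]!r} is zero for strain {strain!r}; cannot normalize"
            )
        out[f"{strain}-{treatment}"] = row / control
    table = pd.DataFrame(out, index=pd.Index(parameters, name="parameter"))
    return table
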