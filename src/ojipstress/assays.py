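"""Oxidative-stress and antioxidant-enzyme assay measurements.

The assays are kit-based readouts: superoxide / oxygen free radical
content (OFR), malondialdehyde (MDA, a lipid-peroxidation end product)
and the activities of the antioxidant enzymes SOD, POD and CAT.  Kit
chemistry is a black box — values live in arbitrary kit units recorded as
a free-text label — so only relative comparisons between condition means
are meaningful.  Percent changes are computed between condition means
(not replicate-paired) and reported rounded to the nearest integer
percent, with the raw value retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import EmptyInputError, TableFormatError, TableParseError

__all__ = ["ANALYTES", "AssayMeasurement", "percent_change", "format_percent", "read_assays"]

#: The closed set of supported analytes.
ANALYTES = ("OFR", "MDA", "SOD", "POD", "CAT")

ASSAY_COLUMNS = ["sample_id", "strain", "treatment", "replicate", "analyte", "value", "unit"]


@dataclass(frozen=True)
class AssayMeasurement:
    """One kit readout for one replicate."""

    sample_id: str
    strain: str
    treatment: str
    replicate: int
    analyte: str
    value: float
    unit: str = "a.u."

    def __post_init__(self):
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}; expected one of {ANALYTES}")
        if not (np.isfinite(self.value) and self.value >= 0):
            raise ValueError(f"{self.sample_id}: assay value must be nonnegative")


def percent_change(control_mean: float, treatment_mean: float) -> float:
    """Signed percent change of a treatment mean relative to its control.

    Positive means an increase; a decrease comes out negative and the
    report layer renders it as "decreased by |x|%".  Satisfies
    ``percent_change(c, t) == 100 * (fold_change(c, t) - 1)``.
    """
    if not control_mean > 0:
        raise ValueError(f"percent change needs a positive control mean, got {control_mean!r}")
    return 100.0 * (treatment_mean - control_mean) / control_mean


def format_percent(pct: float) -> int:
    """Report-style rounding: half-up to the nearest integer percent."""
    return int(Decimal(repr(float(pct))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def read_assays(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a tidy assay table (one row per replicate x analyte)."""
    from .transients import _detect_delimiter

    if delimiter is None:
        delimiter = _detect_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    required = [c for c in ASSAY_COLUMNS if c != "unit"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    if df.empty:
        raise EmptyInputError(f"{path}: header only, no data rows")
    bad = ~np.isfinite(pd.to_numeric(df["value"], errors="coerce"))
    if bad.any():
        raise TableParseError(f"{path}: non-numeric assay value", row=int(df.index[bad][0]) + 2)
    unknown = set(df["analyte"]) - set(ANALYTES)
    if unknown:
        raise TableFormatError(f"{path}: unknown analyte(s) {sorted(unknown)}")
    if "unit" not in df.columns:
        df = df.assign(unit="a.u.")
    return df
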