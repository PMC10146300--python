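"""Non-photochemical quenching (NPQ) from dark/light maximal fluorescence.

NPQ quantifies regulated thermal dissipation of excess excitation energy
as the light-induced lowering of maximal fluorescence.  The Stern-Volmer
form is used throughout:

    NPQ = (F_m - F_m') / F_m'

with F_m the dark-adapted and F_m' the light-adapted maximum — the
universal convention for pulse-amplitude and imaging fluorometry.  Fold
changes between conditions are reported rounded half-up to one decimal
("3.0-fold", "1.3-fold"), with the raw ratio always retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidMeasurementError, TableFormatError, TableParseError

__all__ = ["QuenchingPair", "compute_npq", "fold_change", "format_fold", "read_quenching"]

QUENCHING_COLUMNS = ["sample_id", "strain", "treatment", "replicate", "fm_dark", "fm_light"]


@dataclass(frozen=True)
class QuenchingPair:
    """Dark/light-adapted maximal fluorescence of one sample."""

    sample_id: str
    strain: str
    treatment: str
    replicate: int
    fm_dark: float
    fm_light: float

    def __post_init__(self):
        if not (np.isfinite(self.fm_dark) and self.fm_dark > 0):
            raise InvalidMeasurementError(f"{self.sample_id}: fm_dark must be positive")
        if not (np.isfinite(self.fm_light) and self.fm_light > 0):
            raise InvalidMeasurementError(f"{self.sample_id}: fm_light must be positive")
        if self.fm_light > self.fm_dark:
            warnings.warn(
                f"{self.sample_id}: F_m' ({self.fm_light:g}) exceeds dark F_m "
                f"({self.fm_dark:g}); NPQ will be negative",
                stacklevel=2,
            )


def compute_npq(q: QuenchingPair) -> float:
    """Stern-Volmer NPQ = (F_m - F_m')/F_m' of one quenching pair."""
    return (q.fm_dark - q.fm_light) / q.fm_light


def fold_change(before: float, after: float) -> float:
    """Ratio after/before between two condition means.

    Raises ``ValueError`` if ``before`` is not strictly positive.
    """
    if not before > 0:
        raise ValueError(f"fold change needs a positive baseline, got {before!r}")
    return after / before


def format_fold(ratio: float) -> float:
    """Report-style rounding of a fold ratio: half-up to one decimal."""
    return float(Decimal(repr(float(ratio))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def read_quenching(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a quenching table and return it with an ``npq`` column.

    Accepts either ``fm_dark``/``fm_light`` columns (NPQ is computed) or a
    pre-computed ``npq`` column (taken as is).  Metadata columns
    ``sample_id, strain, treatment, replicate`` are always required.
    """
    from .transients import _detect_delimiter  # same sniffing rule as transients

    if delimiter is None:
        delimiter = _detect_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    meta = ["sample_id", "strain", "treatment", "replicate"]
    missing_meta = [c for c in meta if c not in df.columns]
    if missing_meta:
        raise TableFormatError(f"{path}: missing required column(s) {', '.join(missing_meta)}")
    if df.empty:
        raise EmptyInputError(f"{path}: header only, no data rows")
    if "npq" in df.columns:
        return df
    if not {"fm_dark", "fm_light"}.issubset(df.columns):
        raise TableFormatError(f"{path}: need either an npq column or fm_dark and fm_light")
    for col in ("fm_dark", "fm_light"):
        bad = ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
        if bad.any():
            raise TableParseError(f"{path}: non-numeric {col}", row=int(df.index[bad][0]) + 2)
    npq = [
        compute_npq(
            QuenchingPair(
                sample_id=str(r.sample_id),
                strain=str(r.strain),
                treatment=str(r.treatment),
                replicate=int(r.replicate),
                fm_dark=float(r.fm_dark),
                fm_light=float(r.fm_light),
            )
        )
        for r in df.itertuples()
    ]
    return df.assign(npq=npq)
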