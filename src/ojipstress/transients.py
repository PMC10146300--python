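"""Fast chlorophyll fluorescence (OJIP) transients: data model, I/O, markers.

An OJIP transient is the polyphasic fluorescence rise recorded from a
dark-adapted sample under saturating light, with inflection steps O
(origin, 20 us), K (300 us), J (2 ms), I (30 ms) and P (the peak).  This
module holds the per-sample trace container, tidy-table readers/writers,
and the extraction of the five canonical markers (F_O, F_K, F_J, F_I, F_m)
that every downstream JIP-test parameter is computed from.

Marker times are fixed protocol constants, not configurable per file:
fluorescence instruments log-space their acquisition grids, so marker
lookup interpolates linearly in (log10 time, fluorescence) between the
bracketing samples.  Because the induction rise is monotone by physics,
the trace is first projected onto the nearest (least-squares)
nondecreasing sequence — isotonic regression, which leaves any already
monotone trace untouched — so that instrument point noise neither rides
into the maximum nor leaks into the marker reads.  F_m is then the
maximum of the denoised trace rather than the reading at 1000 ms, because
the peak can genuinely occur slightly before the end of the induction; a
warning is emitted if the maximum is reached suspiciously early
(< 100 ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DegenerateTransientError,
    EmptyInputError,
    TableFormatError,
    TableParseError,
)

__all__ = [
    "MARKER_TIMES",
    "T_MIN",
    "T_MAX",
    "FluorescenceTransient",
    "MarkerSet",
    "read_transients",
    "write_transients",
    "transients_to_frame",
    "extract_markers",
]

#: Protocol marker times in seconds: O at 20 us, K at 300 us, J at 2 ms, I at 30 ms.
MARKER_TIMES: dict[str, float] = {
    "F_O": 2e-5,
    "F_K": 3e-4,
    "F_J": 2e-3,
    "F_I": 3e-2,
}

T_MIN = 2e-5  #: required first sample time (s)
T_MAX = 1.0  #: required last sample time (s)

#: Columns of the tidy transient table, one row per time point.
TRANSIENT_COLUMNS = ["sample_id", "strain", "treatment", "replicate", "time_s", "fluorescence"]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class FluorescenceTransient:
    """One induction trace plus its sample metadata.

    ``times`` must be strictly increasing, start at or before 20 us, extend
    to at least 1 s, and carry strictly positive fluorescence values.
    """

    sample_id: str
    strain: str
    treatment: str
    replicate: int
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise ValueError(f"{self.sample_id}: times and values must be 1-d and equal length")
        if times.size < 5:
            raise ValueError(f"{self.sample_id}: need at least 5 time points, got {times.size}")
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"{self.sample_id}: times must be strictly increasing")
        if times[0] > T_MIN * (1 + _REL_TOL):
            raise ValueError(
                f"{self.sample_id}: first sample at {times[0]:g} s is after the 20 us origin"
            )
        if times[-1] < T_MAX * (1 - _REL_TOL):
            raise ValueError(
                f"{self.sample_id}: last sample at {times[-1]:g} s does not reach 1 s"
            )
        if not np.all(values > 0):
            raise ValueError(f"{self.sample_id}: fluorescence values must be positive")
        if int(self.replicate) < 1:
            raise ValueError(f"{self.sample_id}: replicate must be a positive integer")
        object.__setattr__(self, "replicate", int(self.replicate))

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class MarkerSet:
    """The five canonical fluorescence markers of one transient.

    For a clean monotone rise F_m >= F_I >= F_J >= F_K >= F_O; ordering is
    *not* enforced here because noisy traces may violate it slightly — the
    JIP computation raises a degenerate-transient error where it matters.
    """

    f_o: float  # minimum fluorescence at 20 us, all PSII RCs open
    f_k: float  # K-step, 300 us; rises when the oxygen-evolving complex is hurt
    f_j: float  # J-step, 2 ms
    f_i: float  # I-step, 30 ms
    f_m: float  # maximum fluorescence at peak P

    def __post_init__(self):
        for name in ("f_o", "f_k", "f_j", "f_i", "f_m"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"marker {name} must be finite and positive, got {v!r}")
            object.__setattr__(self, name, v)

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.f_o, self.f_k, self.f_j, self.f_i, self.f_m)

    def is_monotone(self) -> bool:
        t = self.as_tuple()
        return all(a <= b for a, b in zip(t, t[1:]))

    def scaled(self, c: float) -> "MarkerSet":
        """All five markers multiplied by a common positive factor."""
        return MarkerSet(*(c * v for v in self.as_tuple()))


def _detect_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_transients(path, delimiter: str | None = None) -> list[FluorescenceTransient]:
    """Read a tidy transient table into one transient per distinct sample.

    The table must carry the columns ``sample_id, strain, treatment,
    replicate, time_s, fluorescence`` (comma- or tab-delimited, header row
    required).  Rows are grouped by ``sample_id`` and time-sorted; metadata
    is taken from each group's first row.
    """
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    missing = [c for c in TRANSIENT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    if df.empty:
        raise EmptyInputError(f"{path}: header only, no data rows")

    def as_float(s):
        # exact round-trip parsing (pandas' fast parser loses ulps)
        try:
            return float(s)
        except (TypeError, ValueError):
            return np.nan

    for col in ("time_s", "fluorescence", "replicate"):
        parsed = df[col].map(as_float).to_numpy(dtype=float)
        bad = ~np.isfinite(parsed)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TableParseError(
                f"{path}: non-numeric {col} value {df[col].iloc[row]!r}", row=row + 2
            )
        df[col] = parsed

    out: list[FluorescenceTransient] = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("time_s")
        out.append(
            FluorescenceTransient(
                sample_id=str(sample_id),
                strain=str(grp["strain"].iloc[0]),
                treatment=str(grp["treatment"].iloc[0]),
                replicate=int(grp["replicate"].iloc[0]),
                times=grp["time_s"].to_numpy(float),
                values=grp["fluorescence"].to_numpy(float),
            )
        )
    return out


def transients_to_frame(transients: list[FluorescenceTransient]) -> pd.DataFrame:
    """Tidy long-format table of a transient collection (one row per point)."""
    frames = [
        pd.DataFrame(
            {
                "sample_id": t.sample_id,
                "strain": t.strain,
                "treatment": t.treatment,
                "replicate": t.replicate,
                "time_s": t.times,
                "fluorescence": t.values,
            }
        )
        for t in transients
    ]
    if not frames:
        return pd.DataFrame(columns=TRANSIENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_transients(transients: list[FluorescenceTransient], path, delimiter: str = ",") -> None:
    """Write transients in the tidy format that :func:`read_transients` reads.

    Floats are written at full repr precision so a write/read cycle
    round-trips bit-identically.
    """
    transients_to_frame(transients).to_csv(path, sep=delimiter, index=False)


def extract_markers(t: FluorescenceTransient) -> MarkerSet:
    """Extract (F_O, F_K, F_J, F_I, F_m) from a transient.

    The trace is first denoised by isotonic regression over log10 time
    (the least-squares nondecreasing fit, the identity on any trace that
    is already monotone).  F_O, F_K, F_J and F_I are then linear
    interpolations in (log10 time, fluorescence) between the bracketing
    denoised samples at 20 us, 300 us, 2 ms and 30 ms; F_m is the maximum
    of the denoised trace.  On monotone traces this reduces to plain
    log-linear lookup and is invariant under inserting redundant collinear
    (in log-time) samples.

    Raises :class:`CoverageError` if a marker time falls outside the
    sampled range and :class:`DegenerateTransientError` if the trace never
    rises (F_m <= F_O).
    """
    from sklearn.isotonic import IsotonicRegression

    logt = np.log10(t.times)
    values = IsotonicRegression().fit_transform(logt, t.values)
    markers: dict[str, float] = {}
    for name, tm in MARKER_TIMES.items():
        if tm < t.times[0] * (1 - _REL_TOL) or tm > t.times[-1] * (1 + _REL_TOL):
            raise CoverageError(
                f"{t.sample_id}: marker time {tm:g} s outside sampled range "
                f"[{t.times[0]:g}, {t.times[-1]:g}] s"
            )
        markers[name] = float(np.interp(np.log10(tm), logt, values))
    i_max = int(np.argmax(values))
    f_m = float(values[i_max])
    if f_m <= markers["F_O"]:
        raise DegenerateTransientError(
            f"{t.sample_id}: trace never rises above F_O (F_m={f_m:g}, F_O={markers['F_O']:g})"
        )
    if t.times[i_max] < 0.1:
        warnings.warn(
            f"{t.sample_id}: fluorescence maximum at {t.times[i_max]:g} s (< 100 ms); "
            "F_m may not reflect the P step",
            stacklevel=2,
        )
    return MarkerSet(markers["F_O"], markers["F_K"], markers["F_J"], markers["F_I"], f_m)
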