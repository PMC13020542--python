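"""Reading, validation and synchronized merging of 1 Hz trace files.

A *trace* is a two-column series of (timestamp, value) samples recorded at
1 Hz by a sound-level meter (dB(A)) or a vital-signs monitor (bpm). The two
devices are merged on shared integer seconds; missing seconds in either
channel drop that second from the merged record rather than being
interpolated, so no physiology is ever fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class TraceParseError(ValueError):
    """A trace file could not be parsed or failed validation."""


@dataclass
class RawTrace:
    """A validated single-channel 1 Hz series.

    Attributes
    ----------
    timestamps : ndarray of int
        Strictly increasing integer seconds.
    values : ndarray of float
        Signal values (dB(A) or bpm) aligned with ``timestamps``.
    source_label : str
        Free-text provenance label, e.g. ``"noise"`` or ``"hr"``.
    """

    timestamps: np.ndarray
    values: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise TraceParseError("timestamps and values differ in length")
        if self.timestamps.size == 0:
            raise TraceParseError("empty trace")
        diffs = np.diff(self.timestamps)
        if np.any(diffs <= 0):
            bad = self.timestamps[1:][diffs <= 0]
            raise TraceParseError(
                "timestamps not strictly increasing at: "
                + ", ".join(str(t) for t in np.unique(bad)[:10])
            )

    def __len__(self) -> int:
        return int(self.timestamps.size)


@dataclass
class NightTrace:
    """Synchronized noise + heart-rate record for one participant-night."""

    t: np.ndarray
    noise_db: np.ndarray
    hr_bpm: np.ndarray
    participant: str | None = None
    night_period: int | None = None
    condition: str | None = None
    merge_report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(np.asarray(self.t).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "noise_db": self.noise_db, "hr_bpm": self.hr_bpm}
        )


def _parse_timestamp_column(col: pd.Series) -> np.ndarray:
    """Normalize a timestamp column to integer seconds.

    Accepts plain numbers (seconds from night start or epoch) or ISO 8601
    strings; wall-clock input is rebased to seconds from the first sample.
    """
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        secs = numeric.to_numpy(dtype=float)
        return np.round(secs).astype(np.int64)
    parsed = pd.to_datetime(col, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise TraceParseError(
            f"unparseable timestamp at data row {bad + 1}: {col.iloc[bad]!r}"
        )
    secs = parsed.astype("int64").to_numpy() / 1e9
    secs = secs - secs[0]
    return np.round(secs).astype(np.int64)


def read_trace(path: str | Path, source_label: str = "") -> RawTrace:
    """Read and validate a two-column (timestamp, value) CSV trace.

    Raises
    ------
    TraceParseError
        On empty files, non-numeric values (reported with the data row
        number), duplicate timestamps, or out-of-order timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise TraceParseError(f"empty trace file: {path}") from exc
    if df.shape[0] == 0:
        raise TraceParseError(f"trace file has no data rows: {path}")
    if df.shape[1] < 2:
        raise TraceParseError(
            f"expected two columns (timestamp, value), got {df.shape[1]}: {path}"
        )
    ts_col, val_col = df.iloc[:, 0], df.iloc[:, 1]

    values = pd.to_numeric(val_col, errors="coerce")
    if values.isna().any():
        bad = int(np.flatnonzero(values.isna().to_numpy())[0])
        raise TraceParseError(
            f"non-numeric value at data row {bad + 1}: {val_col.iloc[bad]!r}"
        )

    timestamps = _parse_timestamp_column(ts_col)
    uniq, counts = np.unique(timestamps, return_counts=True)
    if np.any(counts > 1):
        dups = uniq[counts > 1]
        raise TraceParseError(
            "duplicate timestamps: " + ", ".join(str(t) for t in dups[:10])
        )
    order = np.argsort(timestamps, kind="stable")
    if not np.array_equal(order, np.arange(len(order))):
        raise TraceParseError("timestamps out of order; refusing to silently sort")

    return RawTrace(timestamps, values.to_numpy(dtype=float), source_label=source_label)


def write_trace(trace: RawTrace, path: str | Path) -> None:
    """Write a RawTrace as a two-column CSV (header ``t,value``)."""
    pd.DataFrame({"t": trace.timestamps, "value": trace.values}).to_csv(
        path, index=False
    )


def merge_traces(noise: RawTrace, hr: RawTrace, **annotations) -> NightTrace:
    """Inner-join two channels on shared integer-second timestamps.

    Seconds missing from either channel are dropped; counts of dropped
    samples per channel are recorded in ``merge_report``.

    Raises
    ------
    ValueError
        If the two traces share no timestamps.
    """
    shared = np.intersect1d(noise.timestamps, hr.timestamps)
    if shared.size == 0:
        raise ValueError(
            "traces have no overlapping timestamps "
            f"(noise spans [{noise.timestamps[0]}, {noise.timestamps[-1]}], "
            f"hr spans [{hr.timestamps[0]}, {hr.timestamps[-1]}])"
        )
    noise_idx = np.searchsorted(noise.timestamps, shared)
    hr_idx = np.searchsorted(hr.timestamps, shared)
    report = {
        "n_merged": int(shared.size),
        "dropped_noise": int(len(noise) - shared.size),
        "dropped_hr": int(len(hr) - shared.size),
    }
    return NightTrace(
        t=shared,
        noise_db=noise.values[noise_idx],
        hr_bpm=hr.values[hr_idx],
        merge_report=report,
        **annotations,
    )


def write_night(night: NightTrace, path: str | Path) -> None:
    """Write a merged night as CSV (columns ``t,noise_db,hr_bpm``)."""
    night.to_frame().to_csv(path, index=False)


def read_night(path: str | Path, **annotations) -> NightTrace:
    """Read a merged night CSV written by :func:`write_night`."""
    df = pd.read_csv(path, comment="#")
    required = {"t", "noise_db", "hr_bpm"}
    if not required.issubset(df.columns):
        raise TraceParseError(
            f"night CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return NightTrace(
        t=df["t"].to_numpy(dtype=np.int64),
        noise_db=df["noise_db"].to_numpy(dtype=float),
        hr_bpm=df["hr_bpm"].to_numpy(dtype=float),
        **annotations,
    )
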