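"""Percentile run-length peak detection and event-locked responses.

The detection algorithm for a single night's 1 Hz channel:

1. Slow trends are estimated by a moving average with a window of
   +/- ``halfwidth`` seconds (default 350), truncated at the boundaries.
2. Heart rate is detrended (observed minus trend); noise level is
   thresholded on raw values by default.
3. The threshold is the per-night 99th percentile of the thresholded
   channel. A peak candidate is a maximal run of consecutive samples
   strictly above the threshold with run length >= ``min_run`` (default 4:
   the triggering sample plus at least three subsequent values).
4. Candidates closer than ``min_separation`` seconds (default 75, the event
   duration) are merged, keeping the run with the larger maximum.

Responses to noise peaks are described two ways: occurrence of a heart-rate
peak in ``[t_peak, t_peak + 180 s)`` (curtailed to end 30 s before the next
noise peak), and the difference between the average heart rate in
``[t_peak, t_peak + 60)`` and ``[t_peak - 120, t_peak - 60)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DetrendConfig:
    halfwidth: int = 350  # seconds each side of the centre sample

    def __post_init__(self):
        if self.halfwidth < 1:
            raise ValueError("halfwidth must be >= 1")


@dataclass(frozen=True)
class PeakConfig:
    """Configuration of the percentile run-length detector.

    ``channel_mode`` selects whether the percentile threshold is applied to
    raw or detrended values ("raw" for noise level, "detrended" for heart
    rate).
    """

    percentile: float = 99.0
    min_run: int = 4
    min_separation: int = 75
    channel_mode: str = "raw"
    halfwidth: int = 350

    def __post_init__(self):
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must be in (0, 100)")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.channel_mode not in ("raw", "detrended"):
            raise ValueError("channel_mode must be 'raw' or 'detrended'")


@dataclass(frozen=True)
class Peak:
    t_peak: int
    run_start: int
    run_end: int  # inclusive
    max_value: float


class PeakSet(list):
    """List of :class:`Peak` with the threshold used to find them."""

    def __init__(self, peaks, threshold: float, config: PeakConfig):
        super().__init__(peaks)
        self.threshold = float(threshold)
        self.config = config

    @property
    def times(self) -> np.ndarray:
        return np.asarray([p.t_peak for p in self], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "t_peak": p.t_peak,
                    "run_start": p.run_start,
                    "run_end": p.run_end,
                    "max_value": p.max_value,
                }
                for p in self
            ],
            columns=["t_peak", "run_start", "run_end", "max_value"],
        )


@dataclass
class ResponseRecord:
    """One noise peak's response window and before/after comparison."""

    t_noise_peak: int
    window_start: int | None = None
    window_end: int | None = None  # exclusive
    hr_peak_occurred: bool | None = None
    hr_before: float | None = None
    hr_after: float | None = None
    delta: float | None = None
    excluded: bool = False
    reason: str = ""


def moving_average(series: np.ndarray, halfwidth: int = 350) -> np.ndarray:
    """Boundary-truncated centred moving average.

    The value at index ``i`` is the mean of samples in
    ``[i - halfwidth, i + halfwidth]`` intersected with the series span.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    n = x.size
    css = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - halfwidth, 0)
    hi = np.minimum(idx + halfwidth, n - 1)
    return (css[hi + 1] - css[lo]) / (hi - lo + 1)


def detrend(series: np.ndarray, halfwidth: int = 350) -> np.ndarray:
    """Series minus its boundary-truncated moving average."""
    x = np.asarray(series, dtype=float)
    return x - moving_average(x, halfwidth)


def _runs_above(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (start, end) inclusive index pairs."""
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_peaks(
    series: np.ndarray,
    config: PeakConfig | None = None,
    t: np.ndarray | None = None,
) -> PeakSet:
    """Detect peaks in a 1 Hz channel by the percentile run-length rule.

    Parameters
    ----------
    series : array
        The channel values (noise level or heart rate).
    config : PeakConfig
        Detector settings; with ``channel_mode="detrended"`` the series is
        detrended (+/- ``halfwidth``) before thresholding.
    t : array, optional
        Sample times in seconds; defaults to ``0..n-1``.

    Returns
    -------
    PeakSet
        Peaks sorted by time, every pair >= ``min_separation`` apart; the
        percentile threshold is attached as ``.threshold``.
    """
    config = config or PeakConfig()
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    tt = np.arange(x.size, dtype=np.int64) if t is None else np.asarray(t, dtype=np.int64)
    if tt.size != x.size:
        raise ValueError("t and series differ in length")

    values = detrend(x, config.halfwidth) if config.channel_mode == "detrended" else x
    threshold = float(np.percentile(values, config.percentile))
    above = values > threshold  # strict: a constant series yields no peaks

    candidates = []
    for start, end in _runs_above(above):
        if end - start + 1 < config.min_run:
            continue
        seg = values[start : end + 1]
        k = int(np.argmax(seg))  # earliest maximum on ties
        candidates.append(
            Peak(
                t_peak=int(tt[start + k]),
                run_start=int(tt[start]),
                run_end=int(tt[end]),
                max_value=float(seg[k]),
            )
        )

    # merge candidates closer than min_separation, keeping the larger
    # maximum (earlier run on ties)
    merged: list[Peak] = []
    for cand in candidates:
        if merged and cand.t_peak - merged[-1].t_peak < config.min_separation:
            if cand.max_value > merged[-1].max_value:
                merged[-1] = cand
        else:
            merged.append(cand)
    return PeakSet(merged, threshold=threshold, config=config)


def response_occurrence(
    noise_peaks,
    hr_peaks,
    horizon: int = 180,
    curtail: int = 30,
) -> list[ResponseRecord]:
    """Occurrence of a heart-rate peak after each noise peak.

    For noise peak ``t`` the window is ``[t, min(t + horizon, t_next -
    curtail))``; occurrence is true iff any heart-rate peak time falls in
    the half-open window. Windows of non-positive length are excluded with a
    reason code.
    """
    noise_times = np.asarray(
        [p.t_peak for p in noise_peaks] if noise_peaks and isinstance(noise_peaks[0], Peak)
        else list(noise_peaks),
        dtype=np.int64,
    )
    hr_times = np.asarray(
        [p.t_peak for p in hr_peaks] if hr_peaks and isinstance(hr_peaks[0], Peak)
        else list(hr_peaks),
        dtype=np.int64,
    )
    records = []
    for i, tp in enumerate(noise_times):
        end = tp + horizon
        if i + 1 < noise_times.size:
            end = min(end, int(noise_times[i + 1]) - curtail)
        if end <= tp:
            records.append(
                ResponseRecord(
                    t_noise_peak=int(tp),
                    excluded=True,
                    reason="window_curtailed_to_empty",
                )
            )
            continue
        occurred = bool(np.any((hr_times >= tp) & (hr_times < end)))
        records.append(
            ResponseRecord(
                t_noise_peak=int(tp),
                window_start=int(tp),
                window_end=int(end),
                hr_peak_occurred=occurred,
            )
        )
    return records


def hr_before_after(
    noise_peaks,
    hr_series: np.ndarray,
    t: np.ndarray | None = None,
    before_window: tuple[int, int] = (-120, -60),
    after_window: tuple[int, int] = (0, 60),
) -> list[ResponseRecord]:
    """Average heart rate before vs after each noise peak.

    ``hr_before`` is the mean over ``[t_peak - 120, t_peak - 60)`` and
    ``hr_after`` the mean over ``[t_peak, t_peak + 60)`` (60 samples each on
    the 1 Hz grid). Peaks whose windows are not fully covered by the series
    are excluded with a reason code.
    """
    hr = np.asarray(hr_series, dtype=float)
    tt = np.arange(hr.size, dtype=np.int64) if t is None else np.asarray(t, dtype=np.int64)
    t0, t_last = int(tt[0]), int(tt[-1])
    times = [p.t_peak for p in noise_peaks] if (
        noise_peaks and isinstance(noise_peaks[0], Peak)
    ) else list(noise_peaks)
    records = []
    for tp in times:
        b_lo, b_hi = tp + before_window[0], tp + before_window[1]
        a_lo, a_hi = tp + after_window[0], tp + after_window[1]
        if b_lo < t0 or a_hi - 1 > t_last:
            records.append(
                ResponseRecord(
                    t_noise_peak=int(tp), excluded=True, reason="window_outside_trace"
                )
            )
            continue
        before = hr[(tt >= b_lo) & (tt < b_hi)]
        after = hr[(tt >= a_lo) & (tt < a_hi)]
        if before.size == 0 or after.size == 0:
            records.append(
                ResponseRecord(
                    t_noise_peak=int(tp), excluded=True, reason="window_has_no_samples"
                )
            )
            continue
        hb, ha = float(before.mean()), float(after.mean())
        records.append(
            ResponseRecord(
                t_noise_peak=int(tp),
                window_start=int(tp),
                window_end=int(a_hi),
                hr_before=hb,
                hr_after=ha,
                delta=ha - hb,
            )
        )
    return records


def responses_to_frame(records) -> pd.DataFrame:
    """Flatten ResponseRecords (from either analysis) to a DataFrame."""
    return pd.DataFrame(
        [
            {
                "t_noise_peak": r.t_noise_peak,
                "window_start": r.window_start,
                "window_end": r.window_end,
                "hr_peak_occurred": r.hr_peak_occurred,
                "hr_before": r.hr_before,
                "hr_after": r.hr_after,
                "delta": r.delta,
                "excluded": r.excluded,
                "reason": r.reason,
            }
            for r in records
        ]
    )
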