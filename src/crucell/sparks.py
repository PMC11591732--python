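"""Ca2+ spark detection and statistics on per-CRU subspace traces.

A spark is a discrete local SR release event from the stochastic opening of
one RyR cluster.  Detection is threshold/hysteresis based on the subspace
Ca2+ concentration: an event opens on an upward crossing of ``threshold`` and
closes on a downward crossing of ``hysteresis * threshold``; events in the
same CRU separated by less than ``merge_gap`` ms are merged.  Events that lie
entirely outside stimulus-coupled (systolic) windows are flagged diastolic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SparkEvent", "SparkSummary", "detect_sparks", "spark_summary",
           "systolic_windows"]

DEFAULT_THRESHOLD = 10.0    # µM subspace Ca2+
DEFAULT_HYSTERESIS = 0.5
DEFAULT_MERGE_GAP = 2.0     # ms
SYSTOLIC_WINDOW_MS = 200.0  # stimulus onset + 200 ms counts as systole


@dataclass(frozen=True)
class SparkEvent:
    cru_id: int
    t_start: float        # ms
    t_end: float          # ms
    peak_ca_ds: float     # µM
    diastolic: bool = False

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SparkSummary:
    n_sparks: int
    rate_per_s: float               # events per recorded cell-time
    sparks_per_beat: float | None
    mean_duration: float | None     # ms
    sd_duration: float | None
    mean_peak: float | None         # µM
    sd_peak: float | None
    diastolic_rate_per_s: float | None


def systolic_windows(stim_times, window_ms: float = SYSTOLIC_WINDOW_MS):
    """[(t_on, t_on + window_ms)] systolic windows from stimulus onsets."""
    return [(float(t), float(t) + window_ms) for t in np.asarray(stim_times)]


def _is_diastolic(t0: float, t1: float, windows) -> bool:
    for w0, w1 in windows:
        if t0 < w1 and t1 > w0:   # any overlap with a systolic window
            return False
    return True


def detect_sparks(t: np.ndarray, ds_traces: np.ndarray,
                  threshold: float = DEFAULT_THRESHOLD,
                  hysteresis: float = DEFAULT_HYSTERESIS,
                  merge_gap: float = DEFAULT_MERGE_GAP,
                  stim_times=(), systolic_window_ms: float = SYSTOLIC_WINDOW_MS,
                  cru_ids=None) -> list[SparkEvent]:
    """Detect sparks in uniformly sampled subspace traces.

    ``ds_traces`` has shape (n_samples, n_cru) (a single 1-D trace is also
    accepted).  Raises on a non-uniform time grid.
    """
    t = np.asarray(t, dtype=float)
    traces = np.asarray(ds_traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[:, None]
    if len(t) != traces.shape[0]:
        raise ValueError("time grid and traces disagree in length")
    if len(t) >= 3:
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("spark detection requires a uniform time grid")
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    low = hysteresis * threshold
    windows = systolic_windows(stim_times, systolic_window_ms)
    if cru_ids is None:
        cru_ids = np.arange(traces.shape[1])

    events: list[SparkEvent] = []
    for j in range(traces.shape[1]):
        y = traces[:, j]
        raw: list[tuple[int, int]] = []   # [start, end) sample indices
        inside = False
        start = 0
        for k in range(len(y)):
            if not inside and y[k] >= threshold:
                inside = True
                start = k
            elif inside and y[k] < low:
                raw.append((start, k))
                inside = False
        if inside:
            raw.append((start, len(y)))
        # merge events closer than merge_gap
        merged: list[list[int]] = []
        for s, e in raw:
            if merged and (s - merged[-1][1]) * dt < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            t0 = float(t[s])
            t1 = float(t[e - 1] + dt) if e > s else t0
            events.append(SparkEvent(
                cru_id=int(cru_ids[j]), t_start=t0, t_end=t1,
                peak_ca_ds=float(y[s:e].max()),
                diastolic=_is_diastolic(t0, t1, windows)))
    return events


def spark_summary(events: list[SparkEvent], duration_s: float,
                  n_beats: int | None = None,
                  diastolic_s: float | None = None) -> SparkSummary:
    """Aggregate spark statistics; SDs are defined only for n >= 2."""
    n = len(events)
    if n == 0:
        return SparkSummary(0, 0.0, 0.0 if n_beats else None, None, None,
                            None, None,
                            0.0 if diastolic_s else None)
    durations = np.array([e.duration for e in events])
    peaks = np.array([e.peak_ca_ds for e in events])
    n_dia = sum(e.diastolic for e in events)
    return SparkSummary(
        n_sparks=n,
        rate_per_s=n / duration_s,
        sparks_per_beat=(n / n_beats) if n_beats else None,
        mean_duration=float(durations.mean()),
        sd_duration=float(durations.std(ddof=1)) if n >= 2 else None,
        mean_peak=float(peaks.mean()),
        sd_peak=float(peaks.std(ddof=1)) if n >= 2 else None,
        diastolic_rate_per_s=(n_dia / diastolic_s) if diastolic_s else None,
    )


def events_to_frame(events: list[SparkEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cru_id": e.cru_id, "t_start": e.t_start, "t_end": e.t_end,
        "duration": e.duration, "peak": e.peak_ca_ds,
        "diastolic": e.diastolic} for e in events])
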