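"""Prepackaged in-silico experiments.

Thin orchestration over the simulator and the analysis layer: paced runs per
remodeling condition, the transient-outward-reduction (G_to-only) comparison,
slow-rapid-slow force-frequency runs, voltage-clamp gain curves, and spark
censuses.  Both the command-line layer and the reproduction script drive the
model through these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import beat_metrics, ecc_gain, staircase_potentiation
from .model import run, run_vclamp_series
from .params import ModelParams, control_params
from .protocols import (apply_remodeling, condition_preset, make_pacing,
                        make_vclamp)
from .sparks import detect_sparks, spark_summary

__all__ = [
    "condition_params", "gto_only_params", "paced_run", "paced_beat_table",
    "gto_reduction_metrics", "spark_census", "staircase_ratio", "gain_curve",
]

# fraction of the printed transient-outward conductance retained in the
# "I_to reduction only" arm (Reduced 67%)
GTO_RETAINED = 1.0 - 0.67


def condition_params(condition: str, n_cru: int = 2000,
                     **overrides) -> ModelParams:
    """Control parameters with a named remodeling condition applied."""
    return apply_remodeling(control_params(n_cru=n_cru, **overrides),
                            condition_preset(condition))


def gto_only_params(n_cru: int = 2000, **overrides) -> ModelParams:
    """Control cell with only the transient-outward conductance reduced."""
    base = control_params(n_cru=n_cru, **overrides)
    return base.replace(G_to=base.G_to * GTO_RETAINED)


def paced_run(params: ModelParams, seed: int, seconds: float = 20.0,
              frequency: float = 1.0, record_cru_fraction: float = 0.0,
              record_dt: float = 0.5):
    prot = make_pacing([(seconds, frequency)])
    return run(prot, params, seed=seed, record_dt=record_dt,
               record_cru_fraction=record_cru_fraction)


def paced_beat_table(params: ModelParams, seed: int, seconds: float = 20.0,
                     frequency: float = 1.0, tail_beats: int = 5
                     ) -> pd.DataFrame:
    """Per-beat metrics of the last ``tail_beats`` beats at steady pacing."""
    trace = paced_run(params, seed, seconds, frequency)
    bm = beat_metrics(trace)
    return bm.iloc[-tail_beats:]


def gto_reduction_metrics(seed: int, n_cru: int = 2000, seconds: float = 12.0,
                          tail_beats: int = 5) -> dict:
    """Paired control vs G_to-reduced runs at 1 Hz (same seed).

    Returns the percent reductions of the per-beat mean peak whole-cell RyR
    open fraction and peak L-type current magnitude, and the time-to-peak
    ratio, over the last ``tail_beats`` beats.
    """
    ctrl = paced_beat_table(control_params(n_cru=n_cru), seed, seconds,
                            tail_beats=tail_beats)
    red = paced_beat_table(gto_only_params(n_cru=n_cru), seed, seconds,
                           tail_beats=tail_beats)
    po_c = ctrl.peak_po_ryr.mean()
    po_r = red.peak_po_ryr.mean()
    ical_c = ctrl.peak_I_CaL.mean()
    ical_r = red.peak_I_CaL.mean()
    return {
        "po_reduction_pct": 100.0 * (1.0 - po_r / po_c),
        "ical_reduction_pct": 100.0 * (1.0 - ical_r / ical_c),
        "ttp_ratio": red.time_to_peak_ca.mean() / ctrl.time_to_peak_ca.mean(),
        "notch_control": ctrl.notch_depth.mean(),
        "notch_reduced": red.notch_depth.mean(),
        "control": ctrl, "reduced": red,
    }


def spark_census(params: ModelParams, seed: int, seconds: float = 8.0,
                 frequency: float = 0.5, skip_s: float = 2.0,
                 record_dt: float = 1.0):
    """Paced run with all subspace traces recorded, then spark detection.

    Returns the :class:`SparkSummary` of the post-transient window together
    with the diastolic-only event statistics.
    """
    trace = paced_run(params, seed, seconds, frequency,
                      record_cru_fraction=1.0, record_dt=record_dt)
    w = trace.window(skip_s * 1000.0, seconds * 1000.0)
    events = detect_sparks(w.t, w.cru_ca_ds, stim_times=w.stim_times,
                           cru_ids=w.cru_indices)
    duration_s = seconds - skip_s
    n_beats = len(w.stim_times)
    diastolic_s = duration_s - 0.2 * n_beats
    summary = spark_summary(events, duration_s, n_beats=n_beats,
                            diastolic_s=diastolic_s)
    dia = [e for e in events if e.diastolic]
    dia_durations = np.array([e.duration for e in dia])
    dia_peaks = np.array([e.peak_ca_ds for e in dia])
    return {
        "summary": summary,
        "n_diastolic": len(dia),
        "diastolic_rate_per_s": len(dia) / diastolic_s,
        "mean_diastolic_duration": float(dia_durations.mean()) if len(dia)
        else np.nan,
        "mean_diastolic_peak": float(dia_peaks.mean()) if len(dia) else np.nan,
        "events": events,
    }


def staircase_ratio(params: ModelParams, seed: int,
                    segments=((10.0, 0.5), (4.0, 2.5), (2.0, 0.5)),
                    n_tail: int = 5) -> float:
    """Bowditch potentiation ratio from a slow-rapid-slow run."""
    prot = make_pacing(list(segments))
    trace = run(prot, params, seed=seed)
    bm = beat_metrics(trace)
    b0 = 1000.0 * segments[0][0]
    b1 = b0 + 1000.0 * segments[1][0]
    labels = np.where(bm.t_stim < b0, 0, np.where(bm.t_stim < b1, 1, 2))
    return staircase_potentiation(bm.force.values, labels, n_tail=n_tail)


def gain_curve(params: ModelParams, seed: int,
               conditioning_beats: int = 3) -> pd.DataFrame:
    """EC-coupling gain over the depolarizing step family."""
    prot = make_vclamp(conditioning_beats=conditioning_beats)
    traces = run_vclamp_series(prot, params, seed=seed)
    return ecc_gain(traces)
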