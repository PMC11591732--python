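"""Synthetic ground-truth waveform generators for the analysis layer.

Every generator returns ``(t, trace, truth)`` where ``truth`` holds the
metric values implied analytically by the construction parameters, computed
at generation time.  The fixtures share the default SimTrace sampling grid so
detectors see realistic time quantization; optional additive Gaussian noise
emulates measurement scatter.  They make the metric and spark detectors
testable without running the simulator and do not attempt biophysical realism
beyond what those detectors need.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = ["APSpec", "CaTransientSpec", "SparkTrainSpec",
           "gen_ap", "gen_ca_transient", "gen_spark_train"]

DEFAULT_DT = 0.5   # ms, the default SimTrace recording grid


def _noise(rng, sd, shape):
    return rng.normal(0.0, sd, shape) if sd > 0 else np.zeros(shape)


# ---------------------------------------------------------------------------
# action potential

@dataclass(frozen=True)
class APSpec:
    """Piecewise-linear AP with optional planted notch and EAD humps.

    Geometry: rest -> linear upstroke to ``v_peak`` -> (optional) linear drop
    to a notch minimum and recovery to the dome -> flat dome -> linear
    repolarization back to rest.  APD90 and notch depth are closed-form.
    """

    v_rest: float = -80.0
    v_peak: float = 40.0
    t_upstroke: float = 2.0        # ms from stimulus to peak
    notch_depth: float = 0.0       # mV; 0 disables the notch
    notch_t: float = 12.0          # ms after peak at which the notch bottoms
    dome_v: float | None = None    # default: v_peak - notch_depth/2
    dome_end: float = 150.0        # ms after peak at which repolarization starts
    t_end_repol: float = 300.0     # ms after peak at which v returns to rest
    ead_times: tuple[float, ...] = ()    # ms after peak (during repolarization)
    ead_amplitude: float = 5.0     # mV
    ead_width: float = 12.0        # ms
    noise_sd: float = 0.0
    dt: float = DEFAULT_DT
    duration: float = 350.0        # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_upstroke <= 0 or self.t_end_repol <= self.dome_end:
            raise ValueError("inconsistent timing parameters")
        if self.notch_depth and self.notch_t >= self.dome_end:
            raise ValueError("notch must precede the dome")


def gen_ap(spec: APSpec):
    """Generate an AP trace and its analytic truth.

    Truth fields: ``apd90`` (from upstroke start, where dV/dt is maximal, to
    the 90% repolarization crossing), ``notch_depth`` and ``ead_times``.
    """
    t = np.arange(0.0, spec.duration, spec.dt)
    v = np.full_like(t, spec.v_rest)
    dome_v = spec.dome_v if spec.dome_v is not None else \
        spec.v_peak - spec.notch_depth / 2.0
    t_peak = spec.t_upstroke
    up = (t >= 0) & (t <= t_peak)
    v[up] = spec.v_rest + (spec.v_peak - spec.v_rest) * t[up] / t_peak
    tp = t - t_peak  # time after peak
    if spec.notch_depth > 0:
        notch_v = spec.v_peak - spec.notch_depth
        seg = (tp > 0) & (tp <= spec.notch_t)
        v[seg] = spec.v_peak + (notch_v - spec.v_peak) * tp[seg] / spec.notch_t
        seg = (tp > spec.notch_t) & (tp <= 2 * spec.notch_t)
        v[seg] = notch_v + (dome_v - notch_v) * \
            (tp[seg] - spec.notch_t) / spec.notch_t
        seg = (tp > 2 * spec.notch_t) & (tp <= spec.dome_end)
        v[seg] = dome_v
    else:
        seg = (tp > 0) & (tp <= spec.dome_end)
        v[seg] = spec.v_peak + (dome_v - spec.v_peak) * tp[seg] / spec.dome_end
    seg = (tp > spec.dome_end) & (tp <= spec.t_end_repol)
    v[seg] = dome_v + (spec.v_rest - dome_v) * \
        (tp[seg] - spec.dome_end) / (spec.t_end_repol - spec.dome_end)
    # EAD humps: raised-cosine bumps anchored to the pre-hump potential so
    # the planted rise equals ead_amplitude exactly regardless of limb slope
    for te in spec.ead_times:
        seg = np.abs(tp - te) <= spec.ead_width / 2
        if not seg.any():
            continue
        v_base = v[seg][0]
        hump = v_base + spec.ead_amplitude * 0.5 * (
            1.0 + np.cos(2.0 * math.pi * (tp[seg] - te) / spec.ead_width))
        v[seg] = np.maximum(v[seg], hump)

    # analytic APD90: crossing of v_peak - 0.9*(v_peak - v_rest) on the
    # final linear limb, measured from the upstroke start (t = 0)
    v90 = spec.v_peak - 0.90 * (spec.v_peak - spec.v_rest)
    if v90 >= dome_v:
        # crossing happens on the notch/dome section; restrict to no-notch use
        t_cross = t_peak + spec.dome_end * (spec.v_peak - v90) / \
            (spec.v_peak - dome_v)
    else:
        frac = (dome_v - v90) / (dome_v - spec.v_rest)
        t_cross = t_peak + spec.dome_end + \
            frac * (spec.t_end_repol - spec.dome_end)
    truth = {
        "apd90": t_cross,
        "notch_depth": float(spec.notch_depth),
        "ead_times": tuple(t_peak + te for te in spec.ead_times),
    }
    rng = np.random.default_rng(spec.seed)
    return t, v + _noise(rng, spec.noise_sd, v.shape), truth


# ---------------------------------------------------------------------------
# Ca2+ transient

@dataclass(frozen=True)
class CaTransientSpec:
    """Double-exponential Ca2+ transient with an exact planted peak.

    The rise constant is solved so the analytic peak time equals
    ``time_to_peak`` (ms); amplitude is normalized so the peak value equals
    ``peak``.
    """

    diastolic: float = 0.1        # µM
    peak: float = 1.0             # µM
    time_to_peak: float = 37.0    # ms after the stimulus
    tau_decay: float = 200.0      # ms
    stim_time: float = 0.0        # ms
    noise_sd: float = 0.0
    dt: float = DEFAULT_DT
    duration: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.time_to_peak:
            raise ValueError("time_to_peak must be > 0")
        if self.peak <= self.diastolic:
            raise ValueError("peak must exceed the diastolic level")
        if self.time_to_peak >= self.tau_decay * 3:
            raise ValueError("rise must be faster than decay")


def _solve_tau_rise(ttp: float, tau_d: float) -> float:
    # peak of e^{-t/tau_d} - e^{-t/tau_r} is at t* = ln(tau_d/tau_r) *
    # tau_d tau_r / (tau_d - tau_r); solve tau_r for the requested t*.
    def f(tau_r):
        return math.log(tau_d / tau_r) * tau_d * tau_r / (tau_d - tau_r) - ttp
    return brentq(f, 1e-6, tau_d * (1 - 1e-9))


def gen_ca_transient(spec: CaTransientSpec):
    """Generate a transient and truth {time_to_peak (s), peak, diastolic}."""
    tau_r = _solve_tau_rise(spec.time_to_peak, spec.tau_decay)
    t = np.arange(0.0, spec.duration, spec.dt)
    ts = t - spec.stim_time
    shape = np.where(ts >= 0,
                     np.exp(-np.clip(ts, 0, None) / spec.tau_decay) -
                     np.exp(-np.clip(ts, 0, None) / tau_r), 0.0)
    peak_shape = (math.exp(-spec.time_to_peak / spec.tau_decay) -
                  math.exp(-spec.time_to_peak / tau_r))
    ca = spec.diastolic + (spec.peak - spec.diastolic) * shape / peak_shape
    truth = {
        "time_to_peak": spec.time_to_peak / 1000.0,   # s
        "peak": spec.peak,
        "diastolic": spec.diastolic,
        "tau_rise": tau_r,
    }
    rng = np.random.default_rng(spec.seed)
    return t, ca + _noise(rng, spec.noise_sd, ca.shape), truth


# ---------------------------------------------------------------------------
# spark trains

@dataclass(frozen=True)
class SparkTrainSpec:
    """Per-CRU subspace traces with planted square spark events.

    Events are either placed at given ``(cru, t_start, duration, amplitude)``
    tuples or drawn as a Poisson process of ``rate_per_cru_s`` per CRU with
    fixed duration/amplitude.  The stored truth reflects merged geometry when
    planted events overlap or abut closer than ``merge_gap``.
    """

    n_cru: int = 20
    duration: float = 2000.0      # ms
    dt: float = 1.0
    baseline: float = 0.1         # µM
    amplitude: float = 20.0       # µM
    event_duration: float = 30.0  # ms
    rate_per_cru_s: float = 0.0   # Poisson rate; ignored if events given
    events: tuple = ()            # (cru, t_start_ms, duration_ms, amplitude)
    merge_gap: float = 2.0        # ms, matches the detector default
    noise_sd: float = 0.0
    seed: int = 0


def gen_spark_train(spec: SparkTrainSpec):
    """Generate traces of shape (n_samples, n_cru) and the truth event list.

    Truth events are dicts with cru_id/t_start/t_end/duration/peak, after
    snapping to the sampling grid and merging overlapping placements.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, spec.dt)
    traces = np.full((len(t), spec.n_cru), spec.baseline)
    placed: list[tuple[int, float, float, float]] = []
    if spec.events:
        placed = [tuple(e) for e in spec.events]
    elif spec.rate_per_cru_s > 0:
        for j in range(spec.n_cru):
            n_ev = rng.poisson(spec.rate_per_cru_s * spec.duration / 1000.0)
            starts = np.sort(rng.uniform(0, spec.duration - spec.event_duration,
                                         n_ev))
            placed.extend((j, float(s), spec.event_duration, spec.amplitude)
                          for s in starts)

    truth: list[dict] = []
    by_cru: dict[int, list[list[float]]] = {}
    for cru, t0, dur, amp in placed:
        # snap to the grid so the planted geometry is exactly representable
        i0 = int(round(t0 / spec.dt))
        i1 = max(i0 + 1, int(round((t0 + dur) / spec.dt)))
        i1 = min(i1, len(t))
        if i0 >= len(t):
            continue
        traces[i0:i1, cru] = np.maximum(traces[i0:i1, cru], amp)
        by_cru.setdefault(int(cru), []).append(
            [t[i0], t[i0] + (i1 - i0) * spec.dt, amp])
    for cru, evs in by_cru.items():
        evs.sort()
        merged = [evs[0]]
        for t0, t1, amp in evs[1:]:
            if t0 - merged[-1][1] < spec.merge_gap:
                if t0 < merged[-1][1] and spec.events:
                    warnings.warn(
                        f"planted events overlap on CRU {cru}; truth reflects "
                        "the merged geometry", stacklevel=2)
                merged[-1][1] = max(merged[-1][1], t1)
                merged[-1][2] = max(merged[-1][2], amp)
            else:
                merged.append([t0, t1, amp])
        for t0, t1, amp in merged:
            truth.append({"cru_id": cru, "t_start": t0, "t_end": t1,
                          "duration": t1 - t0, "peak": amp})
    truth.sort(key=lambda e: (e["cru_id"], e["t_start"]))
    return t, traces + _noise(rng, spec.noise_sd, traces.shape), truth
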