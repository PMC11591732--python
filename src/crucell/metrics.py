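"""Derived excitation-contraction coupling quantities.

Per-beat action-potential metrics (APD90, phase-1 notch depth, early
afterdepolarizations), Ca2+-transient metrics (time to peak, amplitude),
predicted isometric force from the Hill force-pCa relation

    force = 1 / (1 + 10 ** (nH * (pCa - pCa50))),    pCa = -log10 [Ca2+]_myo (M)

SR fractional release (diastolic - systolic SR Ca2+) / diastolic, voltage-clamp
EC-coupling gain (peak SR release flux over peak trigger Ca2+ influx), the
staircase (Bowditch) potentiation ratio, and the condition-comparison
statistics (one-way ANOVA plus paired t-tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ForceParams", "predicted_force", "fractional_release",
    "apd", "time_to_peak", "notch_depth", "detect_eads",
    "ecc_gain", "staircase_potentiation", "stats_compare",
    "beat_metrics",
]


@dataclass(frozen=True)
class ForceParams:
    """Hill force-pCa parameters; physiological ranges enforced by default."""

    nH: float = 3.0
    pCa50: float = 6.0
    validate: bool = True

    def __post_init__(self) -> None:
        if self.validate:
            if not 3.0 <= self.nH <= 4.0:
                raise ValueError("nH outside the default range [3, 4]; "
                                 "pass validate=False to override")
            if not 5.5 <= self.pCa50 <= 6.0:
                raise ValueError("pCa50 outside the default range [5.5, 6.0]; "
                                 "pass validate=False to override")


def predicted_force(peak_ca_myo_molar: float, fp: ForceParams = ForceParams()
                    ) -> float:
    """Hill-predicted force in (0, 1) from peak systolic [Ca2+]_myo in molar.

    Strictly increasing in Ca2+; exactly 0.5 at pCa = pCa50.
    """
    if peak_ca_myo_molar <= 0:
        raise ValueError("peak [Ca2+] must be > 0")
    pca = -math.log10(peak_ca_myo_molar)
    return 1.0 / (1.0 + 10.0 ** (fp.nH * (pca - fp.pCa50)))


def predicted_force_um(peak_ca_myo_um: float,
                       fp: ForceParams = ForceParams()) -> float:
    """Same as :func:`predicted_force` but taking µM (1 µM -> pCa 6)."""
    return predicted_force(peak_ca_myo_um * 1e-6, fp)


def inverse_force_um(force: float, fp: ForceParams = ForceParams()) -> float:
    """Peak [Ca2+]_myo (µM) producing the given force — inverse Hill."""
    if not 0.0 < force < 1.0:
        raise ValueError("force must be in (0, 1)")
    pca = fp.pCa50 + math.log10(1.0 / force - 1.0) / fp.nH
    return 10.0 ** (-pca) * 1e6


def fractional_release(ca_sr_diastolic: float, ca_sr_systolic: float) -> float:
    """(diastolic - systolic) / diastolic SR Ca2+, clipped to [0, 1]."""
    if ca_sr_diastolic <= 0:
        raise ValueError("diastolic SR Ca2+ must be > 0")
    systolic = min(max(ca_sr_systolic, 0.0), ca_sr_diastolic)
    return (ca_sr_diastolic - systolic) / ca_sr_diastolic


# ---------------------------------------------------------------------------
# waveform metrics

def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(y) < window:
        return y
    kernel = np.ones(window) / window
    padded = np.pad(y, (window // 2, window - 1 - window // 2), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def apd(t: np.ndarray, v: np.ndarray, level: float = 0.90,
        min_amplitude: float = 15.0) -> float | None:
    """Action-potential duration at fractional repolarization ``level`` (ms).

    Measured from the time of maximal upstroke dV/dt to the crossing of
    peak - level * (peak - diastolic), with the diastolic potential taken as
    the pre-upstroke value.  Returns None when no AP is present.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) < 3:
        return None
    dv = np.gradient(v, t)
    i_up = int(np.argmax(dv))
    i_peak = i_up + int(np.argmax(v[i_up:]))
    v_dia = v[:i_up + 1].min() if i_up > 0 else v[0]
    v_peak = v[i_peak]
    if v_peak - v_dia < min_amplitude:
        return None
    v_level = v_peak - level * (v_peak - v_dia)
    after = v[i_peak:]
    below = np.nonzero(after <= v_level)[0]
    if len(below) == 0:
        return None
    j = below[0] + i_peak
    if j == 0 or v[j] == v[j - 1]:
        t_cross = t[j]
    else:  # linear interpolation across the crossing sample
        frac = (v[j - 1] - v_level) / (v[j - 1] - v[j])
        t_cross = t[j - 1] + frac * (t[j] - t[j - 1])
    return float(t_cross - t[i_up])


def time_to_peak(t: np.ndarray, ca: np.ndarray, stim_time: float) -> float:
    """Time (s) from the stimulus to the Ca2+ transient peak."""
    t = np.asarray(t, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if len(t) == 0:
        raise ValueError("empty trace segment")
    sel = t >= stim_time
    if not sel.any():
        raise ValueError("segment does not cover the stimulus")
    i = int(np.argmax(ca[sel]))
    return float((t[sel][i] - stim_time) / 1000.0)


def notch_depth(t: np.ndarray, v: np.ndarray, smooth_window: int = 5,
                min_prominence: float = 2.0, peak_window_ms: float = 10.0,
                search_ms: float = 80.0) -> float:
    """Phase-1 notch depth (mV): the early (phase-1) peak minus the
    subsequent local minimum before the dome rebound; 0 when early
    repolarization is monotone (no dome, hence no notch).

    The phase-1 peak is the maximum within ``peak_window_ms`` of the maximal
    upstroke; the notch minimum is searched over the following ``search_ms``
    and must be followed by a rebound of at least ``min_prominence`` mV.
    """
    t = np.asarray(t, dtype=float)
    vs = _smooth(np.asarray(v, dtype=float), smooth_window)
    if len(vs) < 5:
        return 0.0
    dt = t[1] - t[0]
    i_up = int(np.argmax(np.gradient(vs, t)))
    n_pk = max(1, int(round(peak_window_ms / dt)))
    w = vs[i_up:i_up + n_pk]
    i_pk = i_up + int(np.argmax(w))
    v_pk = vs[i_pk]
    n_search = int(round(search_ms / dt))
    run_min = v_pk
    for k in range(i_pk + 1, min(i_pk + n_search, len(vs))):
        if vs[k] < run_min:
            run_min = vs[k]
        elif vs[k] > run_min + min_prominence:
            return float(v_pk - run_min)   # rebound -> dome follows a notch
    return 0.0


def detect_eads(t: np.ndarray, v: np.ndarray, rise_threshold: float = 2.0,
                repol_end: float = -70.0, smooth_window: int = 9
                ) -> list[dict]:
    """Early afterdepolarizations in the repolarization phase of one AP.

    An event is a window where dV/dt turns positive and V rises by at least
    ``rise_threshold`` mV from a local minimum before repolarization resumes.
    The search window runs from the AP peak until V first falls below
    ``repol_end``.
    """
    t = np.asarray(t, dtype=float)
    vs = _smooth(np.asarray(v, dtype=float), smooth_window)
    if len(t) < 5:
        return []
    i_peak = int(np.argmax(vs))
    end = np.nonzero(vs[i_peak:] < repol_end)[0]
    i_end = i_peak + (int(end[0]) if len(end) else len(vs) - i_peak)
    events = []
    run_min, run_idx = vs[i_peak], i_peak
    k = i_peak + 1
    while k < i_end:
        if vs[k] < run_min:
            run_min, run_idx = vs[k], k
        elif vs[k] - run_min >= rise_threshold:
            # climb to this hump's local max before resuming the search
            while k + 1 < i_end and vs[k + 1] >= vs[k]:
                k += 1
            events.append({"t_start": float(t[run_idx]),
                           "t_peak": float(t[k]),
                           "amplitude": float(vs[k] - run_min)})
            run_min, run_idx = vs[k], k
        k += 1
    return events


# ---------------------------------------------------------------------------
# protocol-level metrics

def ecc_gain(traces_by_vtest: dict[float, "object"]) -> pd.DataFrame:
    """EC-coupling gain per test potential: peak SR release flux divided by
    the peak trans-sarcolemmal trigger Ca2+ flux during the step.

    Each trace must record ``J_rel`` and ``J_lcc`` in µM/ms.  A step with no
    trigger flux yields a missing (NaN) gain, not infinity.
    """
    rows = []
    for v_test, trace in sorted(traces_by_vtest.items()):
        t0, t1 = trace.meta.get("step_window", (trace.t[0], trace.t[-1]))
        sel = (trace.t >= t0) & (trace.t <= t1)
        peak_rel = float(np.max(trace["J_rel"][sel], initial=0.0))
        peak_trig = float(np.max(trace["J_lcc"][sel], initial=0.0))
        gain = peak_rel / peak_trig if peak_trig > 0 else np.nan
        rows.append({"v_test": v_test, "peak_J_rel": peak_rel,
                     "peak_J_trigger": peak_trig, "gain": gain})
    return pd.DataFrame(rows)


def staircase_potentiation(force_per_beat: np.ndarray,
                           beat_segment_labels: np.ndarray,
                           n_tail: int = 5) -> float:
    """Bowditch potentiation: mean peak force of the last ``n_tail`` beats of
    the rapid segment over the last ``n_tail`` beats of the initial slow
    segment (slow-rapid-slow pacing)."""
    force = np.asarray(force_per_beat, dtype=float)
    labels = np.asarray(beat_segment_labels)
    slow = force[labels == 0]
    rapid = force[labels == 1]
    if len(slow) < n_tail or len(rapid) < n_tail:
        raise ValueError(f"need >= {n_tail} beats in both the initial slow "
                         "and the rapid segment")
    return float(rapid[-n_tail:].mean() / slow[-n_tail:].mean())


def stats_compare(samples_by_condition: dict[str, np.ndarray],
                  alpha: float = 0.05) -> dict:
    """One-way ANOVA across conditions plus pairwise paired t-tests.

    Paired tests require equal-length samples (matched seeds).  Returns the
    ANOVA F and p, a per-pair {pair: p} map, and the significance threshold.
    """
    groups = {k: np.asarray(v, dtype=float)
              for k, v in samples_by_condition.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 conditions")
    for name, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"condition {name!r} has n < 2")
    f_stat, p_anova = stats.f_oneway(*groups.values())
    paired = {}
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(groups[a]) != len(groups[b]):
                raise ValueError(f"paired t-test {a!r} vs {b!r} needs "
                                 "equal-length samples")
            if np.allclose(groups[a], groups[b]):
                paired[(a, b)] = 1.0
            else:
                paired[(a, b)] = float(
                    stats.ttest_rel(groups[a], groups[b]).pvalue)
    return {"anova_F": float(f_stat), "anova_p": float(p_anova),
            "paired_t_p": paired, "alpha": alpha}


# ---------------------------------------------------------------------------
# per-beat metric table

def beat_metrics(trace, force_params: ForceParams = ForceParams(),
                 beat_window_ms: float | None = None) -> pd.DataFrame:
    """Per-beat metric table from a current-clamp trace.

    One row per stimulus: APD90, notch depth, time-to-peak and peak of the
    myoplasmic Ca2+ transient, diastolic/systolic network-SR Ca2+ and the
    fractional release, peak whole-cell RyR open fraction, peak (most
    negative) I_CaL, Hill-predicted force, and the EAD count.
    """
    stims = np.asarray(trace.stim_times, dtype=float)
    rows = []
    t = trace.t
    for k, t_on in enumerate(stims):
        # stop just short of the next stimulus so its upstroke never leaks
        # into this beat's window
        t_next = stims[k + 1] - 2.0 if k + 1 < len(stims) else t[-1] + trace.dt
        if beat_window_ms is not None:
            t_next = min(t_next, t_on + beat_window_ms)
        sel = (t >= t_on) & (t < t_next)
        if sel.sum() < 4:
            continue
        tb = t[sel]
        vb = trace["v"][sel]
        cab = trace["ca_myo"][sel]
        nsrb = trace["ca_nsr"][sel]
        # diastolic SR content just before the stimulus
        pre = (t >= t_on - 10.0) & (t < t_on)
        sr_dia = float(trace["ca_nsr"][pre].mean()) if pre.any() \
            else float(nsrb[0])
        sr_sys = float(nsrb.min())
        peak_ca = float(cab.max())
        rows.append({
            "beat": k,
            "t_stim": float(t_on),
            "apd90": apd(tb, vb),
            "notch_depth": notch_depth(tb, vb),
            "time_to_peak_ca": time_to_peak(tb, cab, t_on),
            "peak_ca_myo": peak_ca,
            "diastolic_ca_nsr": sr_dia,
            "systolic_ca_nsr": sr_sys,
            "fractional_release": fractional_release(sr_dia, sr_sys),
            "peak_po_ryr": float(trace["po_ryr"][sel].max()),
            "peak_I_CaL": float(trace["I_CaL"][sel].min()),
            "force": predicted_force_um(peak_ca, force_params),
            "ead_count": len(detect_eads(tb, vb)),
        })
    return pd.DataFrame(rows)
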