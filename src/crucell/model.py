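"""Whole-cell hybrid stochastic-deterministic myocyte model.

The cell couples ``n_cru`` calcium-release units — each a dyadic subspace plus
a junctional SR compartment with a 49-channel RyR2 cluster and 9 L-type Ca2+
channels — to bulk myoplasm, network SR, the membrane potential and the
membrane currents (I_K1, I_to, I_Kr, I_Ks, a minimal fast I_Na for the
upstroke, L-type Ca2+ current, Na+/Ca2+ exchange and a background Ca2+
current).  Channel gating is advanced stochastically by count-based sampling;
concentrations, gates and voltage deterministically (operator splitting).

Sign/unit conventions: membrane currents are µA/µF, positive outward; Ca2+
fluxes are µM/ms, positive into the receiving compartment; concentrations µM;
time ms.  Whole-cell fluxes are referred to myoplasmic volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _engine as eng
from .gating import LCC_OPEN, N_LCC_STATES, N_RYR_STATES
from .params import ModelParams
from .protocols import Protocol

__all__ = [
    "CellState", "SimTrace", "SimulationError",
    "release_flux", "serca_flux", "ncx_current", "ncx_reversal_voltage",
    "k_currents", "lcc_current", "lcc_single_channel_flux",
    "initial_state", "step", "run", "run_vclamp_series",
]


class SimulationError(RuntimeError):
    """Raised when the integrator detects NaN or a negative concentration."""


# ---------------------------------------------------------------------------
# parameter packing

def build_param_vector(p: ModelParams) -> np.ndarray:
    P = np.zeros(eng.NP_PARAMS)
    P[eng.iG_K1] = p.G_K1
    P[eng.iG_to] = p.G_to
    P[eng.iG_Kr] = p.G_Kr
    P[eng.iG_Ks] = p.G_Ks
    P[eng.iG_NCX] = p.G_NCX
    P[eng.iAp] = p.Ap_serca
    P[eng.iKCO_MAX] = p.ryr.k_plus_scale * p.ryr.base_rate
    P[eng.iKACT_ETA] = p.ryr.K_act ** p.ryr.eta
    P[eng.iETA] = p.ryr.eta
    P[eng.iK_CLOSE] = p.ryr.k_close
    P[eng.iK_INACT] = p.ryr.k_inact
    P[eng.iK_RECOVER] = p.ryr.k_recover
    P[eng.iALPHA0] = p.lcc.alpha0
    P[eng.iBETA0] = p.lcc.beta0
    P[eng.iS_ALPHA] = p.lcc.s_alpha
    P[eng.iS_BETA] = p.lcc.s_beta
    P[eng.iV_HALF] = p.lcc.v_half
    P[eng.iGAMMA0] = p.lcc.gamma0
    P[eng.iOMEGA] = p.lcc.omega
    P[eng.iJSCALE] = p.lcc.g_single
    P[eng.iV_DS] = p.v_ds
    P[eng.iV_JSR] = p.v_jsr
    P[eng.iV_MYO] = p.V_myo
    P[eng.iV_NSR] = p.V_nsr
    P[eng.iW] = p.cru_weight
    P[eng.iB_TRPN] = p.B_trpn
    P[eng.iK_TRPN] = p.K_trpn
    P[eng.iB_CMDN] = p.B_cmdn
    P[eng.iK_CMDN] = p.K_cmdn
    P[eng.iB_CSQN] = p.B_csqn
    P[eng.iK_CSQN] = p.K_csqn
    P[eng.iTAU_EFF] = p.tau_efflux
    P[eng.iTAU_REFILL] = p.tau_refill
    P[eng.iV_RYR] = p.v_ryr
    P[eng.iSERCA_KM] = p.serca_Km
    P[eng.iSERCA_H] = p.serca_hill
    P[eng.iSERCA_VP] = p.serca_vp
    P[eng.iV_LEAK] = p.v_leak
    P[eng.iG_BCA] = p.G_bCa
    P[eng.iG_NA] = p.G_Na
    P[eng.iNCX_DEN_NA] = p.ncx_KmNai ** 3 + p.Na_o ** 3
    P[eng.iNCX_DEN_CA] = p.ncx_KmCa + p.Ca_o
    P[eng.iNCX_KSAT] = p.ncx_ksat
    P[eng.iNCX_GAMMA] = p.ncx_gamma
    P[eng.iNA_I] = p.Na_i
    P[eng.iNA_O] = p.Na_o
    P[eng.iCA_O] = p.Ca_o
    P[eng.iE_K] = p.E_K
    P[eng.iE_NA] = p.E_Na
    P[eng.iC2F] = p.current_to_flux
    P[eng.iRTF] = 26.712
    P[eng.iN_RYR] = p.n_ryr_per_cru
    P[eng.iN_LCC] = p.n_lcc_per_cru
    P[eng.iK_O] = p.K_o
    P[eng.iNCX_ALPHA] = p.ncx_alpha
    P[eng.iY_TAU] = p.lcc.y_tau
    P[eng.iY_PED] = p.lcc.y_pedestal
    P[eng.iY_VHALF] = p.lcc.y_vhalf
    P[eng.iY_SLOPE] = p.lcc.y_slope
    P[eng.iG_NAK] = p.G_NaK
    P[eng.iG_BNA] = p.G_bNa
    return P


# ---------------------------------------------------------------------------
# documented flux / current formulas (mirrored inside the numba kernel)

def release_flux(ca_jsr: float, ca_ds: float, n_open_ryr: int,
                 params: ModelParams) -> float:
    """Per-CRU SR release flux J = v_ryr * (n_open/N) * (ca_jsr - ca_ds),
    in µM/ms referred to the subspace volume."""
    if ca_jsr < 0 or ca_ds < 0:
        raise ValueError("concentrations must be >= 0")
    if not 0 <= n_open_ryr <= params.n_ryr_per_cru:
        raise ValueError("n_open_ryr out of range")
    return params.v_ryr * (n_open_ryr / params.n_ryr_per_cru) * (ca_jsr - ca_ds)


def serca_flux(ca_myo: float, params: ModelParams) -> float:
    """SERCA uptake J_up = vp * Ap * ca^h / (ca^h + Km^h) (µM/ms)."""
    if ca_myo < 0:
        raise ValueError("ca_myo must be >= 0")
    ca_h = ca_myo ** params.serca_hill
    return (params.serca_vp * params.Ap_serca * ca_h /
            (ca_h + params.serca_Km ** params.serca_hill))


def ncx_current(v: float, ca_myo: float, params: ModelParams) -> float:
    """Electrogenic 3Na:1Ca exchanger current (µA/µF, positive outward).

    Positive (reverse mode) corresponds to Ca2+ entry; at resting potential
    and diastolic Ca2+ the current is negative (forward mode, Ca2+ extrusion).
    """
    if ca_myo <= 0:
        raise ValueError("ca_myo must be > 0")
    u = v / 26.712
    cai = ca_myo * 1e-3  # mM
    e1 = math.exp(params.ncx_gamma * u)
    e2 = math.exp((params.ncx_gamma - 1.0) * u)
    num = (e1 * params.Na_i ** 3 * params.Ca_o -
           e2 * params.ncx_alpha * params.Na_o ** 3 * cai)
    den = ((params.ncx_KmNai ** 3 + params.Na_o ** 3) *
           (params.ncx_KmCa + params.Ca_o) * (1.0 + params.ncx_ksat * e2))
    return params.G_NCX * num / den


def ncx_reversal_voltage(ca_myo: float, params: ModelParams) -> float:
    """Voltage (mV) at which the exchanger current crosses zero."""
    return brentq(lambda v: ncx_current(v, ca_myo, params), -250.0, 250.0)


def k_currents(v: float, gates, params: ModelParams):
    """(I_K1, I_to, I_Kr, I_Ks) in µA/µF from gate values (r, s, xr, xs)."""
    r, s, xr, xs = gates
    for gname, gval in zip("rsxr xs".split(), (r, s, xr, xs)):
        if not 0.0 <= gval <= 1.0:
            raise ValueError(f"gate {gname} outside [0, 1]")
    e_k = params.E_K
    sqrt_ko = math.sqrt(params.K_o / 5.4)
    xk1 = 0.008 + 0.992 / (1.0 + math.exp((v - e_k - 35.0) / 16.0))
    i_k1 = params.G_K1 * sqrt_ko * xk1 * (v - e_k)
    i_to = params.G_to * r * s * (v - e_k)
    xr2 = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    i_kr = params.G_Kr * sqrt_ko * xr * xr2 * (v - e_k)
    i_ks = params.G_Ks * xs * xs * (v - e_k)
    return i_k1, i_to, i_kr, i_ks


def lcc_single_channel_flux(v: float, ca_ds: float,
                            params: ModelParams) -> float:
    """GHK Ca2+ influx through one open LCC (µM/ms in subspace volume)."""
    u = 2.0 * v / 26.712
    c0 = 1.0 - 0.5 * u if abs(u) < 1e-6 else u / math.expm1(u)
    jsc = params.lcc.g_single
    return jsc * c0 * (0.341 * params.Ca_o - math.exp(u) * ca_ds * 1e-3)


def lcc_current(v: float, ca_ds: float, n_open_total: int,
                params: ModelParams):
    """Whole-cell L-type current and the per-open-channel subspace influx.

    Returns ``(I_CaL µA/µF, J_single µM/ms)`` where the current follows from
    the summed influx over ``n_open_total`` open channels on the simulated
    CRUs, weighted up to the reference cell and referred to myoplasmic volume.
    """
    j_single = lcc_single_channel_flux(v, ca_ds, params)
    j_myo = (j_single * n_open_total * params.v_ds * params.cru_weight /
             params.V_myo)
    return -j_myo / params.current_to_flux, j_single


# ---------------------------------------------------------------------------
# state containers

@dataclass
class CellState:
    """Full model state: membrane, global Ca2+, per-CRU compartments/channels."""

    v: float
    ca_myo: float
    ca_nsr: float
    gates: np.ndarray            # (m, h, r, s, xr, xs, y)
    ca_ds: np.ndarray            # (n_cru,)
    ca_jsr: np.ndarray           # (n_cru,)
    ryr: np.ndarray              # (n_cru, 3) occupancy counts
    lcc: np.ndarray              # (n_cru, 6) occupancy counts
    rng_states: np.ndarray       # (n_cru,) uint64 per-CRU streams
    time: float = 0.0

    def copy(self) -> "CellState":
        return CellState(self.v, self.ca_myo, self.ca_nsr, self.gates.copy(),
                         self.ca_ds.copy(), self.ca_jsr.copy(),
                         self.ryr.copy(), self.lcc.copy(),
                         self.rng_states.copy(), self.time)

    def validate(self) -> None:
        if self.ca_myo < 0 or self.ca_nsr < 0:
            raise ValueError("negative global Ca2+")
        if (self.ca_ds < 0).any() or (self.ca_jsr < 0).any():
            raise ValueError("negative CRU Ca2+")
        if ((self.gates < 0) | (self.gates > 1)).any():
            raise ValueError("gate outside [0, 1]")


@dataclass
class SimTrace:
    """Uniformly sampled record of a simulation.

    ``data`` maps field names to 1-D arrays on the common time grid (ms);
    ``cru_ca_ds`` optionally holds a per-CRU subspace Ca2+ sample of shape
    (n_samples, n_recorded_crus).  Fluxes are µM/ms (positive into the
    receiving compartment), currents µA/µF (positive outward).
    """

    data: dict[str, np.ndarray]
    cru_ca_ds: np.ndarray | None = None
    cru_indices: np.ndarray | None = None
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key]

    @property
    def t(self) -> np.ndarray:
        return self.data["t"]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data)

    def window(self, t0: float, t1: float) -> "SimTrace":
        sel = (self.t >= t0) & (self.t < t1)
        return SimTrace(
            {k: v[sel] for k, v in self.data.items()},
            cru_ca_ds=None if self.cru_ca_ds is None else self.cru_ca_ds[sel],
            cru_indices=self.cru_indices,
            stim_times=self.stim_times[(self.stim_times >= t0) &
                                       (self.stim_times < t1)],
            meta=dict(self.meta),
        )


def total_calcium(state: "CellState", params: ModelParams) -> float:
    """Total cell Ca2+ (free + buffered, volume-weighted), in µM * pL.

    Rapid-buffering bound fractions: troponin/calmodulin in the myoplasm,
    calsequestrin in the junctional SR; the subspace is unbuffered.  Used by
    the closed-membrane conservation audit.
    """
    ca = state.ca_myo
    bound_myo = (params.B_trpn * ca / (params.K_trpn + ca) +
                 params.B_cmdn * ca / (params.K_cmdn + ca))
    total = (ca + bound_myo) * params.V_myo
    total += state.ca_nsr * params.V_nsr
    jsr = state.ca_jsr
    bound_jsr = params.B_csqn * jsr / (params.K_csqn + jsr)
    w = params.cru_weight
    total += float(np.sum(jsr + bound_jsr)) * params.v_jsr * w
    total += float(np.sum(state.ca_ds)) * params.v_ds * w
    return total


def initial_state(params: ModelParams, seed: int,
                  v: float = -83.3, ca_myo: float = 0.09,
                  ca_nsr: float = 900.0) -> CellState:
    """Quiescent initial condition: all RyRs closed, all LCCs deep-closed,
    gates at their steady state for the resting potential."""
    n = params.n_cru
    ryr = np.zeros((n, N_RYR_STATES))
    ryr[:, 0] = params.n_ryr_per_cru
    lcc = np.zeros((n, N_LCC_STATES))
    lcc[:, 0] = params.n_lcc_per_cru
    gates = np.array([
        1.0 / (1.0 + math.exp(-(v + 40.0) / 6.0)),    # m
        1.0 / (1.0 + math.exp((v + 68.0) / 6.5)),     # h
        1.0 / (1.0 + math.exp((20.0 - v) / 6.0)),     # r
        0.035 + 0.965 / (1.0 + math.exp((v + 20.0) / 5.0)),     # s
        1.0 / (1.0 + math.exp(-(v + 26.0) / 7.0)),    # xr
        1.0 / (1.0 + math.exp(-(v + 5.0) / 14.0)),    # xs
        params.lcc.y_pedestal + (1.0 - params.lcc.y_pedestal) /
        (1.0 + math.exp((v - params.lcc.y_vhalf) / params.lcc.y_slope)),  # y

    ])
    return CellState(
        v=v, ca_myo=ca_myo, ca_nsr=ca_nsr, gates=gates,
        ca_ds=np.full(n, ca_myo), ca_jsr=np.full(n, ca_nsr),
        ryr=ryr, lcc=lcc, rng_states=eng.seed_streams(seed, n),
    )


def _pack_globals(state: CellState) -> np.ndarray:
    g = np.zeros(eng.NG)
    g[eng.gV] = state.v
    g[eng.gCA_MYO] = state.ca_myo
    g[eng.gCA_NSR] = state.ca_nsr
    g[eng.gM:eng.gM + 7] = state.gates
    g[eng.gT] = state.time
    return g


def _unpack_globals(g: np.ndarray, state: CellState) -> None:
    state.v = g[eng.gV]
    state.ca_myo = g[eng.gCA_MYO]
    state.ca_nsr = g[eng.gCA_NSR]
    state.gates = g[eng.gM:eng.gM + 7].copy()
    state.time = g[eng.gT]


def _advance(state: CellState, params: ModelParams, dt: float, n_steps: int,
             stride: int, mode: int, stim_t, stim_amp, stim_w,
             clamp_t, clamp_v, stochastic: bool, sl_enabled: bool,
             ina_enabled: bool, cru_rec_idx: np.ndarray):
    P = build_param_vector(params)
    g = _pack_globals(state)
    n_rec = (n_steps + stride - 1) // stride
    rec = np.zeros((n_rec, eng.NF))
    rec_cru = np.zeros((n_rec, len(cru_rec_idx)))
    code = eng.run_kernel(
        P, dt, n_steps, stride, mode,
        np.asarray(stim_t, dtype=float), np.asarray(stim_amp, dtype=float),
        np.asarray(stim_w, dtype=float),
        np.asarray(clamp_t, dtype=float), np.asarray(clamp_v, dtype=float),
        state.ryr, state.lcc, state.ca_ds, state.ca_jsr, g, state.rng_states,
        1 if stochastic else 0, 1 if sl_enabled else 0,
        1 if ina_enabled else 0,
        rec, cru_rec_idx, rec_cru)
    _unpack_globals(g, state)
    if code == 1:
        raise SimulationError(f"NaN membrane potential at t = {state.time:.3f} ms")
    if code == 2:
        raise SimulationError(f"negative concentration at t = {state.time:.3f} ms")
    return rec, rec_cru


def step(state: CellState, params: ModelParams, dt: float, mode: str,
         drive: float, rng=None, stochastic: bool = True,
         sl_enabled: bool = True, ina_enabled: bool = True) -> CellState:
    """Advance one step of ``dt`` ms and return the new state.

    ``drive`` is the stimulus current (µA/µF, current clamp) or the clamped
    potential (mV, voltage clamp).  The input state is not mutated.
    """
    out = state.copy()
    if mode == "current_clamp":
        m, stim_t, stim_amp, stim_w = 0, [state.time], [drive], [dt * 2]
        clamp_t, clamp_v = [0.0], [0.0]
    elif mode == "voltage_clamp":
        m, stim_t, stim_amp, stim_w = 1, [0.0], [0.0], [0.0]
        clamp_t, clamp_v = [0.0], [drive]
        out.v = drive
    else:
        raise ValueError(f"unknown mode {mode!r}")
    _advance(out, params, dt, 1, 1, m, stim_t, stim_amp, stim_w,
             clamp_t, clamp_v, stochastic, sl_enabled,
             ina_enabled and mode == "current_clamp", np.empty(0, np.int64))
    return out


def run(protocol: Protocol, params: ModelParams, seed: int,
        dt: float = 0.025, record_dt: float = 0.5,
        record_cru_fraction: float = 0.0, init: CellState | None = None,
        stochastic: bool = True, sl_enabled: bool = True,
        ina_enabled: bool = True) -> SimTrace:
    """Run a current-clamp protocol and return the recorded trace.

    Reproducible: identical (protocol, params, seed, dt) give bitwise
    identical traces.  ``record_cru_fraction`` selects the leading fraction of
    CRUs whose subspace Ca2+ is recorded alongside the whole-cell fields.
    """
    if protocol.mode != "current_clamp":
        raise ValueError("run() drives current-clamp protocols; "
                         "use run_vclamp_series() for the step family")
    state = init.copy() if init is not None else initial_state(params, seed)
    stim = protocol.stimulus_times()
    amp = np.array([protocol.segment_of(t).amplitude for t in stim])
    width = np.array([protocol.segment_of(t).width for t in stim])
    n_steps = int(round(protocol.duration_ms / dt))
    stride = max(1, int(round(record_dt / dt)))
    n_idx = int(round(record_cru_fraction * params.n_cru))
    cru_idx = np.arange(n_idx, dtype=np.int64)
    rec, rec_cru = _advance(state, params, dt, n_steps, stride, 0,
                            stim, amp, width, [0.0], [0.0],
                            stochastic, sl_enabled, ina_enabled, cru_idx)
    data = {name: rec[:, k] for k, name in enumerate(eng.FIELDS)}
    return SimTrace(
        data, cru_ca_ds=rec_cru if n_idx else None,
        cru_indices=cru_idx if n_idx else None, stim_times=stim,
        meta={"seed": seed, "dt": dt, "n_cru": params.n_cru,
              "final_state": state},
    )


def run_vclamp_series(protocol: Protocol, params: ModelParams, seed: int,
                      dt: float = 0.025, record_dt: float = 0.5,
                      pre_hold_ms: float = 100.0, tail_ms: float = 100.0,
                      ) -> dict[float, SimTrace]:
    """Run the voltage-clamp step family; returns {V_test: trace}.

    The cell is conditioned by a short 1 Hz current-clamp train, then each
    test step runs from the saved post-conditioning state (default) or
    sequentially with the protocol's inter-step holding interval.  I_Na is
    disabled under clamp.
    """
    if protocol.mode != "voltage_clamp":
        raise ValueError("protocol must be voltage clamp")
    from .protocols import make_pacing
    state = initial_state(params, seed)
    if protocol.conditioning_beats > 0:
        cond = make_pacing([(float(protocol.conditioning_beats), 1.0)])
        tr = run(cond, params, seed, dt=dt, record_dt=record_dt, init=state)
        state = tr.meta["final_state"]
    out: dict[float, SimTrace] = {}
    saved = state.copy()
    for vstep in protocol.steps:
        if protocol.reset_between_steps:
            state = saved.copy()
        else:
            # recover at holding potential between steps
            hold_ms = protocol.inter_step_interval * 1000.0
            if out:
                _advance(state, params, dt, int(round(hold_ms / dt)),
                         10 ** 9, 1, [0.0], [0.0], [0.0],
                         [0.0], [protocol.holding_v], True, True, False,
                         np.empty(0, np.int64))
        step_ms = vstep.duration * 1000.0
        clamp_t = [0.0, pre_hold_ms, pre_hold_ms + step_ms]
        clamp_v = [protocol.holding_v, vstep.v_test, protocol.holding_v]
        total = pre_hold_ms + step_ms + tail_ms
        t0 = state.time
        clamp_t = [t0 + c for c in clamp_t]
        n_steps = int(round(total / dt))
        stride = max(1, int(round(record_dt / dt)))
        rec, _ = _advance(state, params, dt, n_steps, stride, 1,
                          [0.0], [0.0], [0.0], clamp_t, clamp_v,
                          True, True, False, np.empty(0, np.int64))
        data = {name: rec[:, k] for k, name in enumerate(eng.FIELDS)}
        data["t"] = data["t"] - t0
        out[vstep.v_test] = SimTrace(
            data, meta={"v_test": vstep.v_test, "seed": seed,
                        "step_window": (pre_hold_ms, pre_hold_ms + step_ms)})
    return out
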