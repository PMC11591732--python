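"""Continuous-time Markov gating schemes for the two dyadic channel species.

Two channel models live here:

* a 3-state ryanodine receptor (RyR2): closed -> open -> refractory -> closed,
  with Ca2+-dependent, cooperative activation of the closed->open step;
* a 6-state L-type Ca2+ channel (LCC) with voltage-dependent activation along a
  linear closed-closed-open chain and a Ca2+-driven "Ca mode" that mirrors the
  normal-mode topology with conduction disabled (Ca-dependent inactivation).

Rates are in 1/ms, dyadic Ca2+ in µM, voltages in mV.  The module also provides
an exact stationary-distribution solver (the test oracle for long-run open
fractions) and a count-based stochastic transition sampler used for clusters of
identical channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "RyRParams",
    "LCCParams",
    "RYR_CLOSED",
    "RYR_OPEN",
    "RYR_REFRACTORY",
    "LCC_OPEN",
    "N_RYR_STATES",
    "N_LCC_STATES",
    "ryr_rate_matrix",
    "lcc_rate_matrix",
    "stationary_distribution",
    "sample_transitions",
    "ryr_open_rate",
]

# State indices.  RyR: C -> O -> R -> C cycle.
RYR_CLOSED, RYR_OPEN, RYR_REFRACTORY = 0, 1, 2
N_RYR_STATES = 3
# LCC: normal mode 0 (deep closed), 1 (closed), 2 (open); Ca mode 3, 4, 5
# mirror 0, 1, 2 with state 5 non-conducting.  State 2 is the only conductor.
LCC_OPEN = 2
N_LCC_STATES = 6

# Maximum per-channel exit probability the fixed-step sampler accepts; callers
# must substep when dt * max|q_ii| exceeds this.
MAX_STEP_HAZARD = 0.2


@dataclass(frozen=True)
class RyRParams:
    """3-state RyR2 scheme parameters.

    ``k_plus_scale`` is the dimensionless sensitivity multiplier on the
    Ca2+-activated opening rate (control value 14; heart failure raises it by
    50%).  Opening follows a Hill function of dyadic Ca2+ with half-activation
    ``K_act`` (µM) and exponent ``eta``.
    """

    k_plus_scale: float = 14.0
    base_rate: float = 0.18       # 1/ms, reconstructed (not printed in source)
    K_act: float = 150.0          # µM
    eta: float = 2.0
    k_close: float = 0.5          # 1/ms
    k_inact: float = 0.06         # 1/ms, open -> refractory
    k_recover: float = 0.004      # 1/ms, refractory -> closed

    def __post_init__(self) -> None:
        if self.k_plus_scale <= 0:
            raise ValueError("k_plus_scale must be > 0")
        if self.eta < 1:
            raise ValueError("eta must be >= 1")
        for name in ("base_rate", "K_act", "k_close", "k_inact", "k_recover"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LCCParams:
    """6-state mode-switching LCC parameters.

    Voltage activation uses saturating logistic rates
    ``alpha0 / (1 + exp(-(v - v_half)/s_alpha))`` (forward) and
    ``beta0 / (1 + exp((v - v_half)/s_beta))`` (backward) along the
    closed-closed-open chain, monotone in v with bounded hazard.
    Normal->Ca-mode entry is linear in dyadic Ca2+ (``gamma0 * ca_ds``); exit
    is ``omega``.  ``g_single`` is the single-channel GHK flux scale (µM/ms of
    subspace Ca2+ per unit driving term); all defaults are reconstructed, not
    printed in the source configuration.
    """

    alpha0: float = 0.16          # 1/ms, saturating forward rate
    beta0: float = 1.1            # 1/ms, saturating backward rate
    s_alpha: float = 7.0          # mV
    s_beta: float = 60.0          # mV
    v_half: float = -15.0         # mV
    gamma0: float = 0.008         # 1/(ms µM)
    omega: float = 0.012          # 1/ms
    g_single: float = 9500.0      # µM/ms subspace flux scale per open channel
    # deterministic voltage-dependent availability (slow inactivation) of
    # conduction, shared by all channels: y_inf = ped + (1-ped)/(1+exp((v-vh)/s))
    y_tau: float = 50.0           # ms
    y_pedestal: float = 0.002
    y_vhalf: float = -42.0        # mV
    y_slope: float = 4.5          # mV
    n_states: int = field(default=N_LCC_STATES)

    def __post_init__(self) -> None:
        if self.n_states != N_LCC_STATES:
            raise ValueError("the LCC scheme is fixed at 6 states")
        for name in ("alpha0", "beta0", "s_alpha", "s_beta", "gamma0", "omega",
                     "g_single"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def activation_rates(self, v: float) -> tuple[float, float]:
        """Forward/backward activation rates (alpha, beta) at voltage ``v``."""
        dv = v - self.v_half
        return (self.alpha0 / (1.0 + np.exp(-dv / self.s_alpha)),
                self.beta0 / (1.0 + np.exp(dv / self.s_beta)))


def ryr_open_rate(ca_ds: float, params: RyRParams) -> float:
    """Ca2+-activated closed->open rate (1/ms) at dyadic Ca2+ ``ca_ds`` (µM)."""
    if ca_ds < 0:
        raise ValueError(f"ca_ds must be >= 0, got {ca_ds}")
    if ca_ds == 0.0:
        return 0.0
    ca_eta = ca_ds ** params.eta
    hill = ca_eta / (ca_eta + params.K_act ** params.eta)
    return params.k_plus_scale * params.base_rate * hill


def ryr_rate_matrix(ca_ds: float, params: RyRParams) -> np.ndarray:
    """3x3 generator for the RyR2 chain at dyadic Ca2+ ``ca_ds`` (µM).

    Rows/columns are ordered (closed, open, refractory).  Off-diagonals are the
    transition rates in 1/ms; each row sums to zero.
    """
    k_open = ryr_open_rate(ca_ds, params)
    q = np.zeros((3, 3))
    q[RYR_CLOSED, RYR_OPEN] = k_open
    q[RYR_OPEN, RYR_CLOSED] = params.k_close
    q[RYR_OPEN, RYR_REFRACTORY] = params.k_inact
    q[RYR_REFRACTORY, RYR_CLOSED] = params.k_recover
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def lcc_rate_matrix(v: float, ca_ds: float, params: LCCParams) -> np.ndarray:
    """6x6 generator for the mode-switching LCC at voltage ``v`` (mV).

    States 0-2 are the normal mode (2 conducting), 3-5 the Ca mode with the
    same voltage topology but no conduction.  Normal->Ca entry from each state
    is ``gamma0 * ca_ds``; return is ``omega``.
    """
    if ca_ds < 0:
        raise ValueError(f"ca_ds must be >= 0, got {ca_ds}")
    if not np.isfinite(v):
        raise ValueError("v must be finite")
    alpha, beta = params.activation_rates(v)
    gamma = params.gamma0 * ca_ds
    q = np.zeros((6, 6))
    for base in (0, 3):
        q[base + 0, base + 1] = 2.0 * alpha
        q[base + 1, base + 0] = beta
        q[base + 1, base + 2] = alpha
        q[base + 2, base + 1] = 2.0 * beta
    for i in range(3):
        q[i, i + 3] = gamma
        q[i + 3, i] = params.omega
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi of a CTMC generator ``q`` (pi @ q = 0).

    Solves the null space of ``q.T`` by dense linear algebra.  Raises
    ``ValueError`` when the chain does not have a unique stationary law
    (reducible or otherwise rank-deficient generator).
    """
    q = np.asarray(q, dtype=float)
    n = q.shape[0]
    if q.shape != (n, n):
        raise ValueError("generator must be square")
    if not np.allclose(q.sum(axis=1), 0.0, atol=1e-9):
        raise ValueError("rows of a generator must sum to zero")
    ns = linalg.null_space(q.T, rcond=1e-10)
    if ns.shape[1] != 1:
        raise ValueError(
            f"generator has a {ns.shape[1]}-dimensional stationary space; "
            "expected an irreducible chain"
        )
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-10):
        raise ValueError("stationary solve produced negative mass")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def sample_transitions(
    counts: np.ndarray,
    q: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance a cluster of identical channels one fixed step of ``dt`` ms.

    ``counts[i]`` channels occupy state ``i``.  Each channel in state ``i``
    leaves with probability ``1 - exp(q_ii * dt)`` and is apportioned among
    destinations ``j`` with probability ``q_ij / |q_ii|`` (multinomial).  Total
    channel number is conserved exactly.

    Raises ``ValueError`` when ``dt * max|q_ii|`` exceeds the step contract
    (0.2); callers must substep instead.
    """
    counts = np.asarray(counts)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    diag = -np.diag(q)
    if dt * diag.max(initial=0.0) > MAX_STEP_HAZARD + 1e-12:
        raise ValueError(
            f"dt*max|q_ii| = {dt * diag.max():.3f} violates the step contract "
            f"(<= {MAX_STEP_HAZARD}); substep the generator"
        )
    new = counts.astype(np.int64).copy()
    n = len(counts)
    for i in range(n):
        k_i = int(counts[i])
        if k_i == 0 or diag[i] == 0.0:
            continue
        p_exit = -np.expm1(-diag[i] * dt)
        movers = rng.binomial(k_i, p_exit)
        if movers == 0:
            continue
        dest_p = q[i].copy()
        dest_p[i] = 0.0
        dest_p = dest_p / diag[i]
        alloc = rng.multinomial(movers, dest_p)
        new[i] -= movers
        new += alloc
    return new
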