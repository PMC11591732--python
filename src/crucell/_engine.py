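"""Numba kernel for the hybrid stochastic-deterministic whole-cell model.

Layout notes
------------
* All model constants are packed into a flat float64 vector ``P`` (indices
  below) so the kernel never recompiles when parameters change.
* Each CRU owns an independent counter-seeded xorshift64* RNG stream, so the
  stream assigned to CRU ``i`` does not depend on ``n_cru``.
* Channel occupancies are stored as float64 but hold exact small integers in
  stochastic mode; the deterministic mean-field mode propagates expected
  occupancies through the same code path.
* Gating uses fixed-probability substepping with the per-channel hazard bound
  ``dt_sub * max|q_ii| <= 0.2``; the dyadic Ca2+ balance is advanced with an
  exact exponential update of its linear ODE, and the time-averaged dyadic
  concentration over each substep is used for all flux bookkeeping so that
  compartment transfers stay consistent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- indices into the packed parameter vector ------------------------------
iG_K1, iG_to, iG_Kr, iG_Ks, iG_NCX, iAp = 0, 1, 2, 3, 4, 5
iKCO_MAX, iKACT_ETA, iETA, iK_CLOSE, iK_INACT, iK_RECOVER = 6, 7, 8, 9, 10, 11
iALPHA0, iBETA0, iS_ALPHA, iS_BETA, iV_HALF, iGAMMA0, iOMEGA, iJSCALE = (
    12, 13, 14, 15, 16, 17, 18, 19)
iV_DS, iV_JSR, iV_MYO, iV_NSR, iW = 20, 21, 22, 23, 24
iB_TRPN, iK_TRPN, iB_CMDN, iK_CMDN, iB_CSQN, iK_CSQN = 25, 26, 27, 28, 29, 30
iTAU_EFF, iTAU_REFILL, iV_RYR, iSERCA_KM, iSERCA_H, iSERCA_VP = (
    31, 32, 33, 34, 35, 36)
iV_LEAK, iG_BCA, iG_NA = 37, 38, 39
iNCX_DEN_NA, iNCX_DEN_CA, iNCX_KSAT, iNCX_GAMMA = 40, 41, 42, 43
iNA_I, iNA_O, iCA_O, iE_K, iE_NA, iC2F, iRTF = 44, 45, 46, 47, 48, 49, 50
iN_RYR, iN_LCC, iK_O, iNCX_ALPHA = 51, 52, 53, 54
iY_TAU, iY_PED, iY_VHALF, iY_SLOPE = 55, 56, 57, 58
iG_NAK, iG_BNA = 59, 60
NP_PARAMS = 61

# --- global state vector indices -------------------------------------------
gV, gCA_MYO, gCA_NSR, gM, gH, gR, gS, gXR, gXS, gY, gT = range(11)
NG = 11

# --- recorded fields --------------------------------------------------------
FIELDS = ("t", "v", "ca_myo", "ca_nsr", "ca_jsr", "po_ryr", "po_lcc",
          "I_CaL", "I_NCX", "I_K1", "I_to", "I_Kr", "I_Ks", "I_Na", "I_bCa",
          "I_stim", "J_rel", "J_up", "J_lcc", "J_leak", "J_eff", "I_NaK",
          "I_bNa")
NF = len(FIELDS)
(fT, fV, fCA_MYO, fCA_NSR, fCA_JSR, fPO_RYR, fPO_LCC, fI_CAL, fI_NCX, fI_K1,
 fI_TO, fI_KR, fI_KS, fI_NA, fI_BCA, fI_STIM, fJ_REL, fJ_UP, fJ_LCC, fJ_LEAK,
 fJ_EFF, fI_NAK, fI_BNA) = range(NF)

MAX_HAZARD = 0.2

_U64 = np.uint64
_MIX1 = _U64(0x9E3779B97F4A7C15)
_MIX2 = _U64(0xBF58476D1CE4E5B9)
_MIX3 = _U64(0x94D049BB133111EB)
_STAR = _U64(0x2545F4914F6CDD1D)


def seed_streams(seed: int, n_cru: int) -> np.ndarray:
    """Counter-based per-CRU RNG stream seeds (splitmix64 of seed, index)."""
    idx = np.arange(1, n_cru + 1, dtype=np.uint64)
    z = np.uint64(seed & 0x7FFFFFFF) + idx * _MIX1
    z = (z ^ (z >> np.uint64(30))) * _MIX2
    z = (z ^ (z >> np.uint64(27))) * _MIX3
    z = z ^ (z >> np.uint64(31))
    z[z == 0] = 0x1234567
    return z


@njit(cache=True, inline="always")
def _rand_u(states, i):
    x = states[i]
    x ^= x << _U64(13)
    x ^= x >> _U64(7)
    x ^= x << _U64(17)
    states[i] = x
    return float((x * _STAR) >> _U64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _binom(states, i, n, p):
    """Binomial(n, p) by CDF inversion; exact for the small n, p<=0.2 used."""
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    u = _rand_u(states, i)
    q = 1.0 - p
    f = q ** n
    acc = f
    c = p / q
    k = 0
    while u > acc and k < n:
        k += 1
        f *= c * (n - k + 1) / k
        acc += f
    return k


@njit(cache=True, inline="always")
def _p_exit(q, dt):
    x = q * dt
    if x < 1e-3:
        return x
    return -np.expm1(-x)


@njit(cache=True)
def _xk1_inf(v, e_k):
    # inward rectification: full conductance near E_K, rolled off above it
    return 0.008 + 0.992 / (1.0 + np.exp((v - e_k - 35.0) / 16.0))


@njit(cache=True)
def run_kernel(P, dt, n_steps, stride,
               mode, stim_t, stim_amp, stim_w, clamp_t, clamp_v,
               ryr, lcc, ca_ds, ca_jsr, g, rng_states,
               stochastic, sl_enabled, ina_enabled,
               rec, rec_cru_idx, rec_cru):
    """Advance the cell ``n_steps`` of ``dt`` ms, recording every ``stride``.

    Returns 0 on success, 1 on NaN membrane potential, 2 on a negative
    concentration; on failure ``g[gT]`` holds the failure time.
    """
    n_cru = ca_ds.shape[0]
    n_ryr = P[iN_RYR]
    n_lcc = P[iN_LCC]
    e_k = P[iE_K]
    e_na = P[iE_NA]
    rtf = P[iRTF]
    c2f = P[iC2F]
    w = P[iW]
    v_ds = P[iV_DS]
    v_jsr = P[iV_JSR]
    v_myo = P[iV_MYO]
    v_nsr = P[iV_NSR]
    sqrt_ko = np.sqrt(P[iK_O] / 5.4)
    k_close = P[iK_CLOSE]
    k_inact = P[iK_INACT]
    k_recover = P[iK_RECOVER]
    q_open_exit = k_close + k_inact
    p_close_frac = k_close / q_open_exit if q_open_exit > 0 else 0.0
    omega = P[iOMEGA]
    gamma0 = P[iGAMMA0]
    eta = P[iETA]
    kact_eta = P[iKACT_ETA]
    kco_max = P[iKCO_MAX]
    tau_eff = P[iTAU_EFF]
    tau_refill = P[iTAU_REFILL]
    vryr = P[iV_RYR]
    n_rec_cru = rec_cru_idx.shape[0]

    stim_ptr = 0
    clamp_ptr = 0
    n_stim = stim_t.shape[0]
    n_clamp = clamp_t.shape[0]

    for step in range(n_steps):
        t = g[gT]
        v = g[gV]
        ca_myo = g[gCA_MYO]
        ca_nsr = g[gCA_NSR]

        # --- drive -----------------------------------------------------------
        i_stim = 0.0
        if mode == 0:
            while stim_ptr + 1 < n_stim and t >= stim_t[stim_ptr + 1] - 1e-9:
                stim_ptr += 1
            if n_stim > 0 and t >= stim_t[stim_ptr] - 1e-9 and \
                    t < stim_t[stim_ptr] + stim_w[stim_ptr] - 1e-9:
                i_stim = stim_amp[stim_ptr]
        else:
            while clamp_ptr + 1 < n_clamp and t >= clamp_t[clamp_ptr + 1] - 1e-9:
                clamp_ptr += 1
            v = clamp_v[clamp_ptr]
            g[gV] = v

        # --- per-step voltage-dependent scalars ------------------------------
        dv = v - P[iV_HALF]
        alpha = P[iALPHA0] / (1.0 + np.exp(-dv / P[iS_ALPHA]))
        beta = P[iBETA0] / (1.0 + np.exp(dv / P[iS_BETA]))

        # GHK single-channel LCC flux, linear in dyadic Ca2+:
        #   J_in = a_v - b_v * ca_ds   (µM/ms referred to subspace volume)
        u = 2.0 * v / rtf
        if abs(u) < 1e-6:
            c0 = 1.0 - 0.5 * u
        else:
            c0 = u / np.expm1(u)
        # slow voltage-dependent availability of LCC conduction (HH gate y)
        jsc = P[iJSCALE] * g[gY] if sl_enabled == 1 else 0.0
        a_v = jsc * c0 * 0.341 * P[iCA_O]
        b_v = jsc * c0 * np.exp(u) * 1.0e-3

        # --- membrane currents from the current state -------------------------
        xk1 = _xk1_inf(v, e_k)
        i_k1 = P[iG_K1] * sqrt_ko * xk1 * (v - e_k)
        i_to = P[iG_to] * g[gR] * g[gS] * (v - e_k)
        xr2 = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
        i_kr = P[iG_Kr] * sqrt_ko * g[gXR] * xr2 * (v - e_k)
        i_ks = P[iG_Ks] * g[gXS] * g[gXS] * (v - e_k)
        i_na = 0.0
        if ina_enabled == 1 and mode == 0:
            i_na = P[iG_NA] * g[gM] ** 3 * g[gH] * (v - e_na)
        # static Na+/K+ pump (fixed intracellular Na+) and Na+ background
        uu0 = v / rtf
        i_nak = P[iG_NAK] / (1.0 + 0.1245 * np.exp(-0.1 * uu0) +
                             0.0353 * np.exp(-uu0))
        i_bna = P[iG_BNA] * (v - e_na)

        i_ncx = 0.0
        i_bca = 0.0
        if sl_enabled == 1:
            uu = v / rtf
            cai_mm = ca_myo * 1.0e-3
            e1 = np.exp(P[iNCX_GAMMA] * uu)
            e2 = np.exp((P[iNCX_GAMMA] - 1.0) * uu)
            num = (e1 * P[iNA_I] ** 3 * P[iCA_O] -
                   e2 * P[iNCX_ALPHA] * P[iNA_O] ** 3 * cai_mm)
            den = (P[iNCX_DEN_NA] * P[iNCX_DEN_CA] *
                   (1.0 + P[iNCX_KSAT] * e2))
            i_ncx = P[iG_NCX] * num / den
            e_ca = 0.5 * rtf * np.log(P[iCA_O] * 1.0e3 / ca_myo)
            i_bca = P[iG_BCA] * (v - e_ca)

        # --- CRU sweep --------------------------------------------------------
        eff_sum = 0.0      # subspace -> myoplasm, µM*pL/ms (one physical CRU)
        rel_sum = 0.0      # JSR -> subspace release
        lcc_sum = 0.0      # sarcolemma -> subspace (LCC)
        refill_sum = 0.0   # NSR -> JSR
        open_ryr = 0.0
        open_lcc = 0.0
        jsr_tot = 0.0

        for ic in range(n_cru):
            ca = ca_ds[ic]
            jsr = ca_jsr[ic]
            r0 = ryr[ic, 0]
            r1 = ryr[ic, 1]
            r2 = ryr[ic, 2]
            l0 = lcc[ic, 0]
            l1 = lcc[ic, 1]
            l2 = lcc[ic, 2]
            l3 = lcc[ic, 3]
            l4 = lcc[ic, 4]
            l5 = lcc[ic, 5]

            # substep count from the worst-case exit hazard at current ca
            ca_eta = ca ** eta
            kco = kco_max * ca_eta / (ca_eta + kact_eta)
            gam = gamma0 * ca
            qmax = kco
            if q_open_exit > qmax:
                qmax = q_open_exit
            q_l = 2.0 * alpha + gam
            if q_l > qmax:
                qmax = q_l
            q_l = alpha + beta + gam
            if q_l > qmax:
                qmax = q_l
            q_l = 2.0 * beta + omega
            if q_l > qmax:
                qmax = q_l
            q_l = alpha + beta + omega
            if q_l > qmax:
                qmax = q_l
            nsub = int(dt * qmax / MAX_HAZARD) + 1
            dts = dt / nsub

            eff_c = 0.0
            rel_c = 0.0
            lcc_c = 0.0
            refill_c = 0.0

            for _ in range(nsub):
                # rates at current subspace Ca
                ca_eta = ca ** eta
                kco = kco_max * ca_eta / (ca_eta + kact_eta)
                gam = gamma0 * ca

                if stochastic == 1:
                    # RyR transitions (synchronous update)
                    mc = _binom(rng_states, ic, int(r0), _p_exit(kco, dts))
                    mo = _binom(rng_states, ic, int(r1),
                                _p_exit(q_open_exit, dts))
                    mo_c = _binom(rng_states, ic, mo, p_close_frac)
                    mr = _binom(rng_states, ic, int(r2),
                                _p_exit(k_recover, dts))
                    r0 += mr + mo_c - mc
                    r1 += mc - mo
                    r2 += (mo - mo_c) - mr

                    # LCC transitions
                    q0 = 2.0 * alpha + gam
                    m0 = _binom(rng_states, ic, int(l0), _p_exit(q0, dts))
                    m0_a = _binom(rng_states, ic, m0,
                                  2.0 * alpha / q0) if q0 > 0 else 0
                    q1 = beta + alpha + gam
                    m1 = _binom(rng_states, ic, int(l1), _p_exit(q1, dts))
                    m1_b = _binom(rng_states, ic, m1,
                                  beta / q1) if q1 > 0 else 0
                    rest = m1 - m1_b
                    m1_a = _binom(rng_states, ic, rest,
                                  alpha / (alpha + gam)) if rest > 0 else 0
                    q2 = 2.0 * beta + gam
                    m2 = _binom(rng_states, ic, int(l2), _p_exit(q2, dts))
                    m2_b = _binom(rng_states, ic, m2,
                                  2.0 * beta / q2) if q2 > 0 else 0
                    q3 = 2.0 * alpha + omega
                    m3 = _binom(rng_states, ic, int(l3), _p_exit(q3, dts))
                    m3_a = _binom(rng_states, ic, m3,
                                  2.0 * alpha / q3) if q3 > 0 else 0
                    q4 = beta + alpha + omega
                    m4 = _binom(rng_states, ic, int(l4), _p_exit(q4, dts))
                    m4_b = _binom(rng_states, ic, m4,
                                  beta / q4) if q4 > 0 else 0
                    rest4 = m4 - m4_b
                    m4_a = _binom(rng_states, ic, rest4,
                                  alpha / (alpha + omega)) if rest4 > 0 else 0
                    q5 = 2.0 * beta + omega
                    m5 = _binom(rng_states, ic, int(l5), _p_exit(q5, dts))
                    m5_b = _binom(rng_states, ic, m5,
                                  2.0 * beta / q5) if q5 > 0 else 0

                    l0 += m1_b + (m3 - m3_a) - m0
                    l1 += m0_a + m2_b + (m4 - m4_b - m4_a) - m1
                    l2 += m1_a + (m5 - m5_b) - m2
                    l3 += (m0 - m0_a) + m4_b - m3
                    l4 += m1 - m1_b - m1_a
                    l4 += m3_a + m5_b - m4
                    l5 += (m2 - m2_b) + m4_a - m5
                else:
                    # mean-field: expected movers, fractional allocation
                    mc = r0 * _p_exit(kco, dts)
                    mo = r1 * _p_exit(q_open_exit, dts)
                    mo_c = mo * p_close_frac
                    mr = r2 * _p_exit(k_recover, dts)
                    r0 += mr + mo_c - mc
                    r1 += mc - mo
                    r2 += (mo - mo_c) - mr

                    q0 = 2.0 * alpha + gam
                    m0 = l0 * _p_exit(q0, dts)
                    f0 = 2.0 * alpha / q0 if q0 > 0 else 0.0
                    q1 = beta + alpha + gam
                    m1 = l1 * _p_exit(q1, dts)
                    f1b = beta / q1 if q1 > 0 else 0.0
                    f1a = alpha / q1 if q1 > 0 else 0.0
                    q2 = 2.0 * beta + gam
                    m2 = l2 * _p_exit(q2, dts)
                    f2b = 2.0 * beta / q2 if q2 > 0 else 0.0
                    q3 = 2.0 * alpha + omega
                    m3 = l3 * _p_exit(q3, dts)
                    f3a = 2.0 * alpha / q3 if q3 > 0 else 0.0
                    q4 = beta + alpha + omega
                    m4 = l4 * _p_exit(q4, dts)
                    f4b = beta / q4 if q4 > 0 else 0.0
                    f4a = alpha / q4 if q4 > 0 else 0.0
                    q5 = 2.0 * beta + omega
                    m5 = l5 * _p_exit(q5, dts)
                    f5b = 2.0 * beta / q5 if q5 > 0 else 0.0

                    l0n = l0 + m1 * f1b + m3 * (1.0 - f3a) - m0
                    l1n = l1 + m0 * f0 + m2 * f2b + m4 * (1.0 - f4b - f4a) - m1
                    l2n = l2 + m1 * f1a + m5 * (1.0 - f5b) - m2
                    l3n = l3 + m0 * (1.0 - f0) + m4 * f4b - m3
                    l4n = (l4 + m1 * (1.0 - f1b - f1a) + m3 * f3a +
                           m5 * f5b - m4)
                    l5n = l5 + m2 * (1.0 - f2b) + m4 * f4a - m5
                    l0, l1, l2, l3, l4, l5 = l0n, l1n, l2n, l3n, l4n, l5n

                # --- dyadic Ca2+: exact exponential update ---------------
                vr_f = vryr * r1 / n_ryr
                lam = vr_f + b_v * l2 + 1.0 / tau_eff
                src = vr_f * jsr + a_v * l2 + ca_myo / tau_eff
                ca_inf = src / lam
                ca_new = ca_inf + (ca - ca_inf) * np.exp(-lam * dts)
                ca_mean = ca_inf + (ca - ca_new) / (lam * dts)

                rel = vr_f * (jsr - ca_mean)
                eff_c += ((ca_mean - ca_myo) / tau_eff) * dts
                rel_c += rel * dts
                lcc_c += (a_v - b_v * ca_mean) * l2 * dts

                # --- junctional SR (explicit Euler, rapid CSQN buffer) ----
                refill = (ca_nsr - jsr) / tau_refill
                kc = P[iK_CSQN]
                beta_jsr = 1.0 / (1.0 + P[iB_CSQN] * kc / ((kc + jsr) *
                                                           (kc + jsr)))
                jsr += beta_jsr * (refill - rel * v_ds / v_jsr) * dts
                refill_c += refill * dts
                ca = ca_new

            ca_ds[ic] = ca
            ca_jsr[ic] = jsr
            ryr[ic, 0] = r0
            ryr[ic, 1] = r1
            ryr[ic, 2] = r2
            lcc[ic, 0] = l0
            lcc[ic, 1] = l1
            lcc[ic, 2] = l2
            lcc[ic, 3] = l3
            lcc[ic, 4] = l4
            lcc[ic, 5] = l5

            eff_sum += eff_c / dt * v_ds
            rel_sum += rel_c / dt * v_ds
            lcc_sum += lcc_c / dt * v_ds
            refill_sum += refill_c / dt * v_jsr
            open_ryr += r1
            open_lcc += l2
            jsr_tot += jsr

        # --- whole-cell fluxes and currents ----------------------------------
        j_eff = eff_sum * w / v_myo          # subspace -> myoplasm, µM/ms
        j_rel = rel_sum * w / v_myo          # SR release referred to myoplasm
        j_lcc = lcc_sum * w / v_myo          # trans-sarcolemmal trigger flux
        i_cal = -j_lcc / c2f

        ca_h = ca_myo ** P[iSERCA_H]
        km_h = P[iSERCA_KM] ** P[iSERCA_H]
        j_up = P[iSERCA_VP] * P[iAp] * ca_h / (ca_h + km_h)
        j_leak = P[iV_LEAK] * (ca_nsr - ca_myo)

        # --- record (state at step start, fluxes over this step) --------------
        if step % stride == 0:
            k = step // stride
            rec[k, fT] = t
            rec[k, fV] = v
            rec[k, fCA_MYO] = ca_myo
            rec[k, fCA_NSR] = ca_nsr
            rec[k, fCA_JSR] = jsr_tot / n_cru
            rec[k, fPO_RYR] = open_ryr / (n_cru * n_ryr)
            rec[k, fPO_LCC] = open_lcc / (n_cru * n_lcc)
            rec[k, fI_CAL] = i_cal
            rec[k, fI_NCX] = i_ncx
            rec[k, fI_K1] = i_k1
            rec[k, fI_TO] = i_to
            rec[k, fI_KR] = i_kr
            rec[k, fI_KS] = i_ks
            rec[k, fI_NA] = i_na
            rec[k, fI_BCA] = i_bca
            rec[k, fI_STIM] = i_stim
            rec[k, fJ_REL] = j_rel
            rec[k, fJ_UP] = j_up
            rec[k, fJ_LCC] = j_lcc
            rec[k, fJ_LEAK] = j_leak
            rec[k, fJ_EFF] = j_eff
            rec[k, fI_NAK] = i_nak
            rec[k, fI_BNA] = i_bna
            for jj in range(n_rec_cru):
                rec_cru[k, jj] = ca_ds[rec_cru_idx[jj]]

        # --- global concentration and gate updates ----------------------------
        kt = P[iK_TRPN]
        kcm = P[iK_CMDN]
        beta_myo = 1.0 / (1.0 + P[iB_TRPN] * kt / ((kt + ca_myo) *
                                                   (kt + ca_myo)) +
                          P[iB_CMDN] * kcm / ((kcm + ca_myo) *
                                              (kcm + ca_myo)))
        j_sl = (-i_bca + 2.0 * i_ncx) * c2f
        g[gCA_MYO] = ca_myo + beta_myo * (j_eff - j_up + j_leak + j_sl) * dt
        g[gCA_NSR] = ca_nsr + ((j_up - j_leak) * v_myo -
                               refill_sum * w) / v_nsr * dt

        # Rush-Larsen gate updates
        m_inf = 1.0 / (1.0 + np.exp(-(v + 40.0) / 6.0))
        tau_m = 0.2
        h_inf = 1.0 / (1.0 + np.exp((v + 68.0) / 6.5))
        tau_h = 0.7 + 5.0 * np.exp(-((v + 60.0) / 20.0) ** 2)
        r_inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
        tau_r = 0.5 + 8.0 * np.exp(-((v + 40.0) ** 2) / 1800.0)
        s_inf = 0.035 + 0.965 / (1.0 + np.exp((v + 20.0) / 5.0))
        tau_s = (85.0 * np.exp(-((v + 45.0) ** 2) / 320.0) +
                 6.0 / (1.0 + np.exp((v - 15.0) / 4.5)) + 2.5)
        xr_inf = 1.0 / (1.0 + np.exp(-(v + 26.0) / 7.0))
        tau_xr = (450.0 / (1.0 + np.exp(-(v + 45.0) / 10.0)) *
                  6.0 / (1.0 + np.exp((v + 30.0) / 11.5)))
        xs_inf = 1.0 / (1.0 + np.exp(-(v + 5.0) / 14.0))
        tau_xs = 250.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0)) + 60.0

        g[gM] = m_inf + (g[gM] - m_inf) * np.exp(-dt / tau_m)
        g[gH] = h_inf + (g[gH] - h_inf) * np.exp(-dt / tau_h)
        g[gR] = r_inf + (g[gR] - r_inf) * np.exp(-dt / tau_r)
        g[gS] = s_inf + (g[gS] - s_inf) * np.exp(-dt / tau_s)
        g[gXR] = xr_inf + (g[gXR] - xr_inf) * np.exp(-dt / tau_xr)
        g[gXS] = xs_inf + (g[gXS] - xs_inf) * np.exp(-dt / tau_xs)
        y_inf = P[iY_PED] + (1.0 - P[iY_PED]) / (1.0 + np.exp((v - P[iY_VHALF]) / P[iY_SLOPE]))
        g[gY] = y_inf + (g[gY] - y_inf) * np.exp(-dt / P[iY_TAU])

        if mode == 0:
            i_total = (i_k1 + i_to + i_kr + i_ks + i_na + i_bca + i_ncx +
                       i_cal + i_nak + i_bna + i_stim)
            g[gV] = v - i_total * dt

        g[gT] = t + dt

        if not np.isfinite(g[gV]):
            return 1
        if g[gCA_MYO] < 0.0 or g[gCA_NSR] < 0.0:
            return 2

    return 0


@njit(cache=True)
def simulate_cluster_path(q, counts0, dt, n_steps, seed):
    """Fixed-step CTMC path of one channel cluster; returns time-averaged
    state occupancy (fraction of channel-time per state).

    Independent oracle support: uses the same binomial substep sampling as the
    cell kernel but on a frozen generator.
    """
    n = q.shape[0]
    counts = counts0.astype(np.float64).copy()
    occ = np.zeros(n)
    states = np.empty(1, dtype=np.uint64)
    states[0] = np.uint64(seed * 2654435761 + 1)
    total = 0.0
    for c in range(n):
        total += counts[c]
    for _ in range(n_steps):
        moves = np.zeros(n)
        for i_s in range(n):
            k_i = int(counts[i_s])
            if k_i == 0:
                continue
            q_exit = -q[i_s, i_s]
            if q_exit <= 0.0:
                continue
            m = _binom(states, 0, k_i, _p_exit(q_exit, dt))
            if m == 0:
                continue
            moves[i_s] -= m
            remaining = m
            p_left = 1.0
            for j_s in range(n):
                if j_s == i_s or remaining == 0:
                    continue
                frac = q[i_s, j_s] / q_exit
                if frac <= 0.0:
                    continue
                if frac >= p_left:
                    alloc = remaining
                else:
                    alloc = _binom(states, 0, remaining, frac / p_left)
                moves[j_s] += alloc
                remaining -= alloc
                p_left -= frac
        for c in range(n):
            counts[c] += moves[c]
            occ[c] += counts[c]
    return occ / (n_steps * total)
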