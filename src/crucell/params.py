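"""Whole-cell model parameters.

Control (normal) values of the remodeled quantities are the printed settings
of the source configuration: G_K1 = 0.238, G_to = 0.618, G_Kr = 0.0488,
G_Ks = 0.0224 mS/µF, RyR2 sensitivity kryr+ = 14 (dimensionless), SERCA pump
concentration Ap = 150 µM, and G_NCX = 1000 µA/µF.  Everything else (rate
constants, volumes, buffers, the fast Na+ current) is RECONSTRUCTED: those
numbers are not printed in the source and were calibrated once so the control
cell sits in the documented qualitative regime (resting RyR open probability
~0, systolic peak open fraction in the 0.1-0.4 range, Ca2+ transient peak near
1 µM).  See docs/methods.md.

Unit conventions (see also docs/methods.md):
* membrane currents in µA/µF, positive outward;
* Ca2+ fluxes in µM/ms, positive into the receiving compartment;
* concentrations in µM (fixed Na+/K+/Ca2+o in mM), volumes in pL, time in ms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .gating import LCCParams, RyRParams

__all__ = ["ModelParams", "control_params", "FARADAY", "RTF"]

FARADAY = 96.485  # C/mmol
RTF = 26.712      # mV at 310 K


@dataclass
class ModelParams:
    # --- printed control settings (remodeled in heart failure) -------------
    G_K1: float = 0.238          # mS/µF
    G_to: float = 0.618          # mS/µF
    G_Kr: float = 0.0488         # mS/µF
    G_Ks: float = 0.0224         # mS/µF
    G_NCX: float = 1000.0        # µA/µF
    Ap_serca: float = 150.0      # µM pump concentration
    ryr: RyRParams = field(default_factory=RyRParams)   # kryr+ = k_plus_scale
    lcc: LCCParams = field(default_factory=LCCParams)

    # --- CRU geometry -------------------------------------------------------
    n_cru: int = 2000            # desk-scale default; full cell uses 20000
    n_cru_reference: int = 20000  # CRU count the whole-cell densities refer to
    n_ryr_per_cru: int = 49
    n_lcc_per_cru: int = 9

    # --- volumes (pL); per-CRU compartments are for one physical CRU -------
    V_myo: float = 20.0
    V_nsr: float = 1.1
    V_jsr_total: float = 0.15    # summed over the reference CRU count
    V_ds_total: float = 0.020    # summed over the reference CRU count

    # --- buffers (rapid-buffering approximation), µM ------------------------
    B_trpn: float = 70.0
    K_trpn: float = 0.6
    B_cmdn: float = 50.0
    K_cmdn: float = 2.38
    B_csqn: float = 10000.0      # junctional SR calsequestrin
    K_csqn: float = 600.0

    # --- Ca2+ transport -----------------------------------------------------
    tau_efflux: float = 0.007    # ms, dyadic subspace -> myoplasm
    tau_refill: float = 9.0      # ms, network SR -> junctional SR
    v_ryr: float = 125.0          # 1/ms, release-flux coefficient per CRU
    serca_Km: float = 0.45       # µM
    serca_hill: float = 2.0
    serca_vp: float = 0.45 / 150.0  # (µM/ms) per µM pump -> Vmax 0.45 µM/ms
    v_leak: float = 2.5e-5       # 1/ms, network SR -> myoplasm passive leak
    G_bCa: float = 0.002         # mS/µF, background Ca2+ current

    # --- reconstructed membrane currents ------------------------------------
    G_Na: float = 4.5            # mS/µF, minimal fast Na+ upstroke current
    G_NaK: float = 0.6           # µA/µF, Na+/K+ pump scale (static Na+/K+)
    G_bNa: float = 0.0019        # mS/µF, Na+ background (diastolic balance)
    ncx_KmNai: float = 87.5      # mM
    ncx_KmCa: float = 1.38       # mM
    ncx_ksat: float = 0.1
    ncx_gamma: float = 0.35
    ncx_alpha: float = 3.2

    # --- fixed ions / physics ----------------------------------------------
    Na_i: float = 10.0           # mM
    Na_o: float = 140.0          # mM
    K_i: float = 138.0           # mM
    K_o: float = 5.4             # mM
    Ca_o: float = 2.0            # mM
    C_m: float = 1.0             # µF/cm²
    cm_total: float = 153.4      # pF, whole-cell capacitance
    temperature: float = 310.0   # K

    # provenance of remodeling scalings already applied (prevents silent
    # double scaling); empty for control
    remodeling_applied: tuple = ()

    def __post_init__(self) -> None:
        for name in ("G_K1", "G_to", "G_Kr", "G_Ks", "G_NCX", "Ap_serca",
                     "V_myo", "V_nsr", "V_jsr_total", "V_ds_total",
                     "tau_efflux", "tau_refill"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cru < 1:
            raise ValueError("n_cru must be >= 1")

    # Whole-cell densities are defined at the reference CRU count; simulating
    # fewer CRUs keeps per-CRU physics identical and weights each simulated
    # CRU by cru_weight when summing to whole-cell quantities.
    @property
    def cru_weight(self) -> float:
        return self.n_cru_reference / self.n_cru

    @property
    def v_jsr(self) -> float:
        """Junctional SR volume of one physical CRU (pL)."""
        return self.V_jsr_total / self.n_cru_reference

    @property
    def v_ds(self) -> float:
        """Dyadic subspace volume of one physical CRU (pL)."""
        return self.V_ds_total / self.n_cru_reference

    @property
    def E_K(self) -> float:
        import math
        return RTF * math.log(self.K_o / self.K_i)

    @property
    def E_Na(self) -> float:
        import math
        return RTF * math.log(self.Na_o / self.Na_i)

    @property
    def current_to_flux(self) -> float:
        """µM/ms of myoplasmic Ca2+ per µA/µF of Ca2+ current (charge 2).

        I (µA/µF) * cm_total (pF) = pA; dividing by 2F (C/mmol) and V_myo (pL)
        lands directly on µM/ms (pA/(C/mmol)/pL = 1e-18 mol/ms / 1e-12 L).
        """
        return self.cm_total / (2.0 * FARADAY * self.V_myo)

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


def control_params(**overrides) -> ModelParams:
    """The control (normal) parameter set, optionally with field overrides."""
    return ModelParams(**overrides)
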