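"""Stimulus schedules and heart-failure remodeling.

Pacing protocols are ordered lists of (duration, frequency) segments; a
stimulus fires at each segment's start and then every ``1/frequency`` until the
segment end (exclusive).  The voltage-clamp series is the 0.2 s depolarizing
step family from -40 to +30 mV in 5 mV increments.

Heart-failure remodeling applies the published scalings to a control parameter
set: all four K+ conductances reduced (56/67/20/28%), RyR2 sensitivity +50%,
SERCA pump concentration -50%, NCX +100%.  Each mechanism is an independent
toggle so every condition arm (K+-block only, RyR-hyperphosphorylation,
SERCA/NCX, Ca-handling only, full HF) can be built.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import ModelParams

__all__ = [
    "PacingSegment", "VClampStep", "Protocol", "RemodelingFlags",
    "make_pacing", "make_vclamp", "apply_remodeling",
    "CONDITION_PRESETS", "PROTOCOL_PRESETS", "protocol_preset", "condition_preset",
]

# Fractional changes of Table-style HF remodeling.
K_BLOCK_FRACTIONS = {"G_K1": 0.56, "G_to": 0.67, "G_Kr": 0.20, "G_Ks": 0.28}
RYR_SENS_FACTOR = 1.5
SERCA_FACTOR = 0.5
NCX_FACTOR = 2.0


@dataclass(frozen=True)
class PacingSegment:
    duration: float      # s
    frequency: float     # Hz
    amplitude: float = -52.0   # µA/µF (inward square pulse)
    width: float = 1.0         # ms

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        if self.frequency <= 0:
            raise ValueError("segment frequency must be > 0")


@dataclass(frozen=True)
class VClampStep:
    v_test: float        # mV
    duration: float      # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("step duration must be > 0")


@dataclass(frozen=True)
class Protocol:
    """Typed description of a current-clamp or voltage-clamp experiment."""

    mode: str                                  # "current_clamp" | "voltage_clamp"
    segments: tuple[PacingSegment, ...] = ()
    holding_v: float = -50.0                   # mV (voltage clamp)
    steps: tuple[VClampStep, ...] = ()
    inter_step_interval: float = 5.0           # s recovery at holding potential
    conditioning_beats: int = 5                # 1 Hz beats before the step series
    reset_between_steps: bool = True           # re-instate saved state per step

    def __post_init__(self) -> None:
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.mode == "current_clamp" and not self.segments:
            raise ValueError("current-clamp protocol needs >= 1 pacing segment")
        if self.mode == "voltage_clamp" and not self.steps:
            raise ValueError("voltage-clamp protocol needs a nonempty step list")

    @property
    def duration_ms(self) -> float:
        if self.mode == "current_clamp":
            return 1000.0 * sum(s.duration for s in self.segments)
        return 1000.0 * sum(s.duration for s in self.steps)

    def stimulus_times(self) -> np.ndarray:
        """Stimulus onset times (ms) for a current-clamp protocol.

        A stimulus fires at each segment's start, then at 1/frequency
        intervals until the segment end (exclusive).
        """
        if self.mode != "current_clamp":
            raise ValueError("stimulus_times is defined for current clamp only")
        onsets: list[float] = []
        t0 = 0.0
        for seg in self.segments:
            period = 1000.0 / seg.frequency
            dur = 1000.0 * seg.duration
            n = int(np.ceil(dur / period - 1e-9))
            onsets.extend(t0 + k * period for k in range(n))
            t0 += dur
        return np.asarray(onsets)

    def segment_of(self, t_ms: float) -> PacingSegment:
        t0 = 0.0
        for seg in self.segments:
            t0 += 1000.0 * seg.duration
            if t_ms < t0:
                return seg
        return self.segments[-1]


def make_pacing(segments) -> Protocol:
    """Build a current-clamp pacing protocol from (duration_s, frequency_Hz)
    tuples or ready-made :class:`PacingSegment` objects."""
    if not segments:
        raise ValueError("pacing protocol needs at least one segment")
    built = tuple(
        seg if isinstance(seg, PacingSegment) else PacingSegment(*seg)
        for seg in segments
    )
    return Protocol(mode="current_clamp", segments=built)


def make_vclamp(
    v_start: float = -40.0,
    v_stop: float = 30.0,
    dv: float = 5.0,
    step_duration: float = 0.2,
    holding_v: float = -50.0,
    **kw,
) -> Protocol:
    """The depolarizing step series: 0.2 s steps from -40 to +30 mV by 5 mV."""
    n = int(round((v_stop - v_start) / dv)) + 1
    steps = tuple(VClampStep(v_start + i * dv, step_duration) for i in range(n))
    return Protocol(mode="voltage_clamp", steps=steps, holding_v=holding_v, **kw)


@dataclass(frozen=True)
class RemodelingFlags:
    """Independent heart-failure mechanism toggles."""

    k_block: bool = False     # reduce all four K+ conductances
    ryr_hyper: bool = False   # kryr+ x1.5
    serca_down: bool = False  # Ap x0.5
    ncx_up: bool = False      # G_NCX x2

    def active(self) -> tuple[str, ...]:
        return tuple(n for n in ("k_block", "ryr_hyper", "serca_down", "ncx_up")
                     if getattr(self, n))


# Condition arms of the study: in every arm except NORMAL and HF_CA_ONLY the
# K+ downregulation is included.
CONDITION_PRESETS: dict[str, RemodelingFlags] = {
    "NORMAL": RemodelingFlags(),
    "HF_FULL": RemodelingFlags(k_block=True, ryr_hyper=True, serca_down=True,
                               ncx_up=True),
    "HF_K_ONLY": RemodelingFlags(k_block=True),
    "HF_RYR": RemodelingFlags(k_block=True, ryr_hyper=True),
    "HF_SERCA_NCX": RemodelingFlags(k_block=True, serca_down=True, ncx_up=True),
    "HF_CA_ONLY": RemodelingFlags(ryr_hyper=True, serca_down=True, ncx_up=True),
}


def condition_preset(name: str) -> RemodelingFlags:
    key = name.upper().replace("-", "_")
    if key == "HF":
        key = "HF_FULL"
    if key not in CONDITION_PRESETS:
        raise ValueError(f"unknown condition {name!r}; "
                         f"known: {sorted(CONDITION_PRESETS)}")
    return CONDITION_PRESETS[key]


def apply_remodeling(base: ModelParams, flags: RemodelingFlags) -> ModelParams:
    """Return a remodeled copy of ``base``; the input is not mutated.

    Re-applying to already-remodeled parameters raises, preventing silent
    double scaling.
    """
    already = set(base.remodeling_applied) & set(flags.active())
    if already:
        raise ValueError(
            f"remodeling {sorted(already)} already applied to these parameters"
        )
    out = base
    if flags.k_block:
        out = out.replace(**{
            name: getattr(out, name) * (1.0 - frac)
            for name, frac in K_BLOCK_FRACTIONS.items()
        })
    if flags.ryr_hyper:
        out = out.replace(ryr=replace(
            out.ryr, k_plus_scale=out.ryr.k_plus_scale * RYR_SENS_FACTOR))
    if flags.serca_down:
        out = out.replace(Ap_serca=out.Ap_serca * SERCA_FACTOR)
    if flags.ncx_up:
        out = out.replace(G_NCX=out.G_NCX * NCX_FACTOR)
    return out.replace(
        remodeling_applied=base.remodeling_applied + flags.active())


def protocol_preset(name: str) -> Protocol:
    key = name.lower().replace("_", "-")
    if key not in PROTOCOL_PRESETS:
        raise ValueError(f"unknown protocol {name!r}; "
                         f"known: {sorted(PROTOCOL_PRESETS)}")
    return PROTOCOL_PRESETS[key]()


PROTOCOL_PRESETS = {
    "steady1hz": lambda: make_pacing([(20.0, 1.0)]),
    "slow0p5hz": lambda: make_pacing([(20.0, 0.5)]),
    "slow-fast-slow": lambda: make_pacing([(15.0, 0.5), (15.0, 2.5),
                                           (15.0, 0.5)]),
    "vclamp": make_vclamp,
}
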