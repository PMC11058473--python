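"""Kinetic parameters of the scanning / reinitiation / queuing model.

Rates are per second, distances in nucleotides, probabilities per dwell.
The defaults are order-of-magnitude literature values for mammalian
initiation (scanning ~5 nt/s, elongation ~4 codons/s); the parameters
the printed reporter data can identify are set by the calibration stage
(see :mod:`atf4queue.calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .scanner import PICFootprintModel

#: per-dwell initiation probability by (codon, Kozak class).  Codons not
#: listed never initiate (the near-cognate set other than CUG contributes
#: negligibly and is off by default).
DEFAULT_P_INIT = {
    "AUG": {"strong": 0.95, "medium": 0.70, "weak": 0.25},
    "CUG": {"strong": 0.25, "medium": 0.15, "weak": 0.08},
}


@dataclass(frozen=True)
class SimulationParams:
    """All kinetic and probabilistic knobs of the simulator."""

    k_load: float = 0.25          # PIC cap-loading rate (1/s)
    v_scan: float = 5.0           # scanning rate (nt/s)
    v_elong: float = 4.0          # elongation rate (codons/s)
    tc_level: float = 1.0         # ternary-complex availability in [0, 1]
    k_tc: float = 0.5             # TC-binding rate at tc_level = 1 (1/s)
    p_init: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_P_INIT.items()})
    p_init_overrides: dict = field(default_factory=dict)  # position -> prob
    p_rei_uorf: float = 0.54      # post-termination resumption, REI-permissive uORFs
    p_rei_stst: float = 0.5       # resumption after a start-stop event
    stst_block: float = 3.0       # PIC slow-down across the start-stop element
    k0_unwind: float = 6.0        # stall release prefactor (1/s)
    dG_scale: float = 4.0         # kcal/mol scale in k_unwind = k0*exp(dG_eff/scale)
    unwind_mult_80S: float = 1.0  # stall-release multiplier for elongating 80S
    m6a_block: float = 4.0        # scanning slow-down over a modified roadblock A
    a326_destab: float = 3.0      # kcal/mol added to a stem dG while its A is modified
    queue_boost: float = 4.0      # initiation-rate multiplier for queue-blocked PICs
    p_tc_at_load: float = 1.0     # probability a cap-loaded PIC already carries TC
    k_term: float = 1.0           # termination dwell rate (1/s)
    pic_footprint: PICFootprintModel = PICFootprintModel()
    footprint_80S: int = 30
    exclusion: bool = True        # steric exclusion on/off (off = cascade limit)
    stress: bool = False          # condition flag: controls methylation state

    def __post_init__(self):
        if min(self.k_load, self.v_scan, self.v_elong, self.k_tc,
               self.k0_unwind, self.k_term) < 0:
            raise ValueError("rates must be >= 0")
        if not (0.0 <= self.tc_level <= 1.0):
            raise ValueError("tc_level must be in [0, 1]")
        for codon, by_ctx in self.p_init.items():
            for ctx, p in by_ctx.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"p_init[{codon}][{ctx}] outside [0, 1]")
        if not (0.0 <= self.p_rei_uorf <= 1.0 and 0.0 <= self.p_rei_stst <= 1.0
                and 0.0 <= self.p_tc_at_load <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")
        if min(self.stst_block, self.m6a_block) < 1.0:
            raise ValueError("slow-down factors must be >= 1")
        if self.footprint_80S < 1:
            raise ValueError("footprints must be >= 1 nt")

    def p_init_at(self, position: int, codon: str, context_label: str) -> float:
        if position in self.p_init_overrides:
            return self.p_init_overrides[position]
        return self.p_init.get(codon, {}).get(context_label, 0.0)

    def k_unwind(self, delta_G_eff: float) -> float:
        import math

        return self.k0_unwind * math.exp(delta_G_eff / self.dG_scale)

    def with_(self, **kw) -> "SimulationParams":
        return replace(self, **kw)
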