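"""Model/Results interface over the library.

``ATF4TranslationModel`` bundles an annotated leader with a kinetic
parameter set, in the style of statsmodels model classes: construct the
model from data, call :meth:`fit` to estimate free parameters against an
expression-ratio table (returning a :class:`CalibrationResults` with
estimates, residuals and a ``summary()``), or call :meth:`simulate` /
:meth:`fold_change` directly for forward runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import calibration, readouts, synthetic
from .calibration import CalibratedParams, TargetTable
from .engine import SimulationResult, simulate
from .params import SimulationParams
from .types import LeaderAnnotation


class ATF4TranslationModel:
    """Ribosome scanning/queuing model of a 5' leader.

    Parameters
    ----------
    leader:
        An annotated leader (defaults to the packaged reference).
    params:
        Baseline kinetic parameters; condition-specific copies are
        derived per run.
    """

    def __init__(self, leader: LeaderAnnotation | None = None,
                 params: SimulationParams | None = None):
        self.leader = leader if leader is not None else synthetic.build_reference_leader()
        self.params = params or SimulationParams()

    @classmethod
    def from_construct(cls, construct_id: str,
                       params: SimulationParams | None = None) -> "ATF4TranslationModel":
        ref = synthetic.build_reference_leader()
        leader = ref if construct_id in ("wt", "reference") else synthetic.apply_construct(
            ref, construct_id
        )
        return cls(leader, params)

    @classmethod
    def from_fasta(cls, path, cds_start: int,
                   params: SimulationParams | None = None) -> "ATF4TranslationModel":
        return cls(synthetic.load_leader_fasta(path, cds_start), params)

    # ------------------------------------------------------------------
    def simulate(self, t_max: float = 1200.0, seed: int = 0, *,
                 stress: bool = False, tc_level: float | None = None,
                 **kw) -> SimulationResult:
        par = self.params.with_(stress=stress)
        if tc_level is not None:
            par = par.with_(tc_level=tc_level)
        return simulate(self.leader, par, t_max=t_max, seed=seed, **kw)

    def simulate_replicates(self, n: int, seed: int = 0, **kw) -> list[SimulationResult]:
        return [self.simulate(seed=seed + k, **kw) for k in range(n)]

    def fold_change(self, calibrated: CalibratedParams, n_replicates: int = 20,
                    seed: int = 0, t_max: float = 2400.0) -> readouts.FoldChange:
        """Stress / non-stress reporter induction of this model's leader
        under a calibrated parameter set."""
        st = [simulate(self.leader, calibrated.params_stress, t_max=t_max, seed=seed + k,
                       record_occupancy=False) for k in range(n_replicates)]
        ns = [simulate(self.leader, calibrated.params_nonstress, t_max=t_max,
                       seed=seed + 10_000 + k, record_occupancy=False)
              for k in range(n_replicates)]
        return readouts.fold_change(st, ns, seed=seed)

    # ------------------------------------------------------------------
    def fit(self, target_table: TargetTable | None = None,
            free=calibration.DEFAULT_FREE, bounds=None, n_reps: int = 5,
            seed: int = 0, **kw) -> "CalibrationResults":
        fitted = calibration.fit_parameters(
            target_table, free=free, bounds=bounds, n_reps=n_reps,
            seed=seed, base=self.params, **kw
        )
        return CalibrationResults(model=self, calibrated=fitted)


@dataclass
class CalibrationResults:
    """Results object wrapping a fitted parameter set."""

    model: ATF4TranslationModel
    calibrated: CalibratedParams

    @property
    def params(self) -> dict:
        return self.calibrated.free_values

    @property
    def loss(self) -> float:
        return self.calibrated.loss

    def residual_table(self):
        return self.calibrated.residual_table()

    def summary(self) -> str:
        c = self.calibrated
        lines = [
            "ATF4 translation model calibration",
            "==================================",
            f"optimizer: {c.optimizer}   evaluations: {c.n_evals}   "
            f"replicates/eval: {c.n_reps}   seed: {c.seed}",
            f"weighted mean squared log-ratio loss: {c.loss:.4f}",
            "",
            "fitted parameters",
            "-----------------",
        ]
        for k, v in c.free_values.items():
            lines.append(f"  {k:18s} {v:10.4g}")
        lines += ["", "residuals (log sim/target)", "-" * 44]
        lines.append(f"  {'construct':14s}{'comparison':18s}{'target':>8s}{'sim':>8s}{'logres':>8s}")
        for con, cmp_, tgt, sim, lr in c.residuals:
            lines.append(f"  {con:14s}{cmp_:18s}{tgt:8.2f}{sim:8.2f}{lr:8.2f}")
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover
        return f"<CalibrationResults loss={self.loss:.4f} params={self.params}>"
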