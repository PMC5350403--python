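"""Single-design evaluation pipeline and the optimizer glue.

One evaluation runs geometry -> admissibility -> composite-beam solve ->
cement fatigue -> shielding/damage metrics.  The intact-femur solution is
design-independent and cached per configuration.  Inadmissible designs
receive a penalized objective (2.0 + constraint violation magnitude) so
that orthogonal arrays always complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fatigue, geometry as geo, metrics, surrogate
from .config import RunConfig, default_config
from .optimizer import VertexSpace

__all__ = ["DesignEvaluation", "evaluate_design", "make_objective",
           "intact_solution", "implanted_solution", "design_space"]

PENALTY_BASE = 2.0


@dataclass
class DesignEvaluation:
    damage_pct: float
    ss_coef: float
    admissible: bool
    constraint_report: geo.ConstraintReport
    reduction: metrics.ReductionProfile | None
    penalty: float            # 0 for admissible designs

    @property
    def penalized(self) -> bool:
        return self.penalty > 0


def intact_solution(cfg: RunConfig | None = None) -> surrogate.StressSamples:
    cfg = cfg or default_config()
    return surrogate.solve_intact(cfg.femur, cfg.load_case, grid=cfg.grid,
                                  load_geometry=cfg.load_geometry)


def implanted_solution(dv: geo.DesignVector, cfg: RunConfig | None = None,
                       stem_material=None) -> surrogate.ImplantedResult:
    cfg = cfg or default_config()
    from .materials import builtin_catalog
    assembly = surrogate.make_assembly(
        dv, femur=cfg.femur, skel_config=cfg.skeleton, canal_profile=cfg.canal,
        stem_material=stem_material or cfg.stem_material_obj(),
        cement=builtin_catalog()[cfg.cement_material])
    return surrogate.solve_implanted(assembly, cfg.load_case, grid=cfg.grid,
                                     load_geometry=cfg.load_geometry,
                                     cement_grid=cfg.cement_grid)


def evaluate_design(dv: geo.DesignVector, cfg: RunConfig | None = None,
                    intact: surrogate.StressSamples | None = None,
                    require_admissible: bool = False) -> DesignEvaluation:
    """Full evaluation of one stem design under the configured conditions."""
    cfg = cfg or default_config()
    report = geo.check_constraints(dv, cfg.canal, cfg.skeleton,
                                   thickness_limits=cfg.thickness_limits)
    if not report.admissible:
        if require_admissible:
            from .errors import ConstraintError
            raise ConstraintError("design is not clinically admissible",
                                  report.violations)
        return DesignEvaluation(0.0, 0.0, False, report, None,
                                penalty=PENALTY_BASE + report.violation_magnitude)
    if intact is None:
        intact = intact_solution(cfg)
    result = implanted_solution(dv, cfg)
    dmg = fatigue.damage_field(result.cement, cfg.sn_curve,
                               design_life=cfg.design_life,
                               sigma_u=cfg.cement_sigma_u)
    damage_pct = fatigue.damage_parameter(dmg)
    ss = metrics.stress_shielding_coefficient(intact, result.bone, mode=cfg.ss_mode)
    assembly_span = (cfg.femur.length - geo.make_skeleton(cfg.skeleton)
                     .station_axial_positions()[3], cfg.femur.length)
    red = metrics.stress_reduction_profile(intact, result.bone, span=assembly_span)
    return DesignEvaluation(damage_pct, ss, True, report, red, penalty=0.0)


def design_space(cfg: RunConfig | None = None) -> VertexSpace:
    cfg = cfg or default_config()
    return VertexSpace.from_bounds(cfg.bounds)


def make_objective(cfg: RunConfig | None = None):
    """Build the optimizer-facing evaluator.

    Returns (evaluator, state, records): the evaluator maps a 20-vector to
    the dynamically normalized objective; ``state`` carries the running
    maxima; ``records`` accumulates one dict per evaluated design for the
    design-of-experiments log.
    """
    cfg = cfg or default_config()
    intact = intact_solution(cfg)
    state = metrics.ObjectiveState()
    records = []

    def evaluator(x: np.ndarray) -> float:
        dv = geo.DesignVector.from_array(x, cfg.bounds)
        ev = evaluate_design(dv, cfg, intact=intact)
        if ev.admissible:
            y = metrics.objective(ev.damage_pct, ev.ss_coef, state)
        else:
            y = ev.penalty
        records.append({
            "design": [float(v) for v in x],
            "admissible": ev.admissible,
            "damage_pct": ev.damage_pct,
            "ss_coef": ev.ss_coef,
            "objective": y,
            "max_damage_pct": state.max_damage_pct,
            "max_ss_coef": state.max_ss_coef,
        })
        return y

    return evaluator, state, records
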