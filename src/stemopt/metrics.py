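"""Stress-shielding coefficient and the combined normalized objective.

The stress-shielding coefficient compares equivalent stresses at the same
preselected femur-surface locations with and without the implant,

    SS = (1 / sigma_av) * sqrt( sum_i (sigma_i - sigma_i')^2 ),

where sigma_av is the mean intact surface stress: nonnegative, zero iff the
fields coincide, invariant to a common stress rescaling, and smaller for
less effective shielding.  (The typeset source formula is ambiguous about
the radical's scope; the root-sum-of-squares reading is the default and a
sum-of-absolute-differences variant is available via ``mode="abs"``.)

The scalarized objective sums the squares of the damage parameter and the
shielding coefficient, each normalized by its running maximum over all
designs evaluated so far in an optimization run (dynamic normalization):
values at the maxima give 2.0, an ideal design gives 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, DegenerateFieldError
from .surrogate import StressSamples

__all__ = ["ObjectiveState", "stress_shielding_coefficient", "objective",
           "stress_reduction_profile", "ReductionProfile"]


def _check_aligned(intact: StressSamples, implanted: StressSamples):
    if not intact.aligned_with(implanted):
        raise AlignmentError(
            f"stress fields are not on the same grid: "
            f"{intact.sigma.shape} vs {implanted.sigma.shape}")


def stress_shielding_coefficient(intact: StressSamples, implanted: StressSamples,
                                 mode: str = "rss") -> float:
    _check_aligned(intact, implanted)
    sigma_av = float(np.mean(intact.sigma))
    if sigma_av <= 0:
        raise DegenerateFieldError("mean intact surface stress is zero")
    diff = intact.sigma - implanted.sigma
    if mode == "rss":
        return float(np.sqrt(np.sum(diff ** 2)) / sigma_av)
    if mode == "abs":
        return float(np.sum(np.abs(diff)) / sigma_av)
    raise ValueError(f"mode must be 'rss' or 'abs', got {mode!r}")


@dataclass
class ObjectiveState:
    """Running normalization maxima over the design-of-experiments log."""

    max_damage_pct: float = 0.0
    max_ss_coef: float = 0.0

    def update(self, damage_pct: float, ss_coef: float):
        self.max_damage_pct = max(self.max_damage_pct, damage_pct)
        self.max_ss_coef = max(self.max_ss_coef, ss_coef)


def objective(damage_pct: float, ss_coef: float, state: ObjectiveState,
              update: bool = True) -> float:
    """(damage / max_damage)^2 + (ss / max_ss)^2 with running maxima.

    The state maxima are updated with the incoming values *before* the
    evaluation, so the result lies in [0, 2].  A term whose running maximum
    is still zero (no design has produced any damage/shielding yet)
    contributes zero.
    """
    if damage_pct < 0 or ss_coef < 0:
        raise ValueError("damage percentage and shielding coefficient must be >= 0")
    if update:
        state.update(damage_pct, ss_coef)
    if damage_pct > state.max_damage_pct or ss_coef > state.max_ss_coef:
        raise ValueError("state maxima must dominate the current values")
    total = 0.0
    if state.max_damage_pct > 0:
        total += (damage_pct / state.max_damage_pct) ** 2
    if state.max_ss_coef > 0:
        total += (ss_coef / state.max_ss_coef) ** 2
    return total


@dataclass(frozen=True)
class ReductionProfile:
    """Per-axial-station mean surface-stress reduction, percent."""

    z: np.ndarray
    reduction_pct: np.ndarray   # per axial station
    overall_pct: float          # ratio-of-means over the selected span


def stress_reduction_profile(intact: StressSamples, implanted: StressSamples,
                             span: tuple | None = None) -> ReductionProfile:
    """100 * (mean intact - mean implanted) / mean intact per axial station.

    Station means are circumferential; the overall value is the reduction of
    the mean stress over all locations in ``span`` (a (z_min, z_max) window,
    default the whole femur).  Ratios of means are used so that locations
    near the bending neutral axis (vanishing intact stress) cannot blow up
    the percentage.
    """
    _check_aligned(intact, implanted)
    mask = np.ones(intact.z.size, bool)
    if span is not None:
        mask = (intact.z >= span[0] - 1e-9) & (intact.z <= span[1] + 1e-9)
        if not mask.any():
            raise DegenerateFieldError("span contains no axial stations")
    m_int = np.mean(intact.sigma, axis=1)
    m_imp = np.mean(implanted.sigma, axis=1)
    if np.any(m_int[mask] <= 0):
        raise DegenerateFieldError("zero mean intact stress inside the span")
    per_station = 100.0 * (m_int - m_imp) / np.where(m_int > 0, m_int, np.nan)
    overall = 100.0 * (1.0 - np.mean(implanted.sigma[mask]) / np.mean(intact.sigma[mask]))
    return ReductionProfile(intact.z.copy(), per_station, float(overall))
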