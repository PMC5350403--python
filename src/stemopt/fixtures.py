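"""Deterministic synthetic generators: surrogate femurs, paired surface
stress fields with a known planted reduction, and cement stress fields with
a planted damaged-node count.  All generators are pure functions of their
parameters and seed, so every metric in the package can be exercised
against known ground truth without any external data.

Fixture stress magnitudes sit in the 1-50 MPa range typical of cement
mantles and loaded cortical surfaces, so the default S-N curve produces a
mix of finite and runout lives.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError
from .fatigue import SNCurve, default_sn_curve
from .surrogate import CementStressField, StressSamples, SurrogateFemur

__all__ = ["make_surrogate_femur", "make_stress_pair", "make_cement_field"]


def make_surrogate_femur(outer_radius: float = 14.0, canal_radius: float = 7.0,
                         length: float = 250.0, seed: int = 0,
                         taper: float = 0.0, n_stations: int = 4) -> SurrogateFemur:
    """Simple (optionally tapered) tube femur.

    ``taper`` is the fractional increase of both radii from the distal to
    the proximal end; radii vary linearly in between.  Raises if the canal
    would reach the outer surface.
    """
    if canal_radius >= outer_radius:
        raise InvalidParameterError("canal radius must be smaller than outer radius")
    f = np.linspace(0.0, 1.0, n_stations)
    scale = 1.0 + taper * f
    return SurrogateFemur(
        length=length,
        stations_z=tuple(f * length),
        outer_radius=tuple(outer_radius * scale),
        canal_radius=tuple(canal_radius * scale),
    )


def make_stress_pair(n_axial: int = 20, n_circ: int = 8, reduction=0.45,
                     noise: float = 0.0, seed: int = 0,
                     base_mpa: float = 10.0):
    """(intact, implanted) surface fields with a planted percent reduction.

    ``reduction`` is a scalar fraction or a per-axial-station array; the
    implanted field is intact * (1 - reduction) plus optional multiplicative
    Gaussian noise of relative scale ``noise``.
    """
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, 250.0, n_axial)
    theta = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    axial = base_mpa * (0.5 + np.linspace(0.0, 1.0, n_axial))[:, None]
    circ = (1.2 + np.abs(np.sin(theta)))[None, :]
    intact = axial * circ
    red = np.broadcast_to(np.asarray(reduction, float), (n_axial,)) \
        if np.ndim(reduction) <= 1 else np.asarray(reduction, float)
    if np.ndim(red) == 0:
        red = np.full(n_axial, float(red))
    implanted = intact * (1.0 - red[:, None])
    if noise > 0:
        implanted = implanted * (1.0 + noise * rng.standard_normal(implanted.shape))
        implanted = np.abs(implanted)
    return (StressSamples(z, theta, intact),
            StressSamples(z, theta, implanted))


def make_cement_field(imax: int = 1000, n_damaged: int = 21,
                      curve: SNCurve | None = None,
                      design_life: float = 2.0e6, sigma_u: float = 70.0,
                      life_ratio: float = 10.0, sigma_m_frac: float = 0.3,
                      seed: int = 0) -> CementStressField:
    """Cement field in which exactly ``n_damaged`` of ``imax`` nodes fail
    before ``design_life``.

    Damaged nodes are given lives design_life / life_ratio, the rest
    design_life * life_ratio (clamped inside the S-N validity range, so
    the planted count is recovered exactly by the fatigue pipeline).  Each
    node carries a mean stress of ``sigma_m_frac * sigma_u``; amplitudes are
    back-computed through the Goodman correction.
    """
    if not (0 <= n_damaged <= imax):
        raise InvalidParameterError("need 0 <= n_damaged <= imax")
    curve = curve or default_sn_curve()
    if design_life / life_ratio <= curve.n_min or design_life * life_ratio >= curve.n_max:
        raise InvalidParameterError("planted lives fall outside the S-N validity range")
    rng = np.random.default_rng(seed)
    lives = np.full(imax, design_life * life_ratio)
    which = rng.permutation(imax)[:n_damaged]
    lives[which] = design_life / life_ratio
    sigma_eq = curve.stress_at(lives)
    sigma_m = np.full(imax, sigma_m_frac * sigma_u)
    sigma_a = sigma_eq * (1.0 - sigma_m / sigma_u)
    z = np.linspace(100.0, 250.0, imax)
    theta = rng.random(imax) * 2.0 * np.pi
    return CementStressField(z, theta, sigma_a, sigma_m)
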