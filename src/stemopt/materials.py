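"""Material catalogs for homogeneous and functionally graded stems, cement and bone.

All moduli are stored in GPa; stresses elsewhere in the package are MPa
(conversion factor 1 GPa = 1000 MPa is applied inside the solver).
Poisson's ratio is carried for completeness; the one-dimensional beam
surrogate never uses it, but imported three-dimensional stress fields may.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["Material", "FGMLayout", "builtin_catalog", "get_material",
           "default_fgm_layout", "modulus_at", "FGM_MODULI_GPA"]

#: Layer-wise elastic moduli of the default functionally graded stem,
#: numbered from the proximal layer (covering the proximal cement region,
#: stiffest) to the distal tip layer (most compliant).
FGM_MODULI_GPA = (120.0, 110.0, 90.0, 80.0, 70.0, 60.0, 50.0, 40.0, 30.0, 20.0, 10.0)


@dataclass(frozen=True)
class Material:
    """Linear-elastic isotropic material.

    ultimate_strength (MPa) is only required for the cement, where it feeds
    the Goodman mean-stress correction.
    """

    name: str
    elastic_modulus: float  # GPa
    poisson_ratio: float = 0.3
    ultimate_strength: float | None = None  # MPa

    def __post_init__(self):
        if not self.elastic_modulus > 0:
            raise InvalidParameterError(
                f"elastic modulus must be positive, got {self.elastic_modulus}")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise InvalidParameterError(
                f"Poisson ratio must be in (0, 0.5), got {self.poisson_ratio}")

    @property
    def modulus_mpa(self) -> float:
        return self.elastic_modulus * 1e3


def builtin_catalog() -> dict[str, Material]:
    """Built-in catalog: cortical bone, PMMA bone cement and Ti-6Al-4V.

    The PMMA ultimate (compressive/flexural) strength of 70 MPa is a typical
    literature value for surgical bone cement; it is configurable wherever a
    Goodman correction is performed.
    """
    mats = [
        Material("bone", 18.6, 0.3),
        Material("pmma", 2.28, 0.3, ultimate_strength=70.0),
        Material("ti6al4v", 110.0, 0.3),
    ]
    return {m.name: m for m in mats}


def get_material(name: str) -> Material:
    catalog = builtin_catalog()
    try:
        return catalog[name.lower()]
    except KeyError:
        raise LookupError(
            f"unknown material {name!r}; available: {sorted(catalog)}") from None


@dataclass(frozen=True)
class FGMLayout:
    """Lengthwise layered (functionally graded) modulus schedule.

    ``boundaries`` are axial positions in mm measured from the *distal tip*
    (z = 0) to the proximal end (z = L), strictly increasing and spanning
    [0, L].  ``moduli_gpa`` is ordered proximal-first: ``moduli_gpa[0]`` is
    layer 1, the layer adjacent to the proximal cement, so it occupies the
    *last* interval of ``boundaries``.
    """

    boundaries: tuple[float, ...]
    moduli_gpa: tuple[float, ...]

    def __post_init__(self):
        b = np.asarray(self.boundaries, float)
        m = np.asarray(self.moduli_gpa, float)
        if b.size != m.size + 1:
            raise InvalidParameterError(
                f"need n_layers+1 boundaries, got {b.size} for {m.size} layers")
        if not np.all(np.diff(b) > 0):
            raise InvalidParameterError("layer boundaries must be strictly increasing")
        if b[0] != 0.0:
            raise InvalidParameterError("boundaries must start at z = 0 (distal tip)")
        if np.any(m <= 0):
            raise InvalidParameterError("layer moduli must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.moduli_gpa)

    @property
    def length(self) -> float:
        return self.boundaries[-1]


def default_fgm_layout(length: float = 185.0) -> FGMLayout:
    """Eleven equal-length layers, 120 GPa proximally down to 10 GPa distally."""
    n = len(FGM_MODULI_GPA)
    bounds = tuple(np.linspace(0.0, length, n + 1))
    return FGMLayout(bounds, FGM_MODULI_GPA)


def modulus_at(layout: FGMLayout, z) -> np.ndarray | float:
    """Piecewise-constant modulus (GPa) at axial position ``z`` (mm from tip).

    Points exactly on an internal boundary belong to the more-proximal layer
    (the layer on the larger-z side).
    """
    z_arr = np.asarray(z, float)
    L = layout.length
    if np.any(z_arr < 0) or np.any(z_arr > L):
        raise ValueError(f"z outside [0, {L}] mm")
    b = np.asarray(layout.boundaries, float)
    # interval index counted from the distal end; boundary -> proximal side
    idx = np.clip(np.searchsorted(b, z_arr, side="left") - 1, 0, layout.n_layers - 1)
    idx = np.where(np.isin(z_arr, b[1:-1]), idx + 1, idx)
    idx = np.clip(idx, 0, layout.n_layers - 1)
    # moduli are proximal-first; interval k (distal-first) is layer n-k
    m = np.asarray(layout.moduli_gpa, float)[::-1]
    out = m[idx]
    return float(out) if np.isscalar(z) else out
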