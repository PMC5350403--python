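"""Desk-scale structural surrogate of the femur-cement-implant assembly.

The three-dimensional finite-element model of the original workflow is
replaced by a one-dimensional composite (transformed-section) Euler beam:
at every axial station the bone annulus, cement ring and stem cross section
share a common axial strain and curvature, and each material carries stress
sigma = E * (eps0 + kappa * y).  The femur is a tapered cortical tube fixed
at its distal end; the hip joint contact force and the abductor force are
applied as point loads above the proximal resection plane, acting in the
medial (y-z) plane.  Surface stresses are reported as the peak equivalent
uniaxial (von Mises) magnitude of the walking-load cycle; because the load
cycles between zero and its peak, the alternating and mean components are
each half the peak, and every stress-shielding quantity is invariant to
that common factor.

Users with an external 3D FEA can bypass the surrogate entirely through the
CSV stress-field interface (`import_stress_field` / the export helpers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry as geo
from .errors import (AlignmentError, InvalidParameterError, ParseError,
                     SingularSectionError)
from .materials import FGMLayout, Material, builtin_catalog, modulus_at

__all__ = [
    "Load", "LoadCase", "LoadGeometry", "SurrogateFemur", "StressSamples",
    "CementStressField", "ImplantedAssembly", "ImplantedResult",
    "point_loads", "solve_intact", "solve_implanted",
    "export_stress_samples", "export_cement_field", "import_stress_field",
]


# --------------------------------------------------------------------------
# loads
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Load:
    """Point load in the medial plane: position (y, z) mm, force (fy, fz) N,
    optional concentrated moment mx (N mm) about the frontal x-axis."""

    y: float
    z: float
    fy: float
    fz: float
    mx: float = 0.0


@dataclass(frozen=True)
class LoadCase:
    """Average-walking load case: hip joint contact force 2.5 kN applied at
    10 deg from the femur axis plus an abductor force of 1.5 kN at 15 deg
    (together about 3.5 bodyweights for a 700 N subject)."""

    joint_force_kn: float = 2.5
    joint_angle_deg: float = 10.0
    abductor_force_kn: float = 1.5
    abductor_angle_deg: float = 15.0
    bodyweight_n: float = 700.0

    def __post_init__(self):
        if self.joint_force_kn < 0 or self.abductor_force_kn < 0:
            raise InvalidParameterError("forces must be nonnegative")


@dataclass(frozen=True)
class LoadGeometry:
    """Lever arms of the two point loads relative to the proximal resection
    plane (z offsets, mm) and the femur axis (y offsets, mm; +y medial).

    The joint force acts on the femoral head (medial offset), pointing
    distally and laterally; the abductor acts at the greater trochanter
    (lateral offset), pulling proximally and medially."""

    head_offset_y: float = 40.0
    head_offset_z: float = 40.0
    trochanter_offset_y: float = -25.0
    trochanter_offset_z: float = -10.0


def point_loads(case: LoadCase, femur_length: float,
                geom: LoadGeometry | None = None) -> tuple:
    geom = geom or LoadGeometry()
    a_j = np.radians(case.joint_angle_deg)
    a_a = np.radians(case.abductor_angle_deg)
    fj = case.joint_force_kn * 1e3
    fa = case.abductor_force_kn * 1e3
    joint = Load(geom.head_offset_y, femur_length + geom.head_offset_z,
                 fy=-fj * np.sin(a_j), fz=-fj * np.cos(a_j))
    abductor = Load(geom.trochanter_offset_y, femur_length + geom.trochanter_offset_z,
                    fy=fa * np.sin(a_a), fz=fa * np.cos(a_a))
    return (joint, abductor)


def _resultants(loads, z_grid: np.ndarray):
    """Axial force N(z) and bending moment Mx(z) at each section from the
    loads applied above it (cantilever fixed at z = 0)."""
    z = np.asarray(z_grid, float)
    n_force = np.zeros_like(z)
    m_x = np.zeros_like(z)
    for ld in loads:
        above = ld.z >= z
        n_force += np.where(above, ld.fz, 0.0)
        m_x += np.where(above, ld.mx + ld.y * ld.fz - (ld.z - z) * ld.fy, 0.0)
    return n_force, m_x


# --------------------------------------------------------------------------
# femur and fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateFemur:
    """Tapered cortical tube: outer and (natural) canal radii interpolated
    linearly between axial stations.  ``core_modulus`` is the modulus (GPa)
    assigned to the canal contents in the *intact* femur — 0 by default
    (marrow and cancellous bone carry no load in this surrogate)."""

    length: float
    stations_z: tuple
    outer_radius: tuple
    canal_radius: tuple
    bone: Material = field(default_factory=lambda: builtin_catalog()["bone"])
    core_modulus: float = 0.0  # GPa

    def __post_init__(self):
        z = np.asarray(self.stations_z, float)
        ro = np.asarray(self.outer_radius, float)
        rc = np.asarray(self.canal_radius, float)
        if not (z.size == ro.size == rc.size and z.size >= 2):
            raise InvalidParameterError("need matching station arrays (>= 2 stations)")
        if not np.all(np.diff(z) > 0):
            raise InvalidParameterError("femur stations must be strictly increasing")
        if np.any(rc <= 0) or np.any(ro <= rc):
            raise InvalidParameterError("femur requires outer > canal > 0 everywhere")
        if self.core_modulus < 0:
            raise InvalidParameterError("core modulus must be nonnegative")

    def outer_at(self, z):
        return np.interp(z, self.stations_z, self.outer_radius)

    def canal_at(self, z):
        return np.interp(z, self.stations_z, self.canal_radius)


def default_femur(core_modulus: float = 0.0) -> SurrogateFemur:
    """Documented default surrogate femur (mm): 250 mm from the distal fixed
    support to the proximal resection plane; thick diaphyseal cortex around a
    narrow canal distally, flaring to a thin-walled metaphysis proximally."""
    return SurrogateFemur(
        length=250.0,
        stations_z=(0.0, 120.0, 180.0, 250.0),
        outer_radius=(12.5, 13.0, 14.5, 16.0),
        canal_radius=(6.5, 8.0, 10.0, 11.0),
        core_modulus=core_modulus,
    )


@dataclass
class StressSamples:
    """Equivalent (uniaxial von Mises) stresses at an ordered axial x
    circumferential grid of femur-surface locations."""

    z: np.ndarray           # (n_axial,) mm
    theta: np.ndarray       # (n_circ,) rad
    sigma: np.ndarray       # (n_axial, n_circ) MPa, >= 0

    def __post_init__(self):
        self.z = np.asarray(self.z, float)
        self.theta = np.asarray(self.theta, float)
        self.sigma = np.asarray(self.sigma, float)
        if self.sigma.shape != (self.z.size, self.theta.size):
            raise InvalidParameterError("sigma must have shape (n_axial, n_circ)")
        if np.any(self.sigma < 0):
            raise InvalidParameterError("equivalent stresses must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.sigma.size)

    def aligned_with(self, other: "StressSamples") -> bool:
        return (self.sigma.shape == other.sigma.shape
                and np.allclose(self.z, other.z)
                and np.allclose(self.theta, other.theta))


@dataclass
class CementStressField:
    """Alternating / mean stress pairs at cement nodes."""

    z: np.ndarray            # (imax,) mm (femur coordinates)
    theta: np.ndarray        # (imax,) rad
    sigma_a: np.ndarray      # MPa
    sigma_m: np.ndarray      # MPa

    def __post_init__(self):
        self.z = np.atleast_1d(np.asarray(self.z, float))
        self.theta = np.atleast_1d(np.asarray(self.theta, float))
        self.sigma_a = np.atleast_1d(np.asarray(self.sigma_a, float))
        self.sigma_m = np.atleast_1d(np.asarray(self.sigma_m, float))
        n = self.z.size
        if not (self.theta.size == self.sigma_a.size == self.sigma_m.size == n) or n < 1:
            raise InvalidParameterError("cement field arrays must share length >= 1")
        if np.any(self.sigma_a < 0):
            raise InvalidParameterError("alternating stresses must be nonnegative")

    @property
    def imax(self) -> int:
        return int(self.z.size)


# --------------------------------------------------------------------------
# solvers
# --------------------------------------------------------------------------

def _intact_stiffness(femur: SurrogateFemur, z):
    e_b = femur.bone.modulus_mpa
    e_core = femur.core_modulus * 1e3
    ro, rc = femur.outer_at(z), femur.canal_at(z)
    a_out, a_in = np.pi * ro ** 2, np.pi * rc ** 2
    i_out, i_in = np.pi / 4 * ro ** 4, np.pi / 4 * rc ** 4
    ea = e_b * (a_out - a_in) + e_core * a_in
    ei = e_b * (i_out - i_in) + e_core * i_in
    return ea, ei


def _check_stiffness(ea, ei):
    if np.any(ea <= 0) or np.any(ei <= 0):
        raise SingularSectionError("section has nonpositive stiffness")


def solve_intact(femur: SurrogateFemur, loads, grid=(95, 32),
                 load_geometry: LoadGeometry | None = None) -> StressSamples:
    """Surface stress field of the intact femur under the walking load.

    ``loads`` is either a LoadCase (converted with the default lever arms)
    or an explicit sequence of Load objects.
    """
    n_ax, n_circ = grid
    if n_ax < 4 or n_circ < 4:
        raise InvalidParameterError("grid resolution must be at least 4 x 4")
    if isinstance(loads, LoadCase):
        loads = point_loads(loads, femur.length, load_geometry)
    z = np.linspace(0.0, femur.length, n_ax)
    theta = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    n_force, m_x = _resultants(loads, z)
    ea, ei = _intact_stiffness(femur, z)
    _check_stiffness(ea, ei)
    eps0, kappa = n_force / ea, m_x / ei
    y_surf = femur.outer_at(z)[:, None] * np.sin(theta)[None, :]
    sigma = np.abs(femur.bone.modulus_mpa * (eps0[:, None] + kappa[:, None] * y_surf))
    return StressSamples(z, theta, sigma)


@dataclass(frozen=True)
class ImplantedAssembly:
    """Stem + cement + femur ready for the composite-beam solve.

    The stem occupies femur coordinates [length - insertion_depth, length];
    its cross-section properties are interpolated between the in-canal key
    sections (stations 1..4).  The reamed canal follows the canal profile
    (never smaller than the natural canal), and the cement fills the gap
    between stem and reamed canal.
    """

    femur: SurrogateFemur
    design: geo.DesignVector
    skeleton: geo.StemSkeleton
    canal_profile: tuple
    stem_material: Material | FGMLayout
    cement: Material
    insertion_depth: float | None = None

    @property
    def depth(self) -> float:
        if self.insertion_depth is not None:
            return self.insertion_depth
        return float(self.skeleton.station_axial_positions()[3])

    @property
    def tip_z(self) -> float:
        return self.femur.length - self.depth

    def stem_modulus_mpa(self, stem_z) -> np.ndarray:
        """Stem modulus at axial position(s) measured from the distal tip."""
        if isinstance(self.stem_material, FGMLayout):
            zc = np.clip(stem_z, 0.0, self.stem_material.length)
            return np.asarray(modulus_at(self.stem_material, zc), float) * 1e3
        return np.full_like(np.asarray(stem_z, float),
                            self.stem_material.modulus_mpa)


def make_assembly(dv: geo.DesignVector,
                  femur: SurrogateFemur | None = None,
                  skel_config: geo.SkeletonConfig | None = None,
                  canal_profile=None,
                  stem_material: Material | FGMLayout | None = None,
                  cement: Material | None = None,
                  insertion_depth: float | None = None) -> ImplantedAssembly:
    cat = builtin_catalog()
    return ImplantedAssembly(
        femur=femur or default_femur(),
        design=dv,
        skeleton=geo.make_skeleton(skel_config),
        canal_profile=tuple(canal_profile or geo.default_canal_profile()),
        stem_material=stem_material or cat["ti6al4v"],
        cement=cement or cat["pmma"],
        insertion_depth=insertion_depth,
    )


@dataclass
class ImplantedResult:
    bone: StressSamples
    cement: CementStressField
    z: np.ndarray
    eps0: np.ndarray
    kappa: np.ndarray
    ea: np.ndarray
    ei: np.ndarray
    parts: dict              # per-material (E, A, I) arrays for diagnostics

    def __iter__(self):      # allow `(samples, cement) = solve_implanted(...)`
        return iter((self.bone, self.cement))


def _stem_section_tables(assembly: ImplantedAssembly, n_profile: int = 1024):
    """Area / Ixx / polar-radius tables at the in-canal stations (1..4)."""
    secs = geo.all_section_params(assembly.design, assembly.skeleton)[:4]
    z_st = assembly.skeleton.station_axial_positions()[:4]
    props = [geo.section_properties(cs, n=n_profile) for cs in secs]
    areas = np.array([p.area for p in props])
    ixx = np.array([p.ixx for p in props])
    canal_r = np.array([0.5 * (c.a + c.b) for c in assembly.canal_profile])
    return secs, z_st, areas, ixx, canal_r


def solve_implanted(assembly: ImplantedAssembly, loads, grid=(95, 32),
                    load_geometry: LoadGeometry | None = None,
                    cement_grid=(40, 16), n_profile: int = 1024) -> ImplantedResult:
    """Composite-beam solution of the implanted assembly.

    Returns bone-surface samples on the same grid convention as
    ``solve_intact`` plus alternating/mean stress pairs at cement ring nodes
    (mid-thickness, zero-to-peak cycling so sigma_a = sigma_m = peak / 2).
    """
    femur = assembly.femur
    n_ax, n_circ = grid
    if n_ax < 4 or n_circ < 4:
        raise InvalidParameterError("grid resolution must be at least 4 x 4")
    if isinstance(loads, LoadCase):
        loads = point_loads(loads, femur.length, load_geometry)

    secs, z_st, a_stem_st, i_stem_st, canal_r_st = _stem_section_tables(
        assembly, n_profile=n_profile)
    depth = assembly.depth
    tip = assembly.tip_z
    e_b = femur.bone.modulus_mpa
    e_c = assembly.cement.modulus_mpa

    def section_stiffness(z):
        """EA(z), EI(z) and the per-material breakdown at femur coords z."""
        z = np.asarray(z, float)
        stem_z = np.clip(z - tip, 0.0, depth)
        in_span = z >= tip - 1e-12
        a_s = np.where(in_span, np.interp(stem_z, z_st, a_stem_st), 0.0)
        i_s = np.where(in_span, np.interp(stem_z, z_st, i_stem_st), 0.0)
        e_s = np.where(in_span, assembly.stem_modulus_mpa(stem_z), 0.0)
        r_ream = np.where(in_span,
                          np.maximum(np.interp(stem_z, z_st, canal_r_st),
                                     femur.canal_at(z)),
                          femur.canal_at(z))
        ro = femur.outer_at(z)
        if np.any(r_ream >= ro):
            raise SingularSectionError("reamed canal reaches the outer cortex")
        a_bone = np.pi * (ro ** 2 - r_ream ** 2)
        i_bone = np.pi / 4 * (ro ** 4 - r_ream ** 4)
        a_cem = np.where(in_span, np.pi * r_ream ** 2 - a_s, 0.0)
        i_cem = np.where(in_span, np.pi / 4 * r_ream ** 4 - i_s, 0.0)
        a_core = np.where(in_span, 0.0, np.pi * r_ream ** 2)
        i_core = np.where(in_span, 0.0, np.pi / 4 * r_ream ** 4)
        e_core = femur.core_modulus * 1e3
        ea = e_b * a_bone + e_c * a_cem + e_s * a_s + e_core * a_core
        ei = e_b * i_bone + e_c * i_cem + e_s * i_s + e_core * i_core
        parts = dict(bone=(e_b, a_bone, i_bone), cement=(e_c, a_cem, i_cem),
                     stem=(e_s, a_s, i_s), core=(e_core, a_core, i_core),
                     reamed_radius=r_ream, outer_radius=ro)
        return ea, ei, parts

    z = np.linspace(0.0, femur.length, n_ax)
    theta = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    n_force, m_x = _resultants(loads, z)
    ea, ei, parts = section_stiffness(z)
    _check_stiffness(ea, ei)
    eps0, kappa = n_force / ea, m_x / ei
    y_surf = femur.outer_at(z)[:, None] * np.sin(theta)[None, :]
    sigma = np.abs(e_b * (eps0[:, None] + kappa[:, None] * y_surf))
    bone = StressSamples(z, theta, sigma)

    # cement nodes at ring mid-thickness over the cemented span
    n_cz, n_ct = cement_grid
    zc = np.linspace(tip, femur.length, n_cz)
    tc = np.linspace(0.0, 2.0 * np.pi, n_ct, endpoint=False)
    nc_force, mc_x = _resultants(loads, zc)
    ea_c, ei_c, parts_c = section_stiffness(zc)
    eps0_c, kappa_c = nc_force / ea_c, mc_x / ei_c
    stem_zc = np.clip(zc - tip, 0.0, depth)
    r_stem_polar = np.array([geo.polar_radius(cs, tc) for cs in secs])  # (4, n_ct)
    r_sp = np.empty((n_cz, n_ct))
    for j in range(n_ct):
        r_sp[:, j] = np.interp(stem_zc, z_st, r_stem_polar[:, j])
    r_mid = 0.5 * (r_sp + parts_c["reamed_radius"][:, None])
    y_c = r_mid * np.sin(tc)[None, :]
    peak = np.abs(e_c * (eps0_c[:, None] + kappa_c[:, None] * y_c))
    zz, tt = np.meshgrid(zc, tc, indexing="ij")
    cement = CementStressField(zz.ravel(), tt.ravel(),
                               0.5 * peak.ravel(), 0.5 * peak.ravel())
    return ImplantedResult(bone, cement, z, eps0, kappa, ea, ei, parts)


# --------------------------------------------------------------------------
# CSV stress-field interface
# --------------------------------------------------------------------------

_SURFACE_COLS = ["node_id", "z_mm", "angle_rad", "sigma_MPa"]
_CEMENT_COLS = ["node_id", "z_mm", "angle_rad", "sigma_a_MPa", "sigma_m_MPa"]


def export_stress_samples(samples: StressSamples, path):
    zz, tt = np.meshgrid(samples.z, samples.theta, indexing="ij")
    df = pd.DataFrame({
        "node_id": np.arange(samples.n),
        "z_mm": zz.ravel(), "angle_rad": tt.ravel(),
        "sigma_MPa": samples.sigma.ravel(),
    })
    df.to_csv(path, index=False)


def export_cement_field(fieldv: CementStressField, path):
    df = pd.DataFrame({
        "node_id": np.arange(fieldv.imax),
        "z_mm": fieldv.z, "angle_rad": fieldv.theta,
        "sigma_a_MPa": fieldv.sigma_a, "sigma_m_MPa": fieldv.sigma_m,
    })
    df.to_csv(path, index=False)


def import_stress_field(path, kind: str = "surface"):
    """Read an externally computed stress field (e.g. from a 3D FEA export).

    ``kind`` = "surface" expects columns node_id, z_mm, angle_rad, sigma_MPa
    on a full rectangular grid; "cement" expects node_id, z_mm, angle_rad,
    sigma_a_MPa, sigma_m_MPa at arbitrary nodes.
    """
    if kind not in ("surface", "cement"):
        raise ValueError(f"kind must be 'surface' or 'cement', got {kind!r}")
    df = pd.read_csv(path)
    want = _SURFACE_COLS if kind == "surface" else _CEMENT_COLS
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; expected {want}")
    for c in want:
        bad = df.index[~np.isfinite(pd.to_numeric(df[c], errors="coerce"))]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {c!r}, row {bad[0]}")
    if kind == "cement":
        if (df["sigma_a_MPa"] < 0).any():
            row = int(df.index[df["sigma_a_MPa"] < 0][0])
            raise ParseError(f"{path}: negative alternating stress at row {row}")
        return CementStressField(df["z_mm"].to_numpy(), df["angle_rad"].to_numpy(),
                                 df["sigma_a_MPa"].to_numpy(), df["sigma_m_MPa"].to_numpy())
    if (df["sigma_MPa"] < 0).any():
        row = int(df.index[df["sigma_MPa"] < 0][0])
        raise ParseError(f"{path}: negative stress at row {row}")
    z = np.unique(df["z_mm"].to_numpy())
    th = np.unique(df["angle_rad"].to_numpy())
    if z.size * th.size != len(df):
        raise ParseError(
            f"{path}: surface field is not a full {z.size} x {th.size} grid "
            f"({len(df)} rows)")
    piv = df.pivot_table(index="z_mm", columns="angle_rad", values="sigma_MPa")
    try:
        return StressSamples(piv.index.to_numpy(), piv.columns.to_numpy(),
                             piv.to_numpy())
    except InvalidParameterError as exc:
        raise ParseError(f"{path}: {exc}") from exc
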