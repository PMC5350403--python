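"""Parametric stem geometry: two-half superellipse cross sections, skeleton
with a four-point Bezier neck transition, spline loft, cement-ring thickness
and clinical admissibility constraints.

Coordinate convention: the prosthesis axis is +z, the frontal direction is
+x and the medial direction is +y.  Lengths are mm; angles are radians
internally (degrees in configuration objects).

Each variable cross section is a closed curve assembled from two superellipse
halves |x/a|^p + |y/b|^p = 1 sharing the common b-semiaxis (the y-axis of the
local frame): the half toward the frontal side (x >= 0) uses semiaxis ``a1``,
the opposite half ``a2``; both share ``b`` and the integer exponent ``p``.
p = 2 gives an ellipse; larger p approaches a rounded-rectangle ("trapezoid")
profile.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline

from .errors import ConstraintError, GeometryViolationError, InvalidParameterError

__all__ = [
    "CrossSectionParams", "Bounds", "DesignVector", "SkeletonConfig",
    "Station", "StemSkeleton", "StemModel", "CanalSection", "CementRing",
    "ConstraintReport", "profile_point", "boundary_points", "polar_radius",
    "section_properties", "SectionProperties", "make_skeleton", "build_stem",
    "sample_surface", "export_stl", "export_profiles_csv", "cement_sections",
    "cement_thickness_profile", "check_constraints", "default_bounds",
    "default_canal_profile", "superellipse_area",
]

# Exponent bounds for cross sections 2..6 (section 1 is the fixed distal circle).
_EXPONENT_BOUNDS = ((2, 3), (2, 3), (2, 4), (2, 4), (2, 3))


# --------------------------------------------------------------------------
# cross sections
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSectionParams:
    """Two-half superellipse: frontal semiaxis a1, opposite a2, common b, exponent p."""

    a1: float
    a2: float
    b: float
    p: int

    def __post_init__(self):
        for name in ("a1", "a2", "b"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(f"semiaxis {name} must be positive, got {v}")
        if int(self.p) != self.p or self.p < 2:
            raise InvalidParameterError(f"exponent p must be an integer >= 2, got {self.p}")
        object.__setattr__(self, "p", int(self.p))

    @classmethod
    def circle(cls, r: float) -> "CrossSectionParams":
        return cls(r, r, r, 2)


def profile_point(cs: CrossSectionParams, angle):
    """Boundary point(s) of the two-half superellipse at parameter ``angle``.

    The curve is parameterized by x = a(angle)*sign(c)|c|^(2/p),
    y = b*sign(s)|s|^(2/p) with c = cos, s = sin; at the junctions
    (angle = +-pi/2) x vanishes for any semiaxis, so the two halves join
    continuously and the curve is closed.
    """
    # reduce mod 2*pi so the parameter 2*pi maps exactly onto 0: the tiny
    # floating residue of sin(2*pi) would otherwise be amplified by the
    # 2/p power and break closure at the 1e-9 level for p >= 4
    ang = np.mod(np.asarray(angle, float), 2.0 * np.pi)
    c, s = np.cos(ang), np.sin(ang)
    a = np.where(c >= 0, cs.a1, cs.a2)
    e = 2.0 / cs.p
    x = a * np.sign(c) * np.abs(c) ** e
    y = cs.b * np.sign(s) * np.abs(s) ** e
    if np.isscalar(angle):
        return np.array([float(x), float(y)])
    return np.stack([x, y], axis=-1)


def boundary_points(cs: CrossSectionParams, n: int = 256, closed: bool = False) -> np.ndarray:
    """(n, 2) boundary samples at uniform parameter spacing (counterclockwise)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=closed)
    if closed:
        pts = profile_point(cs, theta[:-1])
        return np.vstack([pts, pts[:1]])
    return profile_point(cs, theta)


def polar_radius(cs: CrossSectionParams, phi):
    """Radius of the boundary at *polar* angle ``phi`` (closed form).

    Solves |r cos(phi)/a|^p + |r sin(phi)/b|^p = 1 with a chosen by the sign
    of cos(phi).
    """
    ph = np.asarray(phi, float)
    c, s = np.cos(ph), np.sin(ph)
    a = np.where(c >= 0, cs.a1, cs.a2)
    p = float(cs.p)
    val = (np.abs(c) / a) ** p + (np.abs(s) / cs.b) ** p
    r = val ** (-1.0 / p)
    return float(r) if np.isscalar(phi) else r


def superellipse_area(a: float, b: float, p: float) -> float:
    """Closed-form area of |x/a|^p + |y/b|^p = 1 via the gamma function."""
    from scipy.special import gamma
    return 4.0 * a * b * gamma(1.0 + 1.0 / p) ** 2 / gamma(1.0 + 2.0 / p)


@dataclass(frozen=True)
class SectionProperties:
    area: float          # mm^2
    centroid: tuple      # (x, y) mm
    ixx: float           # mm^4, about the centroidal x-axis (integral of y^2 dA)
    iyy: float           # mm^4, about the centroidal y-axis


def section_properties(cs: CrossSectionParams, n: int = 2048) -> SectionProperties:
    """Area, centroid and centroidal second moments by polygonal quadrature.

    Converges as O(n^-2); the default resolution reproduces the gamma-function
    closed form for the area to better than 1e-5 relative.
    """
    pts = boundary_points(cs, n=n, closed=True)
    x, y = pts[:-1, 0], pts[:-1, 1]
    x1, y1 = pts[1:, 0], pts[1:, 1]
    cross = x * y1 - x1 * y
    area = 0.5 * np.sum(cross)
    cx = np.sum((x + x1) * cross) / (6.0 * area)
    cy = np.sum((y + y1) * cross) / (6.0 * area)
    ixx0 = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    iyy0 = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    return SectionProperties(
        area=float(area),
        centroid=(float(cx), float(cy)),
        ixx=float(ixx0 - area * cy * cy),
        iyy=float(iyy0 - area * cx * cx),
    )


# --------------------------------------------------------------------------
# design vector and bounds
# --------------------------------------------------------------------------

_VAR_NAMES = tuple(
    f"s{sec}_{name}" for sec in range(2, 7) for name in ("a1", "a2", "b", "p")
)


@dataclass(frozen=True)
class Bounds:
    """Box bounds for the 20 design variables (5 sections x {a1, a2, b, p})."""

    lower: tuple
    upper: tuple

    def __post_init__(self):
        lo, up = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != (20,) or up.shape != (20,):
            raise InvalidParameterError("bounds must have exactly 20 entries")
        if np.any(lo > up):
            raise InvalidParameterError("lower bound exceeds upper bound")
        object.__setattr__(self, "lower", tuple(lo))
        object.__setattr__(self, "upper", tuple(up))

    @property
    def integer_mask(self) -> np.ndarray:
        mask = np.zeros(20, bool)
        mask[3::4] = True  # every 4th variable is an exponent
        return mask

    @property
    def names(self) -> tuple:
        return _VAR_NAMES


def default_bounds() -> Bounds:
    """Default search intervals.

    Semiaxis intervals are matched to the default canal profile so that an
    oval (p = 2) stem keeps the cement mantle between 2 and 3 mm; exponent
    intervals follow the per-section schedule (sections 2..6 of the skeleton).
    """
    semiaxes = ((7.5, 8.5), (9.0, 10.0), (11.0, 12.0), (11.0, 13.0), (10.0, 12.0))
    lower, upper = [], []
    for (alo, ahi), (plo, phi) in zip(semiaxes, _EXPONENT_BOUNDS):
        lower += [alo, alo, alo, plo]
        upper += [ahi, ahi, ahi, phi]
    return Bounds(tuple(lower), tuple(upper))


@dataclass(frozen=True)
class DesignVector:
    """The 20 geometric degrees of freedom of the stem (cross sections 2..6)."""

    sections: tuple            # 5 x CrossSectionParams
    bounds: Bounds = field(default_factory=default_bounds)

    def __post_init__(self):
        if len(self.sections) != 5:
            raise InvalidParameterError("a design vector has exactly 5 variable sections")
        object.__setattr__(self, "sections", tuple(self.sections))

    def to_array(self) -> np.ndarray:
        return np.array(
            [v for cs in self.sections for v in (cs.a1, cs.a2, cs.b, cs.p)], float)

    @classmethod
    def from_array(cls, values, bounds: Bounds | None = None) -> "DesignVector":
        v = np.asarray(values, float)
        if v.shape != (20,):
            raise InvalidParameterError(f"expected 20 values, got shape {v.shape}")
        secs = tuple(
            CrossSectionParams(v[4 * i], v[4 * i + 1], v[4 * i + 2], int(round(v[4 * i + 3])))
            for i in range(5))
        return cls(secs, bounds or default_bounds())

    @classmethod
    def mid(cls, bounds: Bounds | None = None) -> "DesignVector":
        """Mid-interval semiaxes with the lowest (oval, p = 2) exponents."""
        b = bounds or default_bounds()
        lo, up = np.asarray(b.lower), np.asarray(b.upper)
        v = 0.5 * (lo + up)
        v[b.integer_mask] = lo[b.integer_mask]
        return cls.from_array(v, b)

    @classmethod
    def at_lower(cls, bounds: Bounds | None = None) -> "DesignVector":
        b = bounds or default_bounds()
        return cls.from_array(np.asarray(b.lower), b)

    @classmethod
    def at_upper(cls, bounds: Bounds | None = None) -> "DesignVector":
        b = bounds or default_bounds()
        return cls.from_array(np.asarray(b.upper), b)

    def bound_violations(self) -> list:
        v = self.to_array()
        lo, up = np.asarray(self.bounds.lower), np.asarray(self.bounds.upper)
        out = []
        for i, name in enumerate(_VAR_NAMES):
            if v[i] < lo[i] - 1e-12 or v[i] > up[i] + 1e-12:
                out.append(f"out_of_bounds:{name}={v[i]:g} not in [{lo[i]:g}, {up[i]:g}]")
        return out


# --------------------------------------------------------------------------
# skeleton
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SkeletonConfig:
    """Placement of the six key cross sections.

    The straight prosthesis axis runs from the distal tip (z = 0) to the
    junction with the neck axis; a four-point Bezier spline blends the two
    axes over ``transition_fraction`` of the total length on each side of
    the junction.  Station fractions for the three distal sections are
    measured along the total length; stations 5 and 6 sit on the neck axis.
    The neck axis makes ``neck_angle_deg`` with the (distal-pointing) stem
    axis, i.e. 135 deg is the conventional neck-shaft angle.
    """

    total_length: float = 185.0
    distal_radius: float = 6.0
    junction_fraction: float = 0.75
    transition_fraction: float = 0.10
    neck_angle_deg: float = 135.0
    neck_length: float = 35.0
    station_fractions: tuple = (0.0, 0.25, 0.55)
    neck_station_fractions: tuple = (0.3, 0.75)
    straight: bool = False  # degenerate straight column (testing / calibration)


@dataclass(frozen=True)
class Station:
    center: np.ndarray   # (3,)
    normal: np.ndarray   # (3,), unit
    e_x: np.ndarray      # in-plane frontal axis
    e_y: np.ndarray      # in-plane common-b axis


@dataclass(frozen=True)
class StemSkeleton:
    config: SkeletonConfig
    stations: tuple            # 6 Station objects, distal first
    bezier: np.ndarray         # (4, 3) control points of the neck transition
    neck_direction: np.ndarray
    junction: np.ndarray

    @property
    def total_length(self) -> float:
        return self.config.total_length

    @property
    def distal_radius(self) -> float:
        return self.config.distal_radius

    def station_axial_positions(self) -> np.ndarray:
        """z-coordinate of each station center (projection on the stem axis)."""
        return np.array([st.center[2] for st in self.stations])


def _bezier_eval(ctrl: np.ndarray, u):
    u = np.asarray(u, float)[..., None]
    c0, c1, c2, c3 = ctrl
    return ((1 - u) ** 3 * c0 + 3 * (1 - u) ** 2 * u * c1
            + 3 * (1 - u) * u ** 2 * c2 + u ** 3 * c3)


def _bezier_tangent(ctrl: np.ndarray, u):
    u = np.asarray(u, float)[..., None]
    c0, c1, c2, c3 = ctrl
    return (3 * (1 - u) ** 2 * (c1 - c0) + 6 * (1 - u) * u * (c2 - c1)
            + 3 * u ** 2 * (c3 - c2))


def _station_frame(center, normal) -> Station:
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    x_hat = np.array([1.0, 0.0, 0.0])
    e_x = x_hat - np.dot(x_hat, n) * n
    e_x = e_x / np.linalg.norm(e_x)
    e_y = np.cross(n, e_x)
    return Station(np.asarray(center, float), n, e_x, e_y)


def make_skeleton(cfg: SkeletonConfig | None = None) -> StemSkeleton:
    cfg = cfg or SkeletonConfig()
    L = cfg.total_length
    z_hat = np.array([0.0, 0.0, 1.0])

    if cfg.straight:
        fracs = np.linspace(0.0, 1.0, 6)
        stations = tuple(_station_frame([0, 0, f * L], z_hat) for f in fracs)
        ctrl = np.outer(np.linspace(0.6, 0.9, 4) * L, z_hat)
        return StemSkeleton(cfg, stations, ctrl, z_hat.copy(), np.array([0, 0, L * 0.75]))

    z_j = cfg.junction_fraction * L
    t = cfg.transition_fraction * L
    junction = z_j * z_hat
    # neck direction in the medial (y-z) plane, neck-shaft angle measured
    # from the distal-pointing axis
    alpha = np.radians(180.0 - cfg.neck_angle_deg)
    d_neck = np.array([0.0, np.sin(alpha), np.cos(alpha)])

    p0 = (z_j - t) * z_hat
    p3 = junction + t * d_neck
    ctrl = np.array([p0, p0 + (t / 3.0) * z_hat, p3 - (t / 3.0) * d_neck, p3])

    stations = [
        _station_frame([0, 0, f * L], z_hat) for f in cfg.station_fractions
    ]
    mid = _bezier_eval(ctrl, 0.5)
    stations.append(_station_frame(mid, _bezier_tangent(ctrl, 0.5)))
    for f in cfg.neck_station_fractions:
        stations.append(_station_frame(p3 + f * cfg.neck_length * d_neck, d_neck))
    return StemSkeleton(cfg, tuple(stations), ctrl, d_neck, junction)


# --------------------------------------------------------------------------
# stem model (loft)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StemModel:
    """Lofted stem: six key cross sections interpolated by third-order splines.

    The loft is a cubic (third-order) B-spline through the station rings —
    a non-rational NURBS with unit weights — evaluated lazily on demand.
    """

    skeleton: StemSkeleton
    design: DesignVector
    profiles: np.ndarray        # (6, n_u_master, 3) station rings
    v_knots: np.ndarray         # (6,) chordal parameter of the stations
    section_params: tuple       # 6 x CrossSectionParams (incl. distal circle)
    layers: tuple | None = None  # optional lengthwise slicing boundaries (z, mm)

    @property
    def n_u_master(self) -> int:
        return self.profiles.shape[1]

    def loft_rings(self, v) -> np.ndarray:
        """Evaluate the axial spline at parameter(s) v in [0, 1] -> rings."""
        spl = make_interp_spline(self.v_knots, self.profiles, k=3, axis=0)
        return spl(np.clip(v, 0.0, 1.0))


def all_section_params(dv: DesignVector, skel: StemSkeleton) -> tuple:
    """Section parameters for stations 1..6 (fixed distal circle + design sections)."""
    return (CrossSectionParams.circle(skel.distal_radius),) + tuple(dv.sections)


def build_stem(dv: DesignVector, skel_config: SkeletonConfig | None = None,
               n_u: int = 64, n_slices: int | None = None,
               validate_bounds: bool = True) -> StemModel:
    """Assemble the lofted stem model from a design vector.

    Deterministic: identical inputs give bit-identical surface samples.
    """
    violations = dv.bound_violations() if validate_bounds else []
    if violations:
        raise ConstraintError("design vector outside bounds", violations)
    skel = make_skeleton(skel_config)
    secs = all_section_params(dv, skel)
    theta = np.linspace(0.0, 2.0 * np.pi, n_u, endpoint=False)
    rings = []
    for st, cs in zip(skel.stations, secs):
        pts2 = profile_point(cs, theta)          # (n_u, 2)
        rings.append(st.center + pts2[:, :1] * st.e_x + pts2[:, 1:2] * st.e_y)
    rings = np.array(rings)
    centers = np.array([st.center for st in skel.stations])
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(centers, axis=0), axis=1))])
    v_knots = chord / chord[-1]
    layers = None
    if n_slices:
        L = skel.total_length
        layers = tuple(np.linspace(0.0, L, n_slices + 1))
    return StemModel(skel, dv, rings, v_knots, secs, layers)


def sample_surface(stem: StemModel, n_u: int, n_v: int) -> np.ndarray:
    """(n_v, n_u, 3) ordered point cloud on the loft, distal ring first."""
    if n_u < 4 or n_v < 4:
        raise InvalidParameterError("surface sampling resolutions must be >= 4")
    v = np.linspace(0.0, 1.0, n_v)
    rings = stem.loft_rings(v)                   # (n_v, n_master, 3)
    if n_u == stem.n_u_master:
        return rings
    th_master = np.linspace(0.0, 2.0 * np.pi, stem.n_u_master + 1)
    th_new = np.linspace(0.0, 2.0 * np.pi, n_u, endpoint=False)
    out = np.empty((n_v, n_u, 3))
    for j in range(n_v):
        ring = np.vstack([rings[j], rings[j][:1]])
        spl = CubicSpline(th_master, ring, axis=0, bc_type="periodic")
        out[j] = spl(th_new)
    return out


def _loft_mesh(stem: StemModel, n_u: int, n_v: int):
    import trimesh

    grid = sample_surface(stem, n_u, n_v)
    verts = grid.reshape(-1, 3)
    faces = []
    for j in range(n_v - 1):
        for i in range(n_u):
            a = j * n_u + i
            b = j * n_u + (i + 1) % n_u
            c = (j + 1) * n_u + i
            d = (j + 1) * n_u + (i + 1) % n_u
            faces.append([a, b, d])
            faces.append([a, d, c])
    c0 = len(verts)
    c1 = c0 + 1
    verts = np.vstack([verts, grid[0].mean(axis=0), grid[-1].mean(axis=0)])
    for i in range(n_u):
        faces.append([c0, (i + 1) % n_u, i])                       # distal cap
        j0 = (n_v - 1) * n_u
        faces.append([c1, j0 + i, j0 + (i + 1) % n_u])             # proximal cap
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def export_stl(stem: StemModel, path, n_u: int = 64, n_v: int = 120):
    """Export a watertight triangulated STL of the lofted stem."""
    mesh = _loft_mesh(stem, n_u, n_v)
    mesh.export(path)
    return mesh


def export_profiles_csv(stem: StemModel, path, n_u: int = 64):
    """CSV of the station boundary curves: station_id, angle_rad, x, y, z."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_u, endpoint=False)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["station_id", "angle_rad", "x_mm", "y_mm", "z_mm"])
        for sid, (st, cs) in enumerate(zip(stem.skeleton.stations, stem.section_params), start=1):
            pts2 = profile_point(cs, theta)
            pts3 = st.center + pts2[:, :1] * st.e_x + pts2[:, 1:2] * st.e_y
            for ang, p in zip(theta, pts3):
                w.writerow([sid, f"{ang:.10g}", f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}"])


# --------------------------------------------------------------------------
# cement mantle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CanalSection:
    """Elliptic (or circular) canal cross section at a station."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise InvalidParameterError("canal semiaxes must be positive")

    def polar_radius(self, phi):
        ph = np.asarray(phi, float)
        r = (self.a * self.b) / np.sqrt(
            (self.b * np.cos(ph)) ** 2 + (self.a * np.sin(ph)) ** 2)
        return float(r) if np.isscalar(phi) else r


def default_canal_profile() -> tuple:
    """Surrogate canal at stations 1..4: circles sized so the mid-bound oval
    design leaves a ~2.5 mm cement mantle."""
    return (CanalSection(8.5, 8.5), CanalSection(10.5, 10.5),
            CanalSection(12.0, 12.0), CanalSection(14.0, 14.0))


@dataclass(frozen=True)
class CementRing:
    station: int
    phi: np.ndarray
    thickness: np.ndarray   # radial canal-minus-stem distance per angle, mm

    @property
    def min_thickness(self) -> float:
        return float(np.min(self.thickness))

    @property
    def max_thickness(self) -> float:
        return float(np.max(self.thickness))


def cement_thickness_profile(stem_cs: CrossSectionParams, canal: CanalSection,
                             n: int = 720, rotation: float = 0.0) -> CementRing:
    """Radial cement thickness vs polar angle for one station.

    ``rotation`` rigidly rotates stem and canal together (the thickness
    profile is invariant up to a relabeling of angles)."""
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r_stem = polar_radius(stem_cs, phi - rotation)
    r_canal = canal.polar_radius(phi - rotation)
    return CementRing(-1, phi, r_canal - r_stem)


def cement_sections(dv_or_stem, canal_profile=None, skel_config: SkeletonConfig | None = None,
                    n: int = 720) -> tuple:
    """Per-station cement ring geometry for the in-canal stations (1..4).

    Raises GeometryViolationError if the stem touches or crosses the canal."""
    if isinstance(dv_or_stem, StemModel):
        dv, skel = dv_or_stem.design, dv_or_stem.skeleton
    else:
        dv = dv_or_stem
        skel = make_skeleton(skel_config)
    canal_profile = canal_profile or default_canal_profile()
    secs = all_section_params(dv, skel)
    rings = []
    for k, canal in enumerate(canal_profile):
        ring = cement_thickness_profile(secs[k], canal, n=n)
        ring = CementRing(k + 1, ring.phi, ring.thickness)
        if ring.min_thickness <= 0.0:
            raise GeometryViolationError(
                f"stem boundary reaches the canal at station {k + 1} "
                f"(min radial gap {ring.min_thickness:.3f} mm)")
        rings.append(ring)
    return tuple(rings)


# --------------------------------------------------------------------------
# constraints
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintReport:
    min_cement_thickness: float
    max_cement_thickness: float
    admissible: bool
    violations: tuple

    @property
    def violation_magnitude(self) -> float:
        """Sum of normalized constraint breaches (mm for thickness, relative
        area for the taper rule); used as an optimization penalty weight."""
        mag = 0.0
        for v in self.violations:
            try:
                mag += float(v.rsplit(":", 1)[-1])
            except ValueError:
                mag += 1.0
        return mag


def check_constraints(dv: DesignVector, canal_profile=None,
                      skel_config: SkeletonConfig | None = None,
                      thickness_limits: tuple = (2.0, 3.0),
                      taper_rule: bool = True) -> ConstraintReport:
    """Clinical admissibility of a design.

    Admissible iff (a) at every in-canal station the radial cement thickness
    stays within ``thickness_limits`` (default 2.0-3.0 mm), and (b) the
    cross-section areas are monotone nonincreasing from station 4 down to the
    distal station 1 (no distal bulge, so the stem is insertable).  Bound or
    canal violations are reported, never raised.
    """
    t_lo, t_hi = thickness_limits
    violations = list(dv.bound_violations())
    skel = make_skeleton(skel_config)
    canal_profile = canal_profile or default_canal_profile()
    secs = all_section_params(dv, skel)
    mins, maxs = [], []
    for k, canal in enumerate(canal_profile):
        ring = cement_thickness_profile(secs[k], canal)
        mins.append(ring.min_thickness)
        maxs.append(ring.max_thickness)
        if ring.min_thickness <= 0.0:
            violations.append(
                f"stem_outside_canal:station{k + 1}:{-ring.min_thickness + 1.0:.4f}")
        elif ring.min_thickness < t_lo:
            violations.append(
                f"cement_too_thin:station{k + 1}:{t_lo - ring.min_thickness:.4f}")
        if ring.max_thickness > t_hi:
            violations.append(
                f"cement_too_thick:station{k + 1}:{ring.max_thickness - t_hi:.4f}")
    if taper_rule:
        areas = [section_properties(secs[k], n=720).area for k in range(4)]
        for k in range(3):
            if areas[k] > areas[k + 1] * (1.0 + 1e-9):
                rel = areas[k] / areas[k + 1] - 1.0
                violations.append(f"taper_violation:station{k + 1}:{rel:.4f}")
    return ConstraintReport(
        min_cement_thickness=float(np.min(mins)),
        max_cement_thickness=float(np.max(maxs)),
        admissible=not violations,
        violations=tuple(violations),
    )
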