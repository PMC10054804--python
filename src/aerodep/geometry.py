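"""Synthetic stand-in geometries for upper-airway aerosol transport.

The patient-specific CT geometry that motivates this package is not
public, so the package generates idealized stand-ins:

* :func:`make_idealized_upper_airway` — a two-nostril duct with circular
  cross-sections whose centerline runs up through the vestibule and nasal
  valve, bends posteriorly through the turbinate passage, bends down and
  merges with the contralateral branch at the nasopharynx, and continues
  through oropharynx, larynx (with a glottal contraction) and trachea.
  The nasal valve is the narrowest single passage and the glottis the
  smallest combined cross-section, reproducing the two sites where real
  upper-airway flow changes dramatically.
* :func:`make_bend_geometry` — a 90 degree circular-arc tube of
  curvature ratio (bend centerline radius / tube radius) 5.6, the
  classical bend-deposition validation case.

Geometries are unions of tubes around piecewise straight/arc centerlines
with a piecewise-linear radius profile r(s).  Inside/outside tests,
arc-length lookup and local duct frames are analytic and vectorized;
the Lagrangian tracker and the duct flow fields share a single
:meth:`DuctGeometry.query` call per step.

Circular sections are a stated idealization: real nasal passages are
slit-like.  The cross-section *area series*, not the section shape,
carries the one-dimensional physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "GeometryQuery",
    "DuctGeometry",
    "AirwayGeometry",
    "BendGeometry",
    "AirwayParams",
    "REGION_ORDER",
    "ANTERIOR_REGIONS",
    "make_idealized_upper_airway",
    "make_bend_geometry",
    "injection_positions",
]

REGION_ORDER = ("vestibule", "nasal_valve", "turbinate", "nasopharynx",
                "oropharynx", "larynx", "trachea")
#: the "anterior region" aggregate used in nasal dosimetry reporting
ANTERIOR_REGIONS = ("vestibule", "nasal_valve")


class ConfigurationError(ValueError):
    """Inconsistent geometry/run parameters."""


# ---------------------------------------------------------------------------
# centerline segments

@dataclass(frozen=True)
class _Straight:
    p0: np.ndarray
    direction: np.ndarray  # unit
    length: float
    s0: float  # global arc length at p0

    def closest(self, x: np.ndarray):
        rel = x - self.p0
        t = np.clip(rel @ self.direction, 0.0, self.length)
        cp = self.p0 + t[..., None] * self.direction
        dist = np.linalg.norm(x - cp, axis=-1)
        axial = np.broadcast_to(self.direction, x.shape)
        ones = np.ones_like(dist)
        return self.s0 + t, dist, cp, axial, ones, np.zeros_like(dist)

    def point(self, s_local: float) -> np.ndarray:
        return self.p0 + s_local * self.direction


@dataclass(frozen=True)
class _Arc:
    center: np.ndarray
    e1: np.ndarray  # unit, points from center to the arc start
    e2: np.ndarray  # unit tangent at the arc start
    radius_c: float  # centerline bend radius
    theta_max: float
    s0: float

    @property
    def length(self) -> float:
        return self.radius_c * self.theta_max

    def closest(self, x: np.ndarray):
        q = x - self.center
        a = q @ self.e1
        b = q @ self.e2
        theta = np.arctan2(b, a)
        # clamp the back half of the circle to the nearer endpoint
        theta = np.where(theta < self.theta_max / 2.0 - np.pi,
                         self.theta_max, np.clip(theta, 0.0, self.theta_max))
        ct, st = np.cos(theta), np.sin(theta)
        cp = (self.center + self.radius_c *
              (ct[..., None] * self.e1 + st[..., None] * self.e2))
        dist = np.linalg.norm(x - cp, axis=-1)
        axial = -st[..., None] * self.e1 + ct[..., None] * self.e2
        # metric factor: arc length per unit centerline s at the point's
        # in-plane radius (outer side of the bend advances s more slowly)
        h = np.sqrt(a * a + b * b) / self.radius_c
        curv = np.full_like(dist, 1.0 / self.radius_c)
        return self.s0 + self.radius_c * theta, dist, cp, axial, h, curv

    def point(self, s_local: float) -> np.ndarray:
        th = s_local / self.radius_c
        return self.center + self.radius_c * (np.cos(th) * self.e1 + np.sin(th) * self.e2)


@dataclass
class _Tube:
    """One duct component: an ordered centerline with a radius profile.

    ``q_fraction`` is the fraction of the total volumetric flow the
    component carries (0.5 per nostril branch, 1.0 for the trunk).
    """

    name: str
    segments: list
    s_knots: np.ndarray  # global arc length
    r_knots: np.ndarray  # duct radius at the knots
    q_fraction: float = 1.0

    def __post_init__(self) -> None:
        # C1 monotone-cubic wall: kink-free tapers (a slope discontinuity
        # in r(s) creates an artificial particle-capture wedge at the knot)
        from scipy.interpolate import PchipInterpolator

        self.s_knots = np.asarray(self.s_knots, dtype=float)
        self.r_knots = np.asarray(self.r_knots, dtype=float)
        self._r_interp = PchipInterpolator(self.s_knots, self.r_knots)
        self._r_slope = self._r_interp.derivative()

    @property
    def s_start(self) -> float:
        return self.segments[0].s0

    @property
    def s_end(self) -> float:
        last = self.segments[-1]
        return last.s0 + last.length

    def radius(self, s):
        return self._r_interp(np.clip(s, self.s_knots[0], self.s_knots[-1]))

    def radius_slope(self, s):
        return self._r_slope(np.clip(s, self.s_knots[0], self.s_knots[-1]))

    def closest(self, x: np.ndarray):
        """Best (s, dist, cp, axial, h) over the tube's segments."""
        results = [seg.closest(x) for seg in self.segments]
        dists = np.stack([r[1] for r in results])
        best = np.argmin(dists, axis=0)
        rows = np.arange(x.shape[0])
        s = np.stack([r[0] for r in results])[best, rows]
        dist = dists[best, rows]
        cp = np.stack([r[2] for r in results])[best, rows]
        axial = np.stack([r[3] for r in results])[best, rows]
        h = np.stack([r[4] for r in results])[best, rows]
        curv = np.stack([r[5] for r in results])[best, rows]
        return s, dist, cp, axial, h, curv

    def centerline_point(self, s: float) -> np.ndarray:
        for seg in self.segments:
            if s <= seg.s0 + seg.length + 1e-12:
                return seg.point(max(s - seg.s0, 0.0))
        last = self.segments[-1]
        return last.point(last.length)


@dataclass
class GeometryQuery:
    """Vectorized local duct frame at a batch of points."""

    s: np.ndarray          # arc length from the nostril-inlet center (m)
    dist: np.ndarray       # radial distance from the centerline (m)
    r: np.ndarray          # local duct radius (m)
    depth: np.ndarray      # dist - r; negative inside the duct
    axial: np.ndarray      # (N,3) local flow direction (unit)
    radial_unit: np.ndarray  # (N,3) unit vector centerline -> point
    drds: np.ndarray       # wall slope dr/ds
    h: np.ndarray          # axial metric factor (1 on straights)
    curvature: np.ndarray  # centerline curvature 1/Rc (0 on straights)
    q_fraction: np.ndarray  # flow fraction of the owning component
    tube: np.ndarray       # owning component index


class DuctGeometry:
    """Union-of-tubes duct with labeled regions and an outlet plane."""

    def __init__(self, tubes: Sequence[_Tube], regions: dict,
                 outlet_point: np.ndarray, outlet_dir: np.ndarray,
                 inlets: Sequence[dict], analysis_planes: Optional[dict] = None):
        self.tubes = list(tubes)
        self.regions = dict(regions)  # name -> (s_start, s_end)
        self.outlet_point = np.asarray(outlet_point, dtype=float)
        self.outlet_dir = np.asarray(outlet_dir, dtype=float)
        self.inlets = list(inlets)  # dicts: center, direction, radius, tube
        self.analysis_planes = dict(analysis_planes or {})
        self.total_length = max(t.s_end for t in self.tubes)
        self._region_edges = np.array([se[0] for se in self.regions.values()]
                                      + [self.total_length])
        self._region_names = list(self.regions.keys())

    # -- queries ---------------------------------------------------------

    def query(self, x: np.ndarray) -> GeometryQuery:
        """Local duct frame for points ``x`` of shape (N, 3).

        Each point is assigned to the component in which it sits deepest
        (most negative ``dist - r``), which resolves the overlap where the
        nostril branches enter the trunk.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        per = []
        for tube in self.tubes:
            s, dist, cp, axial, h, curv = tube.closest(x)
            r = tube.radius(s)
            per.append((s, dist, cp, axial, r, h, curv))
        depth = np.stack([p[1] - p[4] for p in per])
        best = np.argmin(depth, axis=0)
        rows = np.arange(n)
        s = np.stack([p[0] for p in per])[best, rows]
        dist = np.stack([p[1] for p in per])[best, rows]
        cp = np.stack([p[2] for p in per])[best, rows]
        axial = np.stack([p[3] for p in per])[best, rows]
        r = np.stack([p[4] for p in per])[best, rows]
        h = np.stack([p[5] for p in per])[best, rows]
        curv = np.stack([p[6] for p in per])[best, rows]
        with np.errstate(invalid="ignore", divide="ignore"):
            radial_unit = np.where(dist[:, None] > 0, (x - cp) / np.maximum(dist, 1e-300)[:, None], 0.0)
        drds = np.empty(n)
        qf = np.empty(n)
        for i, tube in enumerate(self.tubes):
            m = best == i
            if m.any():
                drds[m] = tube.radius_slope(s[m])
                qf[m] = tube.q_fraction
        return GeometryQuery(s=s, dist=dist, r=r, depth=dist - r, axial=axial,
                             radial_unit=radial_unit, drds=drds, h=h,
                             curvature=curv, q_fraction=qf, tube=best)

    def past_outlet(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.outlet_point) @ self.outlet_dir > 0.0

    def classify(self, x) -> tuple:
        """('interior'|'wall'|'outlet', region label) at a single point."""
        x = np.asarray(x, dtype=float).reshape(1, 3)
        if bool(self.past_outlet(x)[0]):
            return "outlet", self._region_names[-1]
        q = self.query(x)
        region = self.region_at(float(q.s[0]))
        kind = "interior" if q.depth[0] < 0 else "wall"
        return kind, region

    def region_at(self, s):
        """Region label(s) at arc length(s) ``s``."""
        s_arr = np.asarray(s, dtype=float)
        idx = np.clip(np.searchsorted(self._region_edges, s_arr, side="right") - 1,
                      0, len(self._region_names) - 1)
        if s_arr.ndim == 0:
            return self._region_names[int(idx)]
        names = np.array(self._region_names, dtype=object)
        return names[idx]

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        def seg_dict(seg):
            if isinstance(seg, _Straight):
                return {"kind": "straight", "p0": seg.p0.tolist(),
                        "direction": seg.direction.tolist(),
                        "length": seg.length, "s0": seg.s0}
            return {"kind": "arc", "center": seg.center.tolist(),
                    "e1": seg.e1.tolist(), "e2": seg.e2.tolist(),
                    "radius_c": seg.radius_c, "theta_max": seg.theta_max,
                    "s0": seg.s0}

        payload = {
            "tubes": [{"name": t.name, "q_fraction": t.q_fraction,
                       "s_knots": t.s_knots.tolist(), "r_knots": t.r_knots.tolist(),
                       "segments": [seg_dict(s) for s in t.segments]}
                      for t in self.tubes],
            "regions": {k: list(v) for k, v in self.regions.items()},
            "analysis_planes": self.analysis_planes,
            "outlet_point": self.outlet_point.tolist(),
            "outlet_dir": self.outlet_dir.tolist(),
        }
        return json.dumps(payload, indent=2)

    def geometry_hash(self) -> str:
        import hashlib
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class AirwayGeometry(DuctGeometry):
    """Idealized two-nostril upper airway (see module docstring)."""


@dataclass
class BendGeometryInfo:
    tube_radius: float
    bend_radius: float
    curvature_ratio: float
    inlet_extension: float
    outlet_extension: float


class BendGeometry(DuctGeometry):
    """90 degree circular-arc tube with straight inlet/outlet extensions."""

    info: BendGeometryInfo


# ---------------------------------------------------------------------------
# builders

def _chain(p, d, specs, s0=0.0):
    """Build consecutive segments from ('straight', L) / ('arc', n_hat, Rc) specs."""
    segments = []
    s = s0
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    for spec in specs:
        if spec[0] == "straight":
            L = float(spec[1])
            segments.append(_Straight(p0=p, direction=d, length=L, s0=s))
            p = p + L * d
            s += L
        elif spec[0] == "arc":
            n_hat = np.asarray(spec[1], dtype=float)  # unit toward bend center
            rc = float(spec[2])
            theta = float(spec[3]) if len(spec) > 3 else np.pi / 2
            center = p + rc * n_hat
            arc = _Arc(center=center, e1=-n_hat, e2=d, radius_c=rc,
                       theta_max=theta, s0=s)
            segments.append(arc)
            th = theta
            p = center + rc * (np.cos(th) * arc.e1 + np.sin(th) * arc.e2)
            d = -np.sin(th) * arc.e1 + np.cos(th) * arc.e2
            s += arc.length
        else:  # pragma: no cover
            raise ValueError(spec[0])
    return segments, p, d, s


@dataclass
class AirwayParams:
    """Tunable dimensions of the idealized airway (metres).

    Defaults give a 25 cm nostril-to-carina path: 3.5 cm vertical entry
    (vestibule + nasal valve), a 1.5 cm-radius bend to posterior, a
    turbinate passage, a bend down to the 11 cm merge point, and a 14 cm
    vertical pharynx-larynx-trachea trunk.  The nasal valve is the
    narrowest single passage (radius 3.6 mm per side); the glottis is the
    smallest combined cross-section (0.69 cm^2 vs 0.80 cm^2 for the two
    valves together), which concentrates the posterior pressure drop at
    the larynx and produces the laryngeal jet.
    """

    nostril_offset: float = 0.005
    vestibule_length: float = 0.020
    valve_length: float = 0.015
    bend_radius: float = 0.015
    branch_length: float = 0.110      # nostril to merge
    total_length: float = 0.250
    r_vestibule: float = 0.0047
    r_valve: float = 0.00357
    r_turbinate: float = 0.00505
    r_nasopharynx: float = 0.0105
    r_oropharynx: float = 0.0090
    r_glottis: float = 0.0047
    r_trachea: float = 0.0089
    region_bounds: dict = field(default_factory=lambda: {
        "vestibule": (0.000, 0.020),
        "nasal_valve": (0.020, 0.035),
        "turbinate": (0.035, 0.110),
        "nasopharynx": (0.110, 0.145),
        "oropharynx": (0.145, 0.180),
        "larynx": (0.180, 0.210),
        "trachea": (0.210, 0.250),
    })
    plane_first: float = 0.0053       # printed analysis-plane layout
    plane_spacing: float = 0.0111
    plane_a_offset: float = 0.00822   # below the nasopharynx roof (merge datum)
    plane_a_spacing: float = 0.0132
    jitter: float = 0.0               # multiplicative radius jitter fraction


def make_idealized_upper_airway(params: Optional[AirwayParams] = None,
                                seed: int = 0) -> AirwayGeometry:
    """Deterministic idealized airway for given (params, seed).

    Raises :class:`ConfigurationError` if region bounds do not tile
    [0, total_length], if the branch path length is inconsistent with the
    entry/bend dimensions, or if the trunk entrance cannot cover the two
    branch exits.
    """
    p = params or AirwayParams()
    entry = p.vestibule_length + p.valve_length
    arc_len = p.bend_radius * np.pi / 2
    turb_straight = p.branch_length - entry - 2 * arc_len
    if turb_straight <= 0:
        raise ConfigurationError(
            "branch_length too short for entry length plus two bends")
    bounds = p.region_bounds
    edges = [bounds[r] for r in REGION_ORDER]
    if abs(edges[0][0]) > 1e-12 or abs(edges[-1][1] - p.total_length) > 1e-9:
        raise ConfigurationError("region bounds must span [0, total_length]")
    for (a0, a1), (b0, b1) in zip(edges[:-1], edges[1:]):
        if abs(a1 - b0) > 1e-12 or a1 <= a0:
            raise ConfigurationError("regions must tile the centerline without gaps")
    if abs(bounds["turbinate"][1] - p.branch_length) > 1e-9:
        raise ConfigurationError("turbinate must end at the merge point")

    rng = np.random.default_rng(seed)

    def jit(r):
        if p.jitter == 0:
            return r
        return r * (1.0 + p.jitter * rng.uniform(-1, 1))

    branch_knots_s = np.array([0.0, p.vestibule_length,
                               p.vestibule_length + p.valve_length * 2 / 3,
                               entry, entry + arc_len, p.branch_length])
    branch_tubes = []
    for side, xoff in (("left", -p.nostril_offset), ("right", p.nostril_offset)):
        branch_knots_r = np.array([jit(p.r_vestibule), jit(p.r_vestibule),
                                   jit(p.r_valve), jit(p.r_valve) * 1.12,
                                   jit(p.r_turbinate), jit(p.r_turbinate)])
        segs, _, _, _ = _chain(
            [xoff, 0.0, 0.0], [0.0, 0.0, 1.0],
            [("straight", entry),
             ("arc", [0.0, 1.0, 0.0], p.bend_radius),
             ("straight", turb_straight),
             ("arc", [0.0, 0.0, -1.0], p.bend_radius)])
        branch_tubes.append(_Tube(name=f"nostril_{side}", segments=segs,
                                  s_knots=branch_knots_s, r_knots=branch_knots_r,
                                  q_fraction=0.5))

    # trunk start = branch exit projected onto the midline (z back at entry
    # height: the path rises one bend radius and descends it again)
    merge_y = 2 * p.bend_radius + turb_straight
    trunk_p0 = np.array([0.0, merge_y, entry])
    trunk_len = p.total_length - p.branch_length
    lb = bounds["larynx"]
    tb = bounds["trachea"]
    ob = bounds["oropharynx"]
    glottis_s = lb[0] + 2 / 3 * (lb[1] - lb[0])
    trunk_knots_s = np.array([p.branch_length, bounds["nasopharynx"][1],
                              ob[0] + 0.5 * (ob[1] - ob[0]), ob[1],
                              lb[0] + 0.5 * (glottis_s - lb[0]), glottis_s,
                              glottis_s + 0.5 * (lb[1] - glottis_s), lb[1],
                              p.total_length])
    if p.r_nasopharynx + 1e-9 < p.nostril_offset + p.r_turbinate:
        raise ConfigurationError(
            "nasopharynx radius must cover both branch exits "
            f"(need >= {p.nostril_offset + p.r_turbinate:.4g} m)")
    # jitter must not break the merge: the trunk entrance always covers the
    # two (jittered) branch exit circles
    r_exit = float(branch_tubes[0].radius(p.branch_length))
    r_naso_floor = p.nostril_offset + r_exit
    jit_naso = lambda: max(jit(p.r_nasopharynx), r_naso_floor)
    trunk_knots_r = np.array([jit_naso(), jit_naso(),
                              jit(p.r_oropharynx), jit(p.r_oropharynx),
                              jit(p.r_oropharynx) * 0.94, jit(p.r_glottis),
                              jit(p.r_trachea) * 0.9, jit(p.r_trachea),
                              jit(p.r_trachea)])
    trunk_segs, trunk_end, trunk_dir, _ = _chain(
        trunk_p0, [0.0, 0.0, -1.0], [("straight", trunk_len)],
        s0=p.branch_length)
    trunk = _Tube(name="trunk", segments=trunk_segs, s_knots=trunk_knots_s,
                  r_knots=trunk_knots_r, q_fraction=1.0)

    planes = {str(i + 1): p.plane_first + i * p.plane_spacing for i in range(10)}
    planes.update({chr(ord("A") + i): p.branch_length + p.plane_a_offset
                   + i * p.plane_a_spacing for i in range(10)})
    for name, s in planes.items():
        if s >= p.total_length:
            raise ConfigurationError(f"analysis plane {name} beyond the outlet")

    inlets = [{"center": np.array([xoff, 0.0, 0.0]),
               "direction": np.array([0.0, 0.0, 1.0]),
               "radius": float(t.radius(0.0)), "tube": i}
              for i, (t, xoff) in enumerate(zip(
                  branch_tubes, (-p.nostril_offset, p.nostril_offset)))]
    geom = AirwayGeometry(
        tubes=branch_tubes + [trunk],
        regions={r: bounds[r] for r in REGION_ORDER},
        outlet_point=trunk_end, outlet_dir=trunk_dir,
        inlets=inlets, analysis_planes=planes)
    geom.params = p
    return geom


def make_bend_geometry(curvature_ratio: float = 5.6,
                       tube_radius: float = 0.004,
                       extensions: tuple = None) -> BendGeometry:
    """90 degree bend of given curvature ratio with straight extensions.

    Curvature ratio is the bend centerline radius divided by the tube
    radius (5.6 for the validation case).  Extensions default to four
    tube radii on each side.
    """
    if curvature_ratio <= 1:
        raise ConfigurationError("curvature_ratio must exceed 1")
    if tube_radius <= 0:
        raise ConfigurationError("tube_radius must be positive")
    bend_radius = curvature_ratio * tube_radius
    ext_in, ext_out = extensions or (4 * tube_radius, 4 * tube_radius)
    segs, p_end, d_end, s_end = _chain(
        [0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
        [("straight", ext_in),
         ("arc", [0.0, 0.0, -1.0], bend_radius),  # turn +x -> -z
         ("straight", ext_out)])
    arc_len = bend_radius * np.pi / 2
    tube = _Tube(name="bend", segments=segs,
                 s_knots=np.array([0.0, s_end]),
                 r_knots=np.array([tube_radius, tube_radius]),
                 q_fraction=1.0)
    regions = {"inlet_extension": (0.0, ext_in),
               "bend": (ext_in, ext_in + arc_len),
               "outlet_extension": (ext_in + arc_len, s_end)}
    geom = BendGeometry(
        tubes=[tube], regions=regions,
        outlet_point=p_end, outlet_dir=d_end,
        inlets=[{"center": np.array([0.0, 0.0, 0.0]),
                 "direction": np.array([1.0, 0.0, 0.0]),
                 "radius": tube_radius, "tube": 0}])
    geom.info = BendGeometryInfo(
        tube_radius=tube_radius, bend_radius=bend_radius,
        curvature_ratio=curvature_ratio,
        inlet_extension=ext_in, outlet_extension=ext_out)
    return geom


# ---------------------------------------------------------------------------
# injection

def injection_positions(geometry: DuctGeometry, n: int,
                        mode: str = "uniform", seed: int = 0) -> np.ndarray:
    """Sample ``n`` starting positions strictly inside the inlet plane(s).

    ``uniform`` draws uniformly over each inlet disk; ``flow_weighted``
    weights the radial density by the laminar parabolic profile
    (density peaks mid-annulus at r = R/sqrt(3)).  Multi-inlet geometries
    split particles in proportion to the flow each branch carries (equal
    branches: counts differ by at most one, by round-robin assignment).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("uniform", "flow_weighted"):
        raise ConfigurationError(f"unknown injection mode {mode!r}")
    rng = np.random.default_rng(seed)
    inlets = geometry.inlets
    assignment = np.arange(n) % len(inlets)
    out = np.empty((n, 3))
    for i, inlet in enumerate(inlets):
        m = assignment == i
        k = int(m.sum())
        if k == 0:
            continue
        u = rng.uniform(size=k)
        if mode == "uniform":
            rad = np.sqrt(u)
        else:  # inverse CDF of f(r) ∝ r (1 - r^2): r^2 = 1 - sqrt(1 - u)
            rad = np.sqrt(1.0 - np.sqrt(1.0 - u))
        rad = rad * inlet["radius"] * (1.0 - 1e-9)
        theta = rng.uniform(0.0, 2 * np.pi, size=k)
        d = np.asarray(inlet["direction"], dtype=float)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        ex = np.cross(d, ref)
        ex /= np.linalg.norm(ex)
        ey = np.cross(d, ex)
        offs = (rad * np.cos(theta))[:, None] * ex + (rad * np.sin(theta))[:, None] * ey
        # nudge off the inlet plane so every start classifies interior
        out[m] = inlet["center"] + offs + 1e-9 * d
    return out
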