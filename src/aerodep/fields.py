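"""Prescribed steady flow fields and pointwise SST closure coefficients.

The full 3D Reynolds-averaged solution of the airway flow is out of
scope; the tracker instead consumes analytic stand-in fields that honour
continuity exactly:

* :class:`UniformField` — constant velocity (test harness, settling runs).
* :class:`PoiseuillePipeField` — laminar parabolic pipe profile.
* :class:`BendField` — velocity tangent to the 90 degree bend centerline
  (plug or parabolic cross-profile); no secondary Dean flow, since the
  bend benchmark validates inertial-impaction deposition, not the flow.
* :class:`AirwayDuctField` — quasi-1D streamtube field over an
  :class:`~aerodep.geometry.AirwayGeometry`: axial speed Q/A(s) per
  branch, with the radial component implied by the wall taper so tracer
  particles follow the contracting/expanding streamtube.

The shear-stress-transport (SST) low-Reynolds closure coefficients are
implemented pointwise:

    alpha* = (0.024 + Ret/6) / (1 + Ret/6)
    alpha  = (0.52 / alpha*) (1/9 + Ret/2.95) / (1 + Ret/2.95)
    mu_t   = alpha* rho k / omega,   Ret = rho k / (mu omega)

They feed the eddy-interaction dispersion model; the airway field carries
a flat turbulent kinetic energy k = (3/2)(I U)^2 with intensity I = 5%
only at stations whose duct Reynolds number exceeds the pipe-flow
transition threshold, and omega from the mixing-length estimate
omega = sqrt(k) / (0.07 D).  At 5–15 L/min the whole default airway is
below threshold, so k is identically zero there (laminar regime).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ConfigurationError, DuctGeometry, GeometryQuery
from .physics import AIR, FluidProperties

__all__ = [
    "FlowSample",
    "TurbulenceClosureCoefficients",
    "FlowField",
    "UniformField",
    "PoiseuillePipeField",
    "BendField",
    "AirwayDuctField",
    "turbulent_reynolds",
    "sst_alpha_star",
    "sst_alpha",
    "sst_turbulent_viscosity",
    "uniform_field",
    "poiseuille_pipe_field",
    "bend_field",
    "airway_duct_field",
]

RE_TRANSITION = 2300.0
TURBULENCE_INTENSITY = 0.05
MIXING_LENGTH_FRACTION = 0.07


# ---------------------------------------------------------------------------
# SST closure coefficients

def turbulent_reynolds(rho, k, omega, mu):
    """Turbulent Reynolds number Ret = rho k / (mu omega)."""
    return np.asarray(rho * k, dtype=float) / (mu * np.asarray(omega, dtype=float))


def sst_alpha_star(ret):
    """Low-Reynolds damping alpha* = (0.024 + Ret/6)/(1 + Ret/6), in [0.024, 1)."""
    ret_arr = np.asarray(ret, dtype=float)
    if np.any(ret_arr < 0):
        raise ValueError(f"ret must be non-negative, got {ret!r}")
    x = ret_arr / 6.0
    out = (0.024 + x) / (1.0 + x)
    return out if out.ndim else float(out)


def sst_alpha(ret):
    """Production coefficient alpha = (0.52/alpha*)(1/9 + Ret/2.95)/(1 + Ret/2.95).

    Tends to 0.52 from above as Ret -> infinity.
    """
    ret_arr = np.asarray(ret, dtype=float)
    if np.any(ret_arr < 0):
        raise ValueError(f"ret must be non-negative, got {ret!r}")
    x = ret_arr / 2.95
    out = (0.52 / sst_alpha_star(ret_arr)) * (1.0 / 9.0 + x) / (1.0 + x)
    return out if out.ndim else float(out)


def sst_turbulent_viscosity(rho, k, omega, mu):
    """Turbulent viscosity mu_t = alpha*(Ret) rho k / omega; zero where k = 0."""
    k_arr = np.asarray(k, dtype=float)
    om_arr = np.asarray(omega, dtype=float)
    if np.any((k_arr > 0) & (om_arr <= 0)):
        raise ValueError("omega must be positive wherever k > 0")
    om_safe = np.where(om_arr > 0, om_arr, 1.0)
    ret = turbulent_reynolds(rho, k_arr, om_safe, mu)
    mu_t = np.where(k_arr > 0, sst_alpha_star(ret) * rho * k_arr / om_safe, 0.0)
    return mu_t if mu_t.ndim else float(mu_t)


@dataclass(frozen=True)
class TurbulenceClosureCoefficients:
    """Pointwise SST coefficients evaluated at one turbulent Reynolds number."""

    ret: float
    alpha: float
    alpha_star: float

    @classmethod
    def from_state(cls, rho: float, k: float, omega: float,
                   mu: float) -> "TurbulenceClosureCoefficients":
        ret = float(turbulent_reynolds(rho, k, omega, mu))
        return cls(ret=ret, alpha=float(sst_alpha(ret)),
                   alpha_star=float(sst_alpha_star(ret)))


@dataclass(frozen=True)
class FlowSample:
    """Local carrier-flow state: mean velocity plus turbulence statistics."""

    velocity: np.ndarray  # (3,), m/s
    k: float = 0.0        # m^2/s^2
    omega: float = 1.0    # 1/s

    def mu_t(self, rho: float = AIR.rho, mu: float = AIR.mu) -> float:
        return float(sst_turbulent_viscosity(rho, self.k, self.omega, mu))


# ---------------------------------------------------------------------------
# fields

class FlowField:
    """Field contract: batch sampling, wall classification, reference scales.

    ``sample_batch(x)`` returns (velocity (N,3), k (N,), omega (N,)) and
    must give zero velocity at wall-classified points (no-slip).
    """

    bulk_velocity: float
    reference_length: float
    geometry: DuctGeometry | None = None

    def sample(self, x) -> FlowSample:
        u, k, om = self.sample_batch(np.asarray(x, dtype=float).reshape(1, 3))
        return FlowSample(velocity=u[0], k=float(k[0]), omega=float(om[0]))

    def sample_raw(self, x) -> FlowSample:
        """Like :meth:`sample` but without the no-slip wall clamp; used by
        the tracker for mid-step coefficient refreshes that may probe a
        whisker outside the wall."""
        return self.sample(x)

    def sample_batch(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def classify(self, x):
        if self.geometry is None:
            return "interior", None
        return self.geometry.classify(x)


class UniformField(FlowField):
    """Constant velocity everywhere; k = 0; every point interior."""

    def __init__(self, u_vector):
        u = np.asarray(u_vector, dtype=float)
        if u.shape != (3,) or not np.all(np.isfinite(u)):
            raise ValueError("u_vector must be a finite 3-vector")
        self.u = u
        speed = float(np.linalg.norm(u))
        self.bulk_velocity = speed
        self.reference_length = 1.0

    def sample_batch(self, x):
        x = np.atleast_2d(x)
        n = x.shape[0]
        return (np.broadcast_to(self.u, (n, 3)).copy(),
                np.zeros(n), np.ones(n))


class _DuctFieldBase(FlowField):
    """Shared velocity construction over a DuctGeometry query."""

    profile: str = "plug"
    k_of_s = None  # optional callable s -> k

    def sample_raw(self, x) -> FlowSample:
        q = self.geometry.query(np.asarray(x, dtype=float).reshape(1, 3))
        u, k, om = self._velocity_from_query(q, self.flow, no_slip=False)
        return FlowSample(velocity=u[0], k=float(k[0]), omega=float(om[0]))

    def _velocity_from_query(self, q: GeometryQuery, total_flow: float,
                             no_slip: bool = True):
        area = np.pi * q.r ** 2
        u_ax = total_flow * q.q_fraction / area
        if self.profile in ("parabolic", "parabolic-equivalent"):
            shape = 2.0 * np.maximum(1.0 - (q.dist / q.r) ** 2, 0.0)
        else:
            shape = 1.0
        speed = u_ax * shape
        # streamtube radial drift from the wall taper: u_r = u_s (dr/ds)(d/r)/h,
        # with the bend metric h so the drift tracks r(s) at the particle's
        # own rate of progress along the centerline
        vel = speed[:, None] * (q.axial
                                + (q.drds * q.dist / (q.r * q.h))[:, None] * q.radial_unit)
        if no_slip:
            vel[q.depth >= 0] = 0.0  # no-slip at / beyond the wall
        if self.k_of_s is None:
            k = np.zeros(len(q.s))
            om = np.ones(len(q.s))
        else:
            k, om = self.k_of_s(q)
        return vel, k, om


class PoiseuillePipeField(_DuctFieldBase):
    """Laminar pipe flow u(r) = 2 U_mean (1 - r^2/R^2) in a straight tube."""

    profile = "parabolic"

    def __init__(self, radius: float, length: float, volumetric_flow: float,
                 axis_origin=(0.0, 0.0, 0.0), axis_direction=(1.0, 0.0, 0.0)):
        if radius <= 0 or length <= 0 or volumetric_flow <= 0:
            raise ValueError("radius, length and volumetric_flow must be positive")
        from .geometry import _Straight, _Tube  # shared duct machinery

        d = np.asarray(axis_direction, dtype=float)
        d = d / np.linalg.norm(d)
        p0 = np.asarray(axis_origin, dtype=float)
        tube = _Tube(name="pipe",
                     segments=[_Straight(p0=p0, direction=d, length=length, s0=0.0)],
                     s_knots=np.array([0.0, length]),
                     r_knots=np.array([radius, radius]))
        self.geometry = DuctGeometry(
            tubes=[tube], regions={"pipe": (0.0, length)},
            outlet_point=p0 + length * d, outlet_dir=d,
            inlets=[{"center": p0, "direction": d, "radius": radius, "tube": 0}])
        self.radius = radius
        self.flow = volumetric_flow
        self.bulk_velocity = volumetric_flow / (np.pi * radius ** 2)
        self.reference_length = 2 * radius

    def sample_batch(self, x):
        q = self.geometry.query(np.atleast_2d(x))
        return self._velocity_from_query(q, self.flow)


class BendField(_DuctFieldBase):
    """Flow through the 90 degree validation bend: everywhere tangent to the
    local circular-arc centerline, plug (default) or parabolic profile;
    no secondary flow."""

    def __init__(self, geometry, volumetric_flow: float, profile: str = "plug"):
        if profile not in ("plug", "parabolic"):
            raise ConfigurationError(f"unknown bend profile {profile!r}")
        self.geometry = geometry
        self.flow = volumetric_flow
        self.profile = profile
        r = geometry.info.tube_radius
        self.bulk_velocity = volumetric_flow / (np.pi * r ** 2)
        self.reference_length = 2 * r

    def sample_batch(self, x):
        q = self.geometry.query(np.atleast_2d(x))
        return self._velocity_from_query(q, self.flow)


class AirwayDuctField(_DuctFieldBase):
    """Quasi-1D streamtube field over the idealized airway.

    Axial speed U(s) = Q_branch/A(s) (Q/2 per nostril, Q past the merge);
    continuity U A = Q_branch holds at every station by construction.
    Turbulent kinetic energy follows the 1D transition indicator: zero
    where the station Reynolds number is below 2300, else (3/2)(0.05 U)^2
    with omega = sqrt(k)/(0.07 D).
    """

    def __init__(self, geometry, volumetric_flow: float, profile: str = "plug",
                 fluid: FluidProperties = AIR, turbulence: bool = True):
        if volumetric_flow <= 0:
            raise ValueError("volumetric_flow must be positive")
        if profile not in ("plug", "parabolic-equivalent"):
            raise ConfigurationError(f"unknown airway profile {profile!r}")
        self.geometry = geometry
        self.flow = volumetric_flow
        self.profile = profile
        self.fluid = fluid
        self.turbulence = turbulence
        r_in = geometry.inlets[0]["radius"]
        self.bulk_velocity = (volumetric_flow / len(geometry.inlets)
                              / (np.pi * r_in ** 2))
        self.reference_length = 2 * r_in
        if turbulence:
            self.k_of_s = self._k_indicator

    def _k_indicator(self, q: GeometryQuery):
        area = np.pi * q.r ** 2
        u = self.flow * q.q_fraction / area
        re = self.fluid.rho * u * 2 * q.r / self.fluid.mu
        k = np.where(re > RE_TRANSITION,
                     1.5 * (TURBULENCE_INTENSITY * u) ** 2, 0.0)
        om = np.where(k > 0, np.sqrt(np.maximum(k, 0.0))
                      / (MIXING_LENGTH_FRACTION * 2 * q.r), 1.0)
        return k, om

    def sample_batch(self, x):
        q = self.geometry.query(np.atleast_2d(x))
        return self._velocity_from_query(q, self.flow)


# functional aliases matching the operation names used elsewhere
def uniform_field(u_vector) -> UniformField:
    return UniformField(u_vector)


def poiseuille_pipe_field(radius, length, volumetric_flow, **kw) -> PoiseuillePipeField:
    return PoiseuillePipeField(radius, length, volumetric_flow, **kw)


def bend_field(tube_radius, curvature_ratio, volumetric_flow,
               profile="plug", extensions=None) -> BendField:
    from .geometry import make_bend_geometry

    geom = make_bend_geometry(curvature_ratio=curvature_ratio,
                              tube_radius=tube_radius, extensions=extensions)
    return BendField(geom, volumetric_flow, profile)


def airway_duct_field(geometry, volumetric_flow, profile="plug", **kw) -> AirwayDuctField:
    return AirwayDuctField(geometry, volumetric_flow, profile, **kw)
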