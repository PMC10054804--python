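"""Pointwise aerosol property formulas.

Single-particle quantities used throughout the tracker: the Cunningham
slip correction ``Cc`` for particles whose size is comparable to the gas
mean free path, the Stokes relaxation time ``tau_p = rho_p dp^2 Cc / 18 mu``,
the particle Reynolds number ``Re_p``, the piecewise drag-coefficient
correlation (Stokes law below Re_p = 1, the Schiller–Naumann-type
correction ``1 + 0.15 Re_p^0.687`` up to Re_p = 1e3), and the Stokes
number ``Stk = tau_p U / D`` that governs inertial impaction.

All functions are pure, accept scalars or numpy arrays, and work in
strict SI units.  Micrometres and L/min are converted at the interface
layer (:mod:`aerodep.cli`), never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidProperties",
    "ParticleSpec",
    "DragState",
    "StokesPoint",
    "AIR",
    "cunningham_correction",
    "relaxation_time",
    "particle_reynolds",
    "drag_coefficient",
    "drag_factor",
    "stokes_number",
]

REP_MAX = 1.0e3  # upper end of the drag correlation's validity


def _require_positive(name: str, value) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class FluidProperties:
    """Carrier-gas state: density, dynamic viscosity, molecular mean free path."""

    rho: float  # kg/m^3
    mu: float  # Pa s
    lambda_mfp: float  # m
    temperature_note: str = ""

    def __post_init__(self) -> None:
        _require_positive("rho", self.rho)
        _require_positive("mu", self.mu)
        _require_positive("lambda_mfp", self.lambda_mfp)


#: Air at 20 degC / 1 atm; overridable via run configuration.
AIR = FluidProperties(rho=1.204, mu=1.81e-5, lambda_mfp=65e-9,
                      temperature_note="air, 20 degC, 1 atm")


def cunningham_correction(dp, lambda_mfp):
    """Cunningham slip correction ``Cc = 1 + (2 lam/dp)(1.257 + 0.4 exp(-0.55 dp/lam))``.

    Strictly greater than 1, monotonically decreasing in ``dp`` at fixed
    mean free path; tends to 1 in the continuum limit dp >> lambda.
    """
    _require_positive("dp", dp)
    _require_positive("lambda_mfp", lambda_mfp)
    dp = np.asarray(dp, dtype=float)
    kn2 = 2.0 * lambda_mfp / dp  # twice the Knudsen number
    cc = 1.0 + kn2 * (1.257 + 0.4 * np.exp(-0.55 * dp / lambda_mfp))
    return cc if cc.ndim else float(cc)


def relaxation_time(dp, rho_p, fluid: FluidProperties):
    """Particle relaxation time ``tau_p = rho_p dp^2 Cc / (18 mu)`` in seconds."""
    _require_positive("dp", dp)
    _require_positive("rho_p", rho_p)
    cc = cunningham_correction(dp, fluid.lambda_mfp)
    return rho_p * np.asarray(dp, dtype=float) ** 2 * cc / (18.0 * fluid.mu)


@dataclass(frozen=True)
class ParticleSpec:
    """Aerosol particle definition with cached slip correction and relaxation time.

    ``cc`` and ``tau_p`` are derived against the fluid passed to
    :meth:`from_diameter` and are consistent with it by construction.
    """

    dp: float  # m
    rho_p: float  # kg/m^3
    cc: float
    tau_p: float  # s

    def __post_init__(self) -> None:
        _require_positive("dp", self.dp)
        _require_positive("rho_p", self.rho_p)
        if self.cc < 1.0:
            raise ValueError(f"cc must be >= 1, got {self.cc}")
        _require_positive("tau_p", self.tau_p)

    @classmethod
    def from_diameter(cls, dp: float, fluid: FluidProperties = AIR,
                      rho_p: float = 1000.0) -> "ParticleSpec":
        """Build a spec for diameter ``dp`` (m); default unit-density spheres."""
        cc = float(cunningham_correction(dp, fluid.lambda_mfp))
        tau_p = float(relaxation_time(dp, rho_p, fluid))
        return cls(dp=float(dp), rho_p=float(rho_p), cc=cc, tau_p=tau_p)


def particle_reynolds(dp, slip_speed, fluid: FluidProperties):
    """Particle Reynolds number ``Re_p = rho dp |u - v| / mu``."""
    _require_positive("dp", dp)
    if np.any(np.asarray(slip_speed) < 0):
        raise ValueError(f"slip_speed must be non-negative, got {slip_speed!r}")
    return fluid.rho * np.asarray(dp, dtype=float) * np.asarray(slip_speed, dtype=float) / fluid.mu


def drag_coefficient(rep):
    """Drag coefficient: ``24/Re_p`` for Re_p < 1, ``(24/Re_p)(1 + 0.15 Re_p^0.687)``
    for 1 <= Re_p <= 1e3 (as the correlation is printed, with its jump at Re_p = 1).

    Undefined at Re_p = 0 (Stokes drag's Cd diverges); use :func:`drag_factor`
    for the finite group ``Cd Re_p / 24`` appearing in the equation of motion.
    """
    rep_arr = np.asarray(rep, dtype=float)
    if np.any(rep_arr < 0):
        raise ValueError(f"rep must be non-negative, got {rep!r}")
    if np.any(rep_arr > REP_MAX):
        raise ValueError(f"rep outside drag-correlation range (max {REP_MAX:g}): {rep!r}")
    if np.any(rep_arr == 0):
        raise ZeroDivisionError("Cd diverges at rep = 0; use drag_factor instead")
    cd = np.where(rep_arr < 1.0,
                  24.0 / rep_arr,
                  (24.0 / rep_arr) * (1.0 + 0.15 * rep_arr ** 0.687))
    return cd if cd.ndim else float(cd)


def drag_factor(rep):
    """The finite drag group ``f = Cd Re_p / 24``: 1 in the Stokes regime
    (Re_p < 1, including Re_p = 0), ``1 + 0.15 Re_p^0.687`` for 1 <= Re_p <= 1e3.
    """
    rep_arr = np.asarray(rep, dtype=float)
    if np.any(rep_arr < 0):
        raise ValueError(f"rep must be non-negative, got {rep!r}")
    if np.any(rep_arr > REP_MAX):
        raise ValueError(f"rep outside drag-correlation range (max {REP_MAX:g}): {rep!r}")
    f = np.where(rep_arr < 1.0, 1.0, 1.0 + 0.15 * rep_arr ** 0.687)
    return f if f.ndim else float(f)


@dataclass(frozen=True)
class DragState:
    """Diagnostic triple (Re_p, Cd, Cd·Re_p/24) for one particle at one instant."""

    rep: float
    cd: float
    f_drag: float = field(default=0.0)

    @classmethod
    def at(cls, rep: float) -> "DragState":
        f = drag_factor(rep)
        cd = drag_coefficient(rep) if rep > 0 else float("inf")
        return cls(rep=float(rep), cd=cd, f_drag=float(f))


def stokes_number(spec: ParticleSpec, u_ref: float, d_ref: float) -> float:
    """Stokes number ``Stk = tau_p U / D`` with the bulk mean velocity and
    tube diameter as reference scales (the bend-deposition convention)."""
    _require_positive("u_ref", u_ref)
    _require_positive("d_ref", d_ref)
    return spec.tau_p * u_ref / d_ref


@dataclass(frozen=True)
class StokesPoint:
    """A Stokes number together with the reference scales it was formed from."""

    stk: float
    u_ref: float
    d_ref: float
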