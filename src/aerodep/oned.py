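"""Quasi-1D station analysis of the airway: velocity, pressure, TKE proxy.

An emulation layer over a cross-section area series A(s): mean speed
from continuity (U = Q_branch / A, branch flows summing at the merge),
gauge pressure from an extended Bernoulli balance with Darcy–Weisbach
friction (f = 64/Re laminar, f = 0.316 Re^-1/4 past the transition
threshold Re = 2300) and standard minor-loss coefficients at abrupt
sections (K = 0.5 sudden contraction, Borda–Carnot K = (1 - A2/A1)^2
expansion), and a turbulence indicator that is zero where the station
Reynolds number is laminar and k = (3/2)(0.05 U)^2 elsewhere.

No one-dimensional model of this kind exists in a 3D CFD study — it is
this package's desk-scale stand-in for plane-by-plane profiles, and it
reproduces trends (pressure drop concentrated at the constrictions,
zero TKE at 5–15 L/min), not patient-specific numbers.  Elevation head
is neglected (air, centimetre heights).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .geometry import DuctGeometry
from .physics import AIR, FluidProperties

__all__ = [
    "CrossSectionSeries",
    "mean_velocity_profile",
    "pressure_profile",
    "turbulence_indicator",
    "analyze_profiles",
    "RE_TRANSITION",
]

RE_TRANSITION = 2300.0
#: area-ratio beyond which a station pair counts as an abrupt transition
ABRUPT_RATIO = 1.3
K_CONTRACTION = 0.5
#: regions upstream of the merge, duplicated across the two nostrils
_BRANCH_REGIONS = frozenset({"vestibule", "nasal_valve", "turbinate"})


@dataclass
class CrossSectionSeries:
    """Ordered stations (s, area, hydraulic diameter, region, n_parallel).

    ``area_m2`` is the per-passage area; ``n_parallel`` the number of
    identical parallel passages at the station (2 in the nasal branches,
    1 past the merge), so the station flow is Q_total / n_parallel and
    the total sectional area is n_parallel * area.
    """

    stations: pd.DataFrame

    COLUMNS = ("s_m", "area_m2", "dh_m", "region", "n_parallel")

    def __post_init__(self) -> None:
        df = self.stations
        missing = {"s_m", "area_m2", "dh_m", "region"} - set(df.columns)
        if missing:
            raise ValueError(f"area series missing columns {sorted(missing)}")
        if "n_parallel" not in df.columns:
            df = df.copy()
            df["n_parallel"] = [2 if r in _BRANCH_REGIONS else 1
                                for r in df["region"]]
            self.stations = df
        if not (df["area_m2"] > 0).all():
            raise ValueError("all areas must be positive")
        if not np.all(np.diff(df["s_m"].to_numpy()) > 0):
            raise ValueError("station arc lengths must be strictly increasing")

    @classmethod
    def from_geometry(cls, geometry: DuctGeometry, ds: float = 0.005
                      ) -> "CrossSectionSeries":
        """Sample the geometry's radius profile every ``ds`` metres, always
        including region boundaries and the ends."""
        edges = sorted({b for se in geometry.regions.values() for b in se})
        s_vals = np.unique(np.concatenate(
            [np.arange(0.0, geometry.total_length, ds),
             np.asarray(edges), [geometry.total_length]]))
        s_vals = np.clip(s_vals, 0.0, geometry.total_length)
        branch = geometry.tubes[0]
        trunk = geometry.tubes[-1]
        rows = []
        for s in s_vals:
            tube = trunk if s >= trunk.s_start - 1e-12 else branch
            r = float(tube.radius(s))
            rows.append({"s_m": float(s), "area_m2": np.pi * r ** 2,
                         "dh_m": 2 * r, "region": geometry.region_at(float(s)),
                         "n_parallel": 2 if tube is branch and len(geometry.tubes) > 1 else 1})
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path_or_buf: Union[str, io.IOBase]) -> "CrossSectionSeries":
        """Read a delimited series with header ``s_m,area_m2,dh_m,region``
        (optional ``n_parallel`` column)."""
        return cls(pd.read_csv(path_or_buf))

    def to_csv(self, path_or_buf=None):
        return self.stations.to_csv(path_or_buf, index=False)


def _station_velocity(series: CrossSectionSeries, flow: float) -> pd.DataFrame:
    df = series.stations.copy()
    df["U"] = flow / df["n_parallel"] / df["area_m2"]
    return df


def mean_velocity_profile(series: CrossSectionSeries, flow: float) -> pd.DataFrame:
    """Station mean speeds U = (Q / n_parallel) / A; continuity is exact,
    and the merged trunk carries the sum of the branch flows."""
    if flow <= 0:
        raise ValueError("flow must be positive")
    return _station_velocity(series, flow)[
        ["s_m", "region", "area_m2", "n_parallel", "U"]]


def _friction_factor(re):
    re = np.asarray(re, dtype=float)
    lam = 64.0 / np.maximum(re, 1e-12)
    turb = 0.316 * np.maximum(re, 1e-12) ** -0.25
    return np.where(re < RE_TRANSITION, lam, turb)


def pressure_profile(series: CrossSectionSeries, flow: float,
                     fluid: FluidProperties = AIR) -> pd.DataFrame:
    """Gauge pressure along the stations from an extended Bernoulli balance.

    Inlet gauge pressure is zero; between consecutive stations the drop
    combines the dynamic-head change, Darcy–Weisbach wall friction at the
    pair-average conditions, and a minor loss when the area changes
    abruptly (ratio beyond 1.3): K = 0.5 for a sudden contraction,
    K = (1 - A2/A1)^2 for a sudden expansion, charged on the higher
    velocity head.
    """
    df = _station_velocity(series, flow)
    u = df["U"].to_numpy()
    s = df["s_m"].to_numpy()
    dh = df["dh_m"].to_numpy()
    area_tot = (df["area_m2"] * df["n_parallel"]).to_numpy()
    re = fluid.rho * u * dh / fluid.mu
    minor = _minor_losses(area_tot, u, fluid)
    p = np.zeros(len(df))
    for i in range(1, len(df)):
        u1, u2 = u[i - 1], u[i]
        dyn = 0.5 * fluid.rho * (u2 ** 2 - u1 ** 2)
        u_avg = 0.5 * (u1 + u2)
        re_avg = 0.5 * (re[i - 1] + re[i])
        dh_avg = 0.5 * (dh[i - 1] + dh[i])
        fric = (_friction_factor(re_avg) * (s[i] - s[i - 1]) / dh_avg
                * 0.5 * fluid.rho * u_avg ** 2)
        p[i] = p[i - 1] - dyn - fric - minor[i]
    out = df[["s_m", "region", "U"]].copy()
    out["Re"] = re
    out["p"] = p
    return out


def _minor_losses(area_tot, u, fluid: FluidProperties):
    """One loss per contraction/expansion feature, charged at the station
    where the monotone area run ends: K = 0.5 for a contraction whose
    overall ratio exceeds 1.3, Borda–Carnot K = (1 - A_small/A_big)^2 for
    an expansion, both on the higher velocity head."""
    n = len(area_tot)
    minor = np.zeros(n)
    run_start = 0
    direction = 0  # -1 contracting, +1 expanding
    for i in range(1, n + 1):
        d = 0 if i == n else int(np.sign(area_tot[i] - area_tot[i - 1]))
        if d != direction or i == n:
            a0, a1 = area_tot[run_start], area_tot[i - 1]
            if direction == -1 and a0 / a1 > ABRUPT_RATIO:
                minor[i - 1] = K_CONTRACTION * 0.5 * fluid.rho * u[i - 1] ** 2
            elif direction == 1 and a1 / a0 > ABRUPT_RATIO:
                minor[i - 1] = ((1.0 - a0 / a1) ** 2
                                * 0.5 * fluid.rho * u[run_start] ** 2)
            run_start = i - 1
            direction = d
    return minor


def turbulence_indicator(series: CrossSectionSeries, flow: float,
                         fluid: FluidProperties = AIR,
                         intensity: float = 0.05) -> pd.DataFrame:
    """Per-station TKE proxy: 0 below the transition Reynolds number,
    (3/2)(I U)^2 above it; flags the transition stations."""
    df = _station_velocity(series, flow)
    re = fluid.rho * df["U"] * df["dh_m"] / fluid.mu
    k = np.where(re > RE_TRANSITION, 1.5 * (intensity * df["U"]) ** 2, 0.0)
    out = df[["s_m", "region", "U"]].copy()
    out["Re"] = re
    out["k_indicator"] = k
    out["transitional"] = re > RE_TRANSITION
    return out


def analyze_profiles(series: CrossSectionSeries, flow: float,
                     fluid: FluidProperties = AIR) -> pd.DataFrame:
    """Full station table: U, Re, gauge pressure, TKE indicator."""
    p = pressure_profile(series, flow, fluid)
    k = turbulence_indicator(series, flow, fluid)
    out = p.copy()
    out["k_indicator"] = k["k_indicator"].to_numpy()
    out["transitional"] = k["transitional"].to_numpy()
    return out
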