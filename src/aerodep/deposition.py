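"""Aggregate particle fates into deposition statistics.

The central quantity is the regional deposition efficiency

    DE(zone) = (number of particles deposited in the zone)
               / (number injected at the inlet),

reported per anatomical region, as an anterior aggregate
(vestibule + nasal valve), as an axial deposition-fraction profile along
the centerline arc length, and as the lung-delivery efficiency (the
fraction escaping the trachea outlet toward the lower airway).
All quantities are fractions internally; percent is presentation-layer
only.  ``time_expired``/``failed`` particles are counted as *unresolved*:
they enter neither the deposition nor the escape numerators, but they
are reported, so the conservation identity

    sum of per-region DE + lung delivery + unresolved = 1

holds exactly for every ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import ANTERIOR_REGIONS, DuctGeometry

__all__ = [
    "DepositionSummary",
    "records_frame",
    "deposition_efficiency",
    "regional_deposition_table",
    "axial_deposition_profile",
    "lung_delivery_efficiency",
]


def records_frame(records) -> pd.DataFrame:
    """Coerce a record collection (DataFrame or DepositionRecord iterable)
    into the canonical DataFrame form."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = [{"pid": r.particle_id, "dp_m": r.dp, "fate": r.fate,
             "region": r.region_at_fate, "s_m": r.arc_length_at_fate,
             "t_s": r.flight_time} for r in records]
    return pd.DataFrame(rows)


@dataclass
class DepositionSummary:
    """Aggregate deposition statistics for one ensemble."""

    per_region: dict                    # region -> DE fraction
    anterior_fraction: float            # vestibule + nasal valve
    total_deposition: float
    lung_delivery_fraction: float
    unresolved_fraction: float
    n_injected: int
    n_deposited: int
    n_escaped: int
    n_unresolved: int
    axial_profile: Optional[pd.DataFrame] = field(default=None, repr=False)

    def check_conservation(self, tol: float = 1e-12) -> None:
        total = (sum(self.per_region.values()) + self.lung_delivery_fraction
                 + self.unresolved_fraction)
        if abs(total - 1.0) > tol:
            raise AssertionError(f"fraction conservation violated: {total}")

    def to_dict(self) -> dict:
        """Machine-readable summary (axial profile as bin records)."""
        out = {
            "per_region": dict(self.per_region),
            "anterior_fraction": self.anterior_fraction,
            "total_deposition": self.total_deposition,
            "lung_delivery_fraction": self.lung_delivery_fraction,
            "unresolved_fraction": self.unresolved_fraction,
            "n_injected": self.n_injected,
            "n_deposited": self.n_deposited,
            "n_escaped": self.n_escaped,
            "n_unresolved": self.n_unresolved,
        }
        if self.axial_profile is not None:
            out["axial_profile"] = self.axial_profile.to_dict(orient="records")
        return out

    def as_row(self) -> dict:
        row = {f"de_{k}": v for k, v in self.per_region.items()}
        row.update(anterior=self.anterior_fraction,
                   total_deposition=self.total_deposition,
                   lung_delivery=self.lung_delivery_fraction,
                   unresolved=self.unresolved_fraction,
                   n=self.n_injected)
        return row


def deposition_efficiency(records, zone: str, valid_zones=None) -> float:
    """Fraction of injected particles deposited in ``zone``."""
    df = records_frame(records)
    if len(df) == 0:
        raise ValueError("empty record collection")
    if valid_zones is not None and zone not in valid_zones:
        raise ValueError(f"unknown zone {zone!r}; valid zones: {sorted(valid_zones)}")
    deposited = df[df["fate"].astype(str) == "deposited"]
    return float((deposited["region"] == zone).sum()) / len(df)


def lung_delivery_efficiency(records) -> float:
    """Fraction of injected particles escaping the trachea outlet."""
    df = records_frame(records)
    if len(df) == 0:
        raise ValueError("empty record collection")
    return float((df["fate"].astype(str) == "escaped").sum()) / len(df)


def axial_deposition_profile(records, bin_width: float,
                             total_length: Optional[float] = None) -> pd.DataFrame:
    """Histogram of deposited arc lengths, normalized by the injected count.

    Returns bins with ``s_start, s_end, fraction, cumulative``; the
    cumulative column supports first-X-mm claims and ends at the total
    deposited fraction.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    df = records_frame(records)
    n = len(df)
    dep = df[df["fate"].astype(str) == "deposited"]
    s_max = total_length
    if s_max is None:
        s_max = float(dep["s_m"].max()) if len(dep) else bin_width
    edges = np.arange(0.0, s_max + bin_width, bin_width)
    if edges[-1] < s_max:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(dep["s_m"].to_numpy(dtype=float), bins=edges)
    frac = counts / n if n else counts.astype(float)
    return pd.DataFrame({"s_start": edges[:-1], "s_end": edges[1:],
                         "fraction": frac, "cumulative": np.cumsum(frac)})


def regional_deposition_table(records, geometry: DuctGeometry,
                              bin_width: float = 0.01) -> DepositionSummary:
    """Per-region DE for every labeled region, plus aggregates.

    Unknown region labels in the records (not defined by the geometry)
    raise; permutation of record order leaves the table unchanged.
    """
    df = records_frame(records)
    if len(df) == 0:
        raise ValueError("empty record collection")
    n = len(df)
    regions = list(geometry.regions.keys())
    fate = df["fate"].astype(str)
    dep = df[fate == "deposited"]
    labels = set(dep["region"].dropna().unique())
    unknown = labels - set(regions)
    if unknown:
        raise ValueError(f"records reference unknown zones {sorted(unknown)}; "
                         f"valid zones: {regions}")
    counts = dep["region"].value_counts()
    per_region = {r: float(counts.get(r, 0)) / n for r in regions}
    n_dep = int(len(dep))
    n_esc = int((fate == "escaped").sum())
    n_unres = n - n_dep - n_esc
    anterior = sum(per_region.get(r, 0.0) for r in ANTERIOR_REGIONS)
    summary = DepositionSummary(
        per_region=per_region,
        anterior_fraction=anterior,
        total_deposition=n_dep / n,
        lung_delivery_fraction=n_esc / n,
        unresolved_fraction=n_unres / n,
        n_injected=n, n_deposited=n_dep, n_escaped=n_esc, n_unresolved=n_unres,
        axial_profile=axial_deposition_profile(df, bin_width,
                                               geometry.total_length))
    summary.check_conservation()
    return summary
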