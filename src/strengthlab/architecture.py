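"""Quadriceps muscle architecture from tabulated ultrasound measurements.

Inputs are measured quantities, not images: three inter-aponeurosis
distances per image (two edges, one midpoint) whose mean is the site
muscle thickness, and fascicle pennation angles for the vastus
lateralis (VL) at 20, 50 and 60% of thigh length.  Fascicle length is
the standard linear estimate FL = thickness / sin(theta), computed per
measurement and then averaged (flat mean over site x image x repeat).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "SiteMeasurement",
    "ArchitectureRecord",
    "site_thickness",
    "fascicle_length",
    "aggregate_vl",
    "summarize_architecture",
]

VL_SITES = (20, 50, 60)


@dataclass(frozen=True)
class SiteMeasurement:
    """One ultrasound image's measurements at one muscle site."""

    muscle: str                       # VL, RF, VI or VM
    site_pct_thigh: int               # 20, 50 or 60 (% thigh length)
    image_id: int
    thickness_points_mm: tuple        # three inter-aponeurosis distances
    pennation_deg: Optional[float] = None  # VL only

    def __post_init__(self):
        if self.muscle not in ("VL", "RF", "VI", "VM"):
            raise InvalidParameterError(f"unknown muscle {self.muscle!r}")
        if len(self.thickness_points_mm) != 3:
            raise InvalidParameterError("exactly three thickness points required")

    @property
    def thickness_mm(self) -> float:
        return site_thickness(self.thickness_points_mm)


@dataclass(frozen=True)
class ArchitectureRecord:
    """Per-subject/timepoint architecture summary."""

    thickness_mm: dict                # (muscle, site_pct) -> mm
    vl_pennation_deg: float
    vl_fascicle_mm: float


def site_thickness(points_mm: Sequence[float]) -> float:
    """Mean of the three evenly spaced inter-aponeurosis distances."""
    if len(points_mm) != 3:
        raise InvalidParameterError("exactly three thickness points required")
    if any(p <= 0 for p in points_mm):
        raise InvalidParameterError("thickness points must be positive")
    return float(np.mean(points_mm))


def fascicle_length(thickness_mm: float, pennation_deg: float) -> float:
    """Linear fascicle-length estimate: thickness / sin(pennation).

    Strictly decreasing in the pennation angle on (0, 90) degrees,
    with FL * sin(theta) = thickness as the round-trip identity.
    """
    if thickness_mm <= 0:
        raise InvalidParameterError("thickness must be positive")
    if not 0 < pennation_deg < 90:
        raise InvalidParameterError("pennation angle must lie in (0, 90) degrees")
    return thickness_mm / math.sin(math.radians(pennation_deg))


def aggregate_vl(measurements: Iterable[SiteMeasurement]) -> tuple[float, float]:
    """Overall VL pennation angle and fascicle length.

    Fascicle length is computed per measurement entry, then averaged
    together with the angles as a flat mean over all VL entries.
    Missing sites reduce the averaging pool with a warning.
    """
    entries = [m for m in measurements if m.muscle == "VL" and m.pennation_deg is not None]
    if not entries:
        raise InvalidParameterError("no VL measurements with pennation angles")
    present = {m.site_pct_thigh for m in entries}
    missing = set(VL_SITES) - present
    if missing:
        warnings.warn(f"VL sites {sorted(missing)} missing; averaging over available sites")
    angles = [m.pennation_deg for m in entries]
    fls = [fascicle_length(m.thickness_mm, m.pennation_deg) for m in entries]
    return float(np.mean(angles)), float(np.mean(fls))


def summarize_architecture(table: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-subject/timepoint summary of an architecture table.

    Expects columns ``subject, timepoint, muscle, site_pct, image_id,
    point1_mm, point2_mm, point3_mm, pennation_deg`` and returns a long
    table ``subject, timepoint, measure, value`` where measures are
    ``thickness_<muscle>_<site>``, ``pennation_vl`` and
    ``fascicle_vl``.
    """
    required = {"subject", "timepoint", "muscle", "site_pct", "image_id",
                "point1_mm", "point2_mm", "point3_mm"}
    if not required.issubset(table.columns):
        raise InvalidParameterError(f"architecture table needs columns {sorted(required)}")
    rows = []
    for (subj, tp), sub in table.groupby(["subject", "timepoint"], sort=True):
        meas = []
        for rec in sub.itertuples(index=False):
            pen = getattr(rec, "pennation_deg", None)
            if pen is not None and not np.isfinite(pen):
                pen = None
            meas.append(SiteMeasurement(
                muscle=str(rec.muscle),
                site_pct_thigh=int(rec.site_pct),
                image_id=int(rec.image_id),
                thickness_points_mm=(rec.point1_mm, rec.point2_mm, rec.point3_mm),
                pennation_deg=pen,
            ))
        # thickness per (muscle, site), averaged over images
        by_site: dict[tuple, list] = {}
        for m in meas:
            by_site.setdefault((m.muscle, m.site_pct_thigh), []).append(m.thickness_mm)
        for (muscle, site), vals in sorted(by_site.items()):
            rows.append((subj, tp, f"thickness_{muscle.lower()}_{site}", float(np.mean(vals))))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pen_mean, fl_mean = aggregate_vl(meas)
        rows.append((subj, tp, "pennation_vl", pen_mean))
        rows.append((subj, tp, "fascicle_vl", fl_mean))
    return pd.DataFrame(rows, columns=["subject", "timepoint", "measure", "value"])
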