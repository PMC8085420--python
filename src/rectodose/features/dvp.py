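"""Dose-volume parameters D_x-cc on the accumulated surface dose.

D_x-cc is the minimum dose received by the most exposed x cm^3 of the
wall.  On a surface representation each vertex carries a volume equal to
its area weight times the wall thickness; vertices are sorted by dose
(descending) and D_x-cc is the dose of the vertex at which the running
volume first reaches x cm^3.
"""

from __future__ import annotations

import logging

import numpy as np

from ..surface import SurfaceDose

log = logging.getLogger(__name__)

DVP_LEVELS_CC = np.round(np.arange(1, 51) * 0.1, 1)          # 0.1 ... 5.0 cm^3
DVP_NAMES = [f"D_{x:.1f}cc" for x in DVP_LEVELS_CC]


def compute_dvps(surface_dose: SurfaceDose, region: str = "whole",
                 wall_thickness: float | str = 3.0,
                 wall_volume_mm3: float | None = None) -> dict[str, float]:
    """D_0.1cc ... D_5.0cc (EQD2 Gy) for one region of the surface dose.

    ``wall_thickness`` is the assumed wall thickness in mm, or ``"auto"``
    to derive it as delineated wall volume / total surface area (requires
    ``wall_volume_mm3``).  If the region's total volume is below x cm^3,
    D_x-cc falls back to the region's minimum dose (logged).
    """
    if wall_thickness == "auto":
        if wall_volume_mm3 is None:
            raise ValueError("'auto' wall thickness requires wall_volume_mm3")
        wall_thickness = wall_volume_mm3 / surface_dose.lattice.total_area
    wall_thickness = float(wall_thickness)
    if wall_thickness <= 0:
        raise ValueError("wall thickness must be positive")

    m = surface_dose.region_mask(region)
    if not np.any(m):
        raise ValueError(f"region {region!r} has no vertices")
    dose = surface_dose.dose[m]
    vol = surface_dose.lattice.area_weights[m] * wall_thickness  # mm^3

    order = np.argsort(dose)[::-1]
    dose = dose[order]
    cumvol = np.cumsum(vol[order])
    total = cumvol[-1]

    out = {}
    targets = DVP_LEVELS_CC * 1000.0       # mm^3
    idx = np.searchsorted(cumvol, targets, side="left")
    for name, x_mm3, i in zip(DVP_NAMES, targets, idx):
        if x_mm3 > total:
            log.debug("region volume %.0f mm^3 < %s target; using minimum dose",
                      total, name)
            out[name] = float(dose[-1])
        else:
            out[name] = float(dose[min(i, len(dose) - 1)])
    return out
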