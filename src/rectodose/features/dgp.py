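"""Dose-geometric parameters of thresholded dose regions on the 2D map.

At each dose level L (1-30 Gy) the map is thresholded — ``dose >= L``
for the whole and anterior maps, ``dose < L`` (within foreground) for
the posterior map, where sparing rather than exposure is the quantity of
interest — and nine descriptors of the thresholded region are computed.
All pixels of the mask are pooled into a single region even when it is
disconnected (one value per level is reported); pixels are 1 mm^2.

Descriptors: absolute and relative area, eccentricity / major / minor
axis of the second-moment-equivalent ellipse, perimeter, and distances
from the region centroid to the bottom-most row / left-most column /
right-most column of the rectum foreground.  An empty region yields nine
zeros at that level.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from ..rsdm import RSDM

DGP_LEVELS_GY = list(range(1, 31))
_DGP_PROPS = ["Area", "Rel_area", "Ecc", "Maj", "Min", "Per",
              "Cen2Bot", "Cen2Lft", "Cen2Rgt"]
DGP_NAMES = [f"{p}_{lv}Gy" for p in _DGP_PROPS for lv in DGP_LEVELS_GY]


def mask_perimeter(mask: np.ndarray) -> float:
    """Boundary length of a binary mask.

    Rule: total polyline length of the marching-squares iso-contours at
    level 0.5 of the zero-padded mask — axis-aligned boundary runs count
    1 per pixel edge and staircase corners are cut diagonally, which is
    the diagonal correction relative to raw edge counting.
    """
    if not mask.any():
        return 0.0
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        total += float(np.linalg.norm(np.diff(contour, axis=0), axis=1).sum())
    return total


def _region_shape(mask: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """(eccentricity, major axis, minor axis, centroid) of pooled pixels."""
    props = measure.regionprops(mask.astype(np.uint8))[0]
    ecc = float(props.eccentricity)
    maj = float(props.axis_major_length)
    mnr = float(props.axis_minor_length)
    return ecc, maj, mnr, np.asarray(props.centroid)


def compute_dgps(rsdm: RSDM, levels=DGP_LEVELS_GY) -> dict[str, float]:
    """The 9 x len(levels) dose-geometric parameters of one map region."""
    fg = rsdm.mask
    fg_area = float(fg.sum())
    if fg_area == 0:
        raise ValueError("empty foreground")
    below = rsdm.region == "posterior"   # sparing-oriented threshold
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    bottom_row, left_col, right_col = rows.max(), cols.min(), cols.max()

    out: dict[str, float] = {}
    for lv in levels:
        if below:
            m = fg & (rsdm.dose < lv)
        else:
            m = fg & (rsdm.dose >= lv)
        if not m.any():
            vals = dict.fromkeys(_DGP_PROPS, 0.0)
        else:
            ecc, maj, mnr, cen = _region_shape(m)
            vals = {
                "Area": float(m.sum()),
                "Rel_area": 100.0 * float(m.sum()) / fg_area,
                "Ecc": ecc, "Maj": maj, "Min": mnr,
                "Per": mask_perimeter(m),
                "Cen2Bot": float(abs(bottom_row - cen[0])),
                "Cen2Lft": float(abs(cen[1] - left_col)),
                "Cen2Rgt": float(abs(right_col - cen[1])),
            }
        for p in _DGP_PROPS:
            out[f"{p}_{lv}Gy"] = vals[p]
    return out
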