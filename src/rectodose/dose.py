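"""Radiobiological dose conversion and dose-grid sampling.

The linear-quadratic (LQ) model converts a physical dose delivered in a
single fraction of size ``d`` into the equivalent dose in 2 Gy fractions::

    EQD2 = d * (d + alpha/beta) / (2 + alpha/beta)

For rectum (late-responding tissue) the conventional sensitivity ratio is
``alpha/beta = 3`` Gy, which is the default here.  Conversion is applied
per fraction, *before* accumulation, so that differently sized fractions
are put on a common radiobiological scale prior to summation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import nibabel as nib
from scipy.interpolate import RegularGridInterpolator

log = logging.getLogger(__name__)

__all__ = ["LQParams", "DoseGrid", "eqd2_convert", "sample_trilinear"]


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic conversion parameters.

    alpha_beta : tissue alpha/beta ratio in Gy (3 Gy for rectal wall).
    reference_fraction : reference fraction size in Gy; EQD2 is by
        definition referenced to 2 Gy and this field is fixed.
    """

    alpha_beta: float = 3.0
    reference_fraction: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha_beta must be > 0, got {self.alpha_beta}")
        if self.reference_fraction != 2.0:
            raise ValueError("EQD2 is referenced to 2 Gy fractions")


@dataclass
class DoseGrid:
    """Regular 3D scalar dose field in patient (LPS, mm) coordinates.

    values : dose array indexed [ix, iy, iz], Gy.
    origin : mm coordinate of voxel (0, 0, 0) centre.
    spacing : mm per voxel along each axis.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.values.shape[k])
            for k in range(3)
        )

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "DoseGrid":
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        origin = affine[:3, 3]
        return cls(np.asarray(img.dataobj, dtype=float), origin, spacing)


def eqd2_convert(fraction_dose, lq: LQParams = LQParams()):
    """Convert single-fraction physical dose to EQD2 (element-wise).

    ``EQD2 = d * (d + alpha/beta) / (2 + alpha/beta)``; strictly increasing
    in ``d`` and exactly the identity at ``d = 2`` for any alpha/beta.
    """
    d = np.asarray(fraction_dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("fraction dose must be non-negative")
    out = d * (d + lq.alpha_beta) / (2.0 + lq.alpha_beta)
    if np.isscalar(fraction_dose):
        return float(out)
    return out


def sample_trilinear(grid: DoseGrid, points) -> np.ndarray:
    """Trilinear interpolation of the dose grid at mm coordinates.

    Points outside the grid bounding box return 0 with a logged warning —
    contour margins may exceed the planned dose grid by millimetres and
    that should not abort an accumulation run.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.zeros(0)
    pts = pts.reshape(-1, 3)
    interp = RegularGridInterpolator(
        grid.axis_coords(), grid.values, method="linear",
        bounds_error=False, fill_value=0.0,
    )
    vals = interp(pts)
    lo = grid.origin
    hi = grid.origin + grid.spacing * (np.array(grid.shape) - 1)
    outside = np.any((pts < lo) | (pts > hi), axis=1)
    if np.any(outside):
        log.warning("%d of %d sample points outside dose grid; returning 0 there",
                    int(outside.sum()), len(pts))
    return vals


def read_dicom_rtdose(path) -> DoseGrid:
    """Read a DICOM RT-DOSE file into a :class:`DoseGrid` (LPS mm)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    values = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    # pixel_array is (frames, rows, cols) = (z, y, x); reorder to (x, y, z)
    values = np.transpose(values, (2, 1, 0))
    dx, dy = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    origin = np.asarray([float(v) for v in ds.ImagePositionPatient])
    return DoseGrid(values, origin, np.array([dx, dy, dz]))
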