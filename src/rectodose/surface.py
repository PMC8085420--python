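"""Parameterized rectal surface lattice, dose transfer and accumulation.

The rectal wall is an open tube: each contour slice is resampled to a
fixed number of angular samples by arc length, giving a rings-by-theta
lattice with per-vertex parameters ``u`` (normalized inferior-to-superior
position) and ``v`` (normalized circumferential position from the
left-lateral anchor).  Inter-fraction correspondence is by shared (u, v):
two vertices on different fractions correspond when they sit at the same
normalized longitudinal and circumferential position.  This replaces a
full deformable surface registration with a deterministic, anatomically
reasonable parameterization for a tubular organ; a different
registration can be plugged in through the ``correspondence`` hook of
:func:`accumulate_fractions`.

The circumferential traversal starts at the left-lateral anchor (the
boundary point hit by the +x ray from the slice centroid) and runs
through the anterior (-y) half first, so v in [0, 0.5) is anterior and
v in [0.5, 1) is posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely.geometry.polygon import LinearRing

from .cohort import ContourStack
from .dose import DoseGrid, LQParams, eqd2_convert, sample_trilinear

log = logging.getLogger(__name__)

__all__ = [
    "SurfaceLattice", "SurfaceDose", "GeometryReport",
    "build_surface_lattice", "map_dose_to_surface", "accumulate_fractions",
    "geometry_metrics",
]


@dataclass
class SurfaceLattice:
    """Rings-by-theta vertex lattice over the rectal wall surface."""

    vertices: np.ndarray        # (rings, n_theta, 3) mm
    u: np.ndarray               # (rings,) in [0, 1], inferior -> superior
    v: np.ndarray               # (n_theta,) in [0, 1), from left-lateral anchor
    area_weights: np.ndarray    # (rings, n_theta) mm^2, sums to surface area
    circumferences: np.ndarray  # (rings,) mm
    zs: np.ndarray              # (rings,) mm

    @property
    def rings(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_theta(self) -> int:
        return self.vertices.shape[1]

    @property
    def total_area(self) -> float:
        return float(self.area_weights.sum())

    @property
    def length(self) -> float:
        return float(self.zs[-1] - self.zs[0])


@dataclass
class SurfaceDose:
    """Cumulative (or single-fraction) EQD2 dose on a surface lattice."""

    lattice: SurfaceLattice
    dose: np.ndarray            # (rings, n_theta) EQD2 Gy
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.lattice.vertices.shape[:2]:
            raise ValueError("dose array must match lattice shape")
        if np.any(self.dose < 0):
            raise ValueError("surface dose must be non-negative")

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean (rings, n_theta) mask for 'whole' / 'anterior' / 'posterior'."""
        v = self.lattice.v
        if region == "whole":
            col = np.ones_like(v, dtype=bool)
        elif region == "anterior":
            col = v < 0.5
        elif region == "posterior":
            col = v >= 0.5
        else:
            raise ValueError(f"unknown region {region!r}")
        return np.broadcast_to(col, self.dose.shape)


@dataclass
class GeometryReport:
    wall_volume_cm3: float
    ap_separation_mm: float
    lateral_separation_mm: float
    map_length_mm: float                    # max ring circumference
    anterior_extremum_to_ctv_mm: float | None = None
    posterior_extremum_to_ctv_mm: float | None = None
    anterior_extremum: str = "hottest"
    posterior_extremum: str = "coldest"

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _resample_ring(poly: np.ndarray, n_theta: int) -> tuple[np.ndarray, float]:
    """Arc-length resample one slice polygon from its left-lateral anchor.

    Orientation is forced clockwise in (x, y) so traversal from the +x
    anchor runs through the anterior (-y) half first.  The anchor is the
    nearest intersection of the +x ray from the slice centroid with the
    polygon boundary.
    """
    if not LinearRing(poly).is_simple:
        raise ValueError("polygon is self-intersecting")
    x, y = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y2 - x2 * y
    signed_area = 0.5 * cross.sum()
    if signed_area > 0:          # CCW -> reverse to clockwise
        poly = poly[::-1]
        x, y = poly[:, 0], poly[:, 1]
        x2, y2 = np.roll(x, -1), np.roll(y, -1)
        cross = x * y2 - x2 * y
        signed_area = 0.5 * cross.sum()
    cx = float(((x + x2) * cross).sum() / (6 * signed_area))
    cy = float(((y + y2) * cross).sum() / (6 * signed_area))

    seg = np.hypot(x2 - x, y2 - y)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perim = cum[-1]

    # +x ray from centroid: edges crossing y == cy (half-open rule)
    crosses = ((y <= cy) & (y2 > cy)) | ((y2 <= cy) & (y > cy))
    idx = np.flatnonzero(crosses)
    if idx.size == 0:
        raise ValueError("anchor ray does not intersect the contour")
    t = (cy - y[idx]) / (y2[idx] - y[idx])
    x_cross = x[idx] + t * (x2[idx] - x[idx])
    right = x_cross > cx
    if not np.any(right):
        raise ValueError("anchor ray does not intersect the contour on +x side")
    j = np.argmin(np.where(right, x_cross, np.inf))
    s0 = cum[idx[j]] + t[j] * seg[idx[j]]

    s = (s0 + perim * np.arange(n_theta) / n_theta) % perim
    xe = np.append(x, x[0])
    ye = np.append(y, y[0])
    xy = np.column_stack([np.interp(s, cum, xe), np.interp(s, cum, ye)])
    return xy, float(perim)


def build_surface_lattice(contours: ContourStack, n_theta: int = 256) -> SurfaceLattice:
    """Resample a contour stack into a rings-by-theta surface lattice.

    Per-vertex area weights are computed from the quads between adjacent
    rings: each quad (split into two triangles in 3D) contributes a
    quarter of its area to each of its four corner vertices.
    """
    if contours.n_slices < 2:
        raise ValueError("at least two contour slices are required")
    rings_xy, perims = [], []
    for i, poly in enumerate(contours.polygons):
        try:
            xy, perim = _resample_ring(poly, n_theta)
        except ValueError as e:
            raise ValueError(f"slice {i}: {e}") from e
        rings_xy.append(xy)
        perims.append(perim)
    zs = contours.zs
    verts = np.zeros((len(zs), n_theta, 3))
    for i, xy in enumerate(rings_xy):
        verts[i, :, :2] = xy
        verts[i, :, 2] = zs[i]
    u = (zs - zs[0]) / (zs[-1] - zs[0])
    v = np.arange(n_theta) / n_theta

    # quad areas between ring i and i+1, theta k..k+1 (wrapping)
    weights = np.zeros((len(zs), n_theta))
    a = verts[:-1]                       # (R-1, T, 3)
    b = np.roll(verts[:-1], -1, axis=1)
    c = np.roll(verts[1:], -1, axis=1)
    d = verts[1:]
    t1 = 0.5 * np.linalg.norm(np.cross(b - a, d - a), axis=2)
    t2 = 0.5 * np.linalg.norm(np.cross(b - c, d - c), axis=2)
    quad = t1 + t2                        # (R-1, T)
    qw = quad / 4.0
    weights[:-1] += qw + np.roll(qw, 1, axis=1)
    weights[1:] += qw + np.roll(qw, 1, axis=1)
    return SurfaceLattice(vertices=verts, u=u, v=v, area_weights=weights,
                          circumferences=np.asarray(perims), zs=zs.copy())


def map_dose_to_surface(grid: DoseGrid, lattice: SurfaceLattice,
                        lq: LQParams = LQParams(), fraction_id=None) -> SurfaceDose:
    """Sample the fraction dose grid at the lattice vertices and convert to EQD2."""
    phys = sample_trilinear(grid, lattice.vertices.reshape(-1, 3))
    dose = eqd2_convert(phys, lq).reshape(lattice.rings, lattice.n_theta)
    return SurfaceDose(lattice=lattice, dose=dose,
                       provenance=[fraction_id] if fraction_id is not None else [])


def _resample_in_u(dose: np.ndarray, u_src: np.ndarray, u_dst: np.ndarray) -> np.ndarray:
    """Linear interpolation of a (rings, n_theta) field from u_src rows to u_dst rows."""
    out = np.empty((len(u_dst), dose.shape[1]))
    for k in range(dose.shape[1]):
        out[:, k] = np.interp(u_dst, u_src, dose[:, k])
    return out


def accumulate_fractions(fraction_doses: list[SurfaceDose], reference: int = 0,
                         correspondence=None) -> SurfaceDose:
    """Sum fractional surface doses onto the reference fraction's lattice.

    Default correspondence is by shared (u, v): each fraction's dose field
    is resampled to the reference ring count by linear interpolation in u
    and summed at identical theta columns.  ``correspondence`` may be a
    callable (surface_dose, reference_lattice) -> (rings, n_theta) dose
    array to plug in an alternative registration.
    """
    if not fraction_doses:
        raise ValueError("no fraction doses to accumulate")
    ref = fraction_doses[reference]
    n_theta = ref.lattice.n_theta
    total = np.zeros_like(ref.dose)
    prov = []
    for sd in fraction_doses:
        if sd.lattice.n_theta != n_theta:
            raise ValueError("all fractions must share n_theta")
        if correspondence is not None:
            total += correspondence(sd, ref.lattice)
        elif sd.lattice.rings == ref.lattice.rings:
            total += sd.dose
        else:
            total += _resample_in_u(sd.dose, sd.lattice.u, ref.lattice.u)
        prov.extend(sd.provenance)
    return SurfaceDose(lattice=ref.lattice, dose=total, provenance=prov)


def _chord_extent(poly: np.ndarray, axis: int) -> float:
    """Length of the chord through the slice centroid parallel to an axis."""
    pg = Polygon(poly)
    c = np.asarray(pg.centroid.coords[0])
    span = float(np.abs(poly - c).max()) * 4 + 1
    d = np.zeros(2)
    d[axis] = span
    line = LineString([c - d, c + d])
    inter = line.intersection(pg)
    return float(inter.length)


def geometry_metrics(contours: ContourStack, ctv_centroid=None,
                     surface_dose: SurfaceDose | None = None,
                     anterior_extremum: str = "hottest",
                     posterior_extremum: str = "coldest") -> GeometryReport:
    """Geometric summary of one delineated rectum (and its surface dose).

    wall volume integrates slice polygon areas over z (trapezoidal rule,
    cm^3); AP / lateral separations are the mean over slices of the chord
    through the slice centroid along the y / x axis; the CTV distances go
    from the dose extremum vertex on each wall half to the CTV centroid.
    Which extremum belongs to which wall is configurable; the default
    (anterior = hottest, posterior = coldest) reflects the anterior wall
    facing the source.
    """
    areas = contours.slice_areas()
    volume = float(np.trapezoid(areas, contours.zs)) / 1000.0
    ap = float(np.mean([_chord_extent(p, 1) for p in contours.polygons]))
    lat = float(np.mean([_chord_extent(p, 0) for p in contours.polygons]))

    ant_d = post_d = None
    map_len = 0.0
    if surface_dose is not None:
        map_len = float(surface_dose.lattice.circumferences.max())
        if ctv_centroid is not None:
            ctv = np.asarray(ctv_centroid, dtype=float)
            verts = surface_dose.lattice.vertices.reshape(-1, 3)
            dose = surface_dose.dose.ravel()
            for region, mode in (("anterior", anterior_extremum),
                                 ("posterior", posterior_extremum)):
                m = surface_dose.region_mask(region).ravel()
                idx = np.flatnonzero(m)
                sel = idx[np.argmax(dose[idx])] if mode == "hottest" else idx[np.argmin(dose[idx])]
                dist = float(np.linalg.norm(verts[sel] - ctv))
                if region == "anterior":
                    ant_d = dist
                else:
                    post_d = dist
    elif ctv_centroid is None:
        log.info("no CTV centroid: CTV distance metrics omitted")
    return GeometryReport(
        wall_volume_cm3=volume, ap_separation_mm=ap, lateral_separation_mm=lat,
        map_length_mm=map_len, anterior_extremum_to_ctv_mm=ant_d,
        posterior_extremum_to_ctv_mm=post_d,
        anterior_extremum=anterior_extremum, posterior_extremum=posterior_extremum,
    )


def write_ply(surface_dose: SurfaceDose, path) -> None:
    """ASCII PLY export: lattice vertices, quad faces, per-vertex dose."""
    lat = surface_dose.lattice
    R, T = lat.rings, lat.n_theta
    verts = lat.vertices.reshape(-1, 3)
    dose = surface_dose.dose.ravel()
    faces = []
    for i in range(R - 1):
        for k in range(T):
            k2 = (k + 1) % T
            faces.append((i * T + k, i * T + k2, (i + 1) * T + k2, (i + 1) * T + k))
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(verts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float dose\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p, d in zip(verts, dose):
            fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {d:.6f}\n")
        for f in faces:
            fh.write("4 " + " ".join(map(str, f)) + "\n")
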