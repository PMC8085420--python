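"""Synthetic paired-cohort generator for gel-spacer brachytherapy studies.

Emulates the anatomy and dose structure of an HDR cervix-brachytherapy
cohort in which a protective gel is inserted into the rectum: each
synthetic patient exists in two conditions (``pre`` and ``post`` gel),
each imaged over several treatment fractions.  The rectum is modelled as
a stack of elliptical cross-sections with smooth low-order Fourier
perturbations in angle and along the longitudinal axis; the gel effect
dilates the cross-section (more laterally than antero-posteriorly) and
shifts it posteriorly, away from the clinical target volume (CTV).

Dose is produced by a bare inverse-square point-kernel sum over dwell
positions placed near the CTV — no anisotropy or scatter, but the steep
radial fall-off that drives rectal-wall dose gradients is reproduced.

Coordinates are LPS (x = patient left, y = posterior, z = superior);
anterior is -y.  All lengths in mm, doses in Gy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from shapely.geometry import Polygon

from .dose import DoseGrid

log = logging.getLogger(__name__)

__all__ = [
    "GelEffectParams", "CohortConfig", "ContourStack", "PatientCase",
    "generate_cohort", "apply_gel_effect", "compute_fraction_dose", "GridSpec",
]


@dataclass(frozen=True)
class GelEffectParams:
    """Population-level geometric effect of the rectal gel.

    Dilation factors are post/pre ratios of wall separation (lateral
    28.1/22.7, antero-posterior 26.5/23.3); the net posterior shift of
    the cross-section centroid is ``posterior_push - anterior_pull``
    (positive = posterior, i.e. away from the CTV).
    """

    lateral_dilation_factor: float = 28.1 / 22.7
    ap_dilation_factor: float = 26.5 / 23.3
    posterior_push: float = 1.7
    anterior_pull: float = 1.3
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.enabled and (self.lateral_dilation_factor < 1 or self.ap_dilation_factor < 1):
            raise ValueError("dilation factors must be >= 1 when the gel effect is enabled")


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort.

    Defaults follow the clinical fractionation (5 HDR fractions of 6 Gy)
    and a rectum of realistic calibre: base semi-axes of about 11 mm give
    pre-gel lateral / AP wall separations near 23 mm.
    """

    n_patients: int = 30
    n_fractions: int = 5
    fraction_dose_nominal: float = 6.0
    slice_spacing: float = 2.5
    n_slices: int = 21
    base_semi_axes: tuple[float, float] = (11.35, 11.65)  # (lateral, AP) mm
    wall_thickness: float = 3.0
    gel: GelEffectParams = field(default_factory=GelEffectParams)
    interfraction_sd: float = 1.0
    patient_shape_sd: float = 0.18  # relative SD of per-patient calibre
    ctv_anterior_gap: float = 24.7  # anterior wall to CTV centroid, mm
    n_dwells: int = 7
    dwell_spacing: float = 5.0
    source_strength: float = 500.0  # Gy*mm^2 per dwell-unit-time
    grid_spacing: float = 2.0
    points_per_contour: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_fractions < 1 or self.n_slices < 2:
            raise ValueError("n_patients, n_fractions >= 1 and n_slices >= 2 required")
        for name in ("slice_spacing", "wall_thickness", "source_strength", "grid_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.base_semi_axes) <= 0:
            raise ValueError("base_semi_axes must be positive")


@dataclass
class ContourStack:
    """Slice-wise closed rectal-wall polygons in patient mm coordinates."""

    zs: np.ndarray                 # (n_slices,), strictly increasing
    polygons: list[np.ndarray]     # each (n_points, 2) of (x, y), closed implicitly

    def __post_init__(self) -> None:
        self.zs = np.asarray(self.zs, dtype=float)
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        if len(self.polygons) != len(self.zs):
            raise ValueError("one polygon per slice required")
        if np.any(np.diff(self.zs) <= 0):
            raise ValueError("slice z must be strictly increasing")

    @property
    def n_slices(self) -> int:
        return len(self.zs)

    def validate_simple(self) -> None:
        for i, p in enumerate(self.polygons):
            if len(p) < 3 or not Polygon(p).is_simple:
                raise ValueError(f"slice {i} polygon is not a simple closed polygon")

    def slice_areas(self) -> np.ndarray:
        return np.array([Polygon(p).area for p in self.polygons])

    def to_json_dict(self) -> dict:
        return {"slices": [{"z_mm": float(z), "points": p.tolist()}
                           for z, p in zip(self.zs, self.polygons)]}

    @classmethod
    def from_json_dict(cls, d: dict) -> "ContourStack":
        return cls(zs=[s["z_mm"] for s in d["slices"]],
                   polygons=[np.asarray(s["points"]) for s in d["slices"]])


@dataclass(frozen=True)
class GridSpec:
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]


@dataclass
class PatientCase:
    """One patient in one condition: anatomy + plan for every fraction."""

    patient_id: str
    condition: str                      # "pre" | "post"
    contours: list[ContourStack]        # one per fraction
    ctv_centroid: np.ndarray            # (3,) mm
    dwells: list[np.ndarray]            # per fraction, (n_dwells, 4) = x,y,z,t
    dose_grids: list[DoseGrid]          # per fraction, physical Gy

    def to_json_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "condition": self.condition,
            "ctv_centroid": np.asarray(self.ctv_centroid).tolist(),
            "contours": [c.to_json_dict() for c in self.contours],
            "dwells": [d.tolist() for d in self.dwells],
            "dose_grids": [
                {"origin": g.origin.tolist(), "spacing": g.spacing.tolist(),
                 "values": np.round(g.values, 9).tolist()}
                for g in self.dose_grids
            ],
        }


# ---------------------------------------------------------------------------
# geometry primitives

def _smooth_radial_field(rng: np.random.Generator, thetas: np.ndarray,
                         us: np.ndarray, sd: float, n_theta_modes: int = 3,
                         n_z_modes: int = 2) -> np.ndarray:
    """Smooth zero-mean radial perturbation field over (slice, angle), SD ~ sd mm.

    Low-order Fourier modes in angle modulated by low-order cosines along
    the normalized longitudinal coordinate ``us``; keeps polygons simple
    for perturbations well below the organ radius.
    """
    out = np.zeros((len(us), len(thetas)))
    n_terms = 0
    for m in range(1, n_theta_modes + 1):
        for kz in range(n_z_modes + 1):
            amp_c, amp_s = rng.normal(size=2)
            zmod = np.cos(np.pi * kz * us + rng.uniform(0, 2 * np.pi))
            out += np.outer(zmod, amp_c * np.cos(m * thetas) + amp_s * np.sin(m * thetas))
            n_terms += 1
    # each term has unit variance ~ amp^2 * 1/2 * 1/2 on average; normalize empirically
    out *= sd / max(out.std(), 1e-9)
    return out


def _build_tube(zs: np.ndarray, semi_axes: tuple[float, float],
                radial_field: np.ndarray, centroids_xy: np.ndarray,
                n_points: int) -> ContourStack:
    thetas = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    a, b = semi_axes
    polys = []
    for i in range(len(zs)):
        r = (a * np.cos(thetas)) ** 2 + (b * np.sin(thetas)) ** 2
        r = a * b / np.sqrt(r)                      # ellipse polar radius
        r = np.maximum(r + radial_field[i], 1.0)    # keep strictly positive
        x = centroids_xy[i, 0] + r * np.cos(thetas)
        y = centroids_xy[i, 1] + r * np.sin(thetas)
        polys.append(np.column_stack([x, y]))
    return ContourStack(zs=zs, polygons=polys)


def apply_gel_effect(contours: ContourStack, params: GelEffectParams,
                     ctv_centroid) -> ContourStack:
    """Dilate and displace the rectum the way the inserted gel does.

    Each slice polygon is rescaled about its own centroid by the lateral
    (x) and AP (y) dilation factors, then the centroid is translated
    posteriorly (+y) by ``posterior_push - anterior_pull``.  Disabled
    params return the input unchanged.
    """
    if not params.enabled:
        return contours
    shift = params.posterior_push - params.anterior_pull
    polys = []
    for p in contours.polygons:
        c = np.asarray(Polygon(p).centroid.coords[0])
        q = (p - c) * np.array([params.lateral_dilation_factor,
                                params.ap_dilation_factor]) + c
        q[:, 1] += shift
        polys.append(q)
    out = ContourStack(zs=contours.zs.copy(), polygons=polys)
    out.validate_simple()  # affine maps preserve simplicity; guards degenerate input
    return out


def compute_fraction_dose(dwells: np.ndarray, grid_spec: GridSpec,
                          source_strength: float, r_min: float = 1.0) -> DoseGrid:
    """Inverse-square point-kernel dose on a regular grid.

    dose(v) = sum_j strength * t_j / max(||v - p_j||, r_min)^2 — the 1/r^2
    geometric fall-off of a point source, with ``r_min`` capping the
    singularity at the dwell itself.
    """
    dw = np.asarray(dwells, dtype=float).reshape(-1, 4)
    if len(dw) == 0:
        raise ValueError("at least one dwell position required")
    origin = np.asarray(grid_spec.origin, float)
    spacing = np.asarray(grid_spec.spacing, float)
    shape = grid_spec.shape
    ax = [origin[k] + spacing[k] * np.arange(shape[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    dose = np.zeros(shape)
    for x, y, z, t in dw:
        r2 = (X - x) ** 2 + (Y - y) ** 2 + (Z - z) ** 2
        r2 = np.maximum(r2, r_min ** 2)
        dose += source_strength * t / r2
    return DoseGrid(dose, origin, spacing)


# ---------------------------------------------------------------------------
# cohort assembly

def _patient_anatomy(cfg: CohortConfig, rng: np.random.Generator):
    """Per-patient base geometry shared by both conditions and all fractions."""
    zs = cfg.slice_spacing * np.arange(cfg.n_slices)
    us = np.linspace(0, 1, cfg.n_slices)
    calibre = float(np.exp(rng.normal(0.0, cfg.patient_shape_sd)))
    semi_axes = (cfg.base_semi_axes[0] * calibre, cfg.base_semi_axes[1] * calibre)
    thetas = np.linspace(0, 2 * np.pi, cfg.points_per_contour, endpoint=False)
    base_field = _smooth_radial_field(rng, thetas, us, sd=1.2)
    # gentle lateral/AP drift of the tube axis along z
    centroids = np.column_stack([
        2.0 * np.sin(np.pi * us + rng.uniform(0, 2 * np.pi)),
        2.0 * np.sin(np.pi * us + rng.uniform(0, 2 * np.pi)),
    ])
    return zs, us, thetas, semi_axes, base_field, centroids


def _grid_for(contour_sets: list[ContourStack], dwell_sets: list[np.ndarray],
              spacing: float, margin: float = 6.0) -> GridSpec:
    pts = [np.column_stack([p, np.full(len(p), z)])
           for cs in contour_sets for z, p in zip(cs.zs, cs.polygons)]
    pts.append(np.vstack([d[:, :3] for d in dwell_sets]))
    allp = np.vstack(pts)
    lo = allp.min(axis=0) - margin
    hi = allp.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    return GridSpec(origin=tuple(lo), spacing=(spacing,) * 3, shape=shape)


def generate_cohort(config: CohortConfig) -> list[PatientCase]:
    """Generate the paired synthetic cohort: 2 cases (pre, post) per patient.

    Reproducible from ``config.seed``; the gel effect is deterministic per
    patient, inter-fraction variability is an independent smooth radial
    field per fraction, shared structure between conditions comes only
    from the common base anatomy.
    """
    cases: list[PatientCase] = []
    root = np.random.SeedSequence(config.seed)
    for pid_idx, child in enumerate(root.spawn(config.n_patients)):
        rng = np.random.default_rng(child)
        zs, us, thetas, semi_axes, base_field, centroids = _patient_anatomy(config, rng)
        base = _build_tube(zs, semi_axes, base_field, centroids, config.points_per_contour)
        base.validate_simple()

        anterior_extreme = min(p[:, 1].min() for p in base.polygons)
        ctv = np.array([0.0, anterior_extreme - config.ctv_anterior_gap, zs.mean()])

        conditions = {"pre": base,
                      "post": apply_gel_effect(base, config.gel, ctv)}
        for cond in ("pre", "post"):
            anatomy = conditions[cond]
            contour_fracs, dwell_fracs = [], []
            for _f in range(config.n_fractions):
                pert = _smooth_radial_field(rng, thetas, us, sd=config.interfraction_sd)
                polys = []
                for i, p in enumerate(anatomy.polygons):
                    c = np.asarray(Polygon(p).centroid.coords[0])
                    d = p - c
                    r = np.linalg.norm(d, axis=1)
                    scale = np.maximum(r + pert[i], 1.0) / np.maximum(r, 1e-9)
                    polys.append(c + d * scale[:, None])
                cs = ContourStack(zs=zs.copy(), polygons=polys)
                try:
                    cs.validate_simple()
                except ValueError:
                    log.info("regenerating fraction contour with halved perturbation "
                             "(patient %d, %s)", pid_idx, cond)
                    pert *= 0.5
                    polys = []
                    for i, p in enumerate(anatomy.polygons):
                        c = np.asarray(Polygon(p).centroid.coords[0])
                        d = p - c
                        r = np.linalg.norm(d, axis=1)
                        scale = np.maximum(r + pert[i], 1.0) / np.maximum(r, 1e-9)
                        polys.append(c + d * scale[:, None])
                    cs = ContourStack(zs=zs.copy(), polygons=polys)
                    cs.validate_simple()
                contour_fracs.append(cs)

                k = np.arange(config.n_dwells) - (config.n_dwells - 1) / 2
                dz = ctv[2] + k * config.dwell_spacing
                jitter = rng.normal(0, 0.5, size=(config.n_dwells, 3))
                pos = np.column_stack([np.full_like(dz, ctv[0]),
                                       np.full_like(dz, ctv[1]), dz]) + jitter
                dwell_fracs.append(np.column_stack([pos, np.ones(config.n_dwells)]))

            spec = _grid_for(contour_fracs, dwell_fracs, config.grid_spacing)
            grids = [compute_fraction_dose(d, spec, config.source_strength)
                     for d in dwell_fracs]
            cases.append(PatientCase(
                patient_id=f"P{pid_idx:03d}", condition=cond,
                contours=contour_fracs, ctv_centroid=ctv,
                dwells=dwell_fracs, dose_grids=grids,
            ))
    return cases


def cohort_to_json(cases: list[PatientCase]) -> str:
    """Canonical serialization used for byte-level determinism checks."""
    return json.dumps([c.to_json_dict() for c in cases], sort_keys=True)


def load_cases(directory) -> list[PatientCase]:
    """Read back a cohort written by the ``simulate`` CLI command."""
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    cases = []
    for entry in manifest:
        stem = f"{entry['patient_id']}_{entry['condition']}"
        with open(directory / f"{stem}_contours.json") as fh:
            contours = [ContourStack.from_json_dict(d) for d in json.load(fh)]
        dwells, grids = [], []
        for f in range(len(contours)):
            dwells.append(np.loadtxt(directory / f"{stem}_dwells_f{f}.csv",
                                     delimiter=",", skiprows=1))
            grids.append(DoseGrid.from_nifti(directory / f"{stem}_dose_f{f}.nii.gz"))
        cases.append(PatientCase(
            patient_id=entry["patient_id"], condition=entry["condition"],
            contours=contours, ctv_centroid=np.asarray(entry["ctv_centroid"]),
            dwells=dwells, dose_grids=grids))
    return cases
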