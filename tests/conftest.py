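"""Shared fixtures: synthetic geometries and a session-scoped study cohort."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import rectodose as rd
from rectodose.features.table import accumulate_case

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# analysis resolution used throughout the tests: synthetic circumferences
# are ~70-90 mm, so 128 angular samples stay below 1 mm arc spacing
N_THETA = 128


def make_cylinder(radius=10.0, length=100.0, n_slices=11, n_points=96,
                  center=(0.0, 0.0), z0=0.0):
    """Circular-cylinder contour stack (closed polygons per slice)."""
    thetas = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    zs = z0 + np.linspace(0, length, n_slices)
    polys = [np.column_stack([center[0] + radius * np.cos(thetas),
                              center[1] + radius * np.sin(thetas)])
             for _ in zs]
    return rd.ContourStack(zs=zs, polygons=polys)


def constant_surface_dose(lattice, value):
    return rd.SurfaceDose(lattice=lattice,
                          dose=np.full((lattice.rings, lattice.n_theta), float(value)))


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 paired patients at reduced geometric resolution (fast unit tests)."""
    cfg = rd.CohortConfig(n_patients=3, seed=7, n_slices=9, points_per_contour=48)
    return rd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_bundle():
    """The default-gel study cohort (n=30, fixed seed) with features and
    the full posterior-region model grid; shared across test modules."""
    cfg = rd.CohortConfig(n_patients=30, seed=1)
    cases = rd.generate_cohort(cfg)
    ext = rd.DosimetricFeatureExtractor(n_theta=N_THETA)
    features = ext.fit(cases).transform(cases)
    sub = features[features.region == "posterior"].reset_index(drop=True)
    results = rd.run_model_grid(sub, sub.condition, sub.patient_id, seed=1)
    return {"config": cfg, "cases": cases, "features": features,
            "posterior_results": results}


@pytest.fixture(scope="session")
def case_surface(tiny_cohort):
    """Accumulated surface dose + unfolded maps of one synthetic case."""
    case = tiny_cohort[0]
    sd = accumulate_case(case, n_theta=N_THETA)
    whole = rd.unfold(sd)
    ant, post = rd.split_anterior_posterior(whole)
    return {"case": case, "surface": sd, "whole": whole,
            "anterior": ant, "posterior": post}
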