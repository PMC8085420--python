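"""Per-case feature extraction and cohort feature-table assembly.

One row per (patient, condition, region); 363 feature columns in a fixed
order: 50 DVPs, 43 textures, 270 DGPs.
"""

from __future__ import annotations

import logging

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ..cohort import PatientCase
from ..dose import LQParams
from ..surface import (SurfaceDose, accumulate_fractions, build_surface_lattice,
                       geometry_metrics, map_dose_to_surface)
from ..rsdm import RSDM, split_anterior_posterior, unfold
from .dvp import DVP_NAMES, compute_dvps
from .texture import TEXTURE_NAMES, compute_textures
from .dgp import DGP_NAMES, compute_dgps

log = logging.getLogger(__name__)

FEATURE_NAMES = DVP_NAMES + TEXTURE_NAMES + DGP_NAMES
REGIONS = ("whole", "anterior", "posterior")
META_COLUMNS = ["patient_id", "condition", "region"]


def accumulate_case(case: PatientCase, n_theta: int = 256,
                    lq: LQParams = LQParams()) -> SurfaceDose:
    """Fraction contours -> lattices -> EQD2 surface doses -> accumulated dose."""
    fracs = []
    for f, (contours, grid) in enumerate(zip(case.contours, case.dose_grids)):
        lattice = build_surface_lattice(contours, n_theta=n_theta)
        fracs.append(map_dose_to_surface(grid, lattice, lq=lq, fraction_id=f))
    return accumulate_fractions(fracs, reference=0)


def extract_case_features(surface_dose: SurfaceDose, rsdm_whole: RSDM,
                          rsdm_anterior: RSDM, rsdm_posterior: RSDM,
                          wall_thickness: float | str = 3.0,
                          wall_volume_mm3: float | None = None,
                          quantization_levels: int = 32) -> dict[str, dict[str, float]]:
    """All 363 features for each of the three regions of one case."""
    maps = {"whole": rsdm_whole, "anterior": rsdm_anterior,
            "posterior": rsdm_posterior}
    out = {}
    for region in REGIONS:
        feats = {}
        feats.update(compute_dvps(surface_dose, region=region,
                                  wall_thickness=wall_thickness,
                                  wall_volume_mm3=wall_volume_mm3))
        feats.update(compute_textures(maps[region], quantization_levels))
        feats.update(compute_dgps(maps[region]))
        missing = set(FEATURE_NAMES) - set(feats)
        if missing:
            raise RuntimeError(f"feature extraction incomplete: {sorted(missing)[:5]}")
        out[region] = feats
    return out


def assemble_feature_table(records: list[dict]) -> pd.DataFrame:
    """Stack per-case records into the cohort feature table.

    Each record: {patient_id, condition, region -> features} (the output
    of :func:`extract_case_features` plus identifiers).  Cases missing a
    region are rejected with a log message rather than propagated as
    missing values.
    """
    rows = []
    for rec in records:
        regions = rec.get("features", {})
        if set(REGIONS) - set(regions):
            log.warning("case %s/%s missing regions %s: row rejected",
                        rec.get("patient_id"), rec.get("condition"),
                        sorted(set(REGIONS) - set(regions)))
            continue
        for region in REGIONS:
            row = {"patient_id": rec["patient_id"],
                   "condition": rec["condition"], "region": region}
            row.update({k: regions[region][k] for k in FEATURE_NAMES})
            rows.append(row)
    df = pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_NAMES)
    if df[FEATURE_NAMES].isna().any().any():
        raise ValueError("feature table contains missing values")
    return df


class DosimetricFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transform a list of :class:`PatientCase` into the cohort feature table.

    Stateless transformer (``fit`` only validates parameters) so it can
    sit at the head of an sklearn pipeline operating on synthetic or
    imported cases.
    """

    def __init__(self, n_theta: int = 256, wall_thickness: float | str = 3.0,
                 quantization_levels: int = 32, alpha_beta: float = 3.0):
        self.n_theta = n_theta
        self.wall_thickness = wall_thickness
        self.quantization_levels = quantization_levels
        self.alpha_beta = alpha_beta

    def fit(self, X, y=None):
        if self.n_theta < 8:
            raise ValueError("n_theta must be at least 8")
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X: list[PatientCase]) -> pd.DataFrame:
        lq = LQParams(alpha_beta=self.alpha_beta)
        records = []
        for case in X:
            sd = accumulate_case(case, n_theta=self.n_theta, lq=lq)
            whole = unfold(sd)
            ant, post = split_anterior_posterior(whole)
            wall_vol = None
            if self.wall_thickness == "auto":
                rep = geometry_metrics(case.contours[0])
                wall_vol = rep.wall_volume_cm3 * 1000.0
            feats = extract_case_features(
                sd, whole, ant, post, wall_thickness=self.wall_thickness,
                wall_volume_mm3=wall_vol,
                quantization_levels=self.quantization_levels)
            records.append({"patient_id": case.patient_id,
                            "condition": case.condition, "features": feats})
        return assemble_feature_table(records)
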