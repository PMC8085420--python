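"""Feature families: DVPs, textures, DGPs, and the assembled table."""

import numpy as np
import pytest

import rectodose as rd
from rectodose.features import DVP_NAMES, TEXTURE_NAMES, DGP_NAMES, FEATURE_NAMES
from rectodose.features.texture import glcm_matrix, quantize, _glcm_features
from rectodose.features.dgp import mask_perimeter
from rectodose.rsdm import RSDM
from rectodose.surface import SurfaceLattice, SurfaceDose

import oracles
from conftest import make_cylinder, constant_surface_dose, N_THETA


def toy_surface_dose(doses, area_weights, v=None):
    """Hand-built one-ring surface dose for DVP unit checks."""
    doses = np.atleast_2d(np.asarray(doses, float))
    aw = np.atleast_2d(np.asarray(area_weights, float))
    n = doses.shape[1]
    v = np.asarray(v if v is not None else np.arange(n) / n, float)
    lat = SurfaceLattice(
        vertices=np.zeros((1, n, 3)), u=np.array([0.0]), v=v,
        area_weights=aw, circumferences=np.array([float(n)]),
        zs=np.array([0.0]))
    return SurfaceDose(lattice=lat, dose=doses)


def random_rsdm(seed, shape=(8, 8), region="whole"):
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < 0.8
    while mask.sum() < 16:
        mask |= rng.random(shape) < 0.5
    dose = np.where(mask, rng.uniform(0, 40, shape), np.nan)
    return RSDM(dose=dose, mask=mask, region=region)


class TestDVP:
    def test_uniform_dose_all_levels_equal(self):
        sd = toy_surface_dose([6.0] * 8, [800.0] * 8)   # 6.4 cc at 1 mm thickness
        out = rd.compute_dvps(sd, "whole", wall_thickness=1.0)
        assert len(out) == 50
        assert all(v == pytest.approx(6.0) for v in out.values())

    def test_two_element_toy_matches_sort_and_accumulate_oracle(self):
        sd = toy_surface_dose([10.0, 5.0], [1000.0, 1000.0])
        out = rd.compute_dvps(sd, "whole", wall_thickness=1.0)
        assert out["D_0.5cc"] == out["D_1.0cc"] == 10.0
        assert out["D_1.5cc"] == out["D_2.0cc"] == 5.0
        for x in (0.5, 1.0, 1.5, 2.0, 3.0):
            assert out[f"D_{x:.1f}cc"] == oracles.dvp_oracle(
                [10.0, 5.0], [1000.0, 1000.0], x)

    def test_output_non_increasing_and_length_50(self, case_surface):
        for region in ("whole", "anterior", "posterior"):
            out = rd.compute_dvps(case_surface["surface"], region, 3.0)
            vals = [out[n] for n in DVP_NAMES]
            assert len(vals) == 50
            assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_auto_thickness(self):
        sd = toy_surface_dose([4.0, 2.0], [1000.0, 1000.0])
        out = rd.compute_dvps(sd, "whole", wall_thickness="auto",
                              wall_volume_mm3=4000.0)   # => 2 mm thickness
        assert out["D_2.0cc"] == 4.0
        with pytest.raises(ValueError):
            rd.compute_dvps(sd, "whole", wall_thickness="auto")

    def test_nonpositive_thickness_rejected(self):
        sd = toy_surface_dose([1.0, 1.0], [10.0, 10.0])
        with pytest.raises(ValueError):
            rd.compute_dvps(sd, "whole", wall_thickness=0.0)

    def test_region_masks_partition_vertices(self):
        sd = toy_surface_dose([1.0, 2.0, 3.0, 4.0], [10.0] * 4)
        ant = sd.region_mask("anterior").sum()
        post = sd.region_mask("posterior").sum()
        assert ant + post == sd.region_mask("whole").sum() == 4


class TestTextures:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agree_with_brute_force_oracle(self, seed):
        m = random_rsdm(seed)
        ours = rd.compute_textures(m, quantization_levels=8)
        ref = oracles.texture_features_oracle(
            np.nan_to_num(m.dose).tolist(), m.mask.tolist(), 8)
        assert set(ours) == set(TEXTURE_NAMES)
        for name in TEXTURE_NAMES:
            assert ours[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name

    def test_constant_map_degenerate_values(self):
        mask = np.ones((6, 6), bool)
        m = RSDM(dose=np.full((6, 6), 5.0), mask=mask)
        out = rd.compute_textures(m)
        assert out["Global_Variance"] == 0.0
        assert out["GLCM_Energy"] == pytest.approx(1.0)
        assert out["NGTDM_Contrast"] == 0.0

    def test_checkerboard_glcm_contrast_horizontal(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 + 1   # levels 1, 2
        P = glcm_matrix(board, 2, offsets=((0, 1),))
        feats = _glcm_features(P)
        assert feats["GLCM_Contrast"] == pytest.approx(1.0)

    def test_exactly_43_names(self):
        m = random_rsdm(9)
        out = rd.compute_textures(m)
        assert len(out) == 43
        assert list(out) != []  # named dict, fixed set
        assert set(out) == set(TEXTURE_NAMES)

    def test_quantization_range(self):
        m = random_rsdm(4)
        q = quantize(m, 32)
        assert q[m.mask].min() >= 1 and q[m.mask].max() <= 32
        assert (q[~m.mask] == 0).all()

    def test_small_foreground_rejected(self):
        mask = np.zeros((4, 4), bool)
        mask[0, :3] = True
        m = RSDM(dose=np.where(mask, 1.0, np.nan), mask=mask)
        with pytest.raises(ValueError):
            rd.compute_textures(m)


class TestDGP:
    def test_level_above_max_all_zero(self):
        mask = np.ones((5, 8), bool)
        m = RSDM(dose=np.full((5, 8), 0.5), mask=mask, region="whole")
        out = rd.compute_dgps(m)
        for prop in ("Area", "Rel_area", "Ecc", "Maj", "Min", "Per",
                     "Cen2Bot", "Cen2Lft", "Cen2Rgt"):
            assert out[f"{prop}_30Gy"] == 0.0

    def test_full_rectangle(self):
        mask = np.ones((5, 8), bool)
        m = RSDM(dose=np.full((5, 8), 10.0), mask=mask, region="whole")
        out = rd.compute_dgps(m, levels=[5])
        assert out["Area_5Gy"] == 40.0
        assert out["Rel_area_5Gy"] == 100.0

    def test_disc_nearly_isotropic(self):
        yy, xx = np.mgrid[:21, :21]
        mask = (yy - 10) ** 2 + (xx - 10) ** 2 <= 64
        m = RSDM(dose=np.where(mask, 10.0, np.nan), mask=mask, region="whole")
        out = rd.compute_dgps(m, levels=[5])
        assert out["Ecc_5Gy"] == pytest.approx(0.0, abs=0.05)
        assert out["Maj_5Gy"] == pytest.approx(out["Min_5Gy"], rel=0.02)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_moments_match_pixel_oracle(self, seed):
        m = random_rsdm(seed, shape=(12, 12))
        out = rd.compute_dgps(m, levels=[10])
        sub = m.mask & (np.nan_to_num(m.dose) >= 10)
        if not sub.any():
            return
        ecc, maj, mnr, cen = oracles.moments_oracle(sub.tolist())
        assert out["Ecc_10Gy"] == pytest.approx(ecc, abs=1e-9)
        assert out["Maj_10Gy"] == pytest.approx(maj, abs=1e-9)
        assert out["Min_10Gy"] == pytest.approx(mnr, abs=1e-9)

    def test_area_monotone_in_level(self, case_surface):
        for region, sign in (("whole", -1), ("anterior", -1), ("posterior", +1)):
            out = rd.compute_dgps(case_surface[region])
            areas = [out[f"Area_{lv}Gy"] for lv in range(1, 31)]
            diffs = np.diff(areas) * sign
            assert np.all(diffs >= 0), region

    def test_posterior_uses_below_threshold(self):
        mask = np.ones((4, 4), bool)
        dose = np.full((4, 4), 3.0)
        post = RSDM(dose=dose, mask=mask, region="posterior")
        out = rd.compute_dgps(post, levels=[2, 10])
        assert out["Area_2Gy"] == 0.0          # nothing below 2 Gy
        assert out["Area_10Gy"] == 16.0        # everything below 10 Gy

    def test_perimeter_of_square(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True                  # 4x4 square
        per = mask_perimeter(mask)
        assert per == pytest.approx(16.0, rel=0.15)

    def test_single_pixel_has_zero_axes(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        m = RSDM(dose=np.where(mask, 9.0, np.nan), mask=mask, region="whole")
        out = rd.compute_dgps(m, levels=[5])
        assert out["Ecc_5Gy"] == 0.0
        assert out["Maj_5Gy"] == 0.0


class TestFeatureTable:
    def test_row_and_column_counts(self, tiny_cohort):
        ext = rd.DosimetricFeatureExtractor(n_theta=64)
        df = ext.fit(tiny_cohort).transform(tiny_cohort)
        assert len(FEATURE_NAMES) == 363 == 50 + 43 + 270
        for region in ("whole", "anterior", "posterior"):
            sub = df[df.region == region]
            assert len(sub) == 2 * 3            # pre+post per patient
            assert sub[FEATURE_NAMES].notna().all().all()
        assert list(df.columns[3:]) == FEATURE_NAMES

    def test_byte_identical_rerun(self, tiny_cohort):
        ext = rd.DosimetricFeatureExtractor(n_theta=64)
        a = ext.fit(tiny_cohort).transform(tiny_cohort).to_csv(index=False)
        b = ext.fit(tiny_cohort).transform(tiny_cohort).to_csv(index=False)
        assert a == b

    def test_missing_region_rejected_with_log(self, caplog):
        rec = {"patient_id": "P0", "condition": "pre",
               "features": {"whole": dict.fromkeys(FEATURE_NAMES, 0.0)}}
        import logging
        with caplog.at_level(logging.WARNING):
            df = rd.assemble_feature_table([rec])
        assert len(df) == 0
        assert "missing regions" in caplog.text

    def test_column_order_is_dvp_texture_dgp(self):
        assert FEATURE_NAMES[:50] == DVP_NAMES
        assert FEATURE_NAMES[50:93] == TEXTURE_NAMES
        assert FEATURE_NAMES[93:] == DGP_NAMES
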