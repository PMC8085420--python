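"""Texture features of the 2D dose map: global, GLCM, GLRLM, GLSZM, NGTDM.

All matrices are computed on the foreground only after quantizing the
foreground doses to ``quantization_levels`` equal-width bins over
[min, max] (a constant map collapses to a single gray level and the
features take their degenerate closed-form values).  GLCM and GLRLM
matrices are merged (summed) over the four distance-1 directions before
feature computation; GLSZM zones are 8-connected equal-level components;
NGTDM neighbourhoods are the 8-neighbours restricted to foreground.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from ..rsdm import RSDM

_EPS = 1e-12

TEXTURE_NAMES = (
    ["Global_Variance", "Global_Skewness", "Global_Kurtosis"]
    + ["GLCM_" + n for n in ["Energy", "Contrast", "Entropy", "Homogeneity",
                             "Correlation", "SumAverage", "Variance",
                             "Dissimilarity", "Autocorrelation"]]
    + ["GLRLM_" + n for n in ["SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
                              "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV"]]
    + ["GLSZM_" + n for n in ["SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
                              "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV"]]
    + ["NGTDM_" + n for n in ["Coarseness", "Contrast", "Busyness",
                              "Complexity", "Strength"]]
)

GLCM_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))   # 0, 45, 90, 135 degrees


def quantize(rsdm: RSDM, levels: int = 32) -> np.ndarray:
    """Foreground doses -> integer gray levels 1..levels (0 = background)."""
    vals = rsdm.foreground_values()
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(rsdm.shape, dtype=int)
    if hi - lo < _EPS:
        q[rsdm.mask] = 1
        return q
    bins = np.floor((rsdm.dose[rsdm.mask] - lo) / (hi - lo) * levels).astype(int)
    q[rsdm.mask] = np.clip(bins, 0, levels - 1) + 1
    return q


def glcm_matrix(levels_img: np.ndarray, n_levels: int,
                offsets=GLCM_OFFSETS) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix merged over offsets."""
    P = np.zeros((n_levels, n_levels))
    for dr, dc in offsets:
        a = levels_img
        if dr >= 0:
            src = a[: a.shape[0] - dr or None, :]
            dst = a[dr:, :]
        if dc > 0:
            src, dst = src[:, :-dc], dst[:, dc:]
        elif dc < 0:
            src, dst = src[:, -dc:], dst[:, :dc]
        ok = (src > 0) & (dst > 0)
        if not ok.any():
            continue
        np.add.at(P, (src[ok] - 1, dst[ok] - 1), 1.0)
    P = P + P.T
    s = P.sum()
    return P / s if s > 0 else P


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    n = P.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((px * i).sum())
    sig = float(np.sqrt((px * (i - mu) ** 2).sum()))
    nz = P > 0
    if sig < _EPS:
        corr = 1.0          # single gray level: perfectly correlated by convention
    else:
        corr = float((P * (ii - mu) * (jj - mu)).sum() / sig ** 2)
    k = np.arange(2, 2 * n + 1)
    pxy = np.array([P[(ii + jj) == kk].sum() for kk in k])
    return {
        "GLCM_Energy": float((P ** 2).sum()),
        "GLCM_Contrast": float((P * (ii - jj) ** 2).sum()),
        "GLCM_Entropy": float(-(P[nz] * np.log2(P[nz])).sum()),
        "GLCM_Homogeneity": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "GLCM_Correlation": corr,
        "GLCM_SumAverage": float((k * pxy).sum()),
        "GLCM_Variance": float((P * (ii - mu) ** 2).sum()),
        "GLCM_Dissimilarity": float((P * np.abs(ii - jj)).sum()),
        "GLCM_Autocorrelation": float((P * ii * jj).sum()),
    }


def _iter_lines(levels_img: np.ndarray):
    """All lines of the image along the four GLRLM directions (bg = 0)."""
    h, w = levels_img.shape
    for r in range(h):
        yield levels_img[r, :]
    for c in range(w):
        yield levels_img[:, c]
    flipped = levels_img[:, ::-1]
    for off in range(-h + 1, w):
        yield np.diagonal(levels_img, offset=off)
        yield np.diagonal(flipped, offset=off)


def glrlm_matrix(levels_img: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length matrix R[level, run_length] merged over the 4 directions."""
    max_run = max(levels_img.shape)
    R = np.zeros((n_levels, max_run))
    for line in _iter_lines(levels_img):
        if line.size == 0:
            continue
        padded = np.concatenate([[-1], line, [-1]])
        change = np.flatnonzero(np.diff(padded) != 0)
        run_vals = padded[change[:-1] + 1]
        run_lens = np.diff(change)
        fg = run_vals > 0
        np.add.at(R, (run_vals[fg] - 1, run_lens[fg] - 1), 1.0)
    return R


def glszm_matrix(levels_img: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix Z[level, zone_size] with 8-connected zones."""
    n_px = int((levels_img > 0).sum())
    Z = np.zeros((n_levels, max(n_px, 1)))
    st = np.ones((3, 3), dtype=int)
    for lv in range(1, n_levels + 1):
        binim = levels_img == lv
        if not binim.any():
            continue
        lab, n = ndi.label(binim, structure=st)
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(Z, (lv - 1, sizes - 1), 1.0)
    return Z


def _rl_family(M: np.ndarray, n_px: int, prefix: str,
               size_names: tuple[str, str, str, str, str]) -> dict[str, float]:
    """The 13 shared run-length / size-zone statistics of a matrix M[level, size]."""
    short, long_, sizen, pct, letter = size_names
    keys = [short, long_, "GLN", sizen, pct, f"LG{letter}E", f"HG{letter}E",
            f"{short[:2]}LGE", f"{short[:2]}HGE", f"{long_[:2]}LGE",
            f"{long_[:2]}HGE", "GLV",
            f"{letter}{'LV' if prefix == 'GLRLM' else 'SV'}"]
    Ns = M.sum()
    if Ns == 0:
        return {f"{prefix}_{k}": 0.0 for k in keys}
    i = np.arange(1, M.shape[0] + 1)[:, None]       # gray level
    j = np.arange(1, M.shape[1] + 1)[None, :]       # run length / zone size
    p = M / Ns
    gi = M.sum(axis=1)
    sj = M.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    vals = [
        float((M / j ** 2).sum() / Ns),
        float((M * j ** 2).sum() / Ns),
        float((gi ** 2).sum() / Ns),
        float((sj ** 2).sum() / Ns),
        float(Ns / n_px),
        float((M / i ** 2).sum() / Ns),
        float((M * i ** 2).sum() / Ns),
        float((M / (i ** 2 * j ** 2)).sum() / Ns),
        float((M * i ** 2 / j ** 2).sum() / Ns),
        float((M * j ** 2 / i ** 2).sum() / Ns),
        float((M * i ** 2 * j ** 2).sum() / Ns),
        float((p * (i - mu_i) ** 2).sum()),
        float((p * (j - mu_j) ** 2).sum()),
    ]
    return {f"{prefix}_{k}": v for k, v in zip(keys, vals)}


def _glrlm_features(levels_img: np.ndarray, n_levels: int, n_px: int) -> dict:
    R = glrlm_matrix(levels_img, n_levels)
    return _rl_family(R, n_px, "GLRLM", ("SRE", "LRE", "RLN", "RP", "R"))


def _glszm_features(levels_img: np.ndarray, n_levels: int, n_px: int) -> dict:
    Z = glszm_matrix(levels_img, n_levels)
    return _rl_family(Z, n_px, "GLSZM", ("SZE", "LZE", "ZSN", "ZP", "Z"))


def _ngtdm_features(levels_img: np.ndarray, n_levels: int) -> dict[str, float]:
    fg = levels_img > 0
    lv = levels_img.astype(float)
    h, w = lv.shape
    pad_l = np.pad(lv, 1)
    pad_f = np.pad(fg, 1)
    nbr_sum = np.zeros((h, w))
    nbr_cnt = np.zeros((h, w))
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nbr_sum += (pad_l * pad_f)[1 + dr: 1 + dr + h, 1 + dc: 1 + dc + w]
            nbr_cnt += pad_f[1 + dr: 1 + dr + h, 1 + dc: 1 + dc + w]
    valid = fg & (nbr_cnt > 0)
    A = np.zeros((h, w))
    A[valid] = nbr_sum[valid] / nbr_cnt[valid]
    N = int(valid.sum())
    s = np.zeros(n_levels)
    n_i = np.zeros(n_levels)
    for lvidx in range(1, n_levels + 1):
        m = valid & (levels_img == lvidx)
        n_i[lvidx - 1] = m.sum()
        s[lvidx - 1] = np.abs(lvidx - A[m]).sum()
    p = n_i / max(N, 1)
    iv = np.arange(1, n_levels + 1, dtype=float)
    nz = p > 0
    Ng = int(nz.sum())
    ps = float((p * s).sum())

    coarseness = 1.0 / ps if ps > _EPS else 0.0
    if Ng > 1:
        pi, pj = np.meshgrid(p[nz], p[nz], indexing="ij")
        ivi, ivj = np.meshgrid(iv[nz], iv[nz], indexing="ij")
        contrast = float((pi * pj * (ivi - ivj) ** 2).sum()) / (Ng * (Ng - 1))
        contrast *= float(s.sum()) / max(N, 1)
        denom = float(np.abs(ivi * pi - ivj * pj).sum())
        busyness = ps / denom if denom > _EPS else 0.0
        si = s[nz]
        sij_i, sij_j = np.meshgrid(si, si, indexing="ij")
        complexity = float((np.abs(ivi - ivj)
                            * (pi * sij_i + pj * sij_j) / (pi + pj)).sum()) / max(N, 1)
        ssum = float(s.sum())
        strength = (float(((pi + pj) * (ivi - ivj) ** 2).sum()) / ssum
                    if ssum > _EPS else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"NGTDM_Coarseness": coarseness, "NGTDM_Contrast": contrast,
            "NGTDM_Busyness": busyness, "NGTDM_Complexity": complexity,
            "NGTDM_Strength": strength}


def _global_features(vals: np.ndarray) -> dict[str, float]:
    mu = vals.mean()
    m2 = ((vals - mu) ** 2).mean()
    if m2 < _EPS:
        return {"Global_Variance": 0.0, "Global_Skewness": 0.0,
                "Global_Kurtosis": 0.0}
    m3 = ((vals - mu) ** 3).mean()
    m4 = ((vals - mu) ** 4).mean()
    return {"Global_Variance": float(m2),
            "Global_Skewness": float(m3 / m2 ** 1.5),
            "Global_Kurtosis": float(m4 / m2 ** 2)}


def compute_textures(rsdm: RSDM, quantization_levels: int = 32) -> dict[str, float]:
    """All 43 texture features of one dose map region."""
    if int(rsdm.mask.sum()) < 16:
        raise ValueError("foreground must contain at least 16 pixels")
    vals = rsdm.foreground_values()
    q = quantize(rsdm, quantization_levels)
    n_px = int(rsdm.mask.sum())
    out: dict[str, float] = {}
    out.update(_global_features(vals))
    out.update(_glcm_features(glcm_matrix(q, quantization_levels)))
    out.update(_glrlm_features(q, quantization_levels, n_px))
    out.update(_glszm_features(q, quantization_levels, n_px))
    out.update(_ngtdm_features(q, quantization_levels))
    assert set(out) == set(TEXTURE_NAMES)
    return out
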