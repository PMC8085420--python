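"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain Python loops over pixels / vertices,
deliberately avoiding the vectorized code paths (and the helper functions)
of the package, so that agreement is a genuine dual-route check.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# quantization (same documented rule, loop implementation)

def quantize_oracle(dose, mask, levels):
    vals = [dose[i][j] for i in range(len(dose)) for j in range(len(dose[0])) if mask[i][j]]
    lo, hi = min(vals), max(vals)
    q = [[0] * len(dose[0]) for _ in range(len(dose))]
    for i in range(len(dose)):
        for j in range(len(dose[0])):
            if not mask[i][j]:
                continue
            if hi - lo < 1e-12:
                q[i][j] = 1
            else:
                b = int((dose[i][j] - lo) / (hi - lo) * levels)
                q[i][j] = min(max(b, 0), levels - 1) + 1
    return q


# ---------------------------------------------------------------------------
# GLCM

def glcm_features_oracle(q, n_levels):
    h, w = len(q), len(q[0])
    offsets = [(0, 1), (1, 1), (1, 0), (1, -1)]
    P = [[0.0] * n_levels for _ in range(n_levels)]
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and q[r][c] > 0 and q[r2][c2] > 0:
                    P[q[r][c] - 1][q[r2][c2] - 1] += 1
                    P[q[r2][c2] - 1][q[r][c] - 1] += 1
    s = sum(sum(row) for row in P)
    if s > 0:
        P = [[v / s for v in row] for row in P]
    px = [sum(P[i]) for i in range(n_levels)]
    mu = sum((i + 1) * px[i] for i in range(n_levels))
    var = sum(px[i] * ((i + 1) - mu) ** 2 for i in range(n_levels))
    sig = math.sqrt(var)
    energy = contrast = entropy = homog = dissim = autoc = glcm_var = corr_num = 0.0
    sum_avg = 0.0
    pxy = {}
    for i in range(n_levels):
        for j in range(n_levels):
            p = P[i][j]
            ii, jj = i + 1, j + 1
            energy += p * p
            contrast += p * (ii - jj) ** 2
            if p > 0:
                entropy -= p * math.log2(p)
            homog += p / (1 + abs(ii - jj))
            dissim += p * abs(ii - jj)
            autoc += p * ii * jj
            glcm_var += p * (ii - mu) ** 2
            corr_num += p * (ii - mu) * (jj - mu)
            pxy[ii + jj] = pxy.get(ii + jj, 0.0) + p
    for k, v in pxy.items():
        sum_avg += k * v
    corr = 1.0 if sig < 1e-12 else corr_num / (sig * sig)
    return {"GLCM_Energy": energy, "GLCM_Contrast": contrast,
            "GLCM_Entropy": entropy, "GLCM_Homogeneity": homog,
            "GLCM_Correlation": corr, "GLCM_SumAverage": sum_avg,
            "GLCM_Variance": glcm_var, "GLCM_Dissimilarity": dissim,
            "GLCM_Autocorrelation": autoc}


# ---------------------------------------------------------------------------
# GLRLM / GLSZM shared statistics

def _rl_stats(M, n_px, prefix, names):
    short, long_, sizen, pct, letter = names
    Ns = sum(sum(row) for row in M)
    nl, nr = len(M), len(M[0])
    gi = [sum(M[i]) for i in range(nl)]
    sj = [sum(M[i][j] for i in range(nl)) for j in range(nr)]
    mu_i = sum((i + 1) * gi[i] for i in range(nl)) / Ns
    mu_j = sum((j + 1) * sj[j] for j in range(nr)) / Ns
    acc = dict.fromkeys(range(11), 0.0)
    glv = rlv = 0.0
    for i in range(nl):
        for j in range(nr):
            m = M[i][j]
            if m == 0:
                continue
            ii, jj = i + 1, j + 1
            acc[0] += m / jj ** 2
            acc[1] += m * jj ** 2
            acc[5] += m / ii ** 2
            acc[6] += m * ii ** 2
            acc[7] += m / (ii ** 2 * jj ** 2)
            acc[8] += m * ii ** 2 / jj ** 2
            acc[9] += m * jj ** 2 / ii ** 2
            acc[10] += m * ii ** 2 * jj ** 2
            glv += m / Ns * (ii - mu_i) ** 2
            rlv += m / Ns * (jj - mu_j) ** 2
    out = {
        f"{prefix}_{short}": acc[0] / Ns,
        f"{prefix}_{long_}": acc[1] / Ns,
        f"{prefix}_GLN": sum(g * g for g in gi) / Ns,
        f"{prefix}_{sizen}": sum(s * s for s in sj) / Ns,
        f"{prefix}_{pct}": Ns / n_px,
        f"{prefix}_LG{letter}E": acc[5] / Ns,
        f"{prefix}_HG{letter}E": acc[6] / Ns,
        f"{prefix}_{short[:2]}LGE": acc[7] / Ns,
        f"{prefix}_{short[:2]}HGE": acc[8] / Ns,
        f"{prefix}_{long_[:2]}LGE": acc[9] / Ns,
        f"{prefix}_{long_[:2]}HGE": acc[10] / Ns,
        f"{prefix}_GLV": glv,
        f"{prefix}_{letter}{'LV' if prefix == 'GLRLM' else 'SV'}": rlv,
    }
    return out


def glrlm_features_oracle(q, n_levels):
    h, w = len(q), len(q[0])
    n_px = sum(1 for i in range(h) for j in range(w) if q[i][j] > 0)
    max_run = max(h, w)
    M = [[0.0] * max_run for _ in range(n_levels)]

    def lines():
        for r in range(h):
            yield [q[r][c] for c in range(w)]
        for c in range(w):
            yield [q[r][c] for r in range(h)]
        # diagonal down-right
        for start in [(0, c) for c in range(w)] + [(r, 0) for r in range(1, h)]:
            line = []
            r, c = start
            while r < h and c < w:
                line.append(q[r][c])
                r += 1
                c += 1
            yield line
        # diagonal down-left
        for start in [(0, c) for c in range(w)] + [(r, w - 1) for r in range(1, h)]:
            line = []
            r, c = start
            while r < h and c >= 0:
                line.append(q[r][c])
                r += 1
                c -= 1
            yield line

    for line in lines():
        run_val, run_len = None, 0
        for v in line + [None]:
            if v == run_val:
                run_len += 1
            else:
                if run_val is not None and run_val > 0:
                    M[run_val - 1][run_len - 1] += 1
                run_val, run_len = v, 1
    return _rl_stats(M, n_px, "GLRLM", ("SRE", "LRE", "RLN", "RP", "R"))


def glszm_features_oracle(q, n_levels):
    h, w = len(q), len(q[0])
    n_px = sum(1 for i in range(h) for j in range(w) if q[i][j] > 0)
    M = [[0.0] * max(n_px, 1) for _ in range(n_levels)]
    seen = [[False] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            if q[i][j] > 0 and not seen[i][j]:
                lv = q[i][j]
                stack = [(i, j)]
                seen[i][j] = True
                size = 0
                while stack:
                    r, c = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = r + dr, c + dc
                            if (0 <= r2 < h and 0 <= c2 < w and not seen[r2][c2]
                                    and q[r2][c2] == lv):
                                seen[r2][c2] = True
                                stack.append((r2, c2))
                M[lv - 1][size - 1] += 1
    return _rl_stats(M, n_px, "GLSZM", ("SZE", "LZE", "ZSN", "ZP", "Z"))


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_features_oracle(q, n_levels):
    h, w = len(q), len(q[0])
    s = [0.0] * n_levels
    n_i = [0] * n_levels
    N = 0
    for i in range(h):
        for j in range(w):
            if q[i][j] == 0:
                continue
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = i + dr, j + dc
                    if 0 <= r2 < h and 0 <= c2 < w and q[r2][c2] > 0:
                        nb.append(q[r2][c2])
            if not nb:
                continue
            N += 1
            lv = q[i][j]
            n_i[lv - 1] += 1
            s[lv - 1] += abs(lv - sum(nb) / len(nb))
    p = [ni / N for ni in n_i] if N else [0.0] * n_levels
    present = [i for i in range(n_levels) if p[i] > 0]
    Ng = len(present)
    ps = sum(p[i] * s[i] for i in range(n_levels))
    coars = 1.0 / ps if ps > 1e-12 else 0.0
    if Ng > 1:
        contrast = sum(p[i] * p[j] * (i - j) ** 2
                       for i in present for j in present) / (Ng * (Ng - 1))
        contrast *= sum(s) / N
        denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                    for i in present for j in present)
        busy = ps / denom if denom > 1e-12 else 0.0
        compl_ = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                     for i in present for j in present) / N
        ssum = sum(s)
        strength = (sum((p[i] + p[j]) * (i - j) ** 2
                        for i in present for j in present) / ssum
                    if ssum > 1e-12 else 0.0)
    else:
        contrast = busy = compl_ = strength = 0.0
    return {"NGTDM_Coarseness": coars, "NGTDM_Contrast": contrast,
            "NGTDM_Busyness": busy, "NGTDM_Complexity": compl_,
            "NGTDM_Strength": strength}


def global_features_oracle(vals):
    n = len(vals)
    mu = sum(vals) / n
    m2 = sum((v - mu) ** 2 for v in vals) / n
    if m2 < 1e-12:
        return {"Global_Variance": 0.0, "Global_Skewness": 0.0,
                "Global_Kurtosis": 0.0}
    m3 = sum((v - mu) ** 3 for v in vals) / n
    m4 = sum((v - mu) ** 4 for v in vals) / n
    return {"Global_Variance": m2, "Global_Skewness": m3 / m2 ** 1.5,
            "Global_Kurtosis": m4 / m2 ** 2}


def texture_features_oracle(dose, mask, n_levels):
    q = quantize_oracle(dose, mask, n_levels)
    vals = [dose[i][j] for i in range(len(dose)) for j in range(len(dose[0]))
            if mask[i][j]]
    out = {}
    out.update(global_features_oracle(vals))
    out.update(glcm_features_oracle(q, n_levels))
    out.update(glrlm_features_oracle(q, n_levels))
    out.update(glszm_features_oracle(q, n_levels))
    out.update(ngtdm_features_oracle(q, n_levels))
    return out


# ---------------------------------------------------------------------------
# pixel-moment ellipse oracle (for DGP shape descriptors)

def moments_oracle(mask):
    """(eccentricity, major, minor, centroid_rc) by direct pixel summation."""
    pts = [(i, j) for i in range(len(mask)) for j in range(len(mask[0])) if mask[i][j]]
    n = len(pts)
    cr = sum(p[0] for p in pts) / n
    cc = sum(p[1] for p in pts) / n
    mu20 = sum((p[0] - cr) ** 2 for p in pts) / n
    mu02 = sum((p[1] - cc) ** 2 for p in pts) / n
    mu11 = sum((p[0] - cr) * (p[1] - cc) for p in pts) / n
    tr = mu20 + mu02
    det = mu20 * mu02 - mu11 ** 2
    disc = math.sqrt(max(tr * tr / 4 - det, 0.0))
    l1 = tr / 2 + disc
    l2 = tr / 2 - disc
    maj = 4 * math.sqrt(max(l1, 0.0))
    mnr = 4 * math.sqrt(max(l2, 0.0))
    ecc = math.sqrt(1 - l2 / l1) if l1 > 1e-12 else 0.0
    return ecc, maj, mnr, (cr, cc)


# ---------------------------------------------------------------------------
# DVP sort-and-accumulate oracle

def dvp_oracle(doses, volumes_mm3, x_cc):
    order = sorted(range(len(doses)), key=lambda i: -doses[i])
    cum = 0.0
    target = x_cc * 1000.0
    for i in order:
        cum += volumes_mm3[i]
        if cum >= target:
            return doses[i]
    return min(doses)


# ---------------------------------------------------------------------------
# discrete mutual information (for selector toy checks)

def mi_oracle(a, b):
    n = len(a)
    pa, pb, pab = {}, {}, {}
    for x, y in zip(a, b):
        pa[x] = pa.get(x, 0) + 1
        pb[y] = pb.get(y, 0) + 1
        pab[(x, y)] = pab.get((x, y), 0) + 1
    mi = 0.0
    for (x, y), c in pab.items():
        p = c / n
        mi += p * math.log(p / (pa[x] / n * pb[y] / n))
    return mi
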