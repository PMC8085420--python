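"""The 24 feature-selection strategies of the discrimination grid.

Four families, all deterministic:

* information-theoretic (MIM, MIFS, MRMR, CIFE, JMI, CMIM, ICAP, DISR,
  LCSI) — greedy forward selection on equal-frequency 5-bin discretized
  features, each criterion a different combination of relevance
  I(f; y), redundancy I(f; s) and class-conditional redundancy
  I(f; s | y) with the already selected set S;
* FCBF — symmetric-uncertainty ranking with predominance-based
  redundancy elimination;
* score/graph-based (fisher_score, f_score, t_score, gini_index, relief,
  lap_score, SPEC, trace_ratio) — univariate or neighbourhood-graph
  scores;
* sparse-learning (ls_l21, ll_l21, RFS, MCFS, NDFS, UDFS) —
  l2,1-regularized objectives solved by fixed-iteration iteratively
  reweighted least squares (or proximal gradient for the logistic loss),
  features ranked by weight-matrix row norms.

Everything is exposed through the sklearn-compatible
:class:`FeatureSelector`, so selectors drop into pipelines and
cross-validation unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.linear_model import Lars
from sklearn.utils.validation import check_is_fitted

_EPS = 1e-12

SELECTOR_NAMES = [
    "CIFE", "CMIM", "DISR", "FCBF", "ICAP", "JMI", "LCSI", "MIFS", "MIM",
    "MRMR", "fisher_score", "lap_score", "relief", "SPEC", "trace_ratio",
    "ll_l21", "ls_l21", "MCFS", "NDFS", "RFS", "UDFS", "f_score",
    "gini_index", "t_score",
]


# ---------------------------------------------------------------------------
# discretization and (conditional) mutual information, vectorized over features

def discretize_equal_frequency(X: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Column-wise equal-frequency binning to integer codes 0..n_bins-1."""
    n, d = X.shape
    codes = np.zeros((n, d), dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(d):
        edges = np.unique(np.quantile(X[:, j], qs))
        codes[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return codes


def _joint_counts(F: np.ndarray, z: np.ndarray, nf: int, nz: int) -> np.ndarray:
    """Per-column joint histogram of F's columns with z -> (d, nf, nz)."""
    n, d = F.shape
    flat = (np.arange(d) * (nf * nz))[None, :] + F * nz + z[:, None]
    return np.bincount(flat.ravel(), minlength=d * nf * nz).reshape(d, nf, nz).astype(float)


def mi_all(F: np.ndarray, z: np.ndarray, nf: int, nz: int) -> np.ndarray:
    """I(f_j; z) in nats for every column of F (discrete codes)."""
    c = _joint_counts(F, z, nf, nz)
    n = F.shape[0]
    p = c / n
    pi = p.sum(axis=2, keepdims=True)
    pj = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p * np.log(p / (pi * pj))
    return np.nansum(t, axis=(1, 2))


def cmi_all(F: np.ndarray, z: np.ndarray, y: np.ndarray,
            nf: int, nz: int, ny: int) -> np.ndarray:
    """I(f_j; z | y) for every column of F."""
    n, d = F.shape
    out = np.zeros(d)
    for c in np.unique(y):
        m = y == c
        w = m.mean()
        out += w * mi_all(F[m], z[m], nf, nz)
    return out


def entropy_codes(z: np.ndarray, nz: int) -> float:
    p = np.bincount(z, minlength=nz) / len(z)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# information-theoretic greedy family

def _greedy_info(Xc: np.ndarray, y: np.ndarray, k: int, criterion: str,
                 n_bins: int = 5) -> list[int]:
    n, d = Xc.shape
    ny = int(y.max()) + 1
    rel = mi_all(Xc, y, n_bins, ny)
    k = min(k, d)
    if criterion == "MIM":
        return list(np.argsort(-rel, kind="stable")[:k])

    selected: list[int] = []
    red_sum = np.zeros(d)        # sum_s I(f; s)
    cond_sum = np.zeros(d)       # sum_s I(f; s | y)
    run_max = np.full(d, -np.inf)   # CMIM: max_s [I(f;s) - I(f;s|y)]
    icap_sum = np.zeros(d)
    disr_sum = np.zeros(d)
    Hy = entropy_codes(y, ny)

    if criterion == "DISR":
        Hf = np.array([entropy_codes(Xc[:, j], n_bins) for j in range(d)])
        first_score = rel / np.maximum(Hf + Hy - rel, _EPS)
    else:
        first_score = rel
    avail = np.ones(d, dtype=bool)
    j0 = int(np.argmax(first_score))
    selected.append(j0)
    avail[j0] = False

    while len(selected) < k:
        s = selected[-1]
        zc = Xc[:, s]
        mi_fs = mi_all(Xc, zc, n_bins, n_bins)
        if criterion in ("CIFE", "JMI", "CMIM", "ICAP", "LCSI"):
            cmi_fs = cmi_all(Xc, zc, y, n_bins, n_bins, ny)
        if criterion == "DISR":
            joint = Xc * n_bins + zc[:, None]        # 25-level joint variable
            i_joint = mi_all(joint, y, n_bins * n_bins, ny)
            cj = _joint_counts(joint, y, n_bins * n_bins, ny) / n
            with np.errstate(divide="ignore", invalid="ignore"):
                h_joint = -np.nansum(cj * np.log(cj), axis=(1, 2))
            disr_sum += i_joint / np.maximum(h_joint, _EPS)
            score = disr_sum
        elif criterion == "MIFS":
            red_sum += mi_fs
            score = rel - red_sum
        elif criterion == "MRMR":
            red_sum += mi_fs
            score = rel - red_sum / len(selected)
        elif criterion == "CIFE":
            red_sum += mi_fs
            cond_sum += cmi_fs
            score = rel - red_sum + cond_sum
        elif criterion == "JMI":
            red_sum += mi_fs
            cond_sum += cmi_fs
            score = rel - (red_sum - cond_sum) / len(selected)
        elif criterion == "CMIM":
            run_max = np.maximum(run_max, mi_fs - cmi_fs)
            score = rel - run_max
        elif criterion == "ICAP":
            icap_sum += np.maximum(0.0, mi_fs - cmi_fs)
            score = rel - icap_sum
        elif criterion == "LCSI":
            red_sum += mi_fs
            cond_sum += cmi_fs
            score = rel - 0.5 * red_sum + 0.5 * cond_sum
        else:
            raise ValueError(f"unknown information criterion {criterion}")
        score = np.where(avail, score, -np.inf)
        jn = int(np.argmax(score))
        selected.append(jn)
        avail[jn] = False
    return selected


def _fcbf(Xc: np.ndarray, y: np.ndarray, k: int, n_bins: int = 5) -> list[int]:
    n, d = Xc.shape
    ny = int(y.max()) + 1
    Hy = entropy_codes(y, ny)
    Hf = np.array([entropy_codes(Xc[:, j], n_bins) for j in range(d)])
    su_y = 2 * mi_all(Xc, y, n_bins, ny) / np.maximum(Hf + Hy, _EPS)
    order = list(np.argsort(-su_y, kind="stable"))
    kept: list[int] = []
    removed: list[int] = []
    while order:
        f = order.pop(0)
        kept.append(f)
        if not order:
            break
        rest = np.array(order)
        su_ff = 2 * mi_all(Xc[:, rest], Xc[:, f], n_bins, n_bins) / np.maximum(
            Hf[rest] + Hf[f], _EPS)
        drop = set(rest[su_ff >= su_y[rest]].tolist())
        removed.extend([j for j in order if j in drop])
        order = [j for j in order if j not in drop]
    out = kept + removed                     # pad predominant set to k if needed
    return out[:min(k, d)]


# ---------------------------------------------------------------------------
# score / graph family

def _fisher_score(X, y):
    classes = np.unique(y)
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        num += len(Xc) * (Xc.mean(axis=0) - mu) ** 2
        den += len(Xc) * Xc.var(axis=0)
    return num / np.maximum(den, _EPS)


def _t_score(X, y):
    classes = np.unique(y)
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    se = np.sqrt(X0.var(axis=0, ddof=1) / len(X0) + X1.var(axis=0, ddof=1) / len(X1))
    return np.abs(X0.mean(axis=0) - X1.mean(axis=0)) / np.maximum(se, _EPS)


def _gini_index(X, y):
    """Negated minimal weighted Gini impurity over all binary splits."""
    n, d = X.shape
    classes, yi = np.unique(y, return_inverse=True)
    scores = np.zeros(d)
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        yo = yi[order]
        left1 = np.cumsum(yo)[:-1]
        nl = np.arange(1, n)
        nr = n - nl
        right1 = left1[-1] + yo[-1] - left1
        gl = 1 - (left1 / nl) ** 2 - (1 - left1 / nl) ** 2
        gr = 1 - (right1 / nr) ** 2 - (1 - right1 / nr) ** 2
        scores[j] = -np.min(nl / n * gl + nr / n * gr)
    return scores


def _relief(X, y):
    """Relief weights using every sample with its nearest hit and miss."""
    Xs = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), _EPS)
    n = len(Xs)
    d2 = ((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(X.shape[1])
    for i in range(n):
        same = y == y[i]
        same_i = same.copy()
        same_i[i] = False
        hit = np.argmin(np.where(same_i, d2[i], np.inf))
        miss = np.argmin(np.where(~same, d2[i], np.inf))
        w += np.abs(Xs[i] - Xs[miss]) - np.abs(Xs[i] - Xs[hit])
    return w / n


def _knn_graph(X, k=5):
    """Heat-kernel kNN affinity on the data as given (no internal
    rescaling: the caller decides the feature scaling)."""
    Xs = np.asarray(X, dtype=float)
    d2 = ((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    n = len(Xs)
    idx = np.argsort(d2, axis=1)[:, :k]
    t = np.mean([d2[i, idx[i]].mean() for i in range(n)]) + _EPS
    W = np.zeros((n, n))
    for i in range(n):
        W[i, idx[i]] = np.exp(-d2[i, idx[i]] / t)
    W = np.maximum(W, W.T)
    return W


def _lap_score(X, y=None):
    W = _knn_graph(X)
    D = W.sum(axis=1)
    scores = np.zeros(X.shape[1])
    ones = np.ones(len(X))
    for j in range(X.shape[1]):
        f = X[:, j]
        f = f - (f @ D) / (ones @ D)
        num = f @ (D * f) - f @ (W @ f)     # f' L f
        den = f @ (D * f)
        if den < _EPS:                       # constant feature: least preferred
            scores[j] = -np.inf
        else:
            scores[j] = -(num / den)         # lower Laplacian score is better
    return scores


def _spec(X, y=None):
    W = _knn_graph(X)
    D = W.sum(axis=1)
    Dm = 1.0 / np.sqrt(np.maximum(D, _EPS))
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        f = X[:, j] * np.sqrt(np.maximum(D, _EPS))
        nf = np.linalg.norm(f)
        if nf < _EPS:
            scores[j] = -np.inf
            continue
        f = f / nf
        Lf = f - Dm * (W @ (Dm * f))        # normalized Laplacian action
        scores[j] = -(f @ Lf)
    return scores


def _trace_ratio(X, y, k):
    classes = np.unique(y)
    mu = X.mean(axis=0)
    b = np.zeros(X.shape[1])
    w = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        b += len(Xc) * (Xc.mean(axis=0) - mu) ** 2
        w += len(Xc) * Xc.var(axis=0)
    w = np.maximum(w, _EPS)
    lam = b.sum() / w.sum()
    sel = None
    for _ in range(30):
        score = b - lam * w
        new = np.argsort(-score, kind="stable")[:k]
        if sel is not None and np.array_equal(new, sel):
            break
        sel = new
        lam = b[sel].sum() / w[sel].sum()
    return list(sel)


# ---------------------------------------------------------------------------
# sparse-learning (l2,1) family

def _onehot(y):
    classes = np.unique(y)
    Y = np.zeros((len(y), len(classes)))
    for i, c in enumerate(classes):
        Y[y == c, i] = 1.0
    return Y


def _ls_l21(X, Y, lam=1.0, n_iter=50, tol=1e-6):
    """min ||XW - Y||_F^2 + lam * ||W||_2,1 by IRLS (Woodbury form)."""
    n, d = X.shape
    dj = np.ones(d)
    W = None
    prev = np.inf
    for _ in range(n_iter):
        Dinv = 1.0 / dj
        G = (X * Dinv) @ X.T + lam * np.eye(n)
        W = (Dinv[:, None] * X.T) @ np.linalg.solve(G, Y)
        rn = np.linalg.norm(W, axis=1)
        obj = ((X @ W - Y) ** 2).sum() + lam * rn.sum()
        dj = 1.0 / (2.0 * np.maximum(rn, _EPS))
        if abs(prev - obj) < tol * max(prev, 1.0):
            break
        prev = obj
    return W


def _rfs(X, Y, gamma=1.0, n_iter=50, tol=1e-6):
    """min ||XW - Y||_2,1 + gamma * ||W||_2,1 (robust feature selection)."""
    n, d = X.shape
    dr = np.ones(n)
    dw = np.ones(d)
    prev = np.inf
    W = None
    for _ in range(n_iter):
        Dwinv = 1.0 / dw
        # normal equations (X'DrX + gamma*Dw)W = X'DrY via Woodbury;
        # Dr = diag(1/(2||r_i||)), Dw = diag(1/(2||w_j||)), dr holds Dr^-1
        G = (X * Dwinv) @ X.T + gamma * np.diag(dr)
        W = (Dwinv[:, None] * X.T) @ np.linalg.solve(G, Y)
        res = np.linalg.norm(X @ W - Y, axis=1)
        rn = np.linalg.norm(W, axis=1)
        obj = res.sum() + gamma * rn.sum()
        dr = 2.0 * np.maximum(res, _EPS)
        dw = 1.0 / (2.0 * np.maximum(rn, _EPS))
        if abs(prev - obj) < tol * max(prev, 1.0):
            break
        prev = obj
    return W


def _ll_l21(X, y, lam=0.1, n_iter=50):
    """Multinomial logistic loss + l2,1 penalty by proximal gradient."""
    Y = _onehot(y)
    n, d = X.shape
    c = Y.shape[1]
    W = np.zeros((d, c))
    step = n / max((X ** 2).sum(), _EPS)
    for _ in range(n_iter):
        Z = X @ W
        Z -= Z.max(axis=1, keepdims=True)
        P = np.exp(Z)
        P /= P.sum(axis=1, keepdims=True)
        grad = X.T @ (P - Y) / n
        V = W - step * grad
        rn = np.linalg.norm(V, axis=1)
        shrink = np.maximum(0.0, 1.0 - step * lam / np.maximum(rn, _EPS))
        W = V * shrink[:, None]
    return W


def _spectral_embedding(X, c=5):
    W = _knn_graph(X)
    D = W.sum(axis=1)
    Dm = 1.0 / np.sqrt(np.maximum(D, _EPS))
    Ln = np.eye(len(X)) - (Dm[:, None] * W * Dm[None, :])
    vals, vecs = eigh(Ln)
    return vecs[:, 1:c + 1]                  # skip the trivial constant vector


def _mcfs(X, k, c=5):
    F = _spectral_embedding(X, c)
    scores = np.zeros(X.shape[1])
    Xs = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), _EPS)
    for i in range(F.shape[1]):
        lars = Lars(n_nonzero_coefs=min(k, X.shape[1]))
        lars.fit(Xs, F[:, i])
        scores = np.maximum(scores, np.abs(lars.coef_))
    return scores


def _ndfs(X, c=2, beta=1.0):
    """Nonnegative-spectral flavour: the nonnegative cluster indicator is
    taken from a spectral bipartition (sign of the Fiedler-like vector of
    the normalized Laplacian) and the l2,1-regularized regression of that
    indicator on the features scores the rows (simplified fixed-target
    solver; deterministic)."""
    E = _spectral_embedding(X, c)
    labels = (E[:, 0] >= np.median(E[:, 0])).astype(int)
    F = _onehot(labels)
    Xs = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), _EPS)
    W = _ls_l21(Xs, F, lam=beta)
    return np.linalg.norm(W, axis=1)


def _udfs(X, c=5, gamma=0.1, n_iter=10):
    """min Tr(W' M W) + gamma ||W||_2,1, W'W = I, with M = X' L X."""
    Xs = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), _EPS)
    Wg = _knn_graph(Xs)
    L = np.diag(Wg.sum(axis=1)) - Wg
    M = Xs.T @ L @ Xs
    d = X.shape[1]
    dj = np.ones(d)
    W = None
    for _ in range(n_iter):
        P = M + gamma * np.diag(dj)
        vals, vecs = eigh(P, subset_by_index=[0, c - 1])
        W = vecs
        rn = np.linalg.norm(W, axis=1)
        dj = 1.0 / (2.0 * np.maximum(rn, _EPS))
    return np.linalg.norm(W, axis=1)


# ---------------------------------------------------------------------------
# registry + sklearn front-end

def _rank_from_scores(scores: np.ndarray, k: int) -> list[int]:
    return list(np.argsort(-scores, kind="stable")[:k])


def _run_strategy(name: str, X: np.ndarray, y: np.ndarray, k: int,
                  n_bins: int) -> list[int]:
    info = {"MIM", "MIFS", "MRMR", "CIFE", "JMI", "CMIM", "ICAP", "DISR", "LCSI"}
    k = min(k, X.shape[1])
    if name in info or name == "FCBF":
        Xc = discretize_equal_frequency(X, n_bins)
        yc = np.unique(y, return_inverse=True)[1]
        if name == "FCBF":
            return _fcbf(Xc, yc, k, n_bins)
        return _greedy_info(Xc, yc, k, name, n_bins)
    if name == "fisher_score":
        return _rank_from_scores(_fisher_score(X, y), k)
    if name == "f_score":
        F, _ = f_classif(X, y)
        return _rank_from_scores(np.nan_to_num(F), k)
    if name == "t_score":
        return _rank_from_scores(_t_score(X, y), k)
    if name == "gini_index":
        return _rank_from_scores(_gini_index(X, y), k)
    if name == "relief":
        return _rank_from_scores(_relief(X, y), k)
    if name == "lap_score":
        return _rank_from_scores(_lap_score(X), k)
    if name == "SPEC":
        return _rank_from_scores(_spec(X), k)
    if name == "trace_ratio":
        return _trace_ratio(X, y, k)
    yc = np.unique(y, return_inverse=True)[1]
    Xs = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), _EPS)
    if name == "ls_l21":
        W = _ls_l21(Xs, _onehot(yc))
        return _rank_from_scores(np.linalg.norm(W, axis=1), k)
    if name == "ll_l21":
        W = _ll_l21(Xs, yc)
        return _rank_from_scores(np.linalg.norm(W, axis=1), k)
    if name == "RFS":
        W = _rfs(Xs, _onehot(yc))
        return _rank_from_scores(np.linalg.norm(W, axis=1), k)
    if name == "MCFS":
        return _rank_from_scores(_mcfs(X, k), k)
    if name == "NDFS":
        return _rank_from_scores(_ndfs(X), k)
    if name == "UDFS":
        return _rank_from_scores(_udfs(X), k)
    raise KeyError(
        f"unknown selector {name!r}; valid strategies: {', '.join(SELECTOR_NAMES)}")


class FeatureSelector(SelectorMixin, BaseEstimator):
    """sklearn-compatible wrapper around the 24 selection strategies.

    Parameters
    ----------
    strategy : one of :data:`SELECTOR_NAMES`.
    k : subset size (20 in the discrimination grid).
    n_bins : equal-frequency bins for the information-theoretic family.

    After ``fit``, ``selected_idx_`` holds the ordered selected feature
    indices and ``transform`` keeps exactly those columns.
    """

    def __init__(self, strategy: str = "MRMR", k: int = 20, n_bins: int = 5):
        self.strategy = strategy
        self.k = k
        self.n_bins = n_bins

    def fit(self, X, y=None):
        if self.strategy not in SELECTOR_NAMES:
            raise KeyError(f"unknown selector {self.strategy!r}; valid "
                           f"strategies: {', '.join(SELECTOR_NAMES)}")
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("feature matrix contains missing values")
        yarr = None if y is None else np.asarray(y)
        # constant columns carry no information and can degenerate the
        # graph/sparse objectives: select among varying features, padding
        # with constant ones only if there are fewer than k alive
        alive = np.flatnonzero(X.std(axis=0) > 1e-12)
        dead = np.flatnonzero(X.std(axis=0) <= 1e-12)
        if alive.size == 0:
            raise ValueError("all features are constant")
        sub = _run_strategy(self.strategy, X[:, alive], yarr,
                            min(self.k, alive.size), self.n_bins)
        idx = [int(alive[j]) for j in sub]
        idx.extend(int(j) for j in dead[:max(0, self.k - len(idx))])
        self.selected_idx_ = np.asarray(idx[:min(self.k, X.shape[1])], dtype=int)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_idx_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_idx_] = True
        return mask


def select_features(strategy: str, features, labels, k: int = 20,
                    n_bins: int = 5) -> list:
    """Ordered top-k feature names (or indices) for one strategy."""
    import pandas as pd

    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
        names = list(features.columns)
    else:
        X = np.asarray(features, dtype=float)
        names = list(range(X.shape[1]))
    sel = FeatureSelector(strategy=strategy, k=k, n_bins=n_bins).fit(X, np.asarray(labels))
    return [names[i] for i in sel.selected_idx_]
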