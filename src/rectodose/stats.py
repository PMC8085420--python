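"""Normality-gated paired comparisons and summary-report generation.

Each variable is compared between the paired pre- and post-gel samples:
Shapiro-Wilk is applied to both samples, and when both pass at alpha the
paired Student t test is used and the summary is reported mean +/- SD;
otherwise the Wilcoxon signed-rank test is used and the summary is
median (IQR).  Two-tailed throughout; significance at p < 0.05.  No
multiple-testing correction is applied by default (a Benjamini-Hochberg
toggle exists for sensitivity analyses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = ["PairedComparison", "normality_gated_paired_test", "build_report"]


@dataclass
class PairedComparison:
    variable: str
    n_pairs: int
    shapiro_p_pre: float
    shapiro_p_post: float
    test_used: str                   # "paired t" | "wilcoxon"
    statistic: float
    p_value: float
    significant: bool
    summary_pre: str
    summary_post: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _summaries(pre, post, normal: bool) -> tuple[str, str]:
    if normal:
        return tuple(f"{v.mean():.2f} ± {v.std(ddof=1):.2f}" for v in (pre, post))
    out = []
    for v in (pre, post):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out.append(f"{med:.2f} ({q1:.2f}–{q3:.2f})")
    return tuple(out)


def normality_gated_paired_test(pre, post, alpha: float = 0.05,
                                variable: str = "",
                                shapiro_on: str = "samples") -> PairedComparison:
    """Paired comparison with a Shapiro-Wilk-gated choice of test.

    ``shapiro_on`` selects what the normality gate is applied to: each
    condition's sample (default) or the paired differences.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 3:
        raise ValueError("pre/post must be equal-length 1D arrays with n >= 3")
    diffs = post - pre

    def _shapiro_p(v):
        if np.ptp(v) == 0:
            return 0.0           # constant sample: treat as non-normal
        return float(sps.shapiro(v).pvalue)

    if shapiro_on == "differences":
        p_pre = p_post = _shapiro_p(diffs)
    else:
        p_pre, p_post = _shapiro_p(pre), _shapiro_p(post)
    normal = p_pre > alpha and p_post > alpha

    degenerate = bool(np.all(diffs == 0))
    if degenerate:
        test, stat, p = "wilcoxon", 0.0, 1.0
    elif normal:
        res = sps.ttest_rel(post, pre)
        test, stat, p = "paired t", float(res.statistic), float(res.pvalue)
    else:
        res = sps.wilcoxon(post, pre, zero_method="wilcox")
        test, stat, p = "wilcoxon", float(res.statistic), float(res.pvalue)

    s_pre, s_post = _summaries(pre, post, normal)
    return PairedComparison(
        variable=variable, n_pairs=len(pre), shapiro_p_pre=p_pre,
        shapiro_p_post=p_post, test_used=test, statistic=stat, p_value=p,
        significant=bool(p < 0.05) and not degenerate,
        summary_pre=s_pre, summary_post=s_post, degenerate=degenerate)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (off by default in reports; sensitivity toggle)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def build_report(comparisons: list[PairedComparison],
                 geometry: pd.DataFrame | None = None,
                 frequency=None, out_dir=None,
                 bh_correct: bool = False) -> dict[str, pd.DataFrame]:
    """Assemble the comparison / geometry / frequency summary tables.

    Returns a dict of DataFrames (written as CSV when ``out_dir`` is
    given): ``comparisons`` mirrors the pre/post/p-value layout with a
    footnote marker for the test used, plus optional geometry and
    selection-frequency tables.
    """
    rows = []
    for c in comparisons:
        rows.append({
            "variable": c.variable, "n_pairs": c.n_pairs,
            "pre": c.summary_pre, "post": c.summary_post,
            "p_value": c.p_value,
            "test": c.test_used, "significant": c.significant,
            "degenerate": c.degenerate,
        })
    comp_df = pd.DataFrame(
        rows, columns=["variable", "n_pairs", "pre", "post", "p_value",
                       "test", "significant", "degenerate"])
    if bh_correct and len(comp_df):
        comp_df["p_adjusted"] = benjamini_hochberg(comp_df["p_value"].to_numpy())
    tables = {"comparisons": comp_df}
    if geometry is not None:
        tables["geometry"] = geometry
    if frequency is not None and not getattr(frequency, "empty", False):
        tables["frequency"] = pd.DataFrame({
            "feature": frequency.counts.index,
            "count": frequency.counts.to_numpy(),
            "percent": frequency.percentages.to_numpy(),
            "top10": [f in frequency.top10 for f in frequency.counts.index],
        })
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return tables
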