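"""Statistical layer: t-test, one-way ANOVA + Tukey HSD, Cohen's d, boxplot
summaries.

Cohen's d follows the convention of the source workflow: the standardizer
``s`` is by default the *maximal* standard deviation across the groups of
the analyzed dataset, so d = |x̄₁ − x̄₂| / max(SD).  With that convention
d ≤ 0.5 is read as a low effect size and d ≥ 1 as a large one.  A ``/ 2s``
variant is selectable because the printed formula is typographically
ambiguous, as is the conventional pooled-SD standardizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "EffectSize", "BoxSummary", "ttest2",
           "anova_tukey", "cohens_d", "box_summary"]


@dataclass
class TestResult:
    statistic: float
    dof: tuple[int, ...]
    p_value: float
    method: str
    groups: tuple[str, ...] = ()
    pairwise: pd.DataFrame | None = None


@dataclass
class EffectSize:
    mean_1: float
    mean_2: float
    s: float
    d: float
    convention: str = "max_sd"


@dataclass
class BoxSummary:
    median: float
    q25: float
    q75: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray
    notch_lo: float
    notch_hi: float


def _as_arrays(*samples: Sequence[float]) -> list[np.ndarray]:
    return [np.asarray(s, float) for s in samples]


def ttest2(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Pooled-variance two-sample Student's t-test, two-sided.

    Two zero-variance samples with equal means give p = 1 by convention.
    """
    a, b = _as_arrays(sample_a, sample_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    dof = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, (dof,), 1.0, "ttest")
        return TestResult(np.inf, (dof,), 0.0, "ttest")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(t), (dof,), float(p), "ttest")


def anova_tukey(groups: dict[str, Sequence[float]] | Sequence[Sequence[float]]
                ) -> TestResult:
    """One-way ANOVA followed by post hoc Tukey HSD.

    Returns the F statistic with (k − 1, N − k) degrees of freedom and a
    pairwise table of Tukey-adjusted p-values (studentized range).
    """
    if isinstance(groups, dict):
        names = list(groups)
        data = _as_arrays(*groups.values())
    else:
        data = _as_arrays(*groups)
        names = [f"group{i}" for i in range(len(data))]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in data):
        raise ValueError("every group needs at least 2 observations")
    k = len(data)
    n_total = sum(len(g) for g in data)
    if all(g.var(ddof=1) == 0 for g in data) and \
            len({g.mean() for g in data}) == 1:
        f_stat, p = 0.0, 1.0
        pairwise = pd.DataFrame(
            [{"group_1": names[i], "group_2": names[j], "p_adj": 1.0,
              "mean_diff": 0.0}
             for i in range(k) for j in range(i + 1, k)])
        return TestResult(f_stat, (k - 1, n_total - k), p, "anova",
                          tuple(names), pairwise)
    f_stat, p = sps.f_oneway(*data)
    tk = sps.tukey_hsd(*data)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append({
                "group_1": names[i],
                "group_2": names[j],
                "mean_diff": float(data[i].mean() - data[j].mean()),
                "p_adj": float(tk.pvalue[i, j]),
            })
    return TestResult(float(f_stat), (k - 1, n_total - k), float(p),
                      "anova", tuple(names), pd.DataFrame(rows))


def cohens_d(sample_a: Sequence[float], sample_b: Sequence[float],
             s_convention: str = "max_sd",
             dataset: Sequence[Sequence[float]] | None = None) -> EffectSize:
    """Cohen's d with a selectable standardizer.

    ``max_sd`` (default): s = maximal SD over the groups of the analyzed
    dataset — pass additional groups via ``dataset`` when the dataset
    comprises multiple sample pairs; otherwise s = max(SD_a, SD_b).
    ``max_sd_half``: d = |x̄₁ − x̄₂| / (2 s).  ``pooled``: the conventional
    pooled-SD standardizer.
    """
    a, b = _as_arrays(sample_a, sample_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    groups = [a, b] + ([np.asarray(g, float) for g in dataset]
                       if dataset is not None else [])
    if s_convention in ("max_sd", "max_sd_half"):
        s = float(max(g.std(ddof=1) for g in groups))
    elif s_convention == "pooled":
        s = float(np.sqrt(((len(a) - 1) * a.var(ddof=1)
                           + (len(b) - 1) * b.var(ddof=1))
                          / (len(a) + len(b) - 2)))
    else:
        raise ValueError(f"unknown s_convention {s_convention!r}")
    if s == 0:
        if a.mean() == b.mean():
            return EffectSize(float(a.mean()), float(b.mean()), 0.0, 0.0,
                              s_convention)
        raise ValueError("zero standard deviation with unequal means")
    denom = 2 * s if s_convention == "max_sd_half" else s
    d = abs(a.mean() - b.mean()) / denom
    return EffectSize(float(a.mean()), float(b.mean()), s, float(d),
                      s_convention)


def box_summary(sample: Sequence[float],
                whisker_rule: str = "iqr") -> BoxSummary:
    """Boxplot summary: quartiles, whiskers, outliers, notch.

    Quartiles use linear interpolation (type 7).  With the default
    ``"iqr"`` rule, points beyond 1.5 IQR from the box are outliers and
    whiskers reach the most extreme remaining points; ``"extreme"`` extends
    whiskers to the literal extremes (no outliers).  The notch is
    median ± 1.57 · IQR / √n (a comparison interval).
    """
    x = np.asarray(sample, float)
    if len(x) < 1:
        raise ValueError("empty sample")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    iqr = q75 - q25
    if whisker_rule == "extreme":
        outliers = np.array([])
        lo, hi = float(x.min()), float(x.max())
    elif whisker_rule == "iqr":
        lo_fence = q25 - 1.5 * iqr
        hi_fence = q75 + 1.5 * iqr
        inlier = (x >= lo_fence) & (x <= hi_fence)
        outliers = np.sort(x[~inlier])
        lo = float(x[inlier].min())
        hi = float(x[inlier].max())
    else:
        raise ValueError(f"unknown whisker_rule {whisker_rule!r}")
    half_notch = 1.57 * iqr / np.sqrt(len(x))
    return BoxSummary(
        median=float(med), q25=float(q25), q75=float(q75),
        whisker_lo=lo, whisker_hi=hi, outliers=outliers,
        notch_lo=float(med - half_notch), notch_hi=float(med + half_notch),
    )
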