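"""Regional statistics, group summaries and method-agreement analyses.

Operates on parameter maps (NIfTI images or arrays on a shared grid) and
per-subject tables: regional medians with interquartile ranges, group
mean/SD rows recomputed from subject rows, Bland-Altman agreement, one-way
ANOVA with Tukey-Kramer post-hoc comparisons, paired t-tests, and GM/WM
ratio tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementResult",
    "regional_medians",
    "group_summary",
    "study_table",
    "bland_altman",
    "method_comparison_tests",
    "gm_wm_ratios",
]

log = logging.getLogger(__name__)


def _as_array(img) -> np.ndarray:
    if hasattr(img, "get_fdata"):
        return np.asarray(img.get_fdata())
    return np.asarray(img, dtype=float)


def _check_aligned(*arrays) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"images must share a grid, got shapes {sorted(shapes)}")


def regional_medians(parameter_map, roi) -> tuple[float, float]:
    """Median and interquartile range of a map over an ROI mask.

    Non-finite voxels are excluded (their count is logged); the IQR is
    Q3 - Q1 with linear interpolation.  An empty mask raises.
    """
    data = _as_array(parameter_map)
    mask = _as_array(roi) > 0
    _check_aligned(data, mask)
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = data[mask]
    finite = np.isfinite(vals)
    dropped = int((~finite).sum())
    if dropped:
        log.info("regional_medians: excluded %d non-finite voxels", dropped)
    vals = vals[finite]
    if vals.size == 0:
        raise ValueError("ROI contains no finite voxels")
    q1, q2, q3 = np.percentile(vals, [25, 50, 75])
    return float(q2), float(q3 - q1)


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise group mean and standard deviation (n-1 denominator).

    Returns a two-row DataFrame indexed ``mean``/``sd`` over the numeric
    columns of ``table``; requires at least two subjects.
    """
    numeric = table.select_dtypes("number")
    if "subject" in numeric.columns:
        numeric = numeric.drop(columns="subject")
    if len(numeric) < 2:
        raise ValueError("group summary requires >= 2 subjects")
    return pd.DataFrame(
        {"mean": numeric.mean(), "sd": numeric.std(ddof=1)}
    ).T


def study_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-subject table with group mean/SD rows appended.

    The group rows are always recomputed from the subject rows.
    """
    summary = group_summary(rows)
    summary.insert(0, "subject", summary.index)
    return pd.concat([rows, summary], ignore_index=True)


@dataclass
class AgreementResult:
    """Bland-Altman agreement between two paired measurement sets."""

    bias: float
    loa_lower: float
    loa_upper: float
    differences: np.ndarray
    means: np.ndarray


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman analysis of paired measurements ``a`` and ``b``.

    Bias is the mean of the differences a - b; the limits of agreement are
    bias +/- 1.96 SD of the differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return AgreementResult(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        differences=diff,
        means=(a + b) / 2.0,
    )


def method_comparison_tests(
    oef_by_method: dict[str, np.ndarray],
    dbv_pair: tuple[np.ndarray, np.ndarray] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Group comparisons of OEF across methods plus a paired DBV test.

    One-way ANOVA across the OEF groups, Tukey-Kramer honest-significant-
    difference p-values for every method pair (studentized-range
    distribution), and, if ``dbv_pair`` is given, a paired t-test between
    the two DBV estimates.  Degenerate (zero-variance) cases are flagged
    rather than raising.
    """
    names = list(oef_by_method)
    groups = [np.asarray(oef_by_method[k], dtype=float) for k in names]
    if len(groups) < 2:
        raise ValueError("need at least two methods to compare")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    grand = np.concatenate(groups)
    df_within = grand.size - k
    means = np.array([g.mean() for g in groups])
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    report: dict = {"alpha": alpha}

    if ss_within == 0:
        report["anova"] = {"F": 0.0 if np.allclose(means, means[0]) else np.inf,
                          "p": np.nan, "degenerate": True}
        report["tukey"] = {}
        return report
    f_stat, p_val = stats.f_oneway(*groups)
    report["anova"] = {"F": float(f_stat), "p": float(p_val), "degenerate": False}

    msw = ss_within / df_within
    tukey = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            p = float(stats.studentized_range.sf(q, k, df_within))
            tukey[(names[i], names[j])] = {
                "q": float(q), "p": p, "significant": p < alpha,
            }
    report["tukey"] = tukey

    if dbv_pair is not None:
        x = np.asarray(dbv_pair[0], dtype=float)
        y = np.asarray(dbv_pair[1], dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired DBV inputs must have equal length")
        if np.std(x - y, ddof=1) == 0:
            equal = np.allclose(x, y)
            report["paired_t"] = {
                "t": 0.0 if equal else np.inf, "p": 1.0 if equal else 0.0,
                "degenerate": True,
            }
        else:
            t_stat, p = stats.ttest_rel(x, y)
            report["paired_t"] = {"t": float(t_stat), "p": float(p),
                                  "degenerate": False}
    return report


def gm_wm_ratios(maps: dict[str, object], gm_mask, wm_mask) -> pd.Series:
    """GM-median to WM-median ratio per parameter map.

    Raises when a WM median is zero (the ratio would be undefined).
    """
    gm = _as_array(gm_mask) > 0
    wm = _as_array(wm_mask) > 0
    if not gm.any() or not wm.any():
        raise ValueError("GM and WM masks must be non-empty")
    out = {}
    for name, m in maps.items():
        gm_med, _ = regional_medians(m, gm)
        wm_med, _ = regional_medians(m, wm)
        if wm_med == 0:
            raise ZeroDivisionError(f"WM median of '{name}' is zero")
        out[name] = gm_med / wm_med
    return pd.Series(out)
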