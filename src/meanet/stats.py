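"""Two-condition, per-DIV group statistics.

The per-culture metric vectors are often non-normal (screened with the
Jarque-Bera test), so group differences are tested with the Mann-Whitney
rank-sum test. Raw p-values are aggregated per DIV into one family and
corrected for the false discovery rate with the dependency-robust
Benjamini-Yekutieli step-up procedure (Benjamini-Hochberg available as an
option); the adjusted p-value is additionally capped from below by the raw
p-value so the correction can never increase significance. The summary is
a metric x DIV "fingerprint" of directions and significance stars.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .types import CultureMetrics, GroupComparison

__all__ = [
    "normality_screen",
    "mann_whitney",
    "fdr_adjust",
    "compare_study",
    "fingerprint_table",
]


def normality_screen(values) -> tuple[float, float]:
    """Jarque-Bera normality test: JB = n/6 (S^2 + K^2/4) against a
    chi-squared(2) reference (anticonservative for small n).

    Returns ``(statistic, p)``; ``(nan, nan)`` for n < 4; raises on a
    zero-variance sample.
    """
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size < 4:
        return np.nan, np.nan
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    res = sstats.jarque_bera(x)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test with midrank ties.

    Exact p by enumeration when the pooled sample is small (n_a + n_b <= 12)
    and tie-free; otherwise the normal approximation with tie and continuity
    corrections. Returns ``(U_a, p)``; identical groups give p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return a.size * b.size / 2.0, 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not ties) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative=alternative, method=method,
                              use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(pvals, method: str = "by") -> np.ndarray:
    """FDR step-up adjustment of one p-value family.

    ``method="by"`` (default) is the Benjamini-Yekutieli procedure, valid
    under arbitrary dependence between the tests; ``"bh"`` is classical
    Benjamini-Hochberg. Adjusted values are clipped to [raw, 1] so the
    correction never increases significance.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"by": "fdr_by", "bh": "fdr_bh"}[method]
    adjusted = multipletests(p, method=sm_method)[1]
    return np.minimum(np.maximum(adjusted, p), 1.0)


def metrics_to_table(metrics: list[CultureMetrics]) -> pd.DataFrame:
    """Long-form table: one row per culture per DIV, metric columns."""
    rows = []
    for m in metrics:
        row = {"culture_id": m.culture_id, "condition": m.condition,
               "div": m.div, "n_active_electrodes": m.n_active_electrodes}
        row.update({f: getattr(m, f) for f in CultureMetrics.METRIC_FIELDS})
        rows.append(row)
    return pd.DataFrame(rows)


def compare_study(table: pd.DataFrame, metrics: list[str] | None = None,
                  fdr_method: str = "by", alpha: float = 0.05,
                  min_fraction_present: float = 0.5,
                  ) -> list[GroupComparison]:
    """Mann-Whitney comparisons of every metric at every DIV with per-DIV
    FDR families.

    ``table`` is the long-form metrics table (one row per culture per DIV
    with a ``condition`` column in {control, deficient}). A metric missing
    for more than half the cultures of either group at a DIV is excluded
    from that DIV's family. Significance is adjusted p < ``alpha``.
    """
    if metrics is None:
        metrics = [m for m in CultureMetrics.METRIC_FIELDS
                   if m in table.columns]
    results: list[GroupComparison] = []
    for div, sub in table.groupby("div"):
        ctrl = sub[sub["condition"] == "control"]
        defi = sub[sub["condition"] == "deficient"]
        if len(ctrl) < 2 or len(defi) < 2:
            raise ValueError(f"DIV {div}: need both conditions with >= 2 "
                             "cultures")
        family: list[GroupComparison] = []
        for metric in metrics:
            a = ctrl[metric].to_numpy(dtype=float)
            b = defi[metric].to_numpy(dtype=float)
            ok_a, ok_b = np.isfinite(a), np.isfinite(b)
            if (ok_a.mean() < min_fraction_present
                    or ok_b.mean() < min_fraction_present
                    or ok_a.sum() < 2 or ok_b.sum() < 2):
                continue
            a, b = a[ok_a], b[ok_b]
            u, p = mann_whitney(a, b)
            try:
                _, jb_a = normality_screen(a)
            except ValueError:
                jb_a = np.nan
            try:
                _, jb_b = normality_screen(b)
            except ValueError:
                jb_b = np.nan
            med_a, med_b = float(np.median(a)), float(np.median(b))
            if med_b > med_a:
                direction = "up"
            elif med_b < med_a:
                direction = "down"
            else:
                direction = "none"
            family.append(GroupComparison(
                metric=metric, div=int(div), n_control=a.size,
                n_deficient=b.size, median_control=med_a,
                median_deficient=med_b, mean_control=float(np.mean(a)),
                mean_deficient=float(np.mean(b)), u_statistic=u, p_raw=p,
                p_adjusted=np.nan, direction=direction, significant=False,
                jb_p_control=jb_a, jb_p_deficient=jb_b))
        if family:
            adj = fdr_adjust([c.p_raw for c in family], method=fdr_method)
            for c, pa in zip(family, adj):
                c.p_adjusted = float(pa)
                c.significant = bool(pa < alpha)
        results.extend(family)
    return results


def comparisons_to_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([{
        "metric": c.metric, "div": c.div,
        "n_control": c.n_control, "n_deficient": c.n_deficient,
        "median_control": c.median_control,
        "median_deficient": c.median_deficient,
        "mean_control": c.mean_control, "mean_deficient": c.mean_deficient,
        "U": c.u_statistic, "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
        "direction": c.direction, "significant": c.significant,
        "stars": c.stars, "jb_p_control": c.jb_p_control,
        "jb_p_deficient": c.jb_p_deficient,
    } for c in comparisons])


def fingerprint_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Metric x DIV summary of the deficient-vs-control contrast:
    'ns', or the direction arrow with significance stars."""
    cells: dict[str, dict[int, str]] = {}
    for c in comparisons:
        arrow = {"up": "+", "down": "-", "none": "="}[c.direction]
        cells.setdefault(c.metric, {})[c.div] = (
            f"{arrow}{c.stars}" if c.significant else "ns")
    df = pd.DataFrame(cells).T
    return df.reindex(sorted(df.columns), axis=1)
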