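"""Normality-gated two-group comparisons and Table-style reports.

The testing convention: each metric is checked for normality in both
groups with the Shapiro-Wilk test (alpha 0.05).  If both samples are
consistent with normality the groups are compared with a two-sided
unpaired t test (equal-variance form by default) and summarised as
mean +- SEM; otherwise a two-sided Mann-Whitney U test is used (exact
null distribution for combined n <= 20 without ties, normal
approximation with tie correction otherwise) and groups are summarised
as median (Q1-Q3).  The gate is applied per metric, per comparison.  No
multiple-testing correction is applied; this is recorded in the report
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

BOTH_NORMAL = "both_normal"
NOT_BOTH_NORMAL = "not_both_normal"


class ConstantSampleError(ValueError):
    """Shapiro-Wilk (and hence the gate) is undefined on a constant sample."""


@dataclass
class GroupComparison:
    metric: str
    summary_a: str
    summary_b: str
    test: str  # "unpaired t" or "Mann-Whitney U"
    statistic: float
    p_value: float
    significant: bool
    n_a: int
    n_b: int
    gate: str

    def as_row(self) -> dict:
        return {
            "metric": self.metric,
            "group_a": self.summary_a,
            "group_b": self.summary_b,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def _clean(sample) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    arr = arr[np.isfinite(arr)]
    return arr


def normality_gate(sample_a, sample_b, alpha: float = ALPHA) -> str:
    """``both_normal`` iff Shapiro-Wilk p > alpha in both samples."""
    out = []
    for name, sample in (("a", sample_a), ("b", sample_b)):
        arr = _clean(sample)
        if len(arr) < 3:
            raise ValueError(
                f"sample {name}: need n >= 3 for the Shapiro-Wilk test, got {len(arr)}"
            )
        if np.ptp(arr) == 0:
            raise ConstantSampleError(
                f"sample {name} is constant; normality test undefined"
            )
        out.append(sps.shapiro(arr).pvalue > alpha)
    return BOTH_NORMAL if all(out) else NOT_BOTH_NORMAL


def summarize(sample, normal: bool) -> str:
    arr = _clean(sample)
    if normal:
        sem = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
        return f"{arr.mean():.3g} ± {sem:.3g}"
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return f"{med:.3g} ({q1:.3g}–{q3:.3g})"


def _mann_whitney(a: np.ndarray, b: np.ndarray):
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "asymptotic"
    return sps.mannwhitneyu(a, b, alternative="two-sided", method=method)


def compare_groups(
    sample_a,
    sample_b,
    gate: str | None = None,
    metric: str = "",
    equal_var: bool = True,
    alpha: float = ALPHA,
) -> GroupComparison:
    """Two-sided two-group comparison following the normality gate.

    ``gate`` may be precomputed (a :func:`normality_gate` result) or
    None, in which case it is computed here.  Identical samples give
    p = 1 under either test.
    """
    a, b = _clean(sample_a), _clean(sample_b)
    if gate is None:
        gate = normality_gate(a, b, alpha=alpha)
    if gate not in (BOTH_NORMAL, NOT_BOTH_NORMAL):
        raise ValueError(f"invalid gate result {gate!r}")
    if gate == BOTH_NORMAL:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test = "unpaired t" if equal_var else "Welch t"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = _mann_whitney(a, b)
        test = "Mann-Whitney U"
        stat, p = float(res.statistic), float(res.pvalue)
    p = min(p, 1.0)
    normal = gate == BOTH_NORMAL
    return GroupComparison(
        metric=metric,
        summary_a=summarize(a, normal),
        summary_b=summarize(b, normal),
        test=test,
        statistic=stat,
        p_value=p,
        significant=p < alpha,
        n_a=len(a),
        n_b=len(b),
        gate=gate,
    )


def report_table(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    metrics: list[str] | None = None,
    provenance_a: dict | None = None,
    provenance_b: dict | None = None,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Compare two per-cell metric tables row by row.

    Both cohorts must have been produced under identical criteria
    configuration (checked via the provenance dicts); otherwise the
    comparison is refused.  Returns (table, metadata).  Metrics whose
    gate is undefined (constant samples, too few values) are reported
    with the failure reason instead of a test.
    """
    if (provenance_a or provenance_b) and provenance_a != provenance_b:
        raise ValueError(
            "cohorts were analysed with different criteria configurations; "
            "refusing to compare"
        )
    if metrics is None:
        metrics = [
            c
            for c in cohort_a.columns
            if c in cohort_b.columns and pd.api.types.is_numeric_dtype(cohort_a[c])
        ]
    rows = []
    for m in metrics:
        a = cohort_a[m].dropna().to_numpy(dtype=float)
        b = cohort_b[m].dropna().to_numpy(dtype=float)
        try:
            cmp = compare_groups(a, b, metric=m, equal_var=equal_var)
            rows.append(cmp.as_row())
        except (ValueError, ConstantSampleError) as exc:
            rows.append(
                {
                    "metric": m,
                    "group_a": summarize(a, False) if len(a) else "",
                    "group_b": summarize(b, False) if len(b) else "",
                    "test": f"not tested ({exc})",
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "significant": False,
                    "n_a": len(a),
                    "n_b": len(b),
                }
            )
    meta = {
        "alpha": ALPHA,
        "two_tailed": True,
        "t_test_variant": "equal variance" if equal_var else "Welch",
        "multiple_testing_correction": "none",
        "criteria": provenance_a,
    }
    return pd.DataFrame(rows), meta
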