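"""Univariate biomarker screening.

Each glycated-peptide feature is screened with the two-sided Mann-Whitney U
test (case vs control abundances), the family-wise error rate over the
feature panel is controlled with the Holm-Bonferroni step-down procedure at
alpha = 0.01, and each feature's standalone diagnostic quality is summarized
as accuracy / specificity / sensitivity at an accuracy-maximizing abundance
threshold (cases are the positive class).

The in-sample threshold scan is an optimistic estimate of single-marker
performance; it is reported because it reproduces the arithmetic relation
Ac = (Sn*n_cases + Sp*n_controls) / n that ties the three percentages to the
cohort sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quantify import FeatureTable

__all__ = [
    "TestResult",
    "FeatureMetrics",
    "mann_whitney_u",
    "holm_bonferroni",
    "per_feature_metrics",
    "screen_features",
]

DEFAULT_ALPHA = 0.01
_EXACT_MAX_N = 8  # exact p below this per-group size (when tie-free)


@dataclass
class TestResult:
    """Mann-Whitney outcome for one feature (min-of-groups U convention)."""

    feature_id: str
    u: float
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False


@dataclass
class FeatureMetrics:
    """Single-feature diagnostic performance at its best threshold."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)


def mann_whitney_u(x, y, feature_id: str = "") -> TestResult:
    """Two-sided Mann-Whitney U test between case and control values.

    U is reported in the min-of-the-two-groups convention (the statistic
    classically tabulated, bounded by n1*n2/2 under perfect symmetry and 0
    under complete separation).  The p-value is exact (permutation
    distribution) for tie-free samples smaller than 8 per group, otherwise
    the tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return TestResult(feature_id, x.size * y.size / 2.0, 1.0)

    has_ties = np.unique(pooled).size < pooled.size
    small = min(x.size, y.size) < _EXACT_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return TestResult(feature_id, u, float(min(res.pvalue, 1.0)))


def holm_bonferroni(
    p_values, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p-values and the rejection set at ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


def per_feature_metrics(x, y) -> FeatureMetrics:
    """Best in-sample univariate threshold and its confusion metrics.

    Candidate thresholds are the midpoints between consecutive distinct
    pooled values (plus open ends); a sample is called positive (case) when
    its value exceeds the threshold, matching the upregulated direction of
    glycation in disease.  Ties in accuracy are broken toward higher
    specificity, then toward the lower threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    values = np.unique(np.concatenate([x, y]))
    mids = (values[:-1] + values[1:]) / 2.0
    candidates = np.concatenate([[values[0] - 1.0], mids, [values[-1] + 1.0]])

    best: FeatureMetrics | None = None
    for thr in candidates:
        tp = int((x > thr).sum())
        fn = x.size - tp
        fp = int((y > thr).sum())
        tn = y.size - fp
        cand = FeatureMetrics(float(thr), tp, fp, tn, fn)
        if (
            best is None
            or cand.accuracy > best.accuracy + 1e-12
            or (
                abs(cand.accuracy - best.accuracy) <= 1e-12
                and (
                    cand.specificity > best.specificity + 1e-12
                    or (
                        abs(cand.specificity - best.specificity) <= 1e-12
                        and cand.threshold < best.threshold
                    )
                )
            )
        ):
            best = cand
    assert best is not None
    return best


def screen_features(
    table: FeatureTable, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Univariate screen of every feature in a cohort table.

    Returns a DataFrame (indexed by feature) with the U statistic, raw and
    Holm-adjusted p-values, the significance call at ``alpha``, and the
    in-sample Ac/Sp/Sn percentages.
    """
    rows = []
    for feat in table.abundances.columns:
        x, y = table.split(feat)
        res = mann_whitney_u(x, y, feat)
        metrics = per_feature_metrics(x, y)
        rows.append(
            {
                "feature": feat,
                "U": res.u,
                "p": res.p_raw,
                "Ac": metrics.accuracy,
                "Sp": metrics.specificity,
                "Sn": metrics.sensitivity,
            }
        )
    df = pd.DataFrame(rows).set_index("feature")
    p_adj, reject = holm_bonferroni(df["p"].to_numpy(), alpha=alpha)
    df.insert(2, "p_adj", p_adj)
    df.insert(3, "significant", reject)
    return df
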