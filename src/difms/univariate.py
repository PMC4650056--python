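"""Per-feature two-sample tests with Benjamini–Hochberg FDR correction.

Each feature (m/z signal) is tested between two sample groups with a
two-sample t-test (Welch by default; pooled-variance Student's t via
``equal_var=True``). p-values are converted to q-values by the BH step-up,
and significance is declared strictly below the q threshold (q < 0.05).
Percent change is reported group2 relative to group1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import FeatureMatrix


def ttest_features(X: np.ndarray, group1: np.ndarray, group2: np.ndarray,
                   equal_var: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided two-sample t per feature (columns of X).

    ``group1``/``group2`` are row-index arrays. Features with zero variance
    in both groups get t = 0, p = 1 when the means are equal.
    """
    a, b = X[group1], X[group2]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both groups need >= 2 samples")
    if np.isnan(X).any():
        raise ValueError("t-tests require a complete matrix; impute first")
    with np.errstate(all="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(t)
    equal_means = np.isclose(a.mean(axis=0), b.mean(axis=0))
    t[degenerate] = 0.0
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    return t, p


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} (m * p_(j) / j) over sorted p, mapped back to the
    input order and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class UnivariateResult:
    table: pd.DataFrame   # feature_mz, t, p, q, direction, pct_change

    def significant(self, q_threshold: float = 0.05) -> np.ndarray:
        """Indices of features with q strictly below the threshold."""
        return np.flatnonzero(self.table["q"].to_numpy() < q_threshold)


def compare_groups(fm: FeatureMatrix, labels: np.ndarray | list,
                   group1, group2, equal_var: bool = False) -> UnivariateResult:
    """Test every feature between two labelled groups of a feature matrix."""
    labels = np.asarray(labels)
    idx1 = np.flatnonzero(labels == group1)
    idx2 = np.flatnonzero(labels == group2)
    t, p = ttest_features(fm.values, idx1, idx2, equal_var=equal_var)
    q = bh_fdr(p)
    mean1 = fm.values[idx1].mean(axis=0)
    mean2 = fm.values[idx2].mean(axis=0)
    diff = mean2 - mean1
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(mean1 != 0, 100.0 * diff / np.abs(mean1), np.nan)
    table = pd.DataFrame({
        "feature_mz": fm.feature_mzs,
        "t": t,
        "p": p,
        "q": q,
        "direction": np.sign(diff).astype(int),
        "pct_change": pct,
    })
    return UnivariateResult(table)


def significant_features(result: UnivariateResult | np.ndarray,
                         q_threshold: float = 0.05) -> np.ndarray:
    """Feature indices with q < threshold (strict, per the q < 0.05 rule)."""
    if isinstance(result, UnivariateResult):
        return result.significant(q_threshold)
    q = np.asarray(result, dtype=float)
    return np.flatnonzero(q < q_threshold)
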