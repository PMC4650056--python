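"""Feature-matrix preprocessing: PQN, KNN imputation, glog transform.

The stage order follows the analysis workflow: probabilistic quotient
normalization on raw intensities (missing cells ignored), then K-nearest-
neighbour imputation so the matrix is complete, then the generalized
logarithm g(x) = log((x + sqrt(x^2 + λ)) / 2) to stabilise technical
variance before multivariate analysis. λ can be fixed or optimized on QC
(or other purely technical) replicate groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .spectra_io import FeatureMatrix


@dataclass
class PreprocessConfig:
    knn_k: int = 5
    glog_lambda: float | str = "optimize"   # λ >= 0, or "optimize"
    lambda_bounds: tuple[float, float] = (1e-8, 1e12)

    def __post_init__(self):
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        lo, hi = self.lambda_bounds
        if not (0 < lo < hi):
            raise ValueError("lambda_bounds must be positive with low < high")
        if isinstance(self.glog_lambda, str) and self.glog_lambda != "optimize":
            raise ValueError("glog_lambda must be a number or 'optimize'")


@dataclass
class NormalizationResult:
    matrix: FeatureMatrix
    dilution_factors: np.ndarray
    lambda_used: float | None = None
    provenance: dict = field(default_factory=dict)


def pqn_normalize(fm: FeatureMatrix,
                  reference_ids: list[str] | None = None
                  ) -> tuple[FeatureMatrix, np.ndarray]:
    """Probabilistic quotient normalization.

    The reference spectrum is the feature-wise median over ``reference_ids``
    (by default all samples; callers typically exclude QCs). Each sample's
    dilution factor is the median of its feature-wise quotients against the
    reference, over cells observed in both; the sample is divided by it.
    """
    if fm.n_samples < 2:
        raise ValueError("PQN requires at least 2 samples")
    X = fm.values
    if reference_ids is None:
        ref_rows = X
    else:
        pos = {s: i for i, s in enumerate(fm.sample_ids)}
        ref_rows = X[[pos[s] for s in reference_ids]]
    with np.errstate(all="ignore"):
        reference = np.nanmedian(ref_rows, axis=0)
    factors = np.empty(fm.n_samples)
    for i, sid in enumerate(fm.sample_ids):
        mask = ~np.isnan(X[i]) & ~np.isnan(reference) & (reference > 0)
        if not mask.any():
            raise ValueError(f"sample {sid!r} shares no observed features "
                             "with the reference spectrum")
        factors[i] = np.median(X[i, mask] / reference[mask])
        if factors[i] <= 0:
            raise ValueError(f"sample {sid!r} has non-positive dilution factor")
    out = fm.copy()
    out.values = X / factors[:, None]
    return out, factors


def knn_impute(fm: FeatureMatrix, k: int = 5) -> FeatureMatrix:
    """Impute each missing cell from the k nearest samples.

    Nearness is plain Euclidean distance over the features observed in both
    samples. For a missing cell, the k nearest samples that observed that
    feature contribute their mean. Features with no observed value raise.
    """
    X = fm.values.copy()
    n = fm.n_samples
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n_samples-1={n - 1}")
    observed = ~np.isnan(X)
    if not observed.any(axis=0).all():
        j = int(np.flatnonzero(~observed.any(axis=0))[0])
        raise ValueError(f"feature {j} (m/z {fm.feature_mzs[j]:.5f}) has no "
                         "observed values; filter it before imputation")
    if observed.all():
        return fm.copy()
    # pairwise distances over mutually observed features
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            mutual = observed[a] & observed[b]
            if mutual.any():
                d = float(np.sqrt(np.sum((X[a, mutual] - X[b, mutual]) ** 2)))
            else:
                d = np.inf
            dist[a, b] = dist[b, a] = d
    out = X.copy()
    for a in range(n):
        missing_j = np.flatnonzero(~observed[a])
        if missing_j.size == 0:
            continue
        order = np.argsort(dist[a], kind="stable")
        order = order[order != a]
        for j in missing_j:
            donors = [b for b in order if observed[b, j]][:k]
            if not donors:
                raise ValueError(f"no donor samples observe feature {j}")
            out[a, j] = float(np.mean(X[donors, j]))
    result = fm.copy()
    result.values = out
    return result


def glog(x: np.ndarray | float, lam: float) -> np.ndarray | float:
    """Generalized logarithm g(x) = log((x + sqrt(x^2 + λ)) / 2)."""
    if lam < 0:
        raise ValueError("glog lambda must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.log((x + np.sqrt(x * x + lam)) / 2.0)


def glog_transform(fm: FeatureMatrix, lam: float) -> FeatureMatrix:
    """Apply the glog cell-wise; the matrix must be complete."""
    if np.isnan(fm.values).any():
        raise ValueError("glog_transform requires a complete matrix; impute first")
    out = fm.copy()
    out.values = glog(fm.values, lam)
    # negative transformed intensities are legitimate; bypass validation
    out.values = np.asarray(out.values)
    return out


def _stability_objective(X_groups: list[np.ndarray], lam: float) -> float:
    """Relative spread of per-feature SDs after glog across replicate groups.

    The statistic is the squared coefficient of variation of the
    per-feature technical standard deviations: zero when every feature has
    the same spread after the transform. Normalizing by the mean SD makes
    the objective invariant to an overall rescaling of the transformed
    data, so it cannot be gamed by a λ large enough to crush all
    variances at once.
    """
    sds = []
    for grp in X_groups:
        g = glog(grp, lam)
        sds.append(np.std(g, axis=0, ddof=1))
    sds = np.concatenate(sds)
    mean = float(np.mean(sds))
    if mean <= 0:
        return 0.0
    return float(np.var(sds) / mean ** 2)


def optimize_lambda(fm: FeatureMatrix,
                    replicate_groups: list[list[str]],
                    bounds: tuple[float, float] = (1e-8, 1e12)) -> float:
    """Choose λ minimizing mean–variance dependence across technical replicates.

    ``replicate_groups`` lists sample-id groups whose members differ only
    technically (QC re-injections, or pooled within-treatment replicates).
    The search is a bounded scalar minimization over log10 λ to a relative
    tolerance of 1e-6.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must be positive with low < high")
    groups = [g for g in replicate_groups if len(g) >= 2]
    if not groups:
        raise ValueError("need at least one replicate group with >= 2 samples")
    if np.isnan(fm.values).any():
        raise ValueError("optimize_lambda requires a complete matrix")
    pos = {s: i for i, s in enumerate(fm.sample_ids)}
    X_groups = [fm.values[[pos[s] for s in g]] for g in groups]

    res = minimize_scalar(lambda u: _stability_objective(X_groups, 10.0 ** u),
                          bounds=(np.log10(lo), np.log10(hi)),
                          method="bounded", options={"xatol": 1e-7})
    return float(10.0 ** res.x)


def preprocess(fm: FeatureMatrix, cfg: PreprocessConfig | None = None,
               qc_ids: list[str] | None = None,
               replicate_groups: list[list[str]] | None = None,
               impute_before_normalize: bool = False) -> NormalizationResult:
    """Run PQN → KNN imputation → glog. Returns the transformed matrix.

    λ is optimized on QC samples when given, else on ``replicate_groups``;
    a numeric ``cfg.glog_lambda`` short-circuits the search.
    ``impute_before_normalize`` swaps the first two stages for sensitivity
    checks.
    """
    cfg = cfg or PreprocessConfig()
    biological = [s for s in fm.sample_ids if not (qc_ids and s in qc_ids)]
    if impute_before_normalize:
        fm = knn_impute(fm, cfg.knn_k)
        normalized, factors = pqn_normalize(fm, reference_ids=biological)
        imputed = normalized
    else:
        normalized, factors = pqn_normalize(fm, reference_ids=biological)
        imputed = knn_impute(normalized, cfg.knn_k)
    if cfg.glog_lambda == "optimize":
        groups = [list(qc_ids)] if qc_ids else (replicate_groups or [])
        lam = optimize_lambda(imputed, groups, cfg.lambda_bounds)
    else:
        lam = float(cfg.glog_lambda)
    transformed = glog_transform(imputed, lam)
    return NormalizationResult(matrix=transformed, dilution_factors=factors,
                               lambda_used=lam,
                               provenance={"imputed_matrix": imputed})
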