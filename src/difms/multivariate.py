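"""PCA and two-class PLS-DA with venetian-blinds CV and permutation testing.

PCA is a mean-centered SVD with per-component one-way ANOVA and Tukey HSD
tests of the scores across treatment groups. PLS-DA is a NIPALS PLS1
regression of mean-centered intensities on a −1/+1 class code; the model is
validated by venetian-blinds cross-validated classification error (sample i
goes to fold i mod n_folds, in fixed input order), its significance by a
label-permutation test on that error, and influential signals are ranked by
VIP (variable importance in projection) and refined by forward selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectra_io import FeatureMatrix

_EPS = 1e-12


def _as_array(m: FeatureMatrix | np.ndarray) -> np.ndarray:
    X = m.values if isinstance(m, FeatureMatrix) else np.asarray(m, dtype=float)
    if np.isnan(X).any():
        raise ValueError("multivariate analysis requires a complete matrix")
    return X


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray        # samples × components
    loadings: np.ndarray      # features × components
    pct_variance: np.ndarray  # % of total variance per component
    pc_tests: list[dict]      # per component: anova_p, tukey (or None)
    mean: np.ndarray


def run_pca(m: FeatureMatrix | np.ndarray,
            groups: np.ndarray | list | None = None,
            n_components: int | None = None) -> PCAResult:
    """Mean-centered SVD with per-component group testing.

    ``pct_variance`` is 100·σ_i²/Σσ² over all singular values. When
    ``groups`` has ≥2 levels, each retained component's scores are tested
    with one-way ANOVA and Tukey HSD pairwise comparisons.
    """
    X = _as_array(m)
    n, f = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    if groups is not None:
        groups = np.asarray(groups)
        if n <= len(np.unique(groups)):
            raise ValueError("fewer samples than groups allow: per-component "
                             "group tests need replication within groups")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s ** 2))
    k = min(n_components or s.size, s.size)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    pct = 100.0 * s[:k] ** 2 / total if total > 0 else np.zeros(k)
    pc_tests: list[dict] = []
    if groups is not None:
        levels = np.unique(groups)
        for j in range(k):
            if len(levels) < 2 or s[j] ** 2 / max(total, _EPS) < 1e-12:
                pc_tests.append({"anova_p": None, "tukey": None})
                continue
            by_group = [scores[groups == g, j] for g in levels]
            if any(len(v) < 2 for v in by_group):
                pc_tests.append({"anova_p": None, "tukey": None})
                continue
            anova = stats.f_oneway(*by_group)
            tukey = stats.tukey_hsd(*by_group)
            pairs = {}
            for a in range(len(levels)):
                for b in range(a + 1, len(levels)):
                    pairs[(str(levels[a]), str(levels[b]))] = float(
                        tukey.pvalue[a, b])
            pc_tests.append({"anova_p": float(anova.pvalue), "tukey": pairs})
    return PCAResult(scores, loadings, np.asarray(pct), pc_tests, mean)


# --------------------------------------------------------------------------
# PLS-DA
# --------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    n_lv: int
    classes: tuple            # (negative class, positive class)
    x_weights: np.ndarray     # features × n_lv, unit norm per column
    x_loadings: np.ndarray    # features × n_lv
    y_loadings: np.ndarray    # n_lv
    x_scores: np.ndarray      # training samples × n_lv
    coef: np.ndarray          # regression vector for centered X
    x_mean: np.ndarray
    y_mean: float
    class_score_means: tuple[float, float]
    cv_error: float | None = None
    perm_p: float | None = None
    important_signals: np.ndarray | None = None
    cv_scheme: dict = field(default_factory=dict)


def _encode_labels(labels) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"PLS-DA requires exactly 2 classes, got {classes.size}")
    y = np.where(labels == classes[1], 1.0, -1.0)
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    return y, (classes[0], classes[1])


def fit_plsda(m: FeatureMatrix | np.ndarray, labels, n_lv: int = 2) -> PLSDAModel:
    """NIPALS PLS1 of mean-centered X on the −1/+1 class code."""
    X = _as_array(m)
    y, classes = _encode_labels(labels)
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean
    n, f = Xr.shape
    W = np.zeros((f, n_lv))
    P = np.zeros((f, n_lv))
    Q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    used = 0
    for a in range(n_lv):
        w = Xr.T @ yr
        norm_w = np.linalg.norm(w)
        if norm_w < _EPS:
            break
        w /= norm_w
        t = Xr @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        p = Xr.T @ t / tt
        q = float(yr @ t) / tt
        W[:, a], P[:, a], Q[a], T[:, a] = w, p, q, t
        Xr = Xr - np.outer(t, p)
        yr = yr - q * t
        used = a + 1
    if used == 0:
        raise ValueError("no predictive latent variable could be extracted")
    W, P, Q, T = W[:, :used], P[:, :used], Q[:used], T[:, :used]
    coef = W @ np.linalg.solve(P.T @ W, Q)
    yhat_train = (X - x_mean) @ coef + y_mean
    neg_mean = float(yhat_train[y < 0].mean())
    pos_mean = float(yhat_train[y > 0].mean())
    return PLSDAModel(n_lv=used, classes=classes, x_weights=W, x_loadings=P,
                      y_loadings=Q, x_scores=T, coef=coef, x_mean=x_mean,
                      y_mean=y_mean, class_score_means=(neg_mean, pos_mean))


def predict_plsda(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Predicted class labels; ŷ >= 0 maps to the positive class.

    A prediction at exactly 0 goes to the class whose training score mean
    is nearer (which for a centered two-class model is the positive class
    only when its scores sit nearer zero).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    yhat = (X - model.x_mean) @ model.coef + model.y_mean
    out = np.where(yhat >= 0, model.classes[1], model.classes[0])
    on_boundary = yhat == 0
    if np.any(on_boundary):
        neg_mean, pos_mean = model.class_score_means
        nearer = model.classes[1] if abs(pos_mean) <= abs(neg_mean) else model.classes[0]
        out[on_boundary] = nearer
    return out


def venetian_blinds(n: int, n_folds: int) -> list[np.ndarray]:
    """Deterministic fold assignment: sample i → fold i mod n_folds."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    return [np.arange(n)[np.arange(n) % n_folds == f] for f in range(n_folds)]


def cv_error(m: FeatureMatrix | np.ndarray, labels, n_lv: int,
             n_folds: int = 7) -> float:
    """Venetian-blinds cross-validated classification error, in percent."""
    X = _as_array(m)
    labels = np.asarray(labels)
    _encode_labels(labels)  # validates
    n = X.shape[0]
    folds = venetian_blinds(n, min(n_folds, n))
    wrong = 0
    for f, test_idx in enumerate(folds):
        if test_idx.size == 0:
            continue
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if np.unique(labels[train_idx]).size < 2:
            raise ValueError(f"training split for fold {f} contains one class only")
        model = fit_plsda(X[train_idx], labels[train_idx], n_lv)
        pred = predict_plsda(model, X[test_idx])
        wrong += int(np.sum(pred != labels[test_idx]))
    return 100.0 * wrong / n


def select_n_lv(m: FeatureMatrix | np.ndarray, labels, max_lv: int = 10,
                n_folds: int = 7) -> int:
    """Smallest latent-variable count achieving the minimal CV error."""
    X = _as_array(m)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if max_lv > rank:
        warnings.warn(f"max_lv={max_lv} exceeds the matrix rank {rank}; capped",
                      stacklevel=2)
        max_lv = max(rank, 1)
    errors = [cv_error(X, labels, a, n_folds) for a in range(1, max_lv + 1)]
    return int(np.argmin(errors)) + 1


def permutation_test(m: FeatureMatrix | np.ndarray, labels, n_lv: int,
                     n_folds: int = 7, n_perm: int = 999,
                     seed: int | np.random.Generator = 0) -> float:
    """p = (1 + #{permuted CV error <= observed}) / (n_perm + 1)."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X = _as_array(m)
    labels = np.asarray(labels)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    observed = cv_error(X, labels, n_lv, n_folds)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        try:
            err = cv_error(X, perm, n_lv, n_folds)
        except ValueError:
            # a permutation emptied one class from a training split;
            # count it as non-extreme
            continue
        if err <= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """VIP per feature; the mean squared VIP equals 1 by construction."""
    W, Q, T = model.x_weights, model.y_loadings, model.x_scores
    ssy = Q ** 2 * np.einsum("ij,ij->j", T, T)   # explained Y-variance per LV
    f = W.shape[0]
    denom = float(np.sum(ssy))
    if denom < _EPS:
        return np.zeros(f)
    return np.sqrt(f * (W ** 2 @ ssy) / denom)


def select_important_signals(m: FeatureMatrix | np.ndarray, labels,
                             n_lv: int, n_folds: int = 7,
                             vip_threshold: float = 1.0) -> np.ndarray:
    """Features with VIP > 1, forward-selected while CV error does not rise.

    Candidates are visited in decreasing VIP order; each is kept if adding
    it leaves the venetian-blinds CV error at or below the best seen so
    far. The scan stops at the first increase, and also once the error
    reaches zero — at the floor no further feature can demonstrate value,
    and tie-admission there would wave through arbitrary passengers.
    """
    X = _as_array(m)
    model = fit_plsda(X, labels, n_lv)
    vip = vip_scores(model)
    candidates = np.flatnonzero(vip > vip_threshold)
    candidates = candidates[np.argsort(-vip[candidates], kind="stable")]
    selected: list[int] = []
    best: float | None = None
    for j in candidates:
        trial = selected + [int(j)]
        err = cv_error(X[:, trial], labels, min(n_lv, len(trial)), n_folds)
        if best is None or err <= best:
            selected.append(int(j))
            best = err
            if best == 0.0:
                break
        else:
            break
    return np.array(sorted(selected), dtype=int)


def plsda_analysis(m: FeatureMatrix | np.ndarray, labels, max_lv: int = 10,
                   n_folds: int = 7, n_perm: int = 999,
                   seed: int | np.random.Generator = 0) -> PLSDAModel:
    """Full PLS-DA workflow: LV selection, CV error, permutation p, VIP set."""
    X = _as_array(m)
    n_lv = select_n_lv(X, labels, max_lv, n_folds)
    model = fit_plsda(X, labels, n_lv)
    model.cv_error = cv_error(X, labels, n_lv, n_folds)
    model.perm_p = permutation_test(X, labels, n_lv, n_folds, n_perm, seed)
    model.important_signals = select_important_signals(X, labels, n_lv, n_folds)
    model.cv_scheme = {"n_folds": n_folds}
    return model
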