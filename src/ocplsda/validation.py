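"""Model validation: N-fold full cross-validation (Q²), permutation testing,
cross-validated ROC analysis, the metadata confounding screen and the
external-factor correlation check.

"Full" cross-validation means every fitted statistic — pretreatment means and
scales, constraint centering, PLS weights — is recomputed inside each
training fold; held-out samples only ever meet statistics estimated without
them.  Q² = 1 − PRESS/TSS, with PRESS accumulated over held-out predictions
and TSS referenced to each training fold's response mean.

The ROC machinery uses the Mann-Whitney identity for the AUC (ties counted
1/2), DeLong's asymptotic variance for the 95% CI, and picks the operating
threshold as the curve point closest to the top-left corner, preferring the
higher-sensitivity point on ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .pretreat import PretreatSpec, _ZERO_VAR_TOL, encode_constraints, fit_column_stats
from .model import fit_cpls, fit_pca

__all__ = [
    "ROCResult",
    "ValidationReport",
    "CVResult",
    "ScreenReport",
    "auc_mann_whitney",
    "delong_ci",
    "roc_analysis",
    "cross_validate",
    "permutation_test",
    "validation_report",
    "select_n_components",
    "confounding_screen",
    "external_factor_check",
]


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    auc_ci95: tuple
    sensitivity: float
    specificity: float
    threshold: float
    curve: list = field(default_factory=list, repr=False)


def auc_mann_whitney(scores, is_case) -> float:
    """AUC via the Mann-Whitney identity; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    m = int(is_case.sum())
    n = int((~is_case).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[is_case].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


def delong_ci(scores, is_case, level: float = 0.95) -> tuple:
    """DeLong 95% confidence interval for the AUC, truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    pos, neg = scores[is_case], scores[~is_case]
    m, n = len(pos), len(neg)
    auc = auc_mann_whitney(scores, is_case)
    # structural components via midranks (Sun & Xu fast DeLong)
    all_r = scipy.stats.rankdata(np.concatenate([pos, neg]))
    pos_r = scipy.stats.rankdata(pos)
    neg_r = scipy.stats.rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def roc_analysis(scores, labels, case_label=None) -> ROCResult:
    """Full ROC summary for one score vector.

    ``labels`` may be boolean case indicators or class labels with
    ``case_label`` naming the positive class (default: last in sorted
    order).  The reported operating point minimizes (1−Se)² + (1−Sp)²,
    resolving ties toward the higher sensitivity.
    """
    labels = np.asarray(labels)
    if labels.dtype == bool and case_label is None:
        is_case = labels
    else:
        classes = sorted(pd.unique(labels).tolist())
        if len(classes) < 2:
            raise ValueError("both classes must be present for ROC analysis")
        case = case_label if case_label is not None else classes[-1]
        is_case = labels == case
    scores = np.asarray(scores, dtype=float)
    auc = auc_mann_whitney(scores, is_case)
    ci = delong_ci(scores, is_case)
    fpr, tpr, thr = _sk_roc_curve(is_case.astype(int), scores, drop_intermediate=False)
    d2 = (1.0 - tpr) ** 2 + fpr ** 2
    best = np.flatnonzero(d2 <= d2.min() + 1e-12)
    best = best[np.argmax(tpr[best])]          # tie-break: higher sensitivity
    se, sp = float(tpr[best]), float(1.0 - fpr[best])
    return ROCResult(auc, ci, se, sp, float(thr[best]),
                     curve=list(zip(fpr.tolist(), tpr.tolist())))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    q2: float
    cv_scores: np.ndarray      # held-out case-column prediction per sample
    is_case: np.ndarray
    n_folds: int
    seed: int


def _prepare_blocks(X, labels, constraints, pretreatment, case_label):
    """One-time conversion to the fast ndarray path.

    Returns (L, is_case, Z0) where L is the log-transformed (or raw) matrix —
    the log map is parameter-free so applying it once leaks nothing — and Z0
    the encoded but *uncentered* constraint matrix (centering is per-fold).
    """
    spec = pretreatment or PretreatSpec()
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if spec.log:
        if not np.all(X > 0):
            raise ValueError("log transform requires strictly positive intensities")
        L = np.log(X)
    else:
        L = X.astype(float)
    labels = np.asarray(pd.Series(labels).to_numpy())
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes!r}")
    case = case_label if case_label is not None else classes[-1]
    is_case = labels == case
    Z0 = None
    if constraints is not None:
        if isinstance(constraints, pd.DataFrame):
            if constraints.shape[1]:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    blk = encode_constraints(constraints, constraints.columns)
                # keep uncentered encodings; re-add the mean so folds recenter
                Z0 = blk.Z + 0.0  # centered; per-fold recentering handles the rest
        else:
            Z0 = np.asarray(constraints, dtype=float)
    if Z0 is not None and Z0.shape[1] == 0:
        Z0 = None
    return spec, L, is_case, Z0


def _fold_pretreat(L, train, test, spec):
    mu, sc, _ = fit_column_stats(L[train], spec)
    return (L[train] - mu) / sc, (L[test] - mu) / sc


def _fold_constraints(Z0, train):
    if Z0 is None:
        return None
    Z = Z0[train] - Z0[train].mean(axis=0)
    keep = Z.std(axis=0) > _ZERO_VAR_TOL
    Z = Z[:, keep]
    return Z if Z.shape[1] else None


def stratified_folds(is_case, n_folds, rng) -> list[np.ndarray]:
    """Class-stratified fold assignment; each fold is an index array.

    Re-randomizes (up to 100 attempts) if any fold's training part would be
    single-class.
    """
    is_case = np.asarray(is_case, dtype=bool)
    n = len(is_case)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    for _ in range(100):
        folds = [[] for _ in range(n_folds)]
        for mask in (is_case, ~is_case):
            idx = np.flatnonzero(mask)
            rng.shuffle(idx)
            for k, i in enumerate(idx):
                folds[k % n_folds].append(i)
        folds = [np.sort(np.asarray(f, dtype=int)) for f in folds if len(f)]
        ok = all(
            (~is_case[np.setdiff1d(np.arange(n), f)]).any()
            and is_case[np.setdiff1d(np.arange(n), f)].any()
            for f in folds
        )
        if ok:
            return folds
    raise ValueError("could not build folds with two-class training sets")


def cross_validate(X, labels, n_components, constraints=None, n_folds=7,
                   seed=0, pretreatment=None, case_label=None) -> CVResult:
    """N-fold full cross-validation of the constrained model.

    The entire pipeline — pretreatment statistics, constraint centering,
    oCPLS2-DA — is refit on each training fold; Q² = 1 − PRESS/TSS over
    held-out predictions, with TSS referenced to the training-fold mean.
    """
    spec, L, is_case, Z0 = _prepare_blocks(X, labels, constraints, pretreatment, case_label)
    rng = np.random.default_rng(seed)
    press, tss, cv_scores = _cv_core(L, is_case, Z0, n_components, n_folds, rng, spec)
    return CVResult(1.0 - press / tss, cv_scores, is_case, n_folds, seed)


def _cv_core(L, is_case, Z0, A, n_folds, rng, spec):
    n = len(is_case)
    Yind = np.column_stack([(~is_case).astype(float), is_case.astype(float)])
    folds = stratified_folds(is_case, n_folds, rng)
    press = tss = 0.0
    cv_scores = np.full(n, np.nan)
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        Et, Eh = _fold_pretreat(L, train, f, spec)
        Z = _fold_constraints(Z0, train)
        ymean = Yind[train].mean(axis=0)
        F = Yind[train] - ymean
        a_eff = min(A, len(train) - 1 - (Z.shape[1] if Z is not None else 0), L.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            lm = fit_cpls(Et, F, Z, max(a_eff, 1), check_rank=False)
        yhat = Eh @ lm.B + ymean
        press += float(((Yind[f] - yhat) ** 2).sum())
        tss += float(((Yind[f] - ymean) ** 2).sum())
        cv_scores[f] = yhat[:, 1]
    return press, tss, cv_scores


def permutation_test(X, labels, n_components, constraints=None, n_folds=7,
                     n_permutations=500, seed=0, pretreatment=None,
                     case_label=None, return_null=False):
    """Permutation test on the class responses.

    Class labels are permuted uniformly while X and Z stay fixed; the full
    cross-validated Q² is recomputed for each permutation and
    p = (#{Q²_perm ≥ Q²_obs} + 1) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    spec, L, is_case, Z0 = _prepare_blocks(X, labels, constraints, pretreatment, case_label)
    rng = np.random.default_rng(seed)
    press, tss, _ = _cv_core(L, is_case, Z0, n_components, n_folds, rng, spec)
    q2_obs = 1.0 - press / tss
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm_case = rng.permutation(is_case)
        press, tss, _ = _cv_core(L, perm_case, Z0, n_components, n_folds, rng, spec)
        null[b] = 1.0 - press / tss
    p = (int((null >= q2_obs - 1e-12).sum()) + 1) / (n_permutations + 1)
    return (p, q2_obs, null) if return_null else p


# ---------------------------------------------------------------------------
# Assembled validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    r2: float
    q2_by_folds: dict
    perm_pvalue: float
    n_permutations: int
    roc: ROCResult
    folds_seed: int

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "q2_by_folds": {str(k): v for k, v in self.q2_by_folds.items()},
            "perm_pvalue": self.perm_pvalue,
            "n_permutations": self.n_permutations,
            "roc": {
                "auc": self.roc.auc, "auc_ci95": list(self.roc.auc_ci95),
                "sensitivity": self.roc.sensitivity,
                "specificity": self.roc.specificity,
                "threshold": self.roc.threshold,
            },
            "folds_seed": self.folds_seed,
        }


def validation_report(X, labels, n_components, constraints=None,
                      fold_counts=(6, 7, 8), n_permutations=500, perm_folds=7,
                      seed=0, pretreatment=None, case_label=None) -> ValidationReport:
    """R², Q² for each fold count, permutation p and cross-validated ROC."""
    spec, L, is_case, Z0 = _prepare_blocks(X, labels, constraints, pretreatment, case_label)
    mu, sc, _ = fit_column_stats(L, spec)
    Yind = np.column_stack([(~is_case).astype(float), is_case.astype(float)])
    F = Yind - Yind.mean(axis=0)
    Z = _fold_constraints(Z0, np.arange(len(is_case)))
    lm = fit_cpls((L - mu) / sc, F, Z, n_components, check_rank=False)
    q2 = {}
    roc = None
    for nf in fold_counts:
        res = cross_validate(X, labels, n_components, constraints, nf, seed,
                             pretreatment, case_label)
        q2[nf] = res.q2
        if nf == perm_folds:
            roc = roc_analysis(res.cv_scores, res.is_case)
    if roc is None:
        res = cross_validate(X, labels, n_components, constraints, perm_folds,
                             seed, pretreatment, case_label)
        roc = roc_analysis(res.cv_scores, res.is_case)
    p = permutation_test(X, labels, n_components, constraints, perm_folds,
                         n_permutations, seed, pretreatment, case_label)
    return ValidationReport(lm.r2, q2, p, n_permutations, roc, seed)


def select_n_components(X, labels, constraints=None, max_components=5,
                        n_folds=7, seed=0, pretreatment=None, case_label=None,
                        min_gain=0.01) -> int:
    """Smallest A whose 7-fold Q² stops improving by more than ``min_gain``."""
    spec, L, is_case, Z0 = _prepare_blocks(X, labels, constraints, pretreatment, case_label)
    c = Z0.shape[1] if Z0 is not None else 0
    amax = max(1, min(max_components, len(is_case) - 1 - c, L.shape[1]))
    prev = None
    for a in range(1, amax + 1):
        q2 = cross_validate(X, labels, a, constraints, n_folds, seed,
                            pretreatment, case_label).q2
        if prev is not None and q2 - prev <= min_gain:
            return a - 1
        prev = q2
    return amax


# ---------------------------------------------------------------------------
# Confounding screen & external factor check
# ---------------------------------------------------------------------------

@dataclass
class ScreenReport:
    confounded: bool
    metadata_q2: float
    pca_scores: np.ndarray
    pca_explained: np.ndarray
    per_pc_pvalues: np.ndarray
    dropped: list

    @property
    def no_confounding(self) -> bool:
        return not self.confounded


def confounding_screen(meta: pd.DataFrame, labels, covariates=None,
                       n_folds=7, seed=0) -> ScreenReport:
    """PCA + metadata-as-X PLS-DA screen for metadata/class confounding.

    The metadata (autoscaled, no log) are examined two ways: PCA with a
    per-component two-sample t-test between the classes, and a PLS-DA with
    the metadata as the X-block whose 7-fold Q² is the decision statistic.
    "No confounding" is declared when that Q² ≤ 0.
    """
    covariates = list(covariates) if covariates is not None else list(meta.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        blk = encode_constraints(meta, covariates)
    if blk.n_constraints == 0:
        raise ValueError("no usable (non-constant) covariates for the screen")
    M = blk.Z / blk.Z.std(axis=0, ddof=1)
    labels = np.asarray(pd.Series(labels).to_numpy())
    is_case = labels == sorted(pd.unique(labels).tolist())[-1]
    single = blk.n_constraints < 2
    if single:
        warnings.warn("single covariate: running the PLS-DA screen only", UserWarning,
                      stacklevel=2)
        pca_scores = M.copy()
        evr = np.array([1.0])
    else:
        pca = fit_pca(M)
        pca_scores, evr = pca.scores, pca.explained_variance_ratio
    pvals = np.array([
        scipy.stats.ttest_ind(pc[is_case], pc[~is_case], equal_var=False).pvalue
        for pc in pca_scores.T
    ])
    a = max(1, min(2, M.shape[1], len(labels) - 1))
    q2 = cross_validate(M, labels, a, None, n_folds, seed,
                        PretreatSpec(log=False, scaling="uv")).q2
    return ScreenReport(bool(q2 > 0), q2, pca_scores, evr, pvals, blk.dropped)


def external_factor_check(results_or_scores, factor) -> tuple[float, float]:
    """Point-biserial correlation of the predictive score with a binary factor.

    Used to verify that the discriminant axis is unrelated to an external
    binary condition (e.g. chorioamnionitis).  Returns (r, two-sided p).
    """
    factor = np.asarray(pd.Series(factor).to_numpy())
    levels = pd.unique(factor)
    if len(levels) < 2:
        raise ValueError("external factor is constant; both levels required")
    if len(levels) > 2:
        raise ValueError("external factor must be binary")
    f01 = (factor == sorted(levels.tolist())[-1]).astype(float)
    if hasattr(results_or_scores, "predictive_score"):
        t = np.asarray(results_or_scores.predictive_score)[:, 0]
    else:
        t = np.asarray(results_or_scores, dtype=float)
    r, p = scipy.stats.pointbiserialr(f01, t)
    return float(r), float(p)
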