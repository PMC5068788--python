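"""Univariate complement: per-feature Welch t-tests with Benjamini-Hochberg
FDR correction and per-feature ROC analysis.

Run on pretreated (log-scale) intensities for consistency with the
multivariate block.  Features whose BH q-value falls below the configured
threshold (default 20%) are flagged significant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .validation import roc_analysis

__all__ = ["univariate_scan"]


def univariate_scan(X, labels, q_threshold: float = 0.20, case_label=None,
                    equal_var: bool = False, compute_roc: bool = True) -> pd.DataFrame:
    """Per-feature two-sample scan of a pretreated matrix.

    Returns one row per feature with the Welch (or Student, if
    ``equal_var``) t-statistic, raw p, BH q-value, AUC with DeLong 95% CI,
    sensitivity/specificity at the closest-to-top-left threshold, and a
    ``significant`` flag at ``q < q_threshold``.
    """
    if not 0 < q_threshold <= 1:
        raise ValueError("q_threshold must lie in (0, 1]")
    feat = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(np.shape(X)[1])
    M = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    labels = np.asarray(pd.Series(labels).to_numpy())
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes!r}")
    case = case_label if case_label is not None else classes[-1]
    is_case = labels == case
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("each class needs at least 2 samples")

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = scipy.stats.ttest_ind(M[is_case], M[~is_case], axis=0,
                                     equal_var=equal_var)
    bad = ~np.isfinite(p)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance feature(s): p set to 1", UserWarning,
            stacklevel=2)
        p = np.where(bad, 1.0, p)
        t = np.where(bad, 0.0, t)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({"t": t, "p": p, "q": q}, index=feat).rename_axis("feature")
    if compute_roc:
        aucs = np.empty(M.shape[1]); lo = np.empty(M.shape[1]); hi = np.empty(M.shape[1])
        se = np.empty(M.shape[1]); sp = np.empty(M.shape[1])
        for j in range(M.shape[1]):
            roc = roc_analysis(M[:, j], is_case)
            aucs[j] = roc.auc
            lo[j], hi[j] = roc.auc_ci95
            se[j], sp[j] = roc.sensitivity, roc.specificity
        out["auc"] = aucs
        out["auc_ci_low"] = lo
        out["auc_ci_high"] = hi
        out["sensitivity"] = se
        out["specificity"] = sp
    out["significant"] = out["q"] < q_threshold
    return out
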