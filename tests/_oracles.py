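"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths: NIPALS weights come from
a full eigendecomposition, Q² from an explicit fold loop with its own
pretreatment arithmetic, AUC from exhaustive pair counting, and BH q-values
from a literal step-up rule.
"""

import numpy as np


def sign_fix(w):
    j = int(np.argmax(np.abs(w)))
    return -w if w[j] < 0 else w


def nipals_pls2_eigen(X, Y, A):
    """PLS2 via full eigendecomposition of EᵀF FᵀE per component."""
    E = np.array(X, dtype=float)
    F = np.array(Y, dtype=float)
    Ws, Ts, Ps, Cs = [], [], [], []
    for _ in range(A):
        M = E.T @ F
        evals, evecs = np.linalg.eigh(M @ M.T)
        w = sign_fix(evecs[:, -1])
        t = E @ w
        tt = float(t @ t)
        p = E.T @ t / tt
        c = F.T @ t / tt
        Ws.append(w); Ts.append(t); Ps.append(p); Cs.append(c)
        E = E - np.outer(t, p)
        F = F - np.outer(t, c)
    W = np.column_stack(Ws); T = np.column_stack(Ts)
    P = np.column_stack(Ps); C = np.column_stack(Cs)
    B = W @ np.linalg.solve(P.T @ W, C.T)
    return W, T, P, C, B


def pretreat_log_center_pareto(L_train, L_test):
    """Log-scale mean-center + Pareto using training statistics only."""
    mu = L_train.mean(axis=0)
    sd = L_train.std(axis=0, ddof=1)
    sc = np.where(sd <= 1e-12, 1.0, np.sqrt(np.where(sd <= 1e-12, 1.0, sd)))
    return (L_train - mu) / sc, (L_test - mu) / sc


def q2_explicit_loop(X, is_case, folds, A):
    """Explicit-loop PRESS/TSS Q² with the eigen-NIPALS fit, log+Pareto."""
    L = np.log(np.asarray(X, dtype=float))
    Yind = np.column_stack([(~is_case).astype(float), is_case.astype(float)])
    n = len(is_case)
    press = tss = 0.0
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        Et, Eh = pretreat_log_center_pareto(L[train], L[f])
        ymean = Yind[train].mean(axis=0)
        _, _, _, _, B = nipals_pls2_eigen(Et, Yind[train] - ymean, A)
        yhat = Eh @ B + ymean
        press += float(((Yind[f] - yhat) ** 2).sum())
        tss += float(((Yind[f] - ymean) ** 2).sum())
    return 1.0 - press / tss


def auc_pair_count(scores, is_case):
    """AUC by exhaustive concordant-pair enumeration (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(is_case, dtype=bool)]
    neg = scores[~np.asarray(is_case, dtype=bool)]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def bh_stepup(pvals):
    """Literal Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j)·m/j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
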