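"""Latent-variable models: PCA, PLS2-DA and orthogonally constrained PLS2-DA.

The centrepiece is oCPLS2-DA: a two-class PLS2 discriminant model whose
latent scores are forced to be orthogonal to a matrix ``Z`` of nuisance
covariates (the constraints), so that class discrimination cannot be carried
by those covariates.  Mechanically this is NIPALS PLS2 in which, at each
component, the candidate weight direction is projected onto the null space
of ``K = Zᵀ·E`` before the dominant direction is extracted; the resulting
score ``t = E·w`` then satisfies ``Zᵀ·t = K·w = 0`` by construction.  With an
empty ``Z`` the algorithm reduces exactly to ordinary PLS2-DA.

A fitted model can be *post-transformed*: rotated in component space so that
the Y-correlated variation concentrates in the leading ``A_pred``
(predictive) components while the remaining ``A_orth`` components are
Y-orthogonal — the familiar "A = 1+2" style of reporting.  The rotation
leaves fitted responses, the X-reconstruction ``T·Pᵀ`` and the regression
coefficients ``B`` unchanged.

The user-facing surface follows the modelling-object convention: build an
:class:`OCPLSDA` from data (or :meth:`OCPLSDA.from_tables`), call ``fit()``,
and work with the returned :class:`OCPLSDAResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pretreat import (
    ConstraintBlock,
    PretreatSpec,
    Pretreatment,
    ResponseBlock,
    encode_constraints,
    make_response,
)

__all__ = [
    "LatentModel",
    "PCAResults",
    "fit_pls2da",
    "fit_ocpls2da",
    "post_transform",
    "fit_pca",
    "OCPLSDA",
    "OCPLSDAResults",
    "CONSTRAINT_RESIDUALS",
]

#: relative |Zᵀt| recorded for every constrained component ever fitted in
#: this process; cheap (one float per component) and lets long simulation
#: campaigns audit the orthogonality constraint across all refits.
CONSTRAINT_RESIDUALS: list[float] = []

_RANK_TOL = 1e-10


def _dominant_left_singular(M: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading left singular vector of a thin (p × k) matrix and its value."""
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    return U[:, 0], s[0]


def _null_project(M: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Project the columns of M onto the null space of K (rows of K removed)."""
    if K.size == 0:
        return M
    # orthonormal basis of row(K) via SVD; robust to near-collinear constraints
    _, s, Vt = np.linalg.svd(K, full_matrices=False)
    keep = s > max(K.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    V = Vt[keep].T
    return M - V @ (V.T @ M)


@dataclass
class LatentModel:
    """A fitted (constrained) PLS2-DA model in matrix form.

    W, P: feature × A weights / X-loadings; C: 2 × A Y-loadings;
    T: sample × A scores; B: feature × 2 regression coefficients mapping
    pretreated X to the centered two-column class response.
    """

    W: np.ndarray
    P: np.ndarray
    C: np.ndarray
    T: np.ndarray
    B: np.ndarray
    r2: float
    n_components: int
    n_pred: int | None = None
    n_orth: int | None = None
    constraint_residual: float = 0.0

    @property
    def is_post_transformed(self) -> bool:
        return self.n_pred is not None

    def fitted_response(self, X: np.ndarray) -> np.ndarray:
        """Centered-scale fitted response Ŷ = X·B for pretreated X."""
        return np.asarray(X, dtype=float) @ self.B


def _check_components(A: int, n: int, p: int, n_constraints: int = 0) -> None:
    if A < 1:
        raise ValueError("n_components must be >= 1")
    amax = min(n - 1 - n_constraints, p)
    if A > amax:
        raise ValueError(
            f"n_components={A} exceeds the available rank "
            f"min(n-1-c, p) = {amax} (n={n}, p={p}, constraints={n_constraints})"
        )


def fit_cpls(E0: np.ndarray, F0: np.ndarray, Z: np.ndarray | None, A: int,
             check_rank: bool = True) -> LatentModel:
    """NIPALS PLS2 with optional score-orthogonality constraints.

    E0: pretreated X (n × p); F0: centered response (n × 2); Z: centered
    constraint matrix (n × c) or None.  Sequentially extracts ``A``
    components, deflating both blocks; stops early with a warning if the
    residual cross-covariance degenerates.
    """
    E = np.array(E0, dtype=float, copy=True)
    F = np.array(F0, dtype=float, copy=True)
    n, p = E.shape
    c = 0
    if Z is not None and Z.size:
        Z = np.asarray(Z, dtype=float)
        if check_rank:
            rk = np.linalg.matrix_rank(Z)
            if rk < Z.shape[1]:
                raise ValueError(
                    f"constraint matrix Z is rank deficient (rank {rk} < {Z.shape[1]} "
                    "columns); remove linearly dependent covariates"
                )
        c = Z.shape[1]
    else:
        Z = None
    _check_components(A, n, p, c)

    Znorm = np.linalg.norm(Z) if Z is not None else 0.0
    Ws, Ts, Ps, Cs = [], [], [], []
    max_rel = 0.0
    ss_f0 = float((F0 ** 2).sum())
    for _ in range(A):
        M = E.T @ F
        K = Z.T @ E if Z is not None else None
        if Z is not None:
            M = _null_project(M, K)
        mnorm = np.linalg.norm(M)
        enorm = np.linalg.norm(E)
        fnorm = np.linalg.norm(F)
        if mnorm <= 1e-12 * max(enorm * fnorm, 1e-300):
            if Ws:
                warnings.warn(
                    f"cross-covariance degenerated; stopping at {len(Ws)} of {A} components",
                    UserWarning, stacklevel=2,
                )
                break
            # no Y-correlated direction survives the constraints (e.g. Z spans
            # the response itself): fall back to the leading constraint-
            # respecting X-variance direction so a null-signal model exists
            warnings.warn(
                "no Y-correlated variation within the constraint null space; "
                "component defaults to the leading constrained X direction",
                UserWarning, stacklevel=2,
            )
            Ep = _null_project(E.T, K).T if K is not None else E
            if np.linalg.norm(Ep) <= _RANK_TOL:
                break
            _, _, Vt = np.linalg.svd(Ep, full_matrices=False)
            w = Vt[0]
        else:
            w, _ = _dominant_left_singular(M)
        t = E @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL:
            warnings.warn(
                f"degenerate score norm; stopping at {len(Ws)} of {A} components",
                UserWarning, stacklevel=2,
            )
            break
        p_a = E.T @ t / tt
        c_a = F.T @ t / tt
        # sign convention: largest-|w| element positive, for reproducible reports
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, p_a, c_a = -w, -t, -p_a, -c_a
        if Z is not None:
            rel = float(np.max(np.abs(Z.T @ t))) / max(Znorm * np.sqrt(tt), 1e-300)
            max_rel = max(max_rel, rel)
            CONSTRAINT_RESIDUALS.append(rel)
        Ws.append(w); Ts.append(t); Ps.append(p_a); Cs.append(c_a)
        E -= np.outer(t, p_a)
        F -= np.outer(t, c_a)

    if not Ws:
        raise ValueError("no components could be extracted (zero cross-covariance)")
    W = np.column_stack(Ws)
    T = np.column_stack(Ts)
    P = np.column_stack(Ps)
    C = np.column_stack(Cs)       # 2 × A
    B = W @ np.linalg.solve(P.T @ W, C.T)
    resid = F0 - E0 @ B
    r2 = 1.0 - float((resid ** 2).sum()) / ss_f0 if ss_f0 > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    return LatentModel(W, P, C, T, B, r2, W.shape[1], constraint_residual=max_rel)


def fit_pls2da(X: np.ndarray, Y: ResponseBlock | np.ndarray, A: int) -> LatentModel:
    """Ordinary two-class PLS2-DA on a pretreated matrix."""
    F = Y.centered if isinstance(Y, ResponseBlock) else np.asarray(Y, dtype=float)
    return fit_cpls(np.asarray(X, dtype=float), F, None, A)


def fit_ocpls2da(X: np.ndarray, Y: ResponseBlock | np.ndarray,
                 Z: ConstraintBlock | np.ndarray | None, A: int) -> LatentModel:
    """Orthogonally constrained PLS2-DA: scores satisfy Zᵀt = 0 exactly."""
    F = Y.centered if isinstance(Y, ResponseBlock) else np.asarray(Y, dtype=float)
    Zm = Z.Z if isinstance(Z, ConstraintBlock) else Z
    return fit_cpls(np.asarray(X, dtype=float), F, Zm, A)


def post_transform(model: LatentModel, Y: ResponseBlock | np.ndarray) -> LatentModel:
    """Rotate a fitted model into predictive + Y-orthogonal components.

    The rotation is computed from the SVD of the norm-weighted score–response
    product D^(-1/2)·Tᵀ·Y_c (D = diag(tᵀt)): its leading ``rank`` directions
    become the predictive components, the rest are exactly Y-orthogonal and
    carry zero Y-loadings.  Fitted responses, T·Pᵀ and B are unchanged.
    """
    F = Y.centered if isinstance(Y, ResponseBlock) else np.asarray(Y, dtype=float)
    T, P, W, C = model.T, model.P, model.W, model.C
    A = T.shape[1]
    d = (T ** 2).sum(axis=0)
    sd = np.sqrt(d)
    M = (T.T @ F) / sd[:, None]
    U, s, _ = np.linalg.svd(M, full_matrices=True)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int((s > max(tol, _RANK_TOL)).sum())
    if r == 0:
        warnings.warn("no Y-correlated variation: A_pred = 0", UserWarning, stacklevel=2)
    G = U / sd[:, None]            # T' = T G
    Ginv_t = U * sd[:, None]       # paired transform for W, P, C keeps B invariant
    T2, P2, W2, C2 = T @ G, P @ Ginv_t, W @ Ginv_t, C @ Ginv_t
    # re-apply the sign convention componentwise
    for a in range(A):
        j = int(np.argmax(np.abs(W2[:, a])))
        if W2[j, a] < 0:
            W2[:, a] *= -1; T2[:, a] *= -1; P2[:, a] *= -1; C2[:, a] *= -1
    return LatentModel(W2, P2, C2, T2, model.B.copy(), model.r2, A,
                       n_pred=r, n_orth=A - r,
                       constraint_residual=model.constraint_residual)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResults:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def fit_pca(X: np.ndarray, n_components: int | None = None) -> PCAResults:
    """PCA of a (centered) matrix by singular-value decomposition."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    amax = min(n - 1, p)
    A = amax if n_components is None else int(n_components)
    if not 1 <= A <= amax:
        raise ValueError(f"n_components must be in [1, {amax}], got {A}")
    mu = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mu, full_matrices=False)
    total = float((s ** 2).sum())
    evr = (s[:A] ** 2) / total if total > 0 else np.zeros(A)
    return PCAResults(U[:, :A] * s[:A], Vt[:A].T, evr, mu)


# ---------------------------------------------------------------------------
# Modelling-object surface
# ---------------------------------------------------------------------------

class OCPLSDA:
    """Orthogonally constrained PLS2-DA model bound to raw data.

    Parameters
    ----------
    features : DataFrame or ndarray, samples × features
        Raw (untreated) intensity table.
    labels : array-like
        Per-sample class labels; exactly two classes.
    constraints : DataFrame or None
        Metadata covariates to constrain against (encoded and centered
        internally; binary string/bool columns become 0/1).
    n_components : int or None
        Total number of latent components. ``None`` selects the smallest A
        whose 7-fold Q² stops improving by more than 0.01.
    pretreatment : PretreatSpec
        Defaults to log + mean-center + Pareto.
    case_label : label of the case (positive) class; defaults to the last in
        sorted order.
    """

    def __init__(self, features, labels, constraints: pd.DataFrame | None = None,
                 n_components: int | None = None,
                 pretreatment: PretreatSpec | None = None,
                 case_label=None):
        self.features = features if isinstance(features, pd.DataFrame) else pd.DataFrame(np.asarray(features, dtype=float))
        if len(self.features) != len(np.asarray(labels)):
            raise ValueError("features and labels disagree on sample count")
        self.labels = np.asarray(pd.Series(labels).to_numpy())
        self.constraints = constraints
        self.n_components = n_components
        self.pretreatment = pretreatment or PretreatSpec()
        self.case_label = case_label

    @classmethod
    def from_tables(cls, feature_table: pd.DataFrame, metadata: pd.DataFrame,
                    class_col: str, case_label=None, constraint_cols=(),
                    n_components: int | None = None,
                    pretreatment: PretreatSpec | None = None) -> "OCPLSDA":
        """Build from a feature table and a metadata table sharing sample ids."""
        if class_col not in metadata.columns:
            raise KeyError(f"class column {class_col!r} not in metadata")
        missing = [c for c in constraint_cols if c not in metadata.columns]
        if missing:
            raise KeyError(f"constraint covariate(s) not in metadata: {missing}")
        meta = metadata.loc[feature_table.index] if not metadata.index.equals(feature_table.index) else metadata
        cons = meta[list(constraint_cols)] if constraint_cols else None
        return cls(feature_table, meta[class_col], constraints=cons,
                   n_components=n_components, pretreatment=pretreatment,
                   case_label=case_label)

    # -- fitting -----------------------------------------------------------
    def fit(self, post: bool = True) -> "OCPLSDAResults":
        pret = Pretreatment(self.pretreatment).fit(self.features)
        Xt = pret.transform(self.features)
        resp = make_response(self.labels, self.case_label)
        cblock = (encode_constraints(self.constraints, self.constraints.columns)
                  if self.constraints is not None and self.constraints.shape[1] else None)
        A = self.n_components
        if A is None:
            from .validation import select_n_components
            A = select_n_components(self.features, self.labels,
                                    constraints=self.constraints,
                                    pretreatment=self.pretreatment,
                                    case_label=self.case_label)
        latent = fit_ocpls2da(Xt, resp, cblock, A)
        if post:
            latent = post_transform(latent, resp)
        return OCPLSDAResults(self, pret, resp, cblock, latent)


class OCPLSDAResults:
    """Results of a fitted (and by default post-transformed) oCPLS2-DA model."""

    def __init__(self, model: OCPLSDA, pretreatment: Pretreatment,
                 response: ResponseBlock, constraints: ConstraintBlock | None,
                 latent: LatentModel):
        self.model = model
        self.pretreatment = pretreatment
        self.response = response
        self.constraints = constraints
        self.latent = latent

    # -- convenient views --------------------------------------------------
    @property
    def r2(self) -> float:
        return self.latent.r2

    @property
    def scores(self) -> np.ndarray:
        return self.latent.T

    @property
    def predictive_score(self) -> np.ndarray:
        """Scores on the predictive component(s); the discriminant axis."""
        npred = self.latent.n_pred if self.latent.is_post_transformed else 1
        return self.latent.T[:, :max(npred, 1)]

    @property
    def coef(self) -> pd.DataFrame:
        return pd.DataFrame(self.latent.B, index=self.model.features.columns,
                            columns=list(self.response.classes))

    @property
    def n_pred(self):
        return self.latent.n_pred

    @property
    def n_orth(self):
        return self.latent.n_orth

    # -- prediction --------------------------------------------------------
    def predict(self, X_new) -> pd.DataFrame:
        """Predict class responses and calls for new raw samples.

        Returns a DataFrame with the two response columns (indicator scale),
        the case-class score used for ROC, the predictive-component score,
        and the argmax class call.
        """
        Xt = self.pretreatment.transform(X_new)
        yhat = Xt @ self.latent.B + self.response.mean
        npred = self.latent.n_pred if self.latent.is_post_transformed else self.latent.n_components
        u = Xt @ self.latent.W[:, :max(npred, 1)]
        calls = np.where(yhat[:, 1] > yhat[:, 0], self.response.classes[1],
                         self.response.classes[0])
        idx = X_new.index if isinstance(X_new, pd.DataFrame) else pd.RangeIndex(len(yhat))
        out = pd.DataFrame(yhat, columns=[f"yhat_{c}" for c in self.response.classes], index=idx)
        out["case_score"] = yhat[:, 1]
        out["t_pred"] = u[:, 0]
        out["class_call"] = calls
        return out

    # -- validation / selection (delegating to the dedicated modules) ------
    def cross_validate(self, n_folds=7, seed=0):
        from . import validation
        return validation.cross_validate(
            self.model.features, self.model.labels,
            n_components=self.latent.n_components,
            constraints=self.model.constraints, n_folds=n_folds, seed=seed,
            pretreatment=self.model.pretreatment, case_label=self.model.case_label)

    def validation_report(self, fold_counts=(6, 7, 8), n_permutations=500,
                          perm_folds=7, seed=0):
        from . import validation
        return validation.validation_report(
            self.model.features, self.model.labels,
            n_components=self.latent.n_components,
            constraints=self.model.constraints, fold_counts=fold_counts,
            n_permutations=n_permutations, perm_folds=perm_folds, seed=seed,
            pretreatment=self.model.pretreatment, case_label=self.model.case_label)

    def permutation_test(self, n_folds=7, n_permutations=500, seed=0) -> float:
        from . import validation
        return validation.permutation_test(
            self.model.features, self.model.labels,
            n_components=self.latent.n_components,
            constraints=self.model.constraints, n_folds=n_folds,
            n_permutations=n_permutations, seed=seed,
            pretreatment=self.model.pretreatment, case_label=self.model.case_label)

    def stability_selection(self, config=None):
        from . import stability
        return stability.stability_select(
            self.model.features, self.model.labels,
            n_components=self.latent.n_components,
            constraints=self.model.constraints, config=config,
            pretreatment=self.model.pretreatment, case_label=self.model.case_label)

    def external_factor_check(self, factor):
        from . import validation
        return validation.external_factor_check(self, factor)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lt = self.latent
        n, p = self.model.features.shape
        n_case = int(self.response.indicator[:, 1].sum())
        comp = (f"{lt.n_pred}+{lt.n_orth}" if lt.is_post_transformed
                else str(lt.n_components))
        lines = [
            "oCPLS2-DA results",
            "=" * 48,
            f"samples: {n}  ({self.response.classes[0]}: {n - n_case}, "
            f"{self.response.classes[1]}: {n_case})",
            f"features: {p}",
            f"constraints: {self.constraints.n_constraints if self.constraints else 0}",
            f"components (pred+orth): {comp}",
            f"R2(Y): {lt.r2:.3f}",
            f"max relative |Z't|: {lt.constraint_residual:.2e}",
        ]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        lt = self.latent
        return {
            "classes": [str(c) for c in self.response.classes],
            "n_components": lt.n_components,
            "n_pred": lt.n_pred,
            "n_orth": lt.n_orth,
            "r2": lt.r2,
            "W": lt.W.tolist(), "P": lt.P.tolist(), "C": lt.C.tolist(),
            "T": lt.T.tolist(), "B": lt.B.tolist(),
            "y_mean": self.response.mean.tolist(),
            "pretreatment": {
                "spec": vars(self.pretreatment.spec).copy(),
                "means": self.pretreatment.means_.tolist(),
                "scales": self.pretreatment.scales_.tolist(),
            },
            "features": [str(f) for f in self.model.features.columns],
            "constraint_names": self.constraints.names if self.constraints else [],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)
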