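"""Column-wise pretreatment and block construction for latent-variable models.

Untargeted LC-MS intensities are strictly positive, right-skewed and
heteroscedastic, so the default recipe is log-transform, mean-centering and
Pareto scaling (divide each centered feature by the square root of its
standard deviation) — the field-standard treatment for ESI-MS peak areas.
Every statistic (mean, scale) is estimated on the data handed to ``fit`` and
nothing else, which is what makes leak-free cross-validation possible: each
training fold refits its own :class:`Pretreatment`.

This module also builds the two auxiliary blocks of a constrained
discriminant model: the centered class-indicator response ``Y`` (two groups
only) and the centered metadata constraint matrix ``Z``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PretreatSpec",
    "Pretreatment",
    "ResponseBlock",
    "ConstraintBlock",
    "make_response",
    "encode_constraints",
]

_CENTERING = ("none", "mean")
_SCALING = ("none", "uv", "pareto")

#: standard deviations below this are treated as zero variance
_ZERO_VAR_TOL = 1e-12


@dataclass(frozen=True)
class PretreatSpec:
    """Configuration of the column-wise pretreatment.

    Parameters
    ----------
    log : bool
        Natural-log transform the intensities first (requires positive data).
    centering : {"mean", "none"}
    scaling : {"pareto", "uv", "none"}
        ``"uv"`` divides by the standard deviation (autoscaling),
        ``"pareto"`` by its square root.
    """

    log: bool = True
    centering: str = "mean"
    scaling: str = "pareto"

    def __post_init__(self) -> None:
        if self.centering not in _CENTERING:
            raise ValueError(f"centering must be one of {_CENTERING}, got {self.centering!r}")
        if self.scaling not in _SCALING:
            raise ValueError(f"scaling must be one of {_SCALING}, got {self.scaling!r}")


class Pretreatment:
    """Fitted column-wise pretreatment: optional log, centering, scaling.

    After :meth:`fit`, ``means_`` and ``scales_`` hold the per-feature
    statistics; zero-variance features get a unit divisor and are flagged in
    ``zero_variance_`` with a warning.  ``transform`` of the training table
    followed by ``inverse_transform`` recovers it to numerical precision.
    """

    def __init__(self, spec: PretreatSpec | None = None, **kwargs):
        self.spec = spec if spec is not None else PretreatSpec(**kwargs)
        self.means_: np.ndarray | None = None
        self.scales_: np.ndarray | None = None
        self.zero_variance_: np.ndarray | None = None
        self.feature_names_: pd.Index | None = None

    # -- fitting -----------------------------------------------------------
    def fit(self, table: pd.DataFrame | np.ndarray) -> "Pretreatment":
        X = self._to_array(table, remember_names=True)
        L = self._maybe_log(X)
        mu, sc, zv = fit_column_stats(L, self.spec)
        if zv.any():
            warnings.warn(
                f"{int(zv.sum())} zero-variance feature(s) excluded from scaling "
                "(divisor set to 1)",
                UserWarning,
                stacklevel=2,
            )
        self.means_, self.scales_, self.zero_variance_ = mu, sc, zv
        return self

    def transform(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = self._to_array(table, remember_names=False)
        if X.shape[1] != self.means_.shape[0]:
            raise ValueError(
                f"feature count mismatch: fitted on {self.means_.shape[0]}, got {X.shape[1]}"
            )
        L = self._maybe_log(X)
        return (L - self.means_) / self.scales_

    def fit_transform(self, table) -> np.ndarray:
        return self.fit(table).transform(table)

    def inverse_transform(self, Xt: np.ndarray) -> np.ndarray:
        self._check_fitted()
        L = np.asarray(Xt, dtype=float) * self.scales_ + self.means_
        return np.exp(L) if self.spec.log else L

    # -- helpers -----------------------------------------------------------
    def _check_fitted(self) -> None:
        if self.means_ is None:
            raise RuntimeError("Pretreatment must be fitted before use")

    def _to_array(self, table, remember_names: bool) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            if remember_names:
                self.feature_names_ = table.columns
            elif self.feature_names_ is not None:
                missing = self.feature_names_.difference(table.columns)
                extra = table.columns.difference(self.feature_names_)
                if len(missing) or len(extra):
                    raise ValueError(
                        f"feature mismatch: missing={list(missing)[:5]}, extra={list(extra)[:5]}"
                    )
                table = table[self.feature_names_]
            X = table.to_numpy(dtype=float)
        else:
            X = np.asarray(table, dtype=float)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("feature table must be a non-empty 2-D array")
        return X

    def _maybe_log(self, X: np.ndarray) -> np.ndarray:
        if not self.spec.log:
            return X.astype(float, copy=True)
        bad = np.argwhere(~(X > 0))
        if bad.size:
            i, j = bad[0]
            name = (
                self.feature_names_[j]
                if self.feature_names_ is not None and j < len(self.feature_names_)
                else f"column {j}"
            )
            raise ValueError(
                f"log transform requires positive intensities; offending cell: "
                f"sample row {i}, feature {name} (value {X[i, j]!r})"
            )
        return np.log(X)


def fit_column_stats(L: np.ndarray, spec: PretreatSpec):
    """Per-feature mean/divisor for an already log-transformed (or raw) matrix.

    Returns ``(means, scales, zero_variance_mask)``.  Kept as a free function
    so fold-wise refitting inside cross-validation can stay on the fast
    ndarray path.
    """
    n, p = L.shape
    mu = L.mean(axis=0) if spec.centering == "mean" else np.zeros(p)
    if spec.scaling == "none":
        return mu, np.ones(p), np.zeros(p, dtype=bool)
    sd = L.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
    zv = sd <= _ZERO_VAR_TOL
    sc = np.where(zv, 1.0, sd if spec.scaling == "uv" else np.sqrt(sd, where=~zv, out=np.ones(p)))
    return mu, sc, zv


# ---------------------------------------------------------------------------
# Response block
# ---------------------------------------------------------------------------

@dataclass
class ResponseBlock:
    """Two-class dummy response.

    ``indicator`` has one row per sample summing to 1 (columns ordered
    control, case); ``centered`` is the column-centered version used as the
    PLS response block.
    """

    indicator: np.ndarray
    centered: np.ndarray
    mean: np.ndarray
    classes: tuple
    labels: np.ndarray

    @property
    def case(self) -> np.ndarray:
        """Boolean mask of case-class samples."""
        return self.indicator[:, 1].astype(bool)


def make_response(labels, case_label=None) -> ResponseBlock:
    """Build the centered class-indicator block from per-sample labels.

    Exactly two classes are supported; ``case_label`` selects which one
    occupies the second (case) column, defaulting to the last in sorted
    order.
    """
    labels = np.asarray(pd.Series(labels).to_numpy())
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes!r}")
    if case_label is not None:
        if case_label not in classes:
            raise ValueError(f"case_label {case_label!r} not among classes {classes!r}")
        classes = [c for c in classes if c != case_label] + [case_label]
    ind = np.column_stack([(labels == c).astype(float) for c in classes])
    if ind[:, 1].sum() == 0 or ind[:, 0].sum() == 0:
        raise ValueError("both classes must be present")
    mean = ind.mean(axis=0)
    return ResponseBlock(ind, ind - mean, mean, tuple(classes), labels)


# ---------------------------------------------------------------------------
# Constraint block
# ---------------------------------------------------------------------------

@dataclass
class ConstraintBlock:
    """Centered, numerically encoded metadata constraints (the Z block)."""

    Z: np.ndarray
    names: list = field(default_factory=list)
    encoding_map: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)

    @property
    def n_constraints(self) -> int:
        return self.Z.shape[1] if self.Z.size else 0


def _encode_column(col: pd.Series) -> np.ndarray:
    if col.isna().any():
        raise ValueError(f"covariate {col.name!r} has missing entries")
    if pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col):
        return col.to_numpy(dtype=float)
    levels = sorted(col.astype(str).unique())
    if len(levels) > 2:
        raise ValueError(
            f"covariate {col.name!r} is non-numeric with {len(levels)} levels; "
            "only binary categorical covariates are supported"
        )
    return (col.astype(str) == levels[-1]).to_numpy(dtype=float)


def encode_constraints(meta: pd.DataFrame, covariates) -> ConstraintBlock:
    """Encode the requested metadata covariates into a centered Z matrix.

    Continuous covariates map to one centered column each; binary covariates
    (numeric 0/1, boolean, or two-level strings) to one centered 0/1 column.
    Column order follows the request list. Covariates constant across samples
    are dropped with a warning.
    """
    covariates = list(covariates)
    missing = [c for c in covariates if c not in meta.columns]
    if missing:
        raise KeyError(f"covariate(s) not found in metadata: {missing}")
    cols, names, enc = [], [], {}
    dropped: list = []
    for c in covariates:
        v = _encode_column(meta[c])
        if np.std(v) <= _ZERO_VAR_TOL:
            dropped.append(c)
            warnings.warn(f"constant covariate {c!r} dropped from constraints", UserWarning,
                          stacklevel=2)
            continue
        enc[c] = [len(cols)]
        cols.append(v - v.mean())
        names.append(c)
    Z = np.column_stack(cols) if cols else np.empty((len(meta), 0))
    return ConstraintBlock(Z, names, enc, dropped)
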