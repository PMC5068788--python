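"""Monte-Carlo stability selection of marker features.

Repeatedly (default 200 times) draw a random subset of the samples — each
sample included independently with probability 0.70 — refit the full
constrained model on the subset, predict the excluded samples, and rank the
features by the magnitude of their regression coefficient for the case
class.  The top 50 features of each model count as "selected"; the final
marker panel keeps the features selected in strictly more than 90% of the
successfully fitted models.  Out-of-subsample ROC statistics (AUC,
specificity, sensitivity at the closest-to-top-left threshold) are averaged
across subsets as the honest estimate of predictive performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import fit_cpls
from .validation import _fold_constraints, _fold_pretreat, _prepare_blocks, roc_analysis
from .datagen import SimulationDesign, simulate_dataset

__all__ = [
    "StabilityConfig",
    "StabilityResult",
    "RecoveryResult",
    "stability_select",
    "panel_from_frequencies",
    "recovery_experiment",
]


@dataclass(frozen=True)
class StabilityConfig:
    """Monte-Carlo stability-selection settings.

    ``inclusion_prob`` is the per-sample inclusion probability of each
    Monte-Carlo draw (set ``fixed_fraction=True`` for a fixed-size 70%
    subsample instead); ``top_k`` features are taken per model by
    |regression coefficient|; the panel keeps features with selection
    frequency strictly greater than ``freq_threshold``.
    """

    n_subsets: int = 200
    inclusion_prob: float = 0.70
    top_k: int = 50
    freq_threshold: float = 0.90
    seed: int = 0
    fixed_fraction: bool = False
    min_class_count: int = 3

    def __post_init__(self):
        if not 0 < self.inclusion_prob < 1:
            raise ValueError("inclusion_prob must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 < self.freq_threshold < 1:
            raise ValueError("freq_threshold must lie in (0, 1)")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")


@dataclass
class StabilityResult:
    selection_freq: pd.Series
    panel: list
    mean_auc: float
    mean_sensitivity: float
    mean_specificity: float
    n_models_fitted: int
    n_roc_evaluated: int

    def to_dict(self) -> dict:
        return {
            "panel": [str(f) for f in self.panel],
            "mean_auc": self.mean_auc,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "n_models_fitted": self.n_models_fitted,
            "n_roc_evaluated": self.n_roc_evaluated,
        }

    def frequencies_frame(self) -> pd.DataFrame:
        return (self.selection_freq.rename("selection_freq").rename_axis("feature")
                .sort_values(ascending=False, kind="stable").reset_index())


def panel_from_frequencies(freq: pd.Series | np.ndarray, threshold: float = 0.90) -> list:
    """Apply the strict selection rule: keep features with freq > threshold."""
    s = pd.Series(freq) if not isinstance(freq, pd.Series) else freq
    return s.index[s.to_numpy() > threshold].tolist()


def _draw_subset(rng, is_case, cfg: StabilityConfig) -> np.ndarray:
    n = len(is_case)
    for _ in range(100):
        if cfg.fixed_fraction:
            k = max(1, int(round(cfg.inclusion_prob * n)))
            inc = np.zeros(n, dtype=bool)
            inc[rng.choice(n, size=k, replace=False)] = True
        else:
            inc = rng.random(n) < cfg.inclusion_prob
        if (is_case & inc).sum() >= cfg.min_class_count and \
           (~is_case & inc).sum() >= cfg.min_class_count:
            return inc
    raise ValueError(
        "could not draw a subset with at least "
        f"{cfg.min_class_count} samples per class in 100 attempts"
    )


def stability_select(X, labels, n_components, constraints=None,
                     config: StabilityConfig | None = None,
                     pretreatment=None, case_label=None) -> StabilityResult:
    """Monte-Carlo stability selection with out-of-subsample ROC.

    For each subset the whole pipeline (pretreatment, constraint centering,
    oCPLS2-DA at the same number of components) is refit; excluded samples
    are predicted and scored.  Selection frequencies are divided by the
    number of successfully fitted models.
    """
    cfg = config or StabilityConfig()
    spec, L, is_case, Z0 = _prepare_blocks(X, labels, constraints, pretreatment, case_label)
    n, p = L.shape
    feat_index = (X.columns if isinstance(X, pd.DataFrame)
                  else pd.RangeIndex(p))
    if p < cfg.top_k:
        warnings.warn(
            f"top_k={cfg.top_k} is not below the feature count ({p}); "
            "every feature is selected by every model", UserWarning, stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    Yind = np.column_stack([(~is_case).astype(float), is_case.astype(float)])
    counts = np.zeros(p)
    aucs, sens, spes = [], [], []
    n_fitted = 0
    for _ in range(cfg.n_subsets):
        inc = _draw_subset(rng, is_case, cfg)
        train = np.flatnonzero(inc)
        test = np.flatnonzero(~inc)
        Et, Eh = _fold_pretreat(L, train, test, spec)
        Z = _fold_constraints(Z0, train)
        ymean = Yind[train].mean(axis=0)
        a_eff = max(1, min(n_components, len(train) - 1 - (Z.shape[1] if Z is not None else 0), p))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                lm = fit_cpls(Et, Yind[train] - ymean, Z, a_eff, check_rank=False)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"subset fit skipped: {exc}", UserWarning, stacklevel=2)
            continue
        n_fitted += 1
        order = np.argsort(-np.abs(lm.B[:, 1]), kind="stable")
        counts[order[:cfg.top_k]] += 1
        if len(test) and is_case[test].any() and (~is_case[test]).any():
            yhat = Eh @ lm.B + ymean
            roc = roc_analysis(yhat[:, 1], is_case[test])
            aucs.append(roc.auc); sens.append(roc.sensitivity); spes.append(roc.specificity)
    if n_fitted == 0:
        raise ValueError("no stability-selection model could be fitted")
    freq = pd.Series(counts / n_fitted, index=feat_index)
    panel = panel_from_frequencies(freq, cfg.freq_threshold)
    return StabilityResult(
        freq, panel,
        float(np.mean(aucs)) if aucs else float("nan"),
        float(np.mean(sens)) if sens else float("nan"),
        float(np.mean(spes)) if spes else float("nan"),
        n_fitted, len(aucs),
    )


# ---------------------------------------------------------------------------
# Recovery experiment: the module's validation harness
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    recall: float
    false_panel: int
    panel_constrained: list
    panel_unconstrained: list
    freq_confounded_constrained: float
    freq_confounded_unconstrained: float
    truth: object = field(repr=False, default=None)


def recovery_experiment(design: SimulationDesign,
                        config: StabilityConfig | None = None,
                        n_components: int = 2,
                        constraint_cols=("maternal_age",)) -> RecoveryResult:
    """Simulate a dataset and run stability selection with and without
    constraints, reporting marker recall, false-panel count and the mean
    selection frequency of confounder-only features under each regime."""
    if design.n_markers < 1:
        raise ValueError("recovery_experiment requires n_markers >= 1")
    table, meta, truth = simulate_dataset(design)
    cfg = config or StabilityConfig()
    cons = meta[list(constraint_cols)]
    from .datagen import CASE_CLASS
    res_c = stability_select(table, meta["group"], n_components, cons, cfg,
                             case_label=CASE_CLASS)
    res_u = stability_select(table, meta["group"], n_components, None, cfg,
                             case_label=CASE_CLASS)
    markers = set(truth.marker_ids) | set(truth.both_ids)
    panel_c = set(res_c.panel)
    recall = len(panel_c & set(truth.marker_ids)) / max(len(truth.marker_ids), 1)
    false_panel = len(panel_c - markers)
    conf = truth.confounded_ids
    fc = float(res_c.selection_freq[conf].mean()) if conf else float("nan")
    fu = float(res_u.selection_freq[conf].mean()) if conf else float("nan")
    return RecoveryResult(recall, false_panel, res_c.panel, res_u.panel, fc, fu, truth)
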