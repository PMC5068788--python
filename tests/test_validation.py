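"""Cross-validation, permutation testing, ROC and the confounding screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ocplsda import (
    SimulationDesign,
    confounding_screen,
    cross_validate,
    external_factor_check,
    inject_binary_factor,
    permutation_test,
    roc_analysis,
    simulate_dataset,
    validation_report,
)
from ocplsda.validation import auc_mann_whitney, delong_ci, stratified_folds

from _oracles import auc_pair_count, q2_explicit_loop


# ---------------------------------------------------------------------------
# Q²
# ---------------------------------------------------------------------------

def test_q2_matches_explicit_loop_oracle(case_label):
    table, meta, _ = simulate_dataset(
        SimulationDesign(n_per_group=6, n_features=20, n_markers=4,
                         marker_effect=1.5, n_confounded=0, seed=9))
    is_case = (meta["group"] == case_label).to_numpy()
    res = cross_validate(table, meta["group"], 2, n_folds=4, seed=5,
                         case_label=case_label)
    folds = stratified_folds(is_case, 4, np.random.default_rng(5))
    q2_oracle = q2_explicit_loop(table.to_numpy(), is_case, folds, 2)
    assert res.q2 == pytest.approx(q2_oracle, abs=1e-10)


def test_strong_signal_q2_above_half(case_label):
    table, meta, _ = simulate_dataset(
        SimulationDesign(n_per_group=12, n_features=300, n_markers=20,
                         n_confounded=0, marker_effect=3.0, seed=4))
    for nf in (6, 7, 8):
        assert cross_validate(table, meta["group"], 2, n_folds=nf, seed=0,
                              case_label=case_label).q2 > 0.5


def test_pure_noise_q2_mostly_nonpositive(case_label):
    neg = 0
    for s in range(50):
        table, meta, _ = simulate_dataset(
            SimulationDesign(n_per_group=30, n_features=60, n_markers=0,
                             n_confounded=0, marker_effect=0.0, seed=9000 + s))
        if cross_validate(table, meta["group"], 2, n_folds=7, seed=s,
                          case_label=case_label).q2 <= 0:
            neg += 1
    assert neg >= 45


def test_q2_not_above_r2(small_dataset, case_label):
    table, meta, _ = small_dataset
    rep = validation_report(table, meta["group"], 3,
                            meta[["maternal_age", "maternal_bmi"]],
                            n_permutations=5, seed=0, case_label=case_label)
    for q2 in rep.q2_by_folds.values():
        assert q2 <= rep.r2 + 1e-12
    assert 0 < rep.perm_pvalue <= 1


def test_single_class_training_fold_rejected():
    is_case = np.array([True] * 1 + [False] * 9)
    with pytest.raises(ValueError):
        # 2 folds and a lone case sample: one training part must lose the case
        stratified_folds(is_case[:2], 2, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def test_permutation_floor(case_label):
    """Observed Q² above every permuted value gives p = 1/(n_perm+1)."""
    table, meta, _ = simulate_dataset(
        SimulationDesign(n_per_group=10, n_features=200, n_markers=25,
                         n_confounded=0, marker_effect=3.0, seed=10))
    p = permutation_test(table, meta["group"], 2, n_folds=7,
                         n_permutations=20, seed=2, case_label=case_label)
    assert p == pytest.approx(1 / 21)


def test_permutation_pvalue_count_formula(case_label):
    table, meta, _ = simulate_dataset(
        SimulationDesign(n_per_group=8, n_features=50, n_markers=5,
                         marker_effect=1.0, n_confounded=0, seed=11))
    p, q2_obs, null = permutation_test(table, meta["group"], 2, n_folds=5,
                                       n_permutations=49, seed=3,
                                       case_label=case_label, return_null=True)
    assert p == ((null >= q2_obs - 1e-12).sum() + 1) / 50


def test_permutation_invariant_to_class_relabeling(small_dataset, case_label):
    table, meta, _ = small_dataset
    relabeled = meta["group"].map({"TD": "groupA", "PTD": "groupB"})
    p1 = permutation_test(table, meta["group"], 2, n_permutations=30, seed=7,
                          case_label=case_label)
    p2 = permutation_test(table, relabeled, 2, n_permutations=30, seed=7,
                          case_label="groupB")
    assert p1 == p2


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_roc_perfect_separation():
    roc = roc_analysis([1, 2, 3, 4], np.array([False, False, True, True]))
    assert (roc.auc, roc.sensitivity, roc.specificity) == (1.0, 1.0, 1.0)


def test_roc_interleaved_hand_example():
    """{1,3} vs {2,4}: 3 concordant of 4 pairs; top-left tie-break -> Se=1."""
    roc = roc_analysis([1, 3, 2, 4], np.array([False, False, True, True]))
    assert roc.auc == pytest.approx(0.75)
    assert roc.sensitivity == 1.0 and roc.specificity == 0.5


def test_roc_all_ties_gives_half():
    roc = roc_analysis([2.0, 2.0, 2.0, 2.0], np.array([False, True, False, True]))
    assert roc.auc == pytest.approx(0.5)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        roc_analysis([1, 2], np.array([True, True]))


def test_roc_curve_endpoints_and_monotone(rng):
    scores = rng.standard_normal(30)
    labels = rng.random(30) < 0.5
    labels[0], labels[1] = True, False
    roc = roc_analysis(scores, labels)
    curve = np.array(roc.curve)
    assert tuple(curve[0]) == (0.0, 0.0) and tuple(curve[-1]) == (1.0, 1.0)
    assert (np.diff(curve[:, 0]) >= -1e-12).all() and (np.diff(curve[:, 1]) >= -1e-12).all()
    lo, hi = roc.auc_ci95
    assert lo <= roc.auc <= hi


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.integers(-5, 5), min_size=2, max_size=12),
       st.data())
def test_auc_equals_pair_counting(scores, data):
    labels = data.draw(st.lists(st.booleans(), min_size=len(scores),
                                max_size=len(scores)))
    labels = np.asarray(labels)
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    assert auc_mann_whitney(np.asarray(scores, float), labels) == pytest.approx(
        auc_pair_count(scores, labels), abs=1e-12)


def test_delong_ci_narrows_with_replication(rng):
    """Duplicating the data shrinks the DeLong interval around the same AUC."""
    scores = rng.standard_normal(24) + np.repeat([0.0, 1.0], 12)
    labels = np.repeat([False, True], 12)
    lo1, hi1 = delong_ci(scores, labels)
    lo2, hi2 = delong_ci(np.tile(scores, 2), np.tile(labels, 2))
    assert (hi2 - lo2) < (hi1 - lo1)
    assert lo2 >= 0 and hi2 <= 1


# ---------------------------------------------------------------------------
# Confounding screen & external factor
# ---------------------------------------------------------------------------

def test_screen_declares_no_confounding_on_independent_metadata():
    ok = 0
    for s in range(50):
        _, meta, _ = simulate_dataset(
            SimulationDesign(n_per_group=30, n_features=5, n_markers=0,
                             n_confounded=0, confounder_class_assoc=0.0,
                             seed=500 + s))
        rep = confounding_screen(meta.drop(columns="group"), meta["group"], seed=s)
        ok += rep.no_confounding
    assert ok >= 45


def test_screen_flags_leaked_class_label(small_dataset, case_label):
    _, meta, _ = small_dataset
    leaky = meta.drop(columns="group").copy()
    leaky["leak"] = (meta["group"] == case_label).astype(float)
    rep = confounding_screen(leaky, meta["group"], seed=0)
    assert rep.confounded and rep.metadata_q2 > 0.3


def test_screen_drops_constant_covariates(small_dataset):
    _, meta, _ = small_dataset
    m = meta.drop(columns="group").copy()
    m["const"] = 1.0
    rep = confounding_screen(m, meta["group"], seed=0)
    assert "const" in rep.dropped


def test_external_factor_positive_control(small_dataset, case_label):
    from ocplsda import OCPLSDA
    table, meta, _ = small_dataset
    res = OCPLSDA(table, meta["group"], n_components=3, case_label=case_label).fit()
    r, p = res.external_factor_check((meta["group"] == case_label).astype(int))
    assert abs(r) > 0.5 and p < 0.01
    # factor = predictive score dichotomized at the median correlates positively
    t = res.predictive_score[:, 0]
    r2, _ = external_factor_check(res, (t > np.median(t)).astype(int))
    assert r2 > 0
    with pytest.raises(ValueError, match="constant"):
        external_factor_check(res, np.ones(len(table)))


def test_external_factor_null_calibration(small_dataset, case_label):
    from ocplsda import OCPLSDA
    table, meta, _ = small_dataset
    res = OCPLSDA(table, meta["group"], n_components=3, case_label=case_label).fit()
    hits = 0
    n_rep = 200
    for s in range(n_rep):
        factor = inject_binary_factor(meta, 0.4, seed=s)["chorioamnionitis"]
        if factor.nunique() < 2:
            continue
        _, p = res.external_factor_check(factor)
        hits += p <= 0.05
    assert 0.01 <= hits / n_rep <= 0.10
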