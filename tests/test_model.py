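"""Latent-variable core: PLS2-DA, constrained fits, post-transformation, PCA."""

import numpy as np
import pandas as pd
import pytest

from ocplsda import (
    OCPLSDA,
    fit_ocpls2da,
    fit_pca,
    fit_pls2da,
    make_response,
    post_transform,
)
from ocplsda.model import fit_cpls

from _oracles import nipals_pls2_eigen, sign_fix


def _random_blocks(rng, n=10, p=6):
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    resp = make_response(labels)
    return X, resp


def test_single_feature_pls_equals_ols(rng):
    X = rng.standard_normal((12, 1))
    X -= X.mean(axis=0)
    _, resp = _random_blocks(rng, 12, 1)
    lm = fit_pls2da(X, resp, 1)
    beta = np.linalg.lstsq(X, resp.centered, rcond=None)[0]
    np.testing.assert_allclose(X @ lm.B, X @ beta, atol=1e-10)


def test_first_weight_matches_eigen_oracle(rng):
    X, resp = _random_blocks(rng, 8, 5)
    lm = fit_pls2da(X, resp, 2)
    M = X.T @ resp.centered
    _, evecs = np.linalg.eigh(M @ M.T)
    w_oracle = sign_fix(evecs[:, -1])
    np.testing.assert_allclose(lm.W[:, 0], w_oracle, atol=1e-8)


def test_full_rank_r2_equals_multivariate_ols(rng):
    X, resp = _random_blocks(rng, 10, 4)
    lm = fit_pls2da(X, resp, 4)
    Yhat = X @ np.linalg.lstsq(X, resp.centered, rcond=None)[0]
    r2_ols = 1 - ((resp.centered - Yhat) ** 2).sum() / (resp.centered ** 2).sum()
    assert lm.r2 == pytest.approx(r2_ols, abs=1e-8)


def test_r2_nondecreasing_in_components(rng):
    X, resp = _random_blocks(rng, 14, 9)
    r2s = [fit_pls2da(X, resp, a).r2 for a in range(1, 5)]
    assert all(b >= a - 1e-10 for a, b in zip(r2s, r2s[1:]))


def test_component_count_exceeding_rank_raises(rng):
    X, resp = _random_blocks(rng, 6, 4)
    with pytest.raises(ValueError, match="n_components"):
        fit_pls2da(X, resp, 6)


def test_empty_constraint_reduces_to_pls(rng):
    for _ in range(10):
        X, resp = _random_blocks(rng, 12, 8)
        a = fit_pls2da(X, resp, 3)
        b = fit_ocpls2da(X, resp, np.empty((12, 0)), 3)
        np.testing.assert_allclose(a.T, b.T, atol=1e-8)
        np.testing.assert_allclose(a.B, b.B, atol=1e-8)


def test_constraint_identity(rng):
    X, resp = _random_blocks(rng, 16, 10)
    Z = rng.standard_normal((16, 3))
    Z -= Z.mean(axis=0)
    lm = fit_ocpls2da(X, resp, Z, 3)
    for a in range(lm.n_components):
        t = lm.T[:, a]
        assert np.max(np.abs(Z.T @ t)) <= 1e-8 * np.linalg.norm(Z) * np.linalg.norm(t)


def test_rank_deficient_constraints_rejected(rng):
    X, resp = _random_blocks(rng, 12, 6)
    z = rng.standard_normal(12)
    Z = np.column_stack([z, 2 * z])
    Z -= Z.mean(axis=0)
    with pytest.raises(ValueError, match="rank deficient"):
        fit_ocpls2da(X, resp, Z, 2)


def test_constraining_on_the_outcome_destroys_discrimination(small_dataset, case_label):
    """Using the class dummy itself as the constraint removes all class signal."""
    from ocplsda import cross_validate
    table, meta, _ = small_dataset
    case = (meta["group"] == case_label).to_numpy().astype(float)
    Z = (case - case.mean()).reshape(-1, 1)
    import scipy.stats
    from ocplsda.pretreat import Pretreatment
    Xt = Pretreatment().fit_transform(table)
    resp = make_response(meta["group"], case_label)
    lm = fit_ocpls2da(Xt, resp, Z, 2)
    t1 = lm.T[:, 0]
    tstat = scipy.stats.ttest_ind(t1[case == 1], t1[case == 0]).statistic
    assert abs(tstat) < 1e-6
    q2 = cross_validate(table, meta["group"], 2, constraints=Z,
                        case_label=case_label, seed=0).q2
    assert q2 <= 0


# ---------------------------------------------------------------------------
# post-transformation
# ---------------------------------------------------------------------------

def _fitted_and_rotated(rng, n=14, p=9, A=3, with_z=True):
    X, resp = _random_blocks(rng, n, p)
    Z = None
    if with_z:
        Z = rng.standard_normal((n, 2))
        Z -= Z.mean(axis=0)
    lm = fit_cpls(X, resp.centered, Z, A)
    return X, resp, Z, lm, post_transform(lm, resp)


def test_post_transform_invariances(rng):
    X, resp, Z, lm, rot = _fitted_and_rotated(rng)
    # fitted response and X-reconstruction unchanged
    np.testing.assert_allclose(rot.T @ rot.C.T, lm.T @ lm.C.T, atol=1e-10)
    np.testing.assert_allclose(rot.T @ rot.P.T, lm.T @ lm.P.T, atol=1e-10)
    # B recomputed from the rotated factors equals the original B
    B_rot = rot.W @ np.linalg.solve(rot.P.T @ rot.W, rot.C.T)
    np.testing.assert_allclose(B_rot, lm.B, atol=1e-10)


def test_post_transform_predictive_orthogonal_split(rng):
    X, resp, Z, lm, rot = _fitted_and_rotated(rng)
    assert rot.n_pred == 1 and rot.n_orth == 2        # "1+2" for two-class Y
    # Y-orthogonal scores are uncorrelated with each centered response column
    for a in range(rot.n_pred, rot.n_components):
        np.testing.assert_allclose(rot.T[:, a] @ resp.centered, 0, atol=1e-8)
    # trailing Y-loadings vanish
    np.testing.assert_allclose(rot.C[:, rot.n_pred:], 0, atol=1e-8)
    # constraints still respected after rotation
    assert np.max(np.abs(Z.T @ rot.T)) <= 1e-8 * np.linalg.norm(Z) * np.linalg.norm(rot.T)
    # rotated scores remain mutually orthogonal
    G = rot.T.T @ rot.T
    np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)


def test_post_transform_no_y_correlation_warns(rng):
    X = rng.standard_normal((10, 5))
    X -= X.mean(axis=0)
    lm = fit_cpls(X, X[:, :2] * 0.1, None, 2)
    with pytest.warns(UserWarning, match="A_pred = 0"):
        rot = post_transform(lm, np.zeros((10, 2)))
    assert rot.n_pred == 0


# ---------------------------------------------------------------------------
# prediction via the modelling surface
# ---------------------------------------------------------------------------

def test_predict_training_reproduces_fit(small_dataset, case_label):
    table, meta, _ = small_dataset
    res = OCPLSDA(table, meta["group"], n_components=3, case_label=case_label).fit()
    pred = res.predict(table)
    fitted = res.pretreatment.transform(table) @ res.latent.B + res.response.mean
    np.testing.assert_allclose(pred[["yhat_TD", "yhat_PTD"]].to_numpy()[:, 0],
                               fitted[:, 0], atol=1e-10)
    # duplicated rows get identical predictions
    dup = pd.concat([table.iloc[[0]], table.iloc[[0]]])
    pd.testing.assert_frame_equal(res.predict(dup).iloc[[0]].reset_index(drop=True),
                                  res.predict(dup).iloc[[1]].reset_index(drop=True))


def test_predict_feature_mismatch_raises(small_dataset, case_label):
    table, meta, _ = small_dataset
    res = OCPLSDA(table, meta["group"], n_components=2, case_label=case_label).fit()
    with pytest.raises(ValueError, match="feature mismatch"):
        res.predict(table.iloc[:, :-1])


def test_heldout_accuracy_with_strong_markers(case_label):
    """Strong synthetic signal yields > 80% held-out accuracy in 6-fold CV."""
    from ocplsda import SimulationDesign, cross_validate, simulate_dataset
    table, meta, _ = simulate_dataset(
        SimulationDesign(n_per_group=12, n_features=500, n_markers=20,
                         n_confounded=0, marker_effect=2.0, seed=21))
    res = cross_validate(table, meta["group"], 2, n_folds=6, seed=0,
                         case_label=case_label)
    calls = res.cv_scores > 0.5
    assert (calls == res.is_case).mean() > 0.8


def test_summary_mentions_structure(small_dataset, case_label):
    table, meta, _ = small_dataset
    cons = meta[["maternal_age", "maternal_bmi"]]
    res = OCPLSDA(table, meta["group"], constraints=cons, n_components=3,
                  case_label=case_label).fit()
    s = res.summary()
    assert "1+2" in s and "R2" in s and "constraints: 2" in s


def test_serialization_round_trip(tmp_path, small_dataset, case_label):
    import json
    table, meta, _ = small_dataset
    res = OCPLSDA(table, meta["group"], n_components=2, case_label=case_label).fit()
    res.save(tmp_path / "model.json")
    with open(tmp_path / "model.json") as fh:
        d = json.load(fh)
    np.testing.assert_allclose(np.array(d["B"]), res.latent.B)
    assert d["n_pred"] == res.n_pred


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_explains_everything(rng):
    u = rng.standard_normal(9)
    v = rng.standard_normal(4)
    X = np.outer(u, v)
    pca = fit_pca(X, 2)
    assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_matches_eigendecomposition(rng):
    X = rng.standard_normal((15, 6))
    pca = fit_pca(X)
    S = np.cov(X, rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(S))[::-1]
    np.testing.assert_allclose(pca.explained_variance_ratio,
                               evals[:len(pca.explained_variance_ratio)] / evals.sum(),
                               atol=1e-10)
    # loadings orthonormal, fractions nonincreasing and summing to <= 1
    np.testing.assert_allclose(pca.loadings.T @ pca.loadings,
                               np.eye(pca.loadings.shape[1]), atol=1e-10)
    evr = pca.explained_variance_ratio
    assert all(b <= a + 1e-12 for a, b in zip(evr, evr[1:])) and evr.sum() <= 1 + 1e-12


def test_pca_column_permutation_invariant_spectrum(rng):
    X = rng.standard_normal((10, 5))
    perm = rng.permutation(5)
    np.testing.assert_allclose(fit_pca(X).explained_variance_ratio,
                               fit_pca(X[:, perm]).explained_variance_ratio, atol=1e-10)


def test_pls_matches_full_eigen_oracle_with_deflation(rng):
    X, resp = _random_blocks(rng, 12, 7)
    lm = fit_pls2da(X, resp, 3)
    W, T, P, C, B = nipals_pls2_eigen(X, resp.centered, 3)
    np.testing.assert_allclose(lm.W, W, atol=1e-8)
    np.testing.assert_allclose(lm.T, T, atol=1e-8)
    np.testing.assert_allclose(lm.B, B, atol=1e-8)
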