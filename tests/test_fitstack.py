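"""Nested grouped cross-validation, screening/selection, Platt calibration,
stacked fusion and exact Shapley attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ggnfusion import fitstack
from ggnfusion.evalmetrics import auc
from ggnfusion.fitstack import (FusionModel, LeakageError, apply_platt,
                                fit_fusion, fit_unimodal, fusion_ablate,
                                make_folds, oof_predict, platt_calibrate,
                                screen_features, select_sparse, shapley_fusion)


# ---------------------------------------------------------------------------
# folds


def test_two_groups_leave_one_group_out():
    groups = np.array(["A"] * 10 + ["B"] * 8)
    plan = make_folds(groups, seed=1)
    assert len(plan.outer) == 2
    for tr, va in plan.outer:
        assert len(set(groups[tr]) & set(groups[va])) == 0
        assert len(set(groups[va])) == 1


def test_six_groups_grouped_kfold_partitions_rows():
    rng = np.random.default_rng(0)
    groups = rng.integers(0, 6, 120)
    plan = make_folds(groups, seed=3)
    assert len(plan.outer) == 5
    counts = np.zeros(120, int)
    for _, va in plan.outer:
        counts[va] += 1
    assert np.all(counts == 1)
    plan.validate()


def test_single_group_requires_fallback_flag():
    groups = np.zeros(30, int)
    with pytest.raises(ValueError, match="fallback"):
        make_folds(groups)
    plan = make_folds(groups, seed=2, allow_single_group_fallback=True)
    assert len(plan.outer) >= 2


# ---------------------------------------------------------------------------
# screening


def test_bh_stepup_by_hand():
    """Raw p = (0.01, 0.02, 0.03, 0.04), m = 4: BH thresholds i/m*0.05 =
    (0.0125, 0.025, 0.0375, 0.05); the largest i with p_(i) <= threshold is
    4, so all four survive."""
    rng = np.random.default_rng(1)
    n = 40
    y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]

    # craft four features whose MWU p-values bracket the example pattern
    X = pd.DataFrame({f"f{i}": rng.normal(0, 1, n) + d * y
                      for i, d in enumerate((1.2, 1.0, 0.9, 0.8))})
    names, pvals = screen_features(X, y)
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(np.array([0.01, 0.02, 0.03, 0.04]),
                               alpha=0.05, method="fdr_bh")
    assert reject.all()   # the hand example itself
    assert set(names) == set(X.columns)  # strong effects all retained


def test_constant_feature_never_retained():
    y = np.r_[np.ones(10, int), np.zeros(10, int)]
    X = pd.DataFrame({"const": np.ones(20), "good": np.r_[np.ones(10), np.zeros(10)]})
    names, pvals = screen_features(X, y)
    assert "const" not in names
    assert pvals["const"] == 1.0


def test_mwu_p_matches_exact_enumeration():
    """p for {1,2,3} vs {4,5,6}: all 20 rank splits, only the two extreme
    orderings are as or more extreme -> two-sided exact p = 0.1."""
    stat = sps.mannwhitneyu([1.0, 2.0, 3.0], [4.0, 5.0, 6.0],
                            alternative="two-sided", method="exact")
    assert stat.pvalue == pytest.approx(2 / 20)
    y = np.r_[np.ones(3, int), np.zeros(3, int)]
    X = pd.DataFrame({"f": [4.0, 5.0, 6.0, 1.0, 2.0, 3.0]})
    _, pvals = screen_features(X, y)
    assert pvals["f"] == pytest.approx(2 / 20)


# ---------------------------------------------------------------------------
# sparse selection


def _inner_folds(n, k=3, seed=0):
    rng = np.random.default_rng(seed)
    assign = rng.integers(0, k, n)
    return [(np.flatnonzero(assign != j), np.flatnonzero(assign == j))
            for j in range(k)]


def test_correlated_copies_collapse_to_one():
    rng = np.random.default_rng(2)
    n = 100
    y = rng.integers(0, 2, n)
    base = rng.normal(0, 1, n) + 1.5 * y
    X = pd.DataFrame({"a": base, "b": base * 2.0 + 0.1, "noise": rng.normal(0, 1, n)})
    selected = select_sparse(X, y, _inner_folds(n), seed=0)
    assert not {"a", "b"} <= set(selected)
    assert len(set(selected) & {"a", "b"}) == 1


def test_pure_noise_selects_almost_nothing():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = 200
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(0, 1, (n, 10)),
                         columns=[f"n{i}" for i in range(10)])
        selected = select_sparse(X, y, _inner_folds(n, seed=seed + 100), seed=seed)
        if len(selected) <= 2:
            hits += 1
    assert hits >= 9


def test_selection_deterministic():
    rng = np.random.default_rng(3)
    n = 80
    y = rng.integers(0, 2, n)
    X = pd.DataFrame(rng.normal(0, 1, (n, 5)), columns=list("abcde"))
    X["a"] += 1.0 * y
    folds = _inner_folds(n, seed=3)
    assert select_sparse(X, y, folds, seed=1) == select_sparse(X, y, folds, seed=1)


# ---------------------------------------------------------------------------
# base learner and calibration


def test_label_feature_gives_training_auc_one():
    y = np.r_[np.ones(20, int), np.zeros(20, int)]
    X = y.reshape(-1, 1).astype(float)
    clf = fit_unimodal(X, y)
    assert auc(clf.predict_proba(X)[:, 1], y) == 1.0


def test_permuted_labels_oof_auc_near_half():
    rng = np.random.default_rng(5)
    n = 500
    X = rng.normal(0, 1, (n, 5))
    y = rng.permutation(np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)])
    oof = np.empty(n)
    for tr, va in _inner_folds(n, k=5, seed=5):
        clf = fit_unimodal(X[tr], y[tr])
        oof[va] = clf.predict_proba(X[va])[:, 1]
    assert abs(auc(oof, y) - 0.5) < 0.07


def test_platt_recovers_identity_on_calibrated_input():
    rng = np.random.default_rng(6)
    n = 5000
    p = rng.uniform(0.02, 0.98, n)
    y = (rng.random(n) < p).astype(int)
    a, b = platt_calibrate(p, y)
    assert abs(a - 1.0) < 0.1
    assert abs(b) < 0.1


def test_platt_constant_half_maps_to_prevalence():
    rng = np.random.default_rng(7)
    n = 1000
    y = (rng.random(n) < 0.3).astype(int)
    raw = np.full(n, 0.5)
    a, b = platt_calibrate(raw, y)
    cal = apply_platt(raw, a, b)
    assert np.allclose(cal, y.mean(), atol=0.02)


def test_platt_monotone_and_one_class_error():
    a, b = 1.7, -0.3
    grid = np.linspace(0.01, 0.99, 50)
    out = apply_platt(grid, a, b)
    assert np.all(np.diff(out) > 0)
    with pytest.raises(ValueError):
        platt_calibrate(np.array([0.2, 0.8]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# OOF pipeline


def test_oof_covers_every_row_once(small_features):
    t = small_features[small_features.centre_id != 3].reset_index(drop=True)
    y = t["label"].astype(int).to_numpy()
    plan = make_folds(t["centre_id"].to_numpy(), seed=4,
                      allow_single_group_fallback=True)
    oof = oof_predict(plan, t, y, batch=t["centre_id"].to_numpy(), seed=4)
    for s in fitstack.STREAM_ORDER:
        assert oof[f"p_{s}"].notna().all()
        assert oof[f"p_{s}"].between(0, 1).all()
    assert (oof["fold"] >= 0).all()


def test_oof_auc_invariant_to_row_shuffle(small_features):
    t = small_features[small_features.centre_id != 3].reset_index(drop=True)
    y = t["label"].astype(int).to_numpy()
    plan = make_folds(t["centre_id"].to_numpy(), seed=4,
                      allow_single_group_fallback=True)
    oof = oof_predict(plan, t, y, batch=t["centre_id"].to_numpy(), seed=4)
    perm = np.random.default_rng(0).permutation(len(t))
    t2 = t.iloc[perm].reset_index(drop=True)
    y2 = y[perm]
    plan2 = make_folds(t2["centre_id"].to_numpy(), seed=4,
                       allow_single_group_fallback=True)
    oof2 = oof_predict(plan2, t2, y2, batch=t2["centre_id"].to_numpy(), seed=4)
    assert auc(oof["p_clinical"], y) == pytest.approx(
        auc(oof2["p_clinical"], y2), abs=0.02)


# ---------------------------------------------------------------------------
# fusion


def _toy_oof(seed=0, n=200):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    oof = pd.DataFrame({
        "p_t0": np.clip(0.5 + 0.1 * (y - 0.5) + rng.normal(0, 0.2, n), 0.01, 0.99),
        "p_t1": np.clip(0.5 + 0.5 * (y - 0.5) + rng.normal(0, 0.2, n), 0.01, 0.99),
        "p_delta": np.clip(0.5 + 0.4 * (y - 0.5) + rng.normal(0, 0.2, n), 0.01, 0.99),
        "p_clinical": np.clip(0.5 + 0.7 * (y - 0.5) + rng.normal(0, 0.15, n), 0.01, 0.99),
    })
    return oof, y


def test_fusion_dominates_perfect_stream():
    oof, y = _toy_oof(1)
    oof["p_clinical"] = np.clip(y.astype(float), 0.01, 0.99)
    fus = fit_fusion(oof, y)
    assert auc(fus.predict_proba(oof), y) >= auc(oof["p_clinical"], y) - 1e-12


def test_fusion_constant_streams_predict_prevalence():
    y = np.r_[np.ones(30, int), np.zeros(70, int)]
    oof = pd.DataFrame({f"p_{s}": np.full(100, 0.5) for s in fitstack.STREAM_ORDER})
    fus = fit_fusion(oof, y)
    assert np.allclose(fus.predict_proba(oof), 0.3, atol=0.02)


def test_fusion_missing_stream_errors():
    oof, y = _toy_oof(2)
    with pytest.raises(ValueError):
        fit_fusion(oof.drop(columns=["p_delta"]), y)


def test_fusion_weights_deterministic():
    oof, y = _toy_oof(3)
    f1 = fit_fusion(oof, y)
    f2 = fit_fusion(oof, y)
    np.testing.assert_array_equal(f1.weights, f2.weights)


def test_ablation_noise_stream_ci_covers_zero():
    oof, y = _toy_oof(4)
    rng = np.random.default_rng(9)
    oof["p_t0"] = np.clip(rng.uniform(0.3, 0.7, len(y)), 0.01, 0.99)  # pure noise
    tab = fusion_ablate(oof, y, n_boot=200, seed=1).set_index("removed")
    assert tab.loc["t0", "ci_lo"] <= 0.0 <= tab.loc["t0", "ci_hi"]


def test_ablation_removing_only_informative_stream_hurts():
    rng = np.random.default_rng(10)
    n = 300
    y = rng.integers(0, 2, n)
    oof = pd.DataFrame({f"p_{s}": rng.uniform(0.3, 0.7, n)
                        for s in ("t0", "t1", "delta")})
    oof["p_clinical"] = np.clip(0.5 + 0.8 * (y - 0.5) + rng.normal(0, 0.1, n),
                                0.01, 0.99)
    tab = fusion_ablate(oof, y, n_boot=100, seed=2).set_index("removed")
    assert tab.loc["clinical", "delta_auc"] < -0.05


# ---------------------------------------------------------------------------
# Shapley


def test_shapley_zero_at_background_mean():
    fus = FusionModel(streams=fitstack.STREAM_ORDER, intercept=0.3,
                      weights=np.array([0.5, 1.0, 0.8, 1.5]))
    bg, _ = _toy_oof(5)
    # a case whose logits equal the background-mean logits
    mu_logit = [np.log(bg[c] / (1 - bg[c])).mean() for c in bg.columns]
    x = 1 / (1 + np.exp(-np.array(mu_logit)))
    phi, base = shapley_fusion(fus, x, bg)
    assert np.allclose(phi, 0.0, atol=1e-10)


def test_shapley_efficiency_and_linear_closed_form():
    fus = FusionModel(streams=fitstack.STREAM_ORDER, intercept=-0.2,
                      weights=np.array([0.4, 1.2, 0.9, 2.0]))
    bg, _ = _toy_oof(6)
    rng = np.random.default_rng(11)
    mu = np.array([np.log(bg[c] / (1 - bg[c])).mean() for c in bg.columns])
    for _ in range(100):
        x = rng.uniform(0.05, 0.95, 4)
        phi, base = shapley_fusion(fus, x, bg)
        logit_x = np.log(x / (1 - x))
        fused_logit = fus.intercept + logit_x @ fus.weights
        assert base + phi.sum() == pytest.approx(fused_logit, abs=1e-10)
        closed = fus.weights * (logit_x - mu)
        np.testing.assert_allclose(phi, closed, atol=1e-10)
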