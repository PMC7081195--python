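"""Fisher LDA, LOOCV, beam search, DeLong test, model selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirpanel.discovery import (
    BeamCandidate,
    BeamState,
    Discriminant,
    apply_model,
    beam_search,
    delong_auc_covariance,
    delong_test,
    fit_fisher_lda,
    loocv_score,
    select_final_model,
    _loocv_batch,
)
from mirpanel.evaluate import roc_auc


def _gauss(rng, n1=20, n0=20, d=2, shift=1.5):
    X = rng.normal(0, 1, (n1 + n0, d))
    X[:n1, 0] += shift
    y = np.repeat([True, False], [n1, n0])
    return X, y


# ---------------------------------------------------------------------------
# Fisher LDA
# ---------------------------------------------------------------------------


def test_symmetric_1d_classes_put_boundary_at_zero():
    X = np.array([[-3.0], [-1.0], [1.0], [3.0]])
    y = np.array([False, False, True, True])
    model = fit_fisher_lda(X, y)
    assert model.weights[0] > 0
    assert model.intercept == pytest.approx(0.0, abs=1e-12)
    idx, calls = apply_model(model, X)
    assert list(calls) == ["non_cancer", "non_cancer", "cancer", "cancer"]


def test_weights_match_closed_form_oracle():
    rng = np.random.default_rng(1)
    X, y = _gauss(rng, 30, 25, d=2)
    model = fit_fisher_lda(X, y)
    # independent linear solve on hand-computed pooled covariance
    m1, m0 = X[y].mean(0), X[~y].mean(0)
    S = (X[y] - m1).T @ (X[y] - m1) + (X[~y] - m0).T @ (X[~y] - m0)
    pooled = S / (y.sum() + (~y).sum() - 2)
    w = np.linalg.solve(pooled, m1 - m0)
    assert np.allclose(model.weights, w, rtol=1e-6)
    # cancer class projects to non-negative mean index
    idx, _ = apply_model(model, X)
    assert idx[y].mean() >= 0


def test_constant_shift_changes_only_intercept():
    rng = np.random.default_rng(2)
    X, y = _gauss(rng, d=2)
    m0 = fit_fisher_lda(X, y)
    Xs = X.copy()
    Xs[:, 1] += 7.0
    m1 = fit_fisher_lda(Xs, y)
    assert np.allclose(m0.weights, m1.weights, rtol=1e-9)
    i0, _ = apply_model(m0, X)
    i1, _ = apply_model(m1, Xs)
    assert np.allclose(i0, i1, atol=1e-9)


def test_feature_rescaling_is_index_invariant():
    rng = np.random.default_rng(3)
    X, y = _gauss(rng, d=3)
    m0 = fit_fisher_lda(X, y)
    Xs = X.copy()
    Xs[:, 2] *= 10.0
    m1 = fit_fisher_lda(Xs, y)
    assert m1.weights[2] == pytest.approx(m0.weights[2] / 10.0, rel=1e-9)
    i0, _ = apply_model(m0, X)
    i1, _ = apply_model(m1, Xs)
    assert np.allclose(i0, i1, atol=1e-9)


def test_degenerate_constant_feature_still_fits():
    X = np.column_stack([np.array([0.0, 0.1, 2.0, 2.1]), np.ones(4)])
    y = np.array([False, False, True, True])
    model = fit_fisher_lda(X, y)  # ridge guard kicks in
    assert all(math.isfinite(w) for w in model.weights)


def test_small_class_rejected():
    X = np.array([[0.0], [1.0], [2.0]])
    with pytest.raises(ValueError):
        fit_fisher_lda(X, np.array([True, False, False]))


# ---------------------------------------------------------------------------
# apply_model
# ---------------------------------------------------------------------------

MODEL1 = Discriminant(("miR-17-3p",), (0.491213,), -2.49845)
MODEL2 = Discriminant(("miR-1268b", "miR-6075"), (-3.56049, 1.99039), 16.7999)


def test_two_mirna_model_arithmetic():
    idx, calls = apply_model(MODEL2, {"miR-1268b": 4.0, "miR-6075": 2.0})
    assert idx[0] == pytest.approx(6.53872, abs=1e-9)
    assert calls[0] == "cancer"


def test_single_mirna_model_arithmetic():
    idx, calls = apply_model(MODEL1, {"miR-17-3p": 2.0})
    assert idx[0] == pytest.approx(-1.516024, abs=1e-9)
    assert calls[0] == "non_cancer"


def test_zero_index_calls_cancer():
    model = Discriminant(("m",), (1.0,), 0.0)
    _, calls = apply_model(model, {"m": 0.0})
    assert calls[0] == "cancer"


def test_missing_panel_mirna_named_in_error():
    with pytest.raises(KeyError, match="miR-6075"):
        apply_model(MODEL2, {"miR-1268b": 4.0})
    with pytest.raises(KeyError, match="miR-6075"):
        apply_model(MODEL2, pd.DataFrame({"miR-1268b": [4.0]}))


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------


def _naive_loocv(X, y):
    hits = 0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        model = fit_fisher_lda(X[mask], y[mask])
        _, call = apply_model(model, X[i])
        hits += (call[0] == "cancer") == y[i]
    return hits / len(y)


def test_separated_clusters_score_one():
    rng = np.random.default_rng(0)
    X, y = _gauss(rng, 15, 15, d=2, shift=20.0)
    assert loocv_score(X, y) == 1.0


def test_loocv_equals_explicit_refit_loop_n6():
    X = np.array([[0.1], [0.4], [0.3], [2.0], [2.2], [1.9]])
    y = np.array([False, False, False, True, True, True])
    assert loocv_score(X, y) == _naive_loocv(X, y)


@pytest.mark.parametrize("k", [1, 2, 3])
@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_batched_loocv_equals_naive_loop(k, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (16, k))
    y = rng.random(16) < 0.5
    y[:3], y[-3:] = True, False  # keep >= 3 per class
    X[y, 0] += 1.0
    assert loocv_score(X, y) == _naive_loocv(X, y)


def test_shuffled_labels_score_near_half():
    rng = np.random.default_rng(4)
    X = rng.normal(0, 1, (200, 1))
    y = np.repeat([True, False], 100)
    rng.shuffle(y)
    assert loocv_score(X, y) == pytest.approx(0.5, abs=0.15)


def test_loocv_needs_three_per_class():
    X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
    y = np.array([True, True, False, False, False])
    with pytest.raises(ValueError):
        loocv_score(X, y)


# ---------------------------------------------------------------------------
# beam search
# ---------------------------------------------------------------------------


def _rank_key(X, y, panel, cols):
    score = _loocv_batch(X, y, np.array([panel]))[0]
    model = fit_fisher_lda(X[:, list(panel)], y)
    idx = X[:, list(panel)] @ np.array(model.weights) + model.intercept
    return (-score, -roc_auc(idx, y), tuple(sorted(cols[j] for j in panel)))


def test_beam_equals_exhaustive_when_wide_enough():
    rng = np.random.default_rng(5)
    M = 6
    X = rng.normal(0, 1, (40, M))
    y = np.repeat([True, False], 20)
    X[y, 0] += 1.5
    X[y, 3] += 0.8
    cols = [f"m{j}" for j in range(M)]
    df = pd.DataFrame(X, columns=cols)
    beams = beam_search(df, y, beam_width=20)  # 20 >= C(6,2)=15 pairs
    for size in (1, 2, 3):
        panels = itertools.combinations(range(M), size)
        best = min(panels, key=lambda p: _rank_key(X, y, p, cols))
        assert set(beams.champion(size).panel) == {cols[j] for j in best}


def test_beam_width_one_is_greedy_forward_selection():
    rng = np.random.default_rng(6)
    M = 8
    X = rng.normal(0, 1, (40, M))
    y = np.repeat([True, False], 20)
    X[y, 2] += 2.0
    X[y, 5] += 1.0
    cols = [f"m{j}" for j in range(M)]
    beams = beam_search(pd.DataFrame(X, columns=cols), y, beam_width=1)
    # greedy oracle: best single, then best extension of it, etc.
    chosen: list[int] = []
    for size in (1, 2, 3):
        cands = [tuple(sorted(chosen + [j])) for j in range(M) if j not in chosen]
        best = min(cands, key=lambda p: _rank_key(X, y, p, cols))
        chosen = list(best)
        assert set(beams.champion(size).panel) == {cols[j] for j in best}
        assert len(beams.levels[size]) == 1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_planted_marker_wins_single_mirna_level(seed):
    rng = np.random.default_rng(seed)
    M, n = 50, 100
    X = rng.normal(0, 1, (2 * n, M))
    y = np.repeat([True, False], n)
    X[y, 17] += 3.0
    cols = [f"m{j}" for j in range(M)]
    beams = beam_search(pd.DataFrame(X, columns=cols), y, max_size=1)
    assert beams.champion(1).panel == ("m17",)


def test_beam_width_must_be_positive():
    with pytest.raises(ValueError):
        beam_search(np.zeros((10, 2)), np.repeat([True, False], 5), beam_width=0)


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------


def _delong_oracle(sa, sb, y):
    """O(n^2) structural-components computation straight from the definition."""
    def psi(x, z):
        return 1.0 if x > z else (0.5 if x == z else 0.0)

    out = {}
    xs = {"a": sa[y], "b": sb[y]}
    zs = {"a": sa[~y], "b": sb[~y]}
    m, n = int(y.sum()), int((~y).sum())
    V10 = {k: np.array([np.mean([psi(x, z) for z in zs[k]]) for x in xs[k]]) for k in "ab"}
    V01 = {k: np.array([np.mean([psi(x, z) for x in xs[k]]) for z in zs[k]]) for k in "ab"}
    auc = {k: V10[k].mean() for k in "ab"}
    S10 = np.array([[np.sum((V10[i] - auc[i]) * (V10[j] - auc[j])) / (m - 1) for j in "ab"]
                    for i in "ab"])
    S01 = np.array([[np.sum((V01[i] - auc[i]) * (V01[j] - auc[j])) / (n - 1) for j in "ab"]
                    for i in "ab"])
    out["auc"] = auc
    out["cov"] = S10 / m + S01 / n
    return out


def test_self_comparison_gives_p_one():
    y = np.repeat([True, False], 6)
    s = np.arange(12, dtype=float)
    auc_a, auc_b, z, p = delong_test(s, s, y)
    assert auc_a == auc_b and p == 1.0 and z == 0.0


def test_labels_as_scores_give_perfect_auc():
    y = np.repeat([True, False], 6)
    auc_a, _, _ = delong_auc_covariance(y.astype(float), np.zeros(12), y)
    assert auc_a == 1.0
    # a perfectly separated curve has zero-variance components; comparing it
    # against a flat curve is degenerate and must refuse rather than invent p
    with pytest.raises(ValueError, match="zero variance"):
        delong_test(y.astype(float), np.zeros(12), y)


def test_covariance_matches_structural_oracle_n12():
    rng = np.random.default_rng(7)
    y = np.repeat([True, False], 6)
    sa = rng.normal(0, 1, 12) + y
    sb = 0.5 * sa + rng.normal(0, 1, 12)
    auc_a, auc_b, cov = delong_auc_covariance(sa, sb, y)
    oracle = _delong_oracle(sa, sb, y)
    assert auc_a == pytest.approx(oracle["auc"]["a"], abs=1e-12)
    assert auc_b == pytest.approx(oracle["auc"]["b"], abs=1e-12)
    assert np.allclose(cov, oracle["cov"], atol=1e-12)


def test_fast_delong_equals_on2_oracle_on_random_instances():
    rng = np.random.default_rng(8)
    for _ in range(100):
        m = int(rng.integers(3, 16))
        n = int(rng.integers(3, 16))
        y = np.repeat([True, False], [m, n])
        # integer scores force midrank tie handling
        sa = rng.integers(0, 6, m + n).astype(float) + y * rng.integers(0, 3)
        sb = sa * 0.5 + rng.integers(0, 4, m + n)
        _, _, cov = delong_auc_covariance(sa, sb, y)
        oracle = _delong_oracle(sa, sb, y)
        assert np.allclose(cov, oracle["cov"], atol=1e-12)


def test_degenerate_variance_with_unequal_aucs_raises():
    # constant scores: AUC 0.5 each, zero variance -> p = 1 path
    y = np.repeat([True, False], 4)
    _, _, _, p = delong_test(np.zeros(8), np.zeros(8), y)
    assert p == 1.0


# ---------------------------------------------------------------------------
# final model selection
# ---------------------------------------------------------------------------


def _beams_for(df, y, panels):
    levels = {}
    for size, panel in panels.items():
        model = fit_fisher_lda(df[list(panel)], y)
        idx, _ = apply_model(model, df)
        levels[size] = [BeamCandidate(tuple(panel), model, 0.0, roc_auc(idx, y))]
    return BeamState(20, levels)


def _selection_fixture(rng):
    n = 60
    y = np.repeat([True, False], n // 2)
    f_weak = rng.normal(0, 1, n) + y * 0.8
    f_strong = rng.normal(0, 0.05, n) + y * 3.0
    f_dup = f_strong + rng.normal(0, 1e-6, n)
    df = pd.DataFrame({"weak": f_weak, "strong": f_strong, "dup": f_dup})
    return df, y


def test_selection_stops_when_no_significant_gain():
    """Strong 2-panel beats 1-panel (p<<0.05); a duplicated third miRNA adds
    nothing (p ~ 1) -> final size 2, mirroring nested-champion footnotes."""
    rng = np.random.default_rng(10)
    df, y = _selection_fixture(rng)
    beams = _beams_for(df, y, {1: ["weak"], 2: ["weak", "strong"], 3: ["weak", "strong", "dup"]})
    res = select_final_model(beams, df, y)
    assert res.delong_p[(1, 2)] < 0.05
    assert res.delong_p[(2, 3)] > 0.05
    assert res.final_size == 2
    assert res.final_model.mirna_ids == ("weak", "strong")


def test_selection_keeps_size_one_when_nothing_improves():
    rng = np.random.default_rng(11)
    df, y = _selection_fixture(rng)
    beams = _beams_for(df, y, {1: ["strong"], 2: ["strong", "dup"], 3: ["strong", "dup", "weak"]})
    res = select_final_model(beams, df, y)
    assert res.final_size == 1
    assert (2, 3) not in res.delong_p  # walk stops at the first failure


def test_selection_reaches_max_size_under_monotone_improvement():
    rng = np.random.default_rng(12)
    n = 400
    y = np.repeat([True, False], n // 2)
    # three independent, individually informative features
    f1 = rng.normal(0, 1, n) + y * 0.6
    f2 = rng.normal(0, 1, n) + y * 1.0
    f3 = rng.normal(0, 1, n) + y * 1.4
    df = pd.DataFrame({"f1": f1, "f2": f2, "f3": f3})
    beams = _beams_for(df, y, {1: ["f1"], 2: ["f1", "f2"], 3: ["f1", "f2", "f3"]})
    res = select_final_model(beams, df, y)
    assert res.final_size == 3
    assert res.aucs[3] > res.aucs[2] > res.aucs[1]


def test_sklearn_lda_agrees_on_decisions():
    """Independent implementation cross-check: equal-prior sklearn LDA makes
    the same calls as the Fisher discriminant."""
    sklearn = pytest.importorskip("sklearn.discriminant_analysis")
    rng = np.random.default_rng(13)
    X, y = _gauss(rng, 30, 30, d=3)
    model = fit_fisher_lda(X, y)
    idx, calls = apply_model(model, X)
    clf = sklearn.LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
    pred = clf.predict(X)
    assert np.array_equal(pred, calls == "cancer")
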