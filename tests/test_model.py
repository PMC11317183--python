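"""Cohort splitting, grid search, kernel RFE, thresholding, evaluation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

from seroscreen.errors import ConfigurationError, InsufficientDataError
from seroscreen.model import (
    ModelConfig,
    Scaler,
    TrainedModel,
    calibrate_threshold,
    compare_single_markers,
    evaluate,
    grid_search,
    rfe_rank,
    select_feature_count,
    split_cohort,
    train_classifier,
)


def _toy_frame(x: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(x, columns=[f"F{i}" for i in range(x.shape[1])])


def _planted_data(seed=0, n=60, n_noise=7, shift=2.5):
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
    x = rng.normal(0, 1, (n, n_noise + 3))
    x[y == 1, :3] += shift
    return _toy_frame(x), y


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------


def test_split_cohort_composition_and_determinism():
    cases = [f"RA{i}" for i in range(182)]
    controls = [f"C{i}" for i in range(261)]
    a = split_cohort(cases, controls, 120, 120, seed=5)
    b = split_cohort(cases, controls, 120, 120, seed=5)
    assert (len(a.test_cases), len(a.test_controls)) == (62, 141)
    assert a == b
    assert set(a.train_cases) | set(a.test_cases) == set(cases)
    assert not set(a.train_cases) & set(a.test_cases)
    assert split_cohort(cases, controls, 120, 120, seed=6) != a


def test_split_sizes_exceeding_cohort_rejected():
    with pytest.raises(ConfigurationError):
        split_cohort(["a"], ["b"], 2, 1, seed=0)


def test_split_with_empty_test_set_warns():
    with pytest.warns(UserWarning, match="test set is empty"):
        s = split_cohort(["a", "b"], ["c"], 2, 1, seed=0)
    assert s.test_ids == []


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


def test_grid_single_point_returned():
    x, y = _planted_data()
    cfg = ModelConfig(c_grid=(4.0,), gamma_grid=(0.25,), seed=0)
    c, gamma, table = grid_search(x, y, cfg)
    assert (c, gamma) == (4.0, 0.25)
    assert len(table) == 1


def test_grid_separable_toy_reaches_perfect_cv_auroc():
    x, y = _planted_data(shift=6.0)
    cfg = ModelConfig(c_grid=(1.0, 8.0), gamma_grid=(0.01, 0.1), seed=0)
    _, _, table = grid_search(x, y, cfg)
    assert table["cv_auroc"].max() == 1.0


def test_grid_pure_noise_near_half():
    rng = np.random.default_rng(7)
    x = _toy_frame(rng.normal(0, 1, (80, 5)))
    y = np.r_[np.ones(40, int), np.zeros(40, int)]
    cfg = ModelConfig(c_grid=(1.0,), gamma_grid=(0.1,), seed=0)
    _, _, table = grid_search(x, y, cfg)
    assert table["cv_auroc"].iloc[0] == pytest.approx(0.5, abs=0.12)


def test_grid_single_class_rejected():
    x = _toy_frame(np.zeros((8, 2)))
    with pytest.raises(InsufficientDataError):
        grid_search(x, np.ones(8, int), ModelConfig())


# ---------------------------------------------------------------------------
# RFE
# ---------------------------------------------------------------------------


def test_constant_feature_eliminated_first():
    x, y = _planted_data(n_noise=4)
    xs = Scaler.fit(x).transform(x)
    xs["F6"] = 0.0  # constant: removing it leaves every pairwise distance unchanged
    order = rfe_rank(xs, y, c=4.0, gamma=0.1)
    assert order[0] == "F6"


def test_first_elimination_matches_bruteforce_delta_j():
    rng = np.random.default_rng(8)
    for trial in range(8):
        n = int(rng.integers(16, 40))
        p = int(rng.integers(3, 8))
        x = rng.normal(0, 1, (n, p))
        y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
        x[y == 1, : max(1, p // 2)] += 1.0
        frame = _toy_frame(x)
        xs = Scaler.fit(frame).transform(frame)
        c, gamma = 2.0, 0.5

        svc = SVC(C=c, gamma=gamma, kernel="rbf").fit(xs.to_numpy(), y)
        sv = xs.to_numpy()[svc.support_]
        ay = svc.dual_coef_[0]
        j_full = 0.5 * ay @ rbf_kernel(sv, sv, gamma=gamma) @ ay
        deltas = []
        for f in range(p):
            reduced = np.delete(sv, f, axis=1)
            j_minus = 0.5 * ay @ rbf_kernel(reduced, reduced, gamma=gamma) @ ay
            deltas.append(abs(j_full - j_minus))
        expected = xs.columns[int(np.argmin(deltas))]
        assert rfe_rank(xs, y, c, gamma)[0] == expected


def test_planted_feature_ranked_most_important():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        n = 40
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        x = rng.normal(0, 1, (n, 6))
        x[y == 1, 0] += 4.0  # single separating feature among 5 noise features
        frame = _toy_frame(x)
        xs = Scaler.fit(frame).transform(frame)
        order = rfe_rank(xs, y, c=4.0, gamma=0.1)
        hits += order[-1] == "F0"
    assert hits >= 19


def test_small_gamma_delta_j_approaches_linear_w2():
    """For gamma -> 0 on standardised data, |Delta J| ~ gamma * w_f^2.

    The identity uses the fitted model's own dual coefficients
    (w_f = sum_i alpha_i y_i x_if); the full ordering also agrees with an
    independently fitted linear SVM at the matching effective box constraint
    (exp(-gamma d^2) ~ const + 2 gamma <x, z>, so C_eff = 2 gamma C).
    """
    x, y = _planted_data(seed=3, n=30, n_noise=3, shift=1.5)
    xs = Scaler.fit(x).transform(x)
    gamma = 1e-6
    from seroscreen.model import rfe_delta_j

    deltas = rfe_delta_j(xs, y, c=1.0, gamma=gamma)
    svc = SVC(C=1.0, gamma=gamma, kernel="rbf").fit(xs.to_numpy(), y)
    w = svc.dual_coef_[0] @ xs.to_numpy()[svc.support_]
    np.testing.assert_allclose(deltas.to_numpy(), gamma * w**2, rtol=1e-2)

    linear = SVC(C=2 * gamma * 1.0, kernel="linear").fit(xs.to_numpy(), y)
    w2_lin = pd.Series(linear.coef_[0] ** 2, index=xs.columns)
    assert list(deltas.sort_values().index) == list(w2_lin.sort_values().index)


# ---------------------------------------------------------------------------
# feature count selection
# ---------------------------------------------------------------------------


def test_single_feature_path_gives_k_one():
    x, y = _planted_data(n_noise=0)
    x = x[["F0"]]
    k, selected, path = select_feature_count(x, y, ["F0"], 1.0, 0.1, ModelConfig(seed=0))
    assert (k, selected) == (1, ["F0"])
    assert list(path["k"]) == [1]


def test_selected_set_contains_planted_features():
    x, y = _planted_data(seed=9, n=80, n_noise=7, shift=2.0)
    cfg = ModelConfig(c_grid=(1.0, 8.0), gamma_grid=(0.01, 0.1), seed=0)
    report = train_classifier(x, y, cfg)
    assert {"F0", "F1", "F2"} <= set(report.model.feature_ids)


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------


def test_threshold_lands_just_above_ninetieth_control_score():
    controls = np.arange(1.0, 101.0)
    cases = np.full(10, 200.0)
    scores = np.r_[cases, controls]
    y = np.r_[np.ones(10, int), np.zeros(100, int)]
    thr = calibrate_threshold(scores, y, 0.90)
    assert thr == 91.0
    assert np.mean(controls < thr) == 0.90


def test_threshold_on_separated_scores():
    scores = np.r_[np.full(5, 10.0), np.full(5, -10.0)]
    y = np.r_[np.ones(5, int), np.zeros(5, int)]
    thr = calibrate_threshold(scores, y, 0.90)
    assert np.mean(scores[y == 0] < thr) == 1.0
    assert np.mean(scores[y == 1] >= thr) == 1.0


def test_threshold_unreachable_warns():
    scores = np.r_[np.zeros(5), np.ones(5)]  # controls above cases
    y = np.r_[np.ones(5, int), np.zeros(5, int)]
    with pytest.warns(UserWarning, match="unreachable"):
        thr = calibrate_threshold(scores, y, 0.99)
    assert thr > scores.max()


# ---------------------------------------------------------------------------
# trained model properties
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def trained():
    x, y = _planted_data(seed=10, n=80, n_noise=5, shift=2.0)
    cfg = ModelConfig(c_grid=(1.0, 8.0), gamma_grid=(0.01, 0.1), seed=0)
    return x, y, train_classifier(x, y, cfg)


def test_kkt_conditions_hold(trained):
    _, _, report = trained
    model = report.model
    assert model.kkt_residual < 1e-6
    assert np.all(np.abs(model.dual_coef) <= model.c * (1 + 1e-8))


def test_training_is_deterministic_and_ignores_test_data(trained):
    x, y, report = trained
    again = train_classifier(x, y, ModelConfig(c_grid=(1.0, 8.0),
                                               gamma_grid=(0.01, 0.1), seed=0))
    assert report.model.to_dict() == again.model.to_dict()
    # scoring two different "test" sets leaves the model untouched
    before = report.model.to_dict()
    rng = np.random.default_rng(0)
    evaluate(report.model, _toy_frame(rng.normal(0, 1, (10, x.shape[1]))),
             np.r_[np.ones(5, int), np.zeros(5, int)])
    assert report.model.to_dict() == before


def test_model_round_trips_through_json(tmp_path, trained):
    x, _, report = trained
    path = tmp_path / "model.json"
    report.model.save(path)
    back = TrainedModel.load(path)
    np.testing.assert_allclose(back.decision_scores(x), report.model.decision_scores(x))
    assert back.feature_ids == report.model.feature_ids
    assert back.threshold == report.model.threshold


def test_self_prediction_is_optimistic(trained):
    x, y, report = trained
    self_eval = evaluate(report.model, x, y)
    assert self_eval.sensitivity + self_eval.specificity >= (
        report.model.cv_sensitivity + report.model.cv_specificity
    )


def test_label_permuted_evaluation_near_chance(trained):
    x, y, report = trained
    rng = np.random.default_rng(11)
    permuted = rng.permutation(y)
    assert evaluate(report.model, x, permuted).auroc == pytest.approx(0.5, abs=0.12)


# ---------------------------------------------------------------------------
# single-marker comparison
# ---------------------------------------------------------------------------


def test_marker_identical_to_model_score_matches_sensitivity(trained):
    x, y, report = trained
    scores = report.model.decision_scores(x)
    markers = pd.DataFrame({"M": scores}, index=x.index)
    out = compare_single_markers(markers, y, markers, y,
                                 target_specificity=0.90)
    model_sens = float(np.mean(scores[y == 1] >= report.model.threshold))
    marker_sens = out.loc[out["marker"] == "M", "sensitivity"].iloc[0]
    # same scoring variable, same calibration rule, same data
    thr = calibrate_threshold(scores, y, 0.90)
    assert marker_sens == float(np.mean(scores[y == 1] >= thr))


def test_disjoint_markers_combine_additively():
    y_cases = np.ones(20, int)
    y = np.r_[y_cases, np.zeros(50, int)]
    a = np.zeros(70)
    b = np.zeros(70)
    a[:6] = 10.0  # 30% of cases
    b[6:12] = 10.0  # a disjoint 30%
    markers = pd.DataFrame({"A": a, "B": b})
    out = compare_single_markers(markers, y, markers, y,
                                 target_specificity=0.90,
                                 combinations=[("A", "B")])
    sens = dict(zip(out["marker"], out["sensitivity"]))
    assert sens["A"] == pytest.approx(0.30)
    assert sens["B"] == pytest.approx(0.30)
    assert sens["A+B"] == pytest.approx(0.60)


def test_noise_marker_sensitivity_matches_false_positive_rate():
    rng = np.random.default_rng(12)
    y = np.r_[np.ones(300, int), np.zeros(300, int)]
    markers = pd.DataFrame({"N": rng.normal(0, 1, 600)})
    out = compare_single_markers(markers, y, markers, y, target_specificity=0.90)
    assert out["sensitivity"].iloc[0] == pytest.approx(0.10, abs=0.05)
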