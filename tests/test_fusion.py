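"""LDA, SVM, threshold, metrics, synchronization and section rejection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from eegcam.config import PipelineConfig, SVMConfig
from eegcam.eeg import EEGStream
from eegcam.fusion import (CentroidScorer, DecisionModel, apply_threshold,
                           error_rates, fisher_ratio, fit_lda, fit_pipeline,
                           reject_sections, roc_curve, select_lda_dim,
                           select_threshold, synchronize, train_svm,
                           twofold_cv, _fit_decision_model, _svc_from_config)


# ---------------------------------------------------------------------------
# Synchronization
# ---------------------------------------------------------------------------

def test_frame_pairs_with_exactly_coincident_epoch():
    ends = np.arange(127, 256) / 128.0          # epoch at sample i ends at i/128
    idx, kept = synchronize(ends, np.array([1.0]))
    assert kept[0]
    assert ends[idx[0]] == 1.0                  # pairs with end at sample 128


def test_frames_before_first_epoch_are_dropped():
    ends = np.arange(127, 256) / 128.0
    idx, kept = synchronize(ends, np.array([0.5, 1.2]))
    assert not kept[0] and kept[1]


def test_pairing_matches_exhaustive_nearest_neighbor(rng):
    ends = np.arange(127, 1280) / 128.0
    frames = np.arange(1, 300) / 30.0
    idx, kept = synchronize(ends, frames)
    assert kept.sum() == np.count_nonzero(frames >= ends[0] - 1e-9)
    for f, i in zip(frames[kept], idx[kept]):
        best = np.argmin(np.abs(ends - f))
        assert abs(ends[i] - f) <= abs(ends[best] - f) + 1e-12


def test_non_overlapping_ranges_error():
    with pytest.raises(ValueError, match="overlap"):
        synchronize(np.array([100.0, 101.0]), np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# Fisher LDA
# ---------------------------------------------------------------------------

def _two_clouds(rng, n=300, sep=4.0, dim=2):
    X1 = rng.normal(0, 1, (n, dim))
    X2 = rng.normal(0, 1, (n, dim))
    X2[:, 0] += sep
    X = np.vstack([X1, X2])
    y = np.array([1] * n + [2] * n)
    return X, y


def test_identical_class_means_give_zero_leading_eigenvalue(rng):
    X = rng.normal(size=(200, 3))
    y = np.array([1, 2] * 100)
    proj = fit_lda(X, y)
    assert proj.eigenvalues[0] == pytest.approx(0.0, abs=0.05)


def test_leading_direction_matches_closed_form(rng):
    X, y = _two_clouds(rng)
    proj = fit_lda(X, y)
    closed = np.linalg.pinv(proj.scatter_within) @ (
        proj.class_means[2] - proj.class_means[1])
    closed /= np.linalg.norm(closed)
    cos = abs(closed @ proj.vectors[:, 0])
    assert cos >= 0.999


def test_leading_direction_beats_200_random_directions(rng):
    X, y = _two_clouds(rng, dim=5)
    proj = fit_lda(X, y)
    best = fisher_ratio(proj, proj.vectors[:, 0])
    for _ in range(200):
        u = rng.normal(size=5)
        u /= np.linalg.norm(u)
        assert best >= fisher_ratio(proj, u) - 1e-9


def test_direction_agrees_with_sklearn_lda(rng):
    X, y = _two_clouds(rng, dim=4)
    proj = fit_lda(X, y)
    sk = LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
    u = sk.coef_.ravel() / np.linalg.norm(sk.coef_)
    assert abs(u @ proj.vectors[:, 0]) >= 0.999


def test_single_sample_class_is_an_error(rng):
    X = rng.normal(size=(5, 2))
    with pytest.raises(ValueError, match="fewer than 2"):
        fit_lda(X, np.array([1, 1, 1, 1, 2]))


def test_projection_fisher_ratio_not_worse_than_any_feature_axis(rng):
    X, y = _two_clouds(rng, dim=6)
    proj = fit_lda(X, y)
    lead = fisher_ratio(proj, proj.vectors[:, 0])
    for axis in range(6):
        e = np.zeros(6)
        e[axis] = 1.0
        assert lead >= fisher_ratio(proj, e) - 1e-9


# ---------------------------------------------------------------------------
# Dimension selection
# ---------------------------------------------------------------------------

def test_noise_dimensions_select_k1(rng):
    n = 400
    X = rng.normal(size=(n, 5))
    y = np.array([1] * (n // 2) + [2] * (n // 2))
    X[y == 2, 0] += 6.0                  # only axis 0 informative
    assert select_lda_dim(X, y, (1, 2, 3, 4, 5), seed=0) == 1


def test_dimension_selection_is_deterministic(rng):
    X, y = _two_clouds(rng, dim=4)
    ks = (1, 2, 3, 4)
    assert select_lda_dim(X, y, ks, seed=3) == select_lda_dim(X, y, ks, seed=3)


def test_empty_candidates_error(rng):
    X, y = _two_clouds(rng)
    with pytest.raises(ValueError, match="non-empty"):
        select_lda_dim(X, y, ())


# ---------------------------------------------------------------------------
# SVM training and the explicit decision sum
# ---------------------------------------------------------------------------

def test_separable_clouds_linear_kernel_zero_training_error(rng):
    X, y = _two_clouds(rng, sep=10.0)
    model = train_svm(X, y, [SVMConfig(kernel="linear")], seed=0)
    pred = apply_threshold(model.decision_values(X), 0.0)
    assert error_rates(pred, y).average == 0.0


def test_xor_needs_the_rbf_kernel(rng):
    centers = np.array([[0, 0], [4, 4], [0, 4], [4, 0]])
    labels = [1, 1, 2, 2]
    X = np.vstack([rng.normal(c, 0.3, (50, 2)) for c in centers])
    y = np.repeat(labels, 50)
    rbf = _fit_decision_model(X, y, SVMConfig(kernel="rbf", r=1.0, cost=10))
    lin = _fit_decision_model(X, y, SVMConfig(kernel="linear", cost=10))
    err_rbf = error_rates(apply_threshold(rbf.decision_values(X), 0.0), y)
    err_lin = error_rates(apply_threshold(lin.decision_values(X), 0.0), y)
    assert err_rbf.average == 0.0
    assert err_lin.average >= 25.0


@pytest.mark.parametrize("cfg", [
    SVMConfig(kernel="linear", cost=1.0),
    SVMConfig(kernel="polynomial", r=0.5, c=1.0, d=3),
    SVMConfig(kernel="rbf", r=2.0, cost=10.0),
    SVMConfig(kernel="sigmoid", r=0.05, c=0.1),
])
def test_explicit_support_vector_sum_matches_sklearn(rng, cfg):
    """The stored-support-set decision sum must equal the library's
    decision function (dual-route check of the kernel expansion)."""
    X, y = _two_clouds(rng, sep=2.0, dim=3)
    model = _fit_decision_model(X, y, cfg)
    svc = _svc_from_config(cfg)
    svc.fit(X, np.where(y == 2, 1, -1))
    Xnew = rng.normal(0, 2, (20, 3))
    np.testing.assert_allclose(model.decision_values(Xnew),
                               svc.decision_function(Xnew), rtol=1e-9)


def test_single_class_training_is_an_error(rng):
    X = rng.normal(size=(30, 2))
    with pytest.raises(ValueError, match="both classes"):
        train_svm(X, np.ones(30, int), [SVMConfig()])


def test_rbf_family_selected_for_nonlinear_fused_structure(rng):
    """On data whose second dimension matters only conditionally (the
    movement class folds back over the still cluster), the kernel grid
    containing RBF r = 8 should settle on the RBF family."""
    n = 600
    y = np.repeat([1, 2], n)
    x_img = np.concatenate([rng.normal(0, 0.3, n),                 # still
                            np.abs(rng.normal(2.0, 1.5, n))])      # moving
    x_eeg = np.concatenate([rng.normal(0, 1.0, n),
                            rng.normal(1.5, 1.0, n)])
    x_img[n:n + n // 10] = rng.normal(0, 0.3, n // 10)             # pauses
    X = np.column_stack([x_img, x_eeg])
    grid = [SVMConfig(kernel="linear"),
            SVMConfig(kernel="rbf", r=8.0, cost=10.0),
            SVMConfig(kernel="rbf", r=0.5, cost=1.0)]
    model = train_svm(X, y, grid, seed=0)
    assert model.config.kernel == "rbf"


# ---------------------------------------------------------------------------
# Threshold selection
# ---------------------------------------------------------------------------

def oracle_best_threshold(scores, y):
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                            [uniq[-1] + 1]])
    best = None
    for t in cands:
        pred = np.where(scores > t, 2, 1)
        err = error_rates(pred, y).average
        if best is None or err < best[0] - 1e-12:
            best = (err, t)
    return best


def test_separated_scores_give_zero_error_threshold():
    scores = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
    y = np.array([1, 1, 1, 2, 2, 2])
    thr = select_threshold(scores, y)
    assert -1.0 < thr < 1.0
    assert error_rates(apply_threshold(scores, thr), y).average == 0.0


def test_identical_score_sets_are_indistinguishable():
    scores = np.array([0.5, 1.5, 2.5, 0.5, 1.5, 2.5])
    y = np.array([1, 1, 1, 2, 2, 2])
    thr = select_threshold(scores, y)
    err = error_rates(apply_threshold(scores, thr), y).average
    assert err == 50.0


def test_threshold_equals_exhaustive_sweep(rng):
    for _ in range(20):
        scores = rng.normal(size=40).round(2)   # force some ties
        y = rng.integers(1, 3, 40)
        if len(set(y)) < 2:
            continue
        thr = select_threshold(scores, y)
        got = error_rates(apply_threshold(scores, thr), y).average
        assert got == pytest.approx(oracle_best_threshold(scores, y)[0])


def test_boundary_decision_goes_to_class_1():
    assert apply_threshold(np.array([0.5]), 0.5)[0] == 1
    assert apply_threshold(np.array([0.5000001]), 0.5)[0] == 2
    np.testing.assert_array_equal(
        apply_threshold(np.array([-1.0, -5.0]), 0.0), [1, 1])


# ---------------------------------------------------------------------------
# Error rates and ROC
# ---------------------------------------------------------------------------

def test_error_rate_counting():
    truth = np.array([1] * 10 + [2] * 20)
    pred = truth.copy()
    pred[:2] = 2                 # 2 of 10 Class-1 wrong
    pred[10] = 1                 # 1 of 20 Class-2 wrong
    rep = error_rates(pred, truth)
    assert (rep.type1, rep.type2, rep.average) == (20.0, 5.0, 12.5)
    assert error_rates(truth, truth).average == 0.0
    assert error_rates(3 - truth, truth).average == 100.0


def test_absent_truth_class_is_an_error():
    with pytest.raises(ValueError, match="absent"):
        error_rates(np.array([1, 1]), np.array([1, 1]))


def oracle_auc_pairwise(scores, y):
    s1 = scores[y == 1]
    s2 = scores[y == 2]
    wins = sum((b > a) + 0.5 * (b == a) for a in s1 for b in s2)
    return wins / (len(s1) * len(s2))


def test_roc_perfect_and_chance_cases():
    y = np.array([1, 1, 1, 2, 2, 2])
    _, _, auc = roc_curve(np.array([0, 1, 2, 5, 6, 7.0]), y)
    assert auc == 1.0
    _, _, auc = roc_curve(np.array([1, 2, 3, 1, 2, 3.0]), y)
    assert auc == 0.5


def test_roc_matches_mann_whitney_oracle(rng):
    scores = rng.normal(size=10).round(1)
    y = np.array([1] * 5 + [2] * 5)
    fpr, tpr, auc = roc_curve(scores, y)
    assert np.all(np.diff(fpr) >= 0)
    assert auc == pytest.approx(oracle_auc_pairwise(scores, y))


def test_roc_single_class_errors():
    with pytest.raises(ValueError):
        roc_curve(np.array([1.0, 2.0]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# Section rejection
# ---------------------------------------------------------------------------

def test_reject_sections_interval_arithmetic():
    eeg = EEGStream(np.arange(64.0), rate=128.0)   # spans [0, 0.5) s
    labels = np.array([1, 1, 2, 2, 1])
    times = np.arange(5) / 30.0
    segments, sections = reject_sections(labels, times, eeg)
    np.testing.assert_allclose(sections["start_s"], [0, 2 / 30, 4 / 30])
    np.testing.assert_allclose(sections["end_s"], [2 / 30, 4 / 30, 5 / 30])
    assert list(sections["label"]) == [1, 2, 1]
    assert len(segments) == 2
    rejected = int(round((2 / 30) * 128))
    assert sum(len(s) for s in segments) == len(eeg) - rejected


def test_all_still_retains_whole_span():
    eeg = EEGStream(np.arange(128.0), rate=128.0)
    times = np.arange(30) / 30.0
    segments, sections = reject_sections(np.ones(30, int), times, eeg)
    assert len(sections) == 1
    assert len(segments) == 1 and len(segments[0]) == 128


def test_all_moving_retains_nothing():
    eeg = EEGStream(np.arange(128.0), rate=128.0)
    times = np.arange(30) / 30.0
    segments, _ = reject_sections(np.full(30, 2), times, eeg)
    assert segments == []


# ---------------------------------------------------------------------------
# Two-fold cross-validation
# ---------------------------------------------------------------------------

def _toy_table(rng, n_per=80):
    rows = []
    for fold in (0, 1):
        for label in (1, 2):
            base = 0.0 if label == 1 else 3.0
            for i in range(n_per):
                rows.append({
                    "time": i / 30, "trial_id": f"c{label}t{fold}",
                    "fold": fold, "label": label,
                    "pixel_diff": base + rng.normal(0, 0.8),
                    "mv_avg_mag": base / 2 + rng.normal(0, 0.5),
                })
    return pd.DataFrame(rows)


def _toy_config(seed=0):
    return PipelineConfig(feature_set="image", candidate_ks=(1, 2),
                          svm_grid=(SVMConfig(kernel="linear"),
                                    SVMConfig(kernel="rbf", r=1.0)),
                          thin_train=1, seed=seed)


def _cfg_features(cfg):
    return dataclasses.replace(cfg, feature_set="image")


def test_identical_folds_give_identical_fold_reports(rng):
    table = _toy_table(rng)
    dup = table.copy()
    dup["fold"] = 1 - dup["fold"]
    dup["trial_id"] = dup["trial_id"] + "_dup"
    both = pd.concat([table[table["fold"] == 0],
                      dup[dup["fold"] == 1]], ignore_index=True)
    # fold 1 is now a copy of fold 0 under new trial ids
    cfg = PipelineConfig(feature_set="image", candidate_ks=(1,),
                         svm_grid=(SVMConfig(kernel="linear"),),
                         thin_train=1)
    cfg.feature_set = "image"
    names = ("pixel_diff", "mv_avg_mag")
    import eegcam.config as cmod
    # restrict to the two toy columns via a custom set
    cmod.FEATURE_SETS["toy"] = names
    cfg.feature_set = "toy"
    rep = twofold_cv(both, cfg, mode="lda_svm")
    f0, f1 = rep["per_fold"]
    assert f0["average"] == pytest.approx(f1["average"])
    assert rep["averaged"]["average"] == pytest.approx(f0["average"])


def test_no_trial_straddles_folds(rng):
    table = _toy_table(rng)
    spans = table.groupby("trial_id")["fold"].nunique()
    assert (spans == 1).all()


def test_cv_report_is_reproducible_and_fold_symmetric(rng):
    import eegcam.config as cmod
    cmod.FEATURE_SETS["toy"] = ("pixel_diff", "mv_avg_mag")
    table = _toy_table(rng)
    cfg = PipelineConfig(feature_set="toy", candidate_ks=(1, 2),
                         svm_grid=(SVMConfig(kernel="linear"),), thin_train=1)
    rep1 = twofold_cv(table, cfg)
    rep2 = twofold_cv(table, cfg)
    assert rep1 == rep2
    swapped = table.copy()
    swapped["fold"] = 1 - swapped["fold"]
    rep3 = twofold_cv(swapped, cfg)
    assert rep3["averaged"] == rep1["averaged"]


def test_fold_missing_a_class_errors(rng):
    table = _toy_table(rng)
    table = table[~((table["fold"] == 0) & (table["label"] == 2))]
    import eegcam.config as cmod
    cmod.FEATURE_SETS["toy"] = ("pixel_diff", "mv_avg_mag")
    cfg = PipelineConfig(feature_set="toy", thin_train=1)
    with pytest.raises(ValueError, match="lacks a class"):
        twofold_cv(table, cfg)
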