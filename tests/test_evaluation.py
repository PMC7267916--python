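"""Evaluation oracles: correlation matrices, permutation test, mixture
model, Dice, repeated-measures ANOVA, curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from resttask.evaluation import (
    compare_models,
    diagonal_dominance,
    dice,
    fit_mixture,
    learning_curve,
    normalize_matrix,
    prediction_accuracy,
    prediction_matrix,
    threshold_map,
)


# ---------------------------------------------------------------------------
# correlation matrices


def test_prediction_matrix_entries_are_pairwise_correlations():
    rng = np.random.default_rng(0)
    predicted = rng.standard_normal((4, 200))
    actual = rng.standard_normal((4, 200))
    pm = prediction_matrix(predicted, actual, subject_ids=list("abcd"))
    for i in range(4):
        for j in range(4):
            expected = np.corrcoef(predicted[i], actual[j])[0, 1]
            assert pm.values[i, j] == pytest.approx(expected, abs=1e-12)
    assert pm.subject_ids == list("abcd")


def test_prediction_matrix_perfect_prediction_has_unit_diagonal():
    rng = np.random.default_rng(1)
    actual = rng.standard_normal((3, 100))
    pm = prediction_matrix(actual * 2.0 + 1.0, actual)  # affine == perfect CC
    np.testing.assert_allclose(np.diag(pm.values), 1.0, atol=1e-12)
    assert prediction_accuracy(pm) == pytest.approx(1.0, abs=1e-12)


def test_prediction_matrix_rejects_degenerate_maps():
    rng = np.random.default_rng(2)
    predicted = rng.standard_normal((2, 50))
    actual = rng.standard_normal((2, 50))
    predicted[1] = 3.0
    with pytest.raises(ValueError, match="zero-variance predicted"):
        prediction_matrix(predicted, actual, subject_ids=["s0", "s1"])
    with pytest.raises(ValueError):
        prediction_matrix(predicted[:1], actual)


def test_normalize_matrix_columns_are_standardised_and_idempotentish():
    rng = np.random.default_rng(3)
    m = rng.standard_normal((6, 6)) + np.linspace(0, 3, 6)[:, None]
    z = normalize_matrix(m)
    np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-10)
    np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-10)
    # rows stay approximately standardised after the column pass
    assert np.abs(z.mean(axis=1)).max() < 0.5
    with pytest.raises(ValueError):
        normalize_matrix(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        normalize_matrix(np.zeros((3, 4)))


def test_diagonal_dominance_detects_an_identity_like_matrix():
    rng = np.random.default_rng(4)
    m = 0.1 * rng.standard_normal((10, 10)) + np.eye(10)
    stat, p = diagonal_dominance(m, n_permutations=500, seed=0)
    assert stat > 0.5
    assert p < 0.01


def test_diagonal_dominance_null_on_exchangeable_matrix():
    rng = np.random.default_rng(5)
    m = rng.standard_normal((10, 10))
    stat, p = diagonal_dominance(m, n_permutations=500, seed=0)
    assert p > 0.05
    # p is a valid Monte-Carlo p-value
    assert 1 / 501 <= p <= 1.0


def test_diagonal_dominance_is_seed_deterministic():
    rng = np.random.default_rng(6)
    m = rng.standard_normal((8, 8)) + 0.3 * np.eye(8)
    assert diagonal_dominance(m, seed=3) == diagonal_dominance(m, seed=3)


# ---------------------------------------------------------------------------
# mixture model


def _sample_mixture(rng, n, w, mu, sigma, pos, neg, loc=0.0):
    comp = rng.choice(3, size=n, p=w)
    out = np.empty(n)
    g = comp == 0
    out[g] = rng.normal(mu, sigma, g.sum())
    p = comp == 1
    out[p] = loc + rng.gamma(pos[0], pos[1], p.sum())
    m = comp == 2
    out[m] = loc - rng.gamma(neg[0], neg[1], m.sum())
    return out


def test_fit_mixture_recovers_parameters():
    rng = np.random.default_rng(7)
    z = _sample_mixture(
        rng, 20000, [0.8, 0.12, 0.08], 0.0, 1.0, (6.0, 0.8), (5.0, 0.7)
    )
    fit = fit_mixture(z)
    assert abs(fit.mu) < 0.05
    assert abs(fit.sigma - 1.0) < 0.1
    assert abs(fit.pos_shape - 6.0) / 6.0 < 0.2
    true_thr = stats.gamma.ppf(0.5, 6.0, scale=0.8)
    assert abs(fit.threshold - true_thr) < 0.15
    assert abs(fit.weights[0] - 0.8) < 0.05


def test_fit_mixture_loglik_is_monotone():
    rng = np.random.default_rng(8)
    z = _sample_mixture(rng, 5000, [0.7, 0.2, 0.1], 0.0, 1.0, (4.0, 1.0), (4.0, 1.0))
    fit = fit_mixture(z)
    assert np.all(np.diff(fit.loglik_trace) >= -1e-6)
    assert fit.converged


def test_fit_mixture_pure_gaussian_drops_gammas_gracefully():
    rng = np.random.default_rng(9)
    z = rng.normal(0.3, 1.2, 20000)
    fit = fit_mixture(z)
    # activation components should carry (nearly) no weight
    assert fit.weights[1] < 0.05
    assert abs(fit.mu - 0.3) < 0.05
    assert abs(fit.sigma - 1.2) < 0.1


def test_fit_mixture_small_sample_warns():
    rng = np.random.default_rng(10)
    z = rng.normal(size=200)
    with pytest.warns(UserWarning, match="fewer than 1000"):
        fit = fit_mixture(z)
    assert "small sample" in fit.flags


def test_threshold_map_masks_above_the_upper_gamma_median():
    rng = np.random.default_rng(11)
    z = _sample_mixture(rng, 20000, [0.8, 0.15, 0.05], 0.0, 1.0, (6.0, 0.8), (4.0, 0.7))
    fit = fit_mixture(z)
    mask = threshold_map(z, fit)
    np.testing.assert_array_equal(mask, z >= fit.threshold)
    assert 0 < mask.sum() < z.size


# ---------------------------------------------------------------------------
# Dice


def brute_force_dice(a, b):
    inter = sum(1 for x, y in zip(a, b) if x and y)
    total = sum(bool(x) for x in a) + sum(bool(y) for y in b)
    return 0.0 if total == 0 else 2.0 * inter / total


def test_dice_against_brute_force_random_pairs():
    rng = np.random.default_rng(12)
    for _ in range(200):
        n = rng.integers(1, 50)
        a = rng.random(n) < rng.random()
        b = rng.random(n) < rng.random()
        assert dice(a, b) == pytest.approx(brute_force_dice(a, b), abs=1e-15)


@settings(max_examples=200, deadline=None)
@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
def test_dice_property(pairs):
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    d = dice(a, b)
    assert d == pytest.approx(brute_force_dice(a, b), abs=1e-15)
    assert 0.0 <= d <= 1.0
    assert dice(a, b) == dice(b, a)  # symmetry
    if a.any():
        assert dice(a, a) == 1.0


def test_dice_edge_cases():
    assert dice(np.zeros(5, bool), np.zeros(5, bool)) == 0.0
    assert dice(np.ones(5, bool), np.ones(5, bool)) == 1.0
    with pytest.raises(ValueError):
        dice(np.ones(4, bool), np.ones(5, bool))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def test_compare_models_matches_hand_computed_anova():
    """Oracle: textbook sums-of-squares on a fixed 5-subject x 3-model table."""
    table = np.array(
        [
            [0.50, 0.62, 0.58],
            [0.44, 0.55, 0.52],
            [0.61, 0.70, 0.69],
            [0.38, 0.49, 0.47],
            [0.55, 0.66, 0.61],
        ]
    )
    n, k = table.shape
    grand = table.mean()
    ss_model = n * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_subject = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_error = ss_total - ss_model - ss_subject
    df_model, df_error = k - 1, (n - 1) * (k - 1)
    f_expected = (ss_model / df_model) / (ss_error / df_error)
    p_expected = stats.f.sf(f_expected, df_model, df_error)

    scores = {"glm": table[:, 0], "nn": table[:, 1], "rfbag": table[:, 2]}
    res = compare_models(scores)
    assert res["F"] == pytest.approx(f_expected, abs=1e-10)
    assert res["p"] == pytest.approx(p_expected, abs=1e-10)
    assert res["bonferroni_factor"] == 3
    assert set(res["pairwise"]) == {"nn > glm", "rfbag > glm", "rfbag > nn"}


def test_compare_models_pairwise_is_bonferroni_corrected_one_sided():
    rng = np.random.default_rng(13)
    base = rng.normal(0.5, 0.05, 12)
    scores = {"glm": base, "nn": base + 0.1 + 0.01 * rng.standard_normal(12)}
    res = compare_models(scores)
    raw = stats.ttest_rel(scores["nn"], scores["glm"], alternative="greater").pvalue
    assert res["pairwise"]["nn > glm"] == pytest.approx(min(1.0, raw * 1), abs=1e-12)
    assert res["bonferroni_factor"] == 1


def test_compare_models_identical_scores_are_degenerate():
    base = np.array([0.1, 0.5, 0.9, 0.3])
    res = compare_models({"a": base, "b": base.copy()})
    assert res["F"] == 0.0
    assert res["p"] == 1.0
    assert res["pairwise"]["b > a"] == 1.0


def test_compare_models_validates_inputs():
    with pytest.raises(ValueError):
        compare_models({"a": np.ones(5)})
    with pytest.raises(ValueError):
        compare_models({"a": np.ones(5), "b": np.ones(4)})
    with pytest.raises(ValueError):
        compare_models({"a": np.ones(2), "b": np.zeros(2)})


# ---------------------------------------------------------------------------
# learning curves


def test_learning_curve_shapes_and_grids(noiseless_cohort):
    subjects, truth, _space, parc = noiseless_cohort
    feats = [truth.subjects[s.subject_id].features for s in subjects]
    targs = [s.task_maps["lin"] for s in subjects]
    curve = learning_curve(
        feats[:6],
        targs[:6],
        feats[6:],
        targs[6:],
        parc,
        "glm",
        n_train_grid=(3, 6),
        m_grid=(1, 2),
        seed=0,
    )
    assert isinstance(curve, pd.DataFrame)
    assert list(curve.columns) == ["sweep", "value", "mean_cc"]
    assert curve[curve.sweep == "n_train"].value.tolist() == [3, 6]
    assert curve[curve.sweep == "m"].value.tolist() == [1, 2]
    assert np.isfinite(curve.mean_cc).all()
    with pytest.raises(ValueError):
        learning_curve(
            feats[:4], targs[:4], feats[6:], targs[6:], parc, "glm", n_train_grid=(5,)
        )
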