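"""Feature-extraction oracles: normalisation, PCA, ICA recovery, dual
regression, symmetry filtering, feature maps."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from resttask.cohort import make_group_networks
from resttask.features import (
    concat_normalized,
    dual_regression,
    extract_cohort_features,
    feature_maps,
    filter_symmetric,
    group_ica,
    group_reduce,
    normalize_timeseries,
    subcortical_signals,
)

from conftest import corr_rows


def test_normalize_timeseries_zscores_each_vertex():
    rng = np.random.default_rng(0)
    run = rng.standard_normal((5, 50)) * 3 + 2
    out, flat = normalize_timeseries(run)
    np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(out.std(axis=1), 1, atol=1e-12)
    assert not flat.any()


def test_normalize_timeseries_flags_constant_vertices():
    run = np.vstack([np.arange(10.0), np.full(10, 3.0)])
    out, flat = normalize_timeseries(run)
    assert flat.tolist() == [False, True]
    np.testing.assert_array_equal(out[1], 0.0)


def test_normalize_timeseries_rejects_bad_shapes():
    with pytest.raises(ValueError):
        normalize_timeseries(np.zeros(10))
    with pytest.raises(ValueError):
        normalize_timeseries(np.zeros((5, 1)))


def test_concat_normalized_stacks_along_time():
    rng = np.random.default_rng(1)
    runs = [rng.standard_normal((4, 20)), rng.standard_normal((4, 30))]
    out = concat_normalized(runs)
    assert out.shape == (4, 50)
    np.testing.assert_allclose(out[:, :20], normalize_timeseries(runs[0])[0])


def test_group_reduce_recovers_a_low_rank_subspace():
    rng = np.random.default_rng(2)
    basis = rng.standard_normal((3, 80))  # three spatial modes
    coeffs = rng.standard_normal((200, 3))
    data = coeffs @ basis
    reduced, explained = group_reduce(data, 5)
    assert reduced.shape == (5, 80)
    # rank-3 data: the first 3 components carry essentially all variance
    assert explained[:3].sum() > 1 - 1e-10
    assert explained[3:].sum() < 1e-10
    assert np.all(np.diff(explained) <= 1e-12)
    # the retained row space spans the basis
    proj = basis @ np.linalg.pinv(reduced[:3]) @ reduced[:3]
    np.testing.assert_allclose(proj, basis, atol=1e-8)


def test_group_reduce_validates_target_dim():
    with pytest.raises(ValueError):
        group_reduce(np.zeros((10, 5)), 6)
    with pytest.raises(ValueError):
        group_reduce(np.zeros((10, 5)), 0)


def test_group_ica_recovers_sparse_sources(space):
    """Oracle: mix known disjoint sparse maps, recover them via Hungarian
    matching on absolute correlation."""
    k = 4
    left, _right = make_group_networks(space, k, seed=5)
    rng = np.random.default_rng(6)
    mixing = rng.standard_normal((30, k))
    mixed = mixing @ left  # (30, n_h) noiseless mixtures
    maps = group_ica(mixed, k, seed=0)
    assert maps.shape == (k, space.n_per_hemisphere)
    cost = -np.abs(corr_rows(maps, left))
    rows, cols = linear_sum_assignment(cost)
    matched = -cost[rows, cols]
    assert matched.min() > 0.95


def test_group_ica_output_is_standardised_and_skew_positive():
    rng = np.random.default_rng(3)
    k = 3
    sources = np.zeros((k, 400))
    for i in range(k):
        sources[i, rng.choice(400, 40, replace=False)] = rng.gamma(3, 1, 40)
    mixed = rng.standard_normal((20, k)) @ sources
    maps = group_ica(mixed, k, seed=1)
    from scipy import stats

    np.testing.assert_allclose(maps.std(axis=1), 1, atol=1e-8)
    assert np.all(stats.skew(maps, axis=1) >= 0)


def test_group_ica_validates_k():
    with pytest.raises(ValueError):
        group_ica(np.zeros((4, 50)), 5)


def test_filter_symmetric_keeps_mirrored_components(space):
    k = 4
    left, right = make_group_networks(space, k, seed=7)
    n_h = space.n_per_hemisphere
    right_order = right  # already in right-vertex order
    # shuffle the right maps and add an unmatched noise component on each side
    rng = np.random.default_rng(8)
    perm = rng.permutation(k)
    noise_l = rng.standard_normal((1, n_h))
    noise_r = rng.standard_normal((1, n_h))
    comp = filter_symmetric(
        np.vstack([left, noise_l]), np.vstack([right_order[perm], noise_r]), space
    )
    assert comp.n_retained == k
    assert all(perm[ri] == li for li, ri, _s in comp.pairs)
    for _li, _ri, score in comp.pairs:
        assert score > 0.999
    full = comp.retained_full_maps(space)
    assert full.shape == (2 * k, space.n_vertices)
    # left block occupies left vertices only, right block right vertices only
    assert np.all(full[:k, n_h:] == 0)
    assert np.all(full[k:, :n_h] == 0)


def test_filter_symmetric_raises_when_nothing_matches(space):
    rng = np.random.default_rng(9)
    left = rng.standard_normal((3, space.n_per_hemisphere))
    right = rng.standard_normal((3, space.n_per_hemisphere))
    with pytest.raises(ValueError), pytest.warns(UserWarning):
        filter_symmetric(left, right, space, threshold=0.99)


def test_dual_regression_exact_on_noiseless_data(noiseless_cohort):
    subjects, truth, space, _parc = noiseless_cohort
    s = subjects[0]
    regressors = truth.network_loadings(space)
    maps = dual_regression(s.runs, regressors)
    c = np.diag(corr_rows(maps[: 2 * truth.k_networks], regressors[: 2 * truth.k_networks]))
    assert c.min() > 0.999


def test_dual_regression_recovers_subject_specific_maps(noisy_cohort):
    """With subject variability, a subject's dual-regression maps correlate
    more with their own true maps than with other subjects'."""
    subjects, truth, space, _parc = noisy_cohort
    group = truth.network_loadings(space)
    k = truth.k_networks
    own, other = [], []
    est = {
        s.subject_id: dual_regression(s.runs, group)[:k, : space.n_per_hemisphere]
        for s in subjects[:4]
    }
    for sid_i, maps_i in est.items():
        for s in subjects[:4]:
            c = np.mean(np.diag(corr_rows(maps_i, truth.subjects[s.subject_id].left_maps)))
            (own if s.subject_id == sid_i else other).append(c)
    assert np.mean(own) > np.mean(other)


def test_subcortical_signals_shape_and_content(noiseless_cohort):
    subjects, truth, space, _parc = noiseless_cohort
    s = subjects[0]
    sig = subcortical_signals(s.runs, space)
    assert sig.shape == (space.n_structures, sum(r.shape[1] for r in s.runs))
    # noiseless: all nodes of a structure share a course, so the mean of the
    # normalised series equals any one member's normalised series
    data = concat_normalized(s.runs)
    members = space.structure_members(1)
    np.testing.assert_allclose(sig[0], data[members[0]], atol=1e-8)


def test_feature_maps_shape_and_normalisation(noisy_cohort):
    subjects, truth, space, _parc = noisy_cohort
    s = subjects[0]
    group = truth.network_loadings(space)[: 2 * truth.k_networks]
    fm = feature_maps(s.runs, group, space, subject_id=s.subject_id)
    f = 2 * truth.k_networks + space.n_structures
    assert fm.values.shape == (space.n_vertices, f)
    np.testing.assert_allclose(fm.values.mean(axis=0), 0, atol=1e-10)
    np.testing.assert_allclose(fm.values.std(axis=0), 1, atol=1e-10)
    assert fm.meta["n_features"] == f


def test_feature_maps_unnormalised_values_are_correlations(noisy_cohort):
    subjects, truth, space, _parc = noisy_cohort
    s = subjects[0]
    group = truth.network_loadings(space)[: 2 * truth.k_networks]
    fm = feature_maps(s.runs, group, space, normalize=False)
    assert np.nanmax(np.abs(fm.values)) <= 1 + 1e-10


def test_extract_cohort_features_end_to_end(noisy_cohort):
    subjects, truth, space, _parc = noisy_cohort
    feats, comp = extract_cohort_features(
        subjects, space, target_dim=40, k_ica=6, seed=0
    )
    assert set(feats) == {s.subject_id for s in subjects}
    assert comp.n_retained >= 1
    f = 2 * comp.n_retained + space.n_structures
    for fm in feats.values():
        assert fm.values.shape == (space.n_vertices, f)
        assert np.isfinite(fm.values).all()
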