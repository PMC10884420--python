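import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psmcr import (
    SimulationConfig,
    propensity_scores,
    psm_update_cause,
    psm_update_joint,
    reference_point,
    simulate_dataset,
    update_indicators,
)

from conftest import make_dataset


def censored_dataset(n_censored=40, n_events=60, seed=0):
    """Continuous covariates (no distance ties), many censored subjects."""
    rng = np.random.default_rng(seed)
    n = n_censored + n_events
    statuses = np.array([0] * n_censored + [1, 2] * (n_events // 2))
    times = np.where(statuses == 0, 5.0, rng.uniform(0.2, 4.8, n))
    return make_dataset(times, statuses, rng.normal(size=(n, 3)), censoring_time=5.0)


class TestReferencePoint:
    def test_sign_pattern_selects_min_or_max(self):
        X = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        ref = reference_point(X, [-1, 1, 1], standardize=False)
        np.testing.assert_array_equal(ref.x_min, [4.0, 2.0, 3.0])

    def test_all_positive_signs_give_column_minima(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        ref = reference_point(X, [1, 1, 1, 1], standardize=False)
        np.testing.assert_array_equal(ref.x_min, X.min(axis=0))

    def test_coordinates_are_attained(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 3))
        ref = reference_point(X, [1, -1, 1])
        for j, val in enumerate(ref.x_min):
            assert val in X[:, j]

    def test_standardized_weights_are_inverse_variances(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2)) * [1.0, 5.0]
        ref = reference_point(X, [1, 1])
        np.testing.assert_allclose(ref.weights, 1.0 / X.std(axis=0, ddof=1) ** 2)


class TestPropensityScores:
    def test_reference_row_scores_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        ref = reference_point(X, [1, 1, 1])
        assert propensity_scores(ref.x_min[None, :], ref)[0] == pytest.approx(0.0)

    def test_pythagorean_example(self):
        from psmcr.psm import ReferencePoint

        ref = ReferencePoint(
            x_min=np.zeros(2), signs=np.ones(2, int), weights=np.ones(2), scale_sds=None
        )
        assert propensity_scores([[3.0, 4.0]], ref)[0] == pytest.approx(25.0)

    def test_linearity_in_weights(self):
        from psmcr.psm import ReferencePoint

        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 2))
        ref = ReferencePoint(np.zeros(2), np.ones(2, int), np.ones(2), None)
        half = ReferencePoint(np.zeros(2), np.ones(2, int), 0.5 * np.ones(2), None)
        np.testing.assert_allclose(
            propensity_scores(X, half), 0.5 * propensity_scores(X, ref)
        )


class TestUpdateIndicators:
    def test_p_one_updates_nobody(self):
        ind, _, _ = update_indicators(np.arange(1.0, 11.0), 1.0)
        assert ind.sum() == 0

    def test_p_zero_updates_everybody(self):
        ind, _, _ = update_indicators(np.arange(1.0, 11.0), 0.0)
        assert ind.sum() == 10

    def test_strict_ecdf_rule_on_deciles(self):
        deltas = np.arange(1.0, 11.0)
        ind, ranks, quantile = update_indicators(deltas, 0.9)
        # F(10) = 1.0 > 0.9 but F(9) = 0.9 is not strictly greater
        np.testing.assert_array_equal(ind, np.r_[np.zeros(9), 1].astype(int))
        assert quantile == 9.0

    def test_empty_deltas_rejected(self):
        with pytest.raises(ValueError):
            update_indicators(np.array([]), 0.9)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), p=st.floats(0.0, 1.0))
    def test_updated_fraction_matches_ecdf_tail(self, seed, p):
        deltas = np.random.default_rng(seed).uniform(size=25)
        ind, _, _ = update_indicators(deltas, p)
        assert ind.sum() == 25 - int(np.floor(p * 25 + 1e-12))


class TestUpdateCause:
    def test_no_censored_subjects_is_noop_with_warning(self):
        ds = make_dataset([1.0, 2.0, 3.0], [1, 2, 1], np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.warns(UserWarning, match="no censored"):
            out, upd = psm_update_cause(ds, 1)
        assert upd.n_updated == 0
        np.testing.assert_array_equal(out.statuses, ds.statuses)

    def test_tenth_of_censored_updated_at_default_threshold(self):
        ds = censored_dataset(n_censored=40)
        out, upd = psm_update_cause(ds, 1, p=0.9)
        assert upd.n_updated == 4  # floor(0.1 * 40)
        assert out.n_events(1) == ds.n_events(1) + 4

    def test_times_never_modified_and_only_zero_to_k(self):
        ds = censored_dataset()
        out, _ = psm_update_cause(ds, 2, p=0.8)
        np.testing.assert_array_equal(out.times, ds.times)
        changed = out.statuses != ds.statuses
        assert (ds.statuses[changed] == 0).all()
        assert (out.statuses[changed] == 2).all()

    def test_monotone_nesting_in_p(self):
        ds = censored_dataset()
        flipped = {}
        for p in (0.5, 0.7, 0.9):
            out, _ = psm_update_cause(ds, 1, p=p)
            flipped[p] = set(np.flatnonzero(out.statuses != ds.statuses))
        assert flipped[0.9] <= flipped[0.7] <= flipped[0.5]

    def test_exhausted_censored_set_is_fixed_point(self):
        ds = censored_dataset()
        once, upd = psm_update_cause(ds, 1, p=0.0)  # flips every censored subject
        assert upd.n_updated == (ds.statuses == 0).sum()
        with pytest.warns(UserWarning):
            twice, upd2 = psm_update_cause(once, 1, p=0.0)
        assert upd2.n_updated == 0
        np.testing.assert_array_equal(twice.statuses, once.statuses)


class TestUpdateJoint:
    def test_partition_conservation(self):
        ds = censored_dataset(seed=7)
        out, upds = psm_update_joint(ds, p=0.8)
        n_flipped = int(np.sum(out.statuses != ds.statuses))
        assert upds[1].n_updated + upds[2].n_updated == n_flipped
        assert out.n_events(1) == ds.n_events(1) + upds[1].n_updated
        assert out.n_events(2) == ds.n_events(2) + upds[2].n_updated

    def test_conflicts_resolved_by_larger_ecdf_rank(self):
        p = 0.8
        ds = censored_dataset(seed=8)
        out, upds = psm_update_joint(ds, p=p)
        censored = np.flatnonzero(ds.statuses == 0)
        # resolved assignments are disjoint
        assert not np.any((upds[1].indicators == 1) & (upds[2].indicators == 1))
        for i, idx in enumerate(censored):
            f1, f2 = upds[1].ecdf_ranks[i], upds[2].ecdf_ranks[i]
            status = out.statuses[idx]
            if status == 2:
                # cause 2 wins only when cause 1 did not flag, or its rank lost
                assert f2 > p and (f1 <= p or f2 > f1)
            elif status == 1:
                assert f1 > p


def test_study_scale_update_counts(sim_dataset):
    # ~10% of censored subjects flipped per cause at the default threshold
    n_censored = int((sim_dataset.statuses == 0).sum())
    _, upd = psm_update_cause(sim_dataset, 1, p=0.9)
    assert upd.n_updated == n_censored - int(np.floor(0.9 * n_censored))
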