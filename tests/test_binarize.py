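"""Severity-threshold fitting, binarization and variance comparability."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import sevnet as sv


def _oracle_cutoff(scores, target):
    """Brute force over all candidate integer cutoffs, lower cutoff on ties."""
    best, best_dev = None, np.inf
    for c in range(1, int(max(scores)) + 2):
        prev = np.mean(np.asarray(scores) >= c)
        if abs(prev - target) < best_dev - 1e-15:
            best, best_dev = c, abs(prev - target)
    return best


def _scheme_for(scores_by_group, target):
    scores = np.concatenate(scores_by_group)[:, None]
    labels = np.concatenate(
        [np.full(len(s), g) for g, s in enumerate(scores_by_group)]
    )
    return scores, labels, sv.fit_thresholds(scores, labels, ["D"], target)


class TestFitThresholds:
    def test_matches_bruteforce_oracle_on_reference_scores(self):
        scores = [0, 0, 1, 2, 3, 3, 4, 5, 6, 8]
        assert _oracle_cutoff(scores, 0.30) == 5  # prevalence exactly 0.30
        _, _, scheme = _scheme_for([np.array(scores)], 0.30)
        assert scheme.cutoffs[0, 0] == 5
        assert scheme.achieved[0, 0] == pytest.approx(0.30)

    @given(
        st.lists(st.integers(0, 12), min_size=5, max_size=40),
        st.floats(0.05, 0.95),
    )
    def test_matches_bruteforce_oracle_generally(self, scores, target):
        scores = np.asarray(scores)
        if np.unique(scores).size < 2:
            scores = np.append(scores, scores.max() + 1)
        _, _, scheme = _scheme_for([scores], target)
        assert scheme.cutoffs[0, 0] == _oracle_cutoff(scores, target)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 9, 200)
        scores, labels, scheme = _scheme_for([base, base + 2], 0.4)
        assert scheme.cutoffs[1, 0] == scheme.cutoffs[0, 0] + 2
        binary = sv.apply_thresholds(scores, labels, scheme)
        np.testing.assert_array_equal(
            binary.values[labels == 0], binary.values[labels == 1]
        )

    def test_symmetric_scores_at_half_target(self):
        scores = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9])
        _, _, scheme = _scheme_for([scores], 0.5)
        assert abs(scheme.achieved[0, 0] - 0.5) <= 1 / len(scores)

    def test_constant_domain_names_group_and_domain(self):
        scores = np.column_stack([np.arange(10), np.full(10, 3)])
        labels = np.zeros(10, dtype=int)
        with pytest.raises(ValueError, match="'B'.*group 1"):
            sv.fit_thresholds(scores, labels, ["A", "B"], 0.3)

    def test_rejects_targets_outside_unit_interval(self):
        scores = np.arange(10)[:, None]
        with pytest.raises(ValueError, match="target"):
            sv.fit_thresholds(scores, np.zeros(10, int), ["D"], 1.5)

    def test_unreachable_target_recorded_as_warning(self):
        # nearly-constant scores: achievable prevalences 0.05 or 0; target 0.9
        scores = np.r_[np.zeros(19), [5]][:, None]
        scheme = sv.fit_thresholds(scores, np.zeros(20, int), ["D"], 0.9)
        assert scheme.warnings and "D" in scheme.warnings[0]

    def test_cutoffs_nondecreasing_for_stochastically_ordered_groups(self):
        # shifted copies of one sample are exactly stochastically ordered
        rng = np.random.default_rng(2)
        base = rng.integers(0, 10, 300)
        groups = [base, base + 1, base + 3, base + 4]
        _, _, scheme = _scheme_for(groups, 0.35)
        assert np.all(np.diff(scheme.cutoffs, axis=0) >= 0)


class TestApplyThresholds:
    def test_cutoff_one_is_any_endorsement(self):
        scores = np.array([[0], [1], [2], [5]])
        scheme = sv.ThresholdScheme(
            np.array([[1]]), np.array([[0.75]]), np.array([0.75]), ["D"]
        )
        binary = sv.apply_thresholds(scores, np.zeros(4, int), scheme)
        np.testing.assert_array_equal(binary.values.ravel(), scores.ravel() > 0)

    def test_cutoff_above_max_gives_flagged_constant_column(self):
        scores = np.array([[0], [1], [2]])
        scheme = sv.ThresholdScheme(
            np.array([[9]]), np.array([[0.0]]), np.array([0.1]), ["D"]
        )
        with pytest.warns(UserWarning, match="constant"):
            binary = sv.apply_thresholds(scores, np.zeros(3, int), scheme)
        assert binary.values.sum() == 0
        assert binary.constant_columns(0) == ["D"]

    def test_matches_elementwise_comparison(self, small_cohort):
        scheme = sv.fit_thresholds(
            small_cohort.domain_scores, small_cohort.group_labels, small_cohort.domains
        )
        binary = sv.apply_thresholds(
            small_cohort.domain_scores, small_cohort.group_labels, scheme
        )
        for i in range(0, small_cohort.n_individuals, 17):
            g = small_cohort.group_labels[i]
            for j in range(len(small_cohort.domains)):
                expected = int(
                    small_cohort.domain_scores[i, j] >= scheme.cutoffs[g, j]
                )
                assert binary.values[i, j] == expected

    def test_missing_scores_are_an_error(self):
        scheme = sv.ThresholdScheme(
            np.array([[1]]), np.array([[0.5]]), np.array([0.5]), ["D"]
        )
        with pytest.raises(ValueError, match="missing"):
            sv.apply_thresholds(np.array([[np.nan]]), np.zeros(1, int), scheme)

    @given(st.integers(0, 199), st.integers(1, 5))
    def test_binarization_is_monotone(self, row, bump):
        """Raising one individual's score never flips endorsement 1 -> 0."""
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 10, (200, 3)).astype(float)
        labels = rng.integers(0, 2, 200)
        scheme = sv.fit_thresholds(scores, labels, ["A", "B", "C"], 0.4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            before = sv.apply_thresholds(scores, labels, scheme).values
            bumped = scores.copy()
            bumped[row, 1] += bump
            after = sv.apply_thresholds(bumped, labels, scheme).values
        assert np.all(after >= before)


class TestPrevalenceTable:
    def test_trivial_columns(self):
        values = np.array([[1, 1], [1, 0], [1, 1], [1, 0]])
        binary = sv.BinaryMatrix(values, ["A", "B"], np.zeros(4, int))
        table = sv.prevalence_table(binary)
        assert table.loc["group1", "A"] == 1.0
        assert table.loc["group1", "B"] == 0.5

    def test_matches_hand_count_and_range(self):
        values = np.array([[1, 0], [0, 0], [1, 1], [1, 1]])
        binary = sv.BinaryMatrix(values, ["A", "B"], np.array([0, 0, 1, 1]))
        table = sv.prevalence_table(binary)
        assert table.loc["group1", "A"] == 0.5
        assert table.loc["group2", "A"] == 1.0
        assert table.loc["range", "A"] == 0.5
        assert table.loc["range", "B"] == 1.0


def _bf_oracle(groups):
    """Textbook Brown-Forsythe: one-way ANOVA F on |x - group median|."""
    z = [np.abs(g - np.median(g)) for g in groups]
    n = sum(len(g) for g in z)
    k = len(z)
    grand = np.concatenate(z).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in z)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in z)
    stat = (ss_between / (k - 1)) / (ss_within / (n - k))
    return stat, stats.f.sf(stat, k - 1, n - k)


class TestVarianceEqualityTest:
    def test_identical_groups_give_zero_statistic(self):
        col = np.array([1, 0, 0, 1, 0, 0])
        values = np.concatenate([col, col])[:, None]
        binary = sv.BinaryMatrix(values, ["D"], np.repeat([0, 1], 6))
        out = sv.variance_equality_test(binary)
        assert out.loc["D", "statistic"] == pytest.approx(0.0)
        assert out.loc["D", "p_value"] == pytest.approx(1.0)

    def test_detects_unequal_prevalences(self):
        rng = np.random.default_rng(11)
        a = (rng.random(500) < 0.5).astype(int)
        b = (rng.random(500) < 0.9).astype(int)
        binary = sv.BinaryMatrix(
            np.concatenate([a, b])[:, None], ["D"], np.repeat([0, 1], 500)
        )
        assert sv.variance_equality_test(binary).loc["D", "p_value"] < 0.05

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(5)
        groups = [(rng.random(40) < q).astype(int) for q in (0.3, 0.4, 0.35)]
        values = np.concatenate(groups)[:, None]
        labels = np.repeat([0, 1, 2], 40)
        out = sv.variance_equality_test(sv.BinaryMatrix(values, ["D"], labels))
        stat, pval = _bf_oracle(groups)
        assert out.loc["D", "statistic"] == pytest.approx(stat, rel=1e-10)
        assert out.loc["D", "p_value"] == pytest.approx(pval, rel=1e-10)

    def test_requires_two_groups(self):
        binary = sv.BinaryMatrix(np.array([[1], [0]]), ["D"], np.zeros(2, int))
        with pytest.raises(ValueError, match="two groups"):
            sv.variance_equality_test(binary)
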