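"""Discretization, JMI ranking and the wrapper forward search."""

import math
from collections import Counter
from itertools import product

import numpy as np
import pytest

import tmrdecode as td
from tmrdecode.selection import Discretizer, joint_mutual_information, mutual_information


# --- independent plug-in MI oracles (Counter + math.log2) -------------------

def mi_oracle(x, y):
    n = len(x)
    cx, cy, cxy = Counter(x), Counter(y), Counter(zip(x, y))
    total = 0.0
    for (vx, vy), c in cxy.items():
        p = c / n
        total += p * math.log2(p / ((cx[vx] / n) * (cy[vy] / n)))
    return total


def jmi_score_oracle(levels, labels, k, ranked):
    """Sum over ranked j of I((X_k, X_j); Y), brute force."""
    pairs = [tuple(zip(levels[:, k], levels[:, j])) for j in ranked]
    return sum(mi_oracle(p, tuple(labels)) for p in pairs)


class TestDiscretize:
    def test_nine_point_grid(self):
        col = np.arange(1.0, 10.0).reshape(-1, 1)
        levels = td.discretize_tertiles(col)
        assert levels.ravel().tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=(60, 3))
        np.testing.assert_array_equal(
            td.discretize_tertiles(x), td.discretize_tertiles(np.exp(x))
        )

    def test_only_three_levels_and_constant_column(self, rng):
        x = rng.normal(size=(50, 2))
        x[:, 1] = 3.0
        levels = td.discretize_tertiles(x)
        assert set(np.unique(levels[:, 0])) <= {0, 1, 2}
        assert np.all(levels[:, 1] == 0)

    def test_cutpoints_fitted_on_training_reused(self, rng):
        train = rng.normal(size=(90, 2))
        disc = Discretizer().fit(train)
        other = rng.normal(size=(30, 2)) + 10  # shifted: mostly top level
        levels = disc.transform(other)
        assert np.mean(levels == 2) > 0.9


class TestMutualInformation:
    def test_label_copy_is_maximally_informative(self, rng):
        y = rng.integers(1, 6, size=200)
        X = np.column_stack([rng.integers(0, 3, size=(200, 4)), (y % 3)])
        mi = mutual_information(X, y)
        assert np.argmax(mi) == 4
        ranking = td.jmi_rank(X, y)
        assert ranking[0] == 4

    def test_independent_feature_has_zero_mi(self):
        # balanced factorial table: X independent of Y by construction
        X, y = [], []
        for lev, lab in product(range(3), range(1, 6)):
            X.extend([lev] * 4)
            y.extend([lab] * 4)
        mi = mutual_information(np.array(X).reshape(-1, 1), np.array(y))
        assert mi[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_counter_oracle(self, rng):
        X = rng.integers(0, 3, size=(120, 5))
        y = rng.integers(1, 4, size=120)
        mi = mutual_information(X, y)
        for k in range(5):
            assert mi[k] == pytest.approx(mi_oracle(tuple(X[:, k]), tuple(y)), abs=1e-12)
        jmi = joint_mutual_information(X, 2, y)
        for k in range(5):
            pair = tuple(zip(X[:, k], X[:, 2]))
            assert jmi[k] == pytest.approx(mi_oracle(pair, tuple(y)), abs=1e-12)


class TestJMIRanking:
    def test_duplicate_of_top_feature_is_penalized(self, rng):
        """JMI prefers a complementary feature over an exact duplicate."""
        n = 300
        y = rng.integers(1, 5, size=n)
        informative = y % 3
        duplicate = informative.copy()
        complementary = (y // 2) % 3  # informative about a different label split
        noise = rng.integers(0, 3, size=n)
        X = np.column_stack([informative, duplicate, complementary, noise])
        ranking = td.jmi_rank(X, y)
        assert ranking[0] == 0  # ties to the lower index of the duplicates
        assert list(ranking).index(2) < list(ranking).index(1)

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_step_scores_match_bruteforce_oracle(self, seed):
        """Every greedy pick attains the maximal oracle JMI score."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(40, 120), rng.integers(3, 7)
        y = rng.integers(1, 6, size=n)
        X = np.where(rng.random((n, m)) < 0.5, (y[:, None] + rng.integers(0, 3, (n, m))) % 3,
                     rng.integers(0, 3, (n, m)))
        ranking = list(td.jmi_rank(X, y))
        assert sorted(ranking) == list(range(m))
        # first pick maximizes I(X;Y)
        first_scores = [mi_oracle(tuple(X[:, k]), tuple(y)) for k in range(m)]
        assert first_scores[ranking[0]] == pytest.approx(max(first_scores), abs=1e-10)
        for step in range(1, m):
            ranked, remaining = ranking[:step], ranking[step:]
            scores = {k: jmi_score_oracle(X, y, k, ranked) for k in remaining}
            assert scores[ranking[step]] == pytest.approx(max(scores.values()), abs=1e-10)


class TestWrapper:
    @staticmethod
    def separable_table(rng, n_per_class=30, n_noise=4):
        """Two columns perfectly separate five classes; the rest are noise."""
        means = np.array([[0, 0], [8, 0], [0, 8], [8, 8], [4, 16]], dtype=float)
        X, y = [], []
        for c in range(5):
            X.append(means[c] + 0.3 * rng.normal(size=(n_per_class, 2)))
            y.extend([c + 1] * n_per_class)
        X = np.vstack(X)
        X = np.column_stack([X, rng.normal(size=(len(y), n_noise))])
        return X, np.array(y)

    def test_noise_candidates_rejected_and_curve_decreases(self, rng):
        X, y = self.separable_table(rng)
        ranking = np.arange(X.shape[1])
        sel = td.wrapper_select(ranking, X, y, seed=5)
        assert list(sel.selected[:2]) == [0, 1]
        assert sel.error_curve[0] == pytest.approx(0.0, abs=1e-12)
        assert len(sel.selected) == 2  # nothing can improve on a 0 error
        assert np.all(np.diff(sel.error_curve) < 0) or len(sel.error_curve) == 1

    def test_all_noise_acceptances_are_rare_record_events(self, rng):
        """On pure noise, acceptances are chance record-lows of the CV error:
        few occur, and each one strictly lowered the running best."""
        accepted = []
        for seed in range(4):
            X = rng.normal(size=(150, 12))
            y = np.repeat(np.arange(1, 6), 30)
            sel = td.wrapper_select(np.arange(12), X, y, seed=seed)
            accepted.append(len(sel.selected) - 2)
            assert np.all(np.diff(sel.error_curve) < 0) or len(sel.error_curve) == 1
            assert list(sel.selected[:2]) == [0, 1]
        # 10 noise candidates per run: record lows stay well below the
        # candidate count (each noise run is a record-breaking process)
        assert np.mean(accepted) <= 5
        assert max(accepted) < 10

    def test_strictly_decreasing_curve_on_informative_data(self, rng):
        # staged informativeness: each column refines the class further
        n = 200
        y = rng.integers(1, 6, size=n)
        X = np.column_stack([
            (y <= 2) + 0.5 * rng.normal(size=n),
            (y % 2) + 0.5 * rng.normal(size=n),
            y + 0.7 * rng.normal(size=n),
            (y == 5) + 0.6 * rng.normal(size=n),
            rng.normal(size=n),
        ])
        sel = td.wrapper_select(np.arange(5), X, y, seed=2)
        assert np.all(np.diff(sel.error_curve) < 0) or len(sel.error_curve) == 1

    def test_invariant_to_trailing_constant_columns(self, rng):
        X, y = self.separable_table(rng)
        Xc = np.column_stack([X, np.full((len(y), 2), 1.5)])
        ranking = np.arange(X.shape[1])
        ranking_c = np.concatenate([ranking, [X.shape[1], X.shape[1] + 1]])
        a = td.wrapper_select(ranking, X, y, seed=5)
        b = td.wrapper_select(ranking_c, Xc, y, seed=5)
        np.testing.assert_array_equal(a.selected, b.selected)
        np.testing.assert_allclose(a.error_curve, b.error_curve)

    def test_too_few_trials_per_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.repeat(np.arange(1, 6), 4)
        with pytest.raises(ValueError, match="10-fold"):
            td.wrapper_select(np.arange(3), X, y, seed=0)

    def test_degenerate_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            td.jmi_rank(rng.integers(0, 3, (30, 3)), np.ones(30, dtype=int))
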