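import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from top2track.feature_selection import (
    DiscretizedMatrix,
    SSParams,
    SUCache,
    cfs_merit,
    discretize_matrix,
    entropy_bits,
    fcbf,
    mdl_cut_points,
    run_selection_cv,
    scatter_search,
    selection_stability,
    symmetrical_uncertainty,
)
from top2track.synthetic_world import simulate_selection_matrix


def su_oracle(x, y):
    """From-scratch SU via explicit probability tables."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)

    def H(v):
        out = 0.0
        for val in set(v.tolist()):
            p = float(np.mean(v == val))
            out -= p * math.log2(p)
        return out

    hx, hy = H(x), H(y)
    if hx + hy == 0:
        return 0.0
    mi = 0.0
    for xv in set(x.tolist()):
        for yv in set(y.tolist()):
            pxy = float(np.mean((x == xv) & (y == yv)))
            if pxy > 0:
                px = float(np.mean(x == xv))
                py = float(np.mean(y == yv))
                mi += pxy * math.log2(pxy / (px * py))
    return 2.0 * mi / (hx + hy)


class TestSymmetricalUncertainty:
    def test_identical_vectors(self):
        assert symmetrical_uncertainty([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_independent_vectors(self):
        assert symmetrical_uncertainty([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # H(X)=0.8113, H(Y)=1, I=0.3113 -> SU ~ 0.344
        su = symmetrical_uncertainty([0, 0, 0, 1], [0, 0, 1, 1])
        assert su == pytest.approx(0.3437, abs=1e-4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            symmetrical_uncertainty([0, 1], [0, 1, 1])

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 60))
            x = rng.integers(0, int(rng.integers(2, 5)), n)
            y = rng.integers(0, int(rng.integers(2, 5)), n)
            assert abs(symmetrical_uncertainty(x, y) - su_oracle(x, y)) < 1e-12

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=40))
    def test_symmetry_and_bounds(self, xs):
        rng = np.random.default_rng(len(xs))
        ys = rng.integers(0, 3, len(xs))
        a = symmetrical_uncertainty(xs, ys)
        b = symmetrical_uncertainty(ys, xs)
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 <= a <= 1.0


class TestMdlDiscretization:
    def test_clean_split_found(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 100)
        x = np.concatenate([rng.normal(0, 0.3, 100), rng.normal(3, 0.3, 100)])
        cuts = mdl_cut_points(x, y)
        assert len(cuts) >= 1
        assert 0.8 < cuts[0] < 2.2

    def test_noise_gets_no_cut(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        x = rng.normal(size=200)
        assert mdl_cut_points(x, y) == []

    def test_fallback_bins_applied(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        X = rng.normal(size=(100, 1))
        dm = discretize_matrix(X, y)
        assert len(dm.bin_edges[0]) >= 5  # equal-frequency fallback
        assert dm.values.max() >= 5

    def test_edges_reapply_to_new_rows(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 50)
        X = (y * 2.0 + rng.normal(0, 0.3, 100)).reshape(-1, 1)
        dm = discretize_matrix(X, y)
        codes = dm.transform(np.array([[-10.0], [10.0]]))
        assert codes[0, 0] == 0
        assert codes[1, 0] == dm.values.max()


def _dm(codes, names=None):
    codes = np.asarray(codes)
    names = names or [f"f{i}" for i in range(codes.shape[1])]
    return DiscretizedMatrix(
        values=codes, feature_names=names, bin_edges=[[] for _ in names]
    )


class TestFcbf:
    def test_redundant_copy_removed_and_constant_excluded(self):
        y = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        f1 = y.copy()
        f2 = y.copy()  # exact copy of f1 -> redundant
        f3 = np.zeros_like(y)  # constant -> SU 0, excluded at delta=0
        dm = _dm(np.column_stack([f1, f2, f3]), ["f1", "f2", "f3"])
        assert fcbf(dm, y) == ["f1"]

    def test_all_constant_gives_empty(self):
        y = np.array([0, 1, 0, 1])
        dm = _dm(np.zeros((4, 3), dtype=int))
        assert fcbf(dm, y) == []

    def test_single_informative_feature(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 40)
        noise = rng.integers(0, 2, 40)
        dm = _dm(np.column_stack([noise * 0, y]), ["const", "good"])
        assert fcbf(dm, y) == ["good"]

    def test_redundancy_invariant_on_random_runs(self):
        # every removed feature is dominated by some kept feature
        rng = np.random.default_rng(5)
        for _ in range(10):
            n, d = 80, 8
            y = rng.integers(0, 2, n)
            codes = rng.integers(0, 3, (n, d))
            codes[:, 0] = y
            codes[:, 1] = codes[:, 0]
            dm = _dm(codes)
            kept = fcbf(dm, y)
            cache = SUCache(codes, y)
            kept_idx = [int(f[1:]) for f in kept]
            for j in range(d):
                if f"f{j}" in kept or cache.su_class[j] <= 0:
                    continue
                assert any(
                    cache.su_pair(i, j) >= cache.su_class[j] for i in kept_idx
                )


class TestCfsMerit:
    def test_singleton_collapses_to_su(self):
        su_class = np.array([0.7, 0.2])
        assert cfs_merit([0], su_class, lambda i, j: 0.0) == pytest.approx(0.7)

    def test_two_uncorrelated_features(self):
        su_class = np.array([0.5, 0.5])
        merit = cfs_merit([0, 1], su_class, lambda i, j: 0.0)
        assert merit == pytest.approx(1 / math.sqrt(2), abs=1e-9)

    def test_duplicating_feature_never_increases_merit(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            su = float(rng.uniform(0.05, 0.9))
            k = int(rng.integers(1, 6))
            su_class = np.full(k + 1, su)

            def pair(i, j, k=k):
                # features 0..k-1 mutually uncorrelated; feature k duplicates 0
                return 1.0 if {i, j} == {0, k} else 0.0

            base = cfs_merit(list(range(k)), su_class, pair)
            with_dup = cfs_merit(list(range(k + 1)), su_class, pair)
            assert with_dup <= base + 1e-12

    def test_empty_subset_errors(self):
        with pytest.raises(ValueError):
            cfs_merit([], np.array([0.5]), lambda i, j: 0.0)


class TestScatterSearch:
    def test_matches_exhaustive_on_small_instances(self):
        for trial in range(8):
            rng = np.random.default_rng(trial)
            n = int(rng.integers(4, 13))
            rows = 120
            y = rng.integers(0, 2, rows)
            X = rng.normal(size=(rows, n))
            for j in range(int(rng.integers(1, 4))):
                X[:, j] += rng.uniform(0.5, 2.0) * y
            codes = np.column_stack(
                [
                    np.digitize(X[:, j], np.quantile(X[:, j], [0.25, 0.5, 0.75]))
                    for j in range(n)
                ]
            )
            dm = _dm(codes)
            cache = SUCache(codes, y)
            best = max(
                cfs_merit(sub, cache.su_class, cache.su_pair)
                for k in range(1, n + 1)
                for sub in itertools.combinations(range(n), k)
            )
            selected = scatter_search(dm, y, SSParams(seed=trial))
            got = cfs_merit(
                [int(s[1:]) for s in selected], cache.su_class, cache.su_pair
            )
            assert got == pytest.approx(best, abs=1e-12)

    def test_all_constant_degenerates_to_single_feature(self):
        y = np.array([0, 1] * 20)
        dm = _dm(np.zeros((40, 5), dtype=int))
        selected = scatter_search(dm, y, SSParams(seed=0))
        assert len(selected) == 1

    def test_merit_at_least_best_singleton(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 100)
        codes = rng.integers(0, 4, (100, 10))
        codes[:, 3] = y ^ (rng.random(100) < 0.1)
        dm = _dm(codes)
        cache = SUCache(codes, y)
        selected = scatter_search(dm, y, SSParams(seed=9))
        got = cfs_merit([int(s[1:]) for s in selected], cache.su_class, cache.su_pair)
        assert got >= cache.su_class.max() - 1e-12

    def test_determinism(self):
        X, names, y = simulate_selection_matrix(n_rows=200, seed=5)
        dm = discretize_matrix(X, y, names)
        a = scatter_search(dm, y, SSParams(seed=3))
        b = scatter_search(dm, y, SSParams(seed=3))
        assert a == b

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SSParams(pop_size=5, b1=5, b2=5)


class TestSelectionStability:
    def test_identical_runs(self):
        assert selection_stability([["a", "b"], ["a", "b"], ["b", "a"]]) == 1.0

    def test_disjoint_runs(self):
        assert selection_stability([["a"], ["b"]]) == 0.0

    def test_jaccard_arithmetic(self):
        assert selection_stability([["a", "b"], ["b", "c"]]) == pytest.approx(1 / 3)

    def test_empty_run_contributes_zero(self):
        assert selection_stability([["a"], []]) == 0.0

    def test_needs_two_runs(self):
        with pytest.raises(ValueError):
            selection_stability([["a"]])


class TestRunSelectionCv:
    def test_ss_recovers_causal_features_with_full_stability(self):
        X, names, y = simulate_selection_matrix(seed=7)
        result = run_selection_cv(X, y, names, method="ss", folds=5, seed=7)
        assert result.stability == 1.0
        assert result.n_features_mean == 3.0
        for run in result.runs:
            assert sorted(run) == ["signal_1", "signal_2", "signal_3"]

    def test_informative_su_exceeds_threshold(self):
        X, names, y = simulate_selection_matrix(seed=7)
        result = run_selection_cv(X, y, names, method="fcbf", folds=5, seed=7)
        for f in ("signal_1", "signal_2", "signal_3"):
            assert result.su_class[f] >= 0.29
        # FCBF keeps the causal features in every fold
        for run in result.runs:
            assert {"signal_1", "signal_2", "signal_3"} <= set(run)
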