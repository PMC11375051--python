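"""Mutual information, discretization, and greedy mRMR selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaborderm.mrmr import (
    ablation_sweep,
    discretize,
    entropy,
    fit_discretization,
    mrmr_select,
    mutual_information,
    redundancy,
    relevance,
)


def brute_force_mrmr(states, labels, k):
    """Independent greedy re-implementation of the selection criterion.

    Deliberately naive: recomputes every MI from contingency tables built
    with python loops, no caching, no shared helpers.
    """

    def mi(a, b):
        n = len(a)
        pa, pb, pab = {}, {}, {}
        for x, y in zip(a, b):
            pa[x] = pa.get(x, 0) + 1
            pb[y] = pb.get(y, 0) + 1
            pab[(x, y)] = pab.get((x, y), 0) + 1
        total = 0.0
        for (x, y), c in pab.items():
            pxy = c / n
            total += pxy * np.log2(pxy / ((pa[x] / n) * (pb[y] / n)))
        return total

    d = states.shape[1]
    rel = [mi(states[:, j], labels) for j in range(d)]
    order = [int(np.argmax(rel))]
    while len(order) < k:
        best, best_score = None, -np.inf
        for i in range(d):
            if i in order:
                continue
            red = np.mean([mi(states[:, i], states[:, j]) for j in order])
            score = rel[i] - red
            if score > best_score + 1e-12:
                best, best_score = i, score
        order.append(best)
    return order


class TestDiscretization:
    def test_normal_sample_mid_fraction_near_68_percent(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal((10000, 1))
        rule = fit_discretization(col)
        states = discretize(col, rule)
        mid_frac = float((states == 1).mean())
        assert mid_frac == pytest.approx(0.683, abs=0.03)

    def test_constant_column_flagged_all_mid(self):
        values = np.column_stack([np.ones(50), np.arange(50.0)])
        rule = fit_discretization(values)
        assert rule.constant_columns.tolist() == [True, False]
        states = discretize(values, rule)
        assert np.all(states[:, 0] == 1)

    def test_train_fit_rule_reused_on_test_rows(self):
        rng = np.random.default_rng(1)
        train = rng.normal(0, 1, (200, 3))
        test = rng.normal(5, 1, (50, 3))  # shifted: mostly 'high' states
        rule = fit_discretization(train)
        states = discretize(test, rule)
        assert (states == 2).mean() > 0.9


class TestMutualInformation:
    def test_identity_is_entropy_log2_3(self):
        x = np.tile([0, 1, 2], 600)
        assert mutual_information(x, x) == pytest.approx(
            np.log2(3), abs=1e-9
        )
        assert entropy(x) == pytest.approx(np.log2(3), abs=1e-12)

    def test_independent_pair_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 5000)
        y = rng.integers(0, 3, 5000)
        assert mutual_information(x, y) <= 0.05

    def test_deterministic_function_gives_entropy(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 4, 1000)
        x = y % 2  # X is a deterministic function of Y
        assert mutual_information(x, y) == pytest.approx(
            entropy(x), abs=1e-12
        )

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            x = rng.integers(0, 4, n)
            y = rng.integers(0, 3, n)
            ixy = mutual_information(x, y)
            iyx = mutual_information(y, x)
            assert ixy >= 0
            assert ixy == pytest.approx(iyx, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information([0, 1], [0, 1, 2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=40),
        st.data(),
    )
    def test_information_inequalities_hold(self, x, data):
        """0 <= I(X;Y) <= min(H(X), H(Y)) and I(X;X) = H(X)."""
        y = data.draw(
            st.lists(st.integers(0, 3), min_size=len(x), max_size=len(x))
        )
        x, y = np.array(x), np.array(y)
        mi = mutual_information(x, y)
        assert 0.0 <= mi <= min(entropy(x), entropy(y)) + 1e-12
        assert mutual_information(x, x) == pytest.approx(
            entropy(x), abs=1e-12
        )


class TestRelevanceRedundancy:
    def test_single_feature_relevance_is_its_mi(self):
        rng = np.random.default_rng(5)
        f = rng.integers(0, 3, 100)
        c = rng.integers(0, 2, 100)
        assert relevance(f[:, None], c) == pytest.approx(
            mutual_information(f, c)
        )

    def test_empty_subset_relevance_zero(self):
        assert relevance(np.empty((10, 0)), np.zeros(10)) == 0.0

    def test_two_feature_relevance_is_arithmetic_mean(self):
        # 6-row toy, worked by hand: f1 = C exactly (I = H(C) = log2 3),
        # f2 exactly independent of C (I = 0); mean = log2(3)/2
        c = np.array([0, 0, 1, 1, 2, 2])
        f1 = c.copy()
        f2 = np.array([0, 1, 0, 1, 0, 1])
        got = relevance(np.column_stack([f1, f2]), c)
        assert got == pytest.approx(np.log2(3) / 2, abs=1e-12)

    def test_single_feature_redundancy_is_entropy(self):
        f = np.array([0, 0, 1, 1, 2, 2])
        assert redundancy(f[:, None]) == pytest.approx(
            entropy(f), abs=1e-12
        )

    def test_printed_normalization_two_independent_features(self):
        # exact-count independent pair: I(f1,f2)=0, so the double sum is
        # H(f1)+H(f2) and the printed |F| normalization halves it
        f1 = np.array([0, 0, 1, 1] * 9)
        f2 = np.array([0, 1, 0, 1] * 9)
        sub = np.column_stack([f1, f2])
        expected = (entropy(f1) + entropy(f2)) / 2
        assert redundancy(sub) == pytest.approx(expected, abs=1e-12)
        assert redundancy(sub, "squared") == pytest.approx(
            expected / 2, abs=1e-12
        )

    def test_duplicated_pair_more_redundant_than_independent(self):
        f1 = np.array([0, 0, 1, 1] * 9)
        f2 = np.array([0, 1, 0, 1] * 9)
        dup = np.column_stack([f1, f1])
        indep = np.column_stack([f1, f2])
        assert redundancy(dup) > redundancy(indep)


class TestMrmrSelect:
    def test_redundancy_penalty_defers_the_duplicate(self):
        rng = np.random.default_rng(10)
        n = 300
        c = rng.integers(0, 3, n)
        f1 = np.where(rng.random(n) < 0.9, c, rng.integers(0, 3, n))
        f2 = f1.copy()  # exact duplicate of the strong predictor
        f3 = np.where(rng.random(n) < 0.6, c, rng.integers(0, 3, n))
        states = np.column_stack([f1, f2, f3])
        result = mrmr_select(states, c, k=3)
        assert result.order == [0, 2, 1]
        assert result.order == brute_force_mrmr(states, c, 3)

    def test_k_one_returns_max_relevance_feature(self):
        rng = np.random.default_rng(11)
        c = rng.integers(0, 2, 200)
        noise = rng.integers(0, 3, 200)
        states = np.column_stack([noise, c])
        result = mrmr_select(states, c, k=1)
        assert result.order == [1]
        assert result.relevance_trace[0] == pytest.approx(
            mutual_information(c, c)
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 300, 8
        labels = rng.integers(0, 7, n)
        raw = rng.normal(size=(n, d))
        raw[:, :3] += labels[:, None] * rng.uniform(0.2, 0.8, 3)
        states = discretize(raw, fit_discretization(raw))
        result = mrmr_select(states, labels, k=d)
        assert result.order == brute_force_mrmr(states, labels, d)

    def test_traces_have_length_k(self):
        rng = np.random.default_rng(12)
        states = rng.integers(0, 3, (100, 5))
        labels = rng.integers(0, 3, 100)
        result = mrmr_select(states, labels, k=4)
        assert result.k == 4
        assert len(result.relevance_trace) == 4
        assert len(result.criterion_trace) == 4
        assert len(set(result.order)) == 4

    def test_k_exceeding_dimension_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            mrmr_select(np.zeros((10, 3), dtype=int), np.zeros(10), k=4)


@pytest.fixture(scope="module")
def sweep_data():
    rng = np.random.default_rng(20)
    n, d = 240, 12
    y = rng.integers(0, 3, n)
    x = rng.normal(size=(n, d))
    x[:, :4] += 1.2 * y[:, None]  # informative block
    return x[:160], y[:160], x[160:], y[160:]


class TestAblationSweep:
    def test_curve_peak_at_least_k10(self, sweep_data):
        xtr, ytr, xte, yte = sweep_data
        curve = ablation_sweep(
            xtr, ytr, xte, yte, ks=[2, 4, 8, 12], kernels=("linear",)
        )
        accs = curve.accuracy["linear"]
        assert max(accs) >= accs[0]
        _, best = curve.best_k("linear")
        assert best == max(accs)

    def test_full_k_equals_no_selection(self, sweep_data):
        from gaborderm.classify import SVMSpec, train_classifier

        xtr, ytr, xte, yte = sweep_data
        curve = ablation_sweep(
            xtr, ytr, xte, yte, ks=[12], kernels=("linear",)
        )
        model = train_classifier(xtr, ytr, SVMSpec("linear"))
        baseline = float(np.mean(model.predict(xte) == yte))
        assert curve.accuracy["linear"][0] == pytest.approx(baseline)

    def test_empty_ks_rejected(self, sweep_data):
        xtr, ytr, xte, yte = sweep_data
        with pytest.raises(ValueError, match="non-empty"):
            ablation_sweep(xtr, ytr, xte, yte, ks=[])
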