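import warnings

import numpy as np
import pytest

from cdenet.curves import StepCDF
from cdenet.evaluate import (
    binomial_ll,
    brier_score,
    c_index_td,
    coverage_rate,
    cross_validate,
    integrate_scores,
    km_censoring,
    made,
    percentile_calibration,
    prediction_errors,
    score_panel,
)


class TestKMCensoring:
    def test_no_censoring_gives_unit_curve(self):
        G = km_censoring([1, 2, 3], [1, 1, 1])
        assert np.all(G(np.array([0.5, 2.0, 10.0])) == 1.0)

    def test_all_censored_at_one_time(self):
        G = km_censoring([1, 1, 1, 1], [0, 0, 0, 0])
        assert G(1.0) == 0.0
        assert G(0.99) == 1.0

    def test_mixed_toy_product_limit(self):
        # censoring events at t=2 (5 at risk: y>=2) and t=4 (3 at risk):
        # G(2) = 4/5, G(4) = 4/5 * 2/3 = 8/15
        y = [1, 2, 3, 4, 5, 6]
        delta = [1, 0, 1, 0, 1, 1]
        G = km_censoring(y, delta)
        assert G(2.0) == pytest.approx(4 / 5)
        assert G(4.0) == pytest.approx(8 / 15)
        assert G.left_limit(2.0) == 1.0
        assert G.left_limit(4.0) == pytest.approx(4 / 5)


class TestCIndex:
    def test_perfectly_ordered_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        delta = np.ones(3, dtype=int)
        # S(y_i | x_j) larger for later-failing subjects at every i
        S = np.array([[0.1, 0.5, 0.9], [0.1, 0.3, 0.8], [0.05, 0.2, 0.6]])
        assert c_index_td(S, y, delta) == 1.0

    def test_uninformative_predictions_score_half(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        S = np.full((4, 4), 0.5)
        assert c_index_td(S, y, np.ones(4, int)) == 0.5

    def test_matches_pair_enumeration(self, rng):
        n = 8
        y = rng.integers(1, 6, n).astype(float)
        delta = (rng.random(n) < 0.7).astype(int)
        S = rng.uniform(size=(n, n))
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if delta[i] == 1 and y[i] < y[j]:
                    den += 1
                    if S[i, i] < S[i, j]:
                        num += 1
                    elif S[i, i] == S[i, j]:
                        num += 0.5
        assert c_index_td(S, y, delta) == pytest.approx(num / den)

    def test_random_instances_match_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 30))
            y = rng.integers(1, 8, n).astype(float)
            delta = (rng.random(n) < 0.6).astype(int)
            S = np.round(rng.uniform(size=(n, n)), 1)  # induce ties
            comparable = [(i, j) for i in range(n) for j in range(n)
                          if delta[i] == 1 and y[i] < y[j]]
            if not comparable:
                with pytest.raises(ValueError):
                    c_index_td(S, y, delta)
                continue
            num = sum(
                1.0 if S[i, i] < S[i, j] else 0.5 if S[i, i] == S[i, j] else 0.0
                for i, j in comparable
            )
            assert c_index_td(S, y, delta) == pytest.approx(num / len(comparable))

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            c_index_td(np.eye(2), np.array([1.0, 1.0]), np.array([1, 1]))


class TestBrierAndBLL:
    def test_bs_zero_before_any_event_with_unit_survival(self):
        y = np.array([2.0, 3.0, 4.0])
        delta = np.ones(3, int)
        G = km_censoring(y, delta)
        assert brier_score(1.0, np.ones(3), y, delta, G) == 0.0

    def test_bs_quarter_for_coin_flip_after_all_events(self):
        y = np.array([1.0, 2.0, 3.0])
        delta = np.ones(3, int)
        G = km_censoring(y, delta)
        assert brier_score(5.0, np.full(3, 0.5), y, delta, G) == pytest.approx(0.25)

    def test_no_censoring_reduces_to_mean_squared_error(self, rng):
        n = 40
        y = rng.exponential(2, n)
        delta = np.ones(n, int)
        G = km_censoring(y, delta)
        t = float(np.median(y))
        S = rng.uniform(size=n)
        expected = np.mean(((y > t).astype(float) - S) ** 2)
        assert brier_score(t, S, y, delta, G) == pytest.approx(expected)

    def test_toy_ipcw_hand_computation(self):
        # y = (1,2,3,4,5), censored at 2; t = 3.5
        # censoring KM: one censoring event at t=2 with 4 at risk -> G = 3/4 after 2
        # died by 3.5 with events: i=1 (G(1-)=1), i=3 (G(3-)=3/4)
        # alive at 3.5: i=4, i=5 (G(3.5)=3/4)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        delta = np.array([1, 0, 1, 1, 1])
        S = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        G = km_censoring(y, delta)
        expected_bs = (
            S[0] ** 2 / 1.0 + S[2] ** 2 / 0.75
            + (1 - S[3]) ** 2 / 0.75 + (1 - S[4]) ** 2 / 0.75
        ) / 5
        assert brier_score(3.5, S, y, delta, G) == pytest.approx(expected_bs)
        expected_bll = (
            np.log(1 - S[0]) / 1.0 + np.log(1 - S[2]) / 0.75
            + np.log(S[3]) / 0.75 + np.log(S[4]) / 0.75
        ) / 5
        assert binomial_ll(3.5, S, y, delta, G) == pytest.approx(expected_bll)

    def test_bll_clipping_warns_but_stays_finite(self):
        y = np.array([1.0, 2.0])
        delta = np.array([1, 1])
        G = km_censoring(y, delta)
        with pytest.warns(UserWarning, match="clipping"):
            val = binomial_ll(1.5, np.array([1.0, 1.0]), y, delta, G)
        assert np.isfinite(val) and val < 0

    def test_true_model_bs_bounded_by_quarter_without_censoring(self, rng):
        # with the true conditional survival plugged in, BS(t) <= Var bound 0.25
        n = 4000
        lam = rng.uniform(0.5, 1.5, n)
        y = rng.exponential(1 / lam)
        delta = np.ones(n, int)
        G = km_censoring(y, delta)
        for t in np.quantile(y, [0.2, 0.5, 0.8]):
            S_true = np.exp(-lam * t)
            assert brier_score(t, S_true, y, delta, G) <= 0.25 + 0.02


class TestIntegrateScores:
    def test_constant_curve(self):
        t = np.linspace(2, 7, 50)
        assert integrate_scores(t, np.full(50, 0.3)) == pytest.approx(0.3)

    def test_linear_curve(self):
        t = np.linspace(0, 1, 101)
        assert integrate_scores(t, t) == pytest.approx(0.5)

    def test_matches_fine_riemann_oracle(self, rng):
        t = np.linspace(0, 4, 100)
        v = np.interp(t, [0, 1, 3, 4], rng.uniform(0, 1, 4))
        fine = np.linspace(0, 4, 100_000)
        oracle = np.interp(fine, t, v).mean()
        assert integrate_scores(t, v) == pytest.approx(oracle, abs=1e-3)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            integrate_scores([1.0, 1.0], [0.5, 0.5])


class TestMade:
    def test_exact_and_shifted(self, rng):
        F = rng.uniform(0.1, 0.9, 50)
        assert made(F, F) == 0.0
        assert made(F + 0.05, F) == pytest.approx(0.05)

    def test_tail_truncation_filter(self, rng):
        F_true = np.array([0.0005, 0.5, 0.9995])
        F_hat = F_true + np.array([0.3, 0.1, 0.3])
        assert made(F_hat, F_true) == pytest.approx(0.1)

    def test_filtered_mean_oracle(self, rng):
        F_true = rng.uniform(0, 1, 200)
        F_hat = np.clip(F_true + rng.normal(0, 0.05, 200), 0, 1)
        keep = (F_true >= 0.001) & (F_true <= 0.999)
        assert made(F_hat, F_true) == pytest.approx(
            np.abs(F_hat - F_true)[keep].mean()
        )

    def test_empty_filter_rejected(self):
        with pytest.raises(ValueError):
            made(np.array([0.5]), np.array([0.9999]))


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        assert prediction_errors([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_toy_hand_values(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.0, 5.0, 4.0, 4.0])
        msq, medsq = prediction_errors(pred, y)
        assert msq == pytest.approx((1 + 0 + 4 + 0 + 1) / 5)
        assert medsq == pytest.approx(1.0)

    def test_whole_line_interval_covers_everything(self, rng):
        y = rng.normal(size=20)
        iv = np.column_stack([np.full(20, -1e9), np.full(20, 1e9)])
        assert coverage_rate(iv, y) == 1.0

    def test_coverage_counts_boundaries(self):
        iv = np.array([[0.0, 1.0], [0.0, 1.0], [2.0, 3.0]])
        assert coverage_rate(iv, [0.0, 1.5, 3.0]) == pytest.approx(2 / 3)


class TestPercentileCalibration:
    def test_true_cdfs_recover_targets(self, rng):
        # y_i ~ N(m_i, 1) with the true conditional CDF per subject
        n = 4000
        m = rng.uniform(-2, 2, n)
        y = m + rng.normal(size=n)
        grid = np.linspace(-6, 6, 1200)
        from scipy.stats import norm

        cdfs = [StepCDF(grid + mi, norm.cdf(grid)) for mi in m]
        targets = np.array([0.1, 0.5, 0.9])
        freq = percentile_calibration(cdfs, y, targets)
        se = np.sqrt(targets * (1 - targets) / n)
        assert np.all(np.abs(freq - targets) < 3 * se + 0.01)

    def test_degenerate_cdfs_below_all_responses(self, rng):
        y = rng.uniform(1, 2, 50)
        cdfs = [StepCDF(np.array([0.0]), np.array([1.0]))] * 50
        assert percentile_calibration(cdfs, y, [0.5])[0] == 0.0


class _FrozenHazard:
    """Stand-in fitted model: fixed exponential conditional survival."""

    def __init__(self, rate=0.5):
        self.rate = rate

    def survival_path(self, path):
        rate = self.rate * (1 + 0.1 * abs(float(np.atleast_2d(path(0.0))[0, 0])))

        class _Curve:
            def survival(_self, t):
                return np.exp(-rate * np.asarray(t, dtype=float))

        return _Curve()


class TestCrossValidate:
    def _records(self, rng, n):
        from conftest import make_records

        y = rng.exponential(2, n) + 0.01
        delta = (rng.random(n) < 0.8).astype(int)
        X = rng.normal(size=(n, 1))
        return make_records(y, delta, X)

    def test_average_matches_manual_recomputation(self, rng):
        records = self._records(rng, 40)
        est = _FrozenHazard()
        panel = cross_validate(records, lambda tr: est, k=4, seed=3)
        # manual recomputation with the same fold assignment
        assignment = np.random.default_rng(3).permutation(40) % 4
        panels = []
        for fold in range(4):
            test = [records[i] for i in np.flatnonzero(assignment == fold)]
            y = np.array([r.y for r in test])
            d = np.array([r.delta for r in test])

            def sm(times):
                return np.column_stack(
                    [est.survival_path(r.path).survival(times) for r in test]
                )

            panels.append(score_panel(sm, y, d))
        assert panel.ibs == pytest.approx(np.mean([p.ibs for p in panels]))
        assert panel.ibll == pytest.approx(np.mean([p.ibll for p in panels]))
        assert panel.c_index == pytest.approx(np.nanmean([p.c_index for p in panels]))

    def test_fold_count_validation(self, rng):
        records = self._records(rng, 10)
        with pytest.raises(ValueError):
            cross_validate(records, lambda tr: _FrozenHazard(), k=1, seed=0)
        with pytest.raises(ValueError):
            cross_validate(records, lambda tr: _FrozenHazard(), k=11, seed=0)

    def test_single_subject_folds_skip_c_index_with_warning(self, rng):
        records = self._records(rng, 8)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            panel = cross_validate(records, lambda tr: _FrozenHazard(), k=8, seed=1)
        assert any("C-index undefined" in str(w.message) for w in caught)
        assert np.isnan(panel.c_index)
        assert np.isfinite(panel.ibs)
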