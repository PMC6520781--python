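import numpy as np
import pandas as pd
import pytest

from pidquant import (
    SeparationError,
    chi2_2x2,
    cox_fit,
    km_estimate,
    logrank,
    roc_optimal_cutoff,
)


class TestChi2:
    def test_independence_gives_zero(self):
        chi2, p = chi2_2x2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_oracle_on_random_tables(self, rng):
        # Σ(O-E)²/E with margin-product expectations
        for _ in range(50):
            t = rng.integers(1, 60, size=(2, 2)).astype(float)
            chi2, _ = chi2_2x2(t)
            n = t.sum()
            expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
            oracle = ((t - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(oracle)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2([[0, 0], [5, 5]])

    def test_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2([[1.5, 2], [3, 4]])


class TestROC:
    def test_perfect_separation(self):
        res = roc_optimal_cutoff([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == pytest.approx(1.0)
        assert 3 < res.optimal_cutoff < 10
        assert res.sens_at_cutoff == 1.0 and res.spec_at_cutoff == 1.0

    def test_identical_scores_give_auc_half(self):
        res = roc_optimal_cutoff([5, 5, 5, 5], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.5)

    def test_one_rank_swap(self):
        # positives {0.2, 0.7}, negatives {0.1, 0.6}: 3 of 4 rank pairs
        # correct -> AUC 0.75; J is maximized (sens+spec = 1.5) at both
        # 0.15 and 0.65, and the tie resolves to the smaller threshold
        res = roc_optimal_cutoff([0.1, 0.6, 0.2, 0.7], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)
        assert res.sens_at_cutoff + res.spec_at_cutoff == pytest.approx(1.5)
        assert res.optimal_cutoff == pytest.approx(0.15)

    def test_auc_equals_rank_statistic_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = rng.normal(size=n).round(1)  # ties included
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            res = roc_optimal_cutoff(scores, labels)
            pos = scores[labels == 1][:, None]
            neg = scores[labels == 0][None, :]
            mw = ((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.size)
            assert res.auc == pytest.approx(mw)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_optimal_cutoff([1, 2, 3], [1, 1, 1])


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = km_estimate([1, 2, 3, 4], [0, 0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_hand_product_limit(self):
        # events at 1 and 2, censored at 3 and 4:
        # S(1) = 3/4, S(2) = 3/4 * 2/3 = 1/2
        km = km_estimate([1, 2, 3, 4], [1, 1, 0, 0])
        assert km.survival_at(1) == pytest.approx(0.75)
        assert km.survival_at(2) == pytest.approx(0.5)
        assert km.survival_at(10) == pytest.approx(0.5)

    def test_single_subject_event(self):
        km = km_estimate([1.0], [1])
        assert km.survival_at(1.0) == pytest.approx(0.0)

    def test_no_censoring_matches_empirical_survival(self, rng):
        t = rng.exponential(5, size=40)
        km = km_estimate(t, np.ones(40, dtype=int))
        for q in np.quantile(t, [0.2, 0.5, 0.9]):
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            km_estimate([0.0, 1.0], [1, 1])


def brute_force_logrank(times, events, group):
    """Sum over event times of (observed - expected) in group 1 with
    hypergeometric variance."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        stat, p = logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_risk_set_computation(self, rng):
        for _ in range(20):
            n = 30
            t = rng.exponential(3, size=n).round(1) + 0.1
            e = rng.integers(0, 2, size=n)
            g = rng.integers(0, 2, size=n)
            if e.sum() == 0 or g.min() == g.max():
                continue
            stat, _ = logrank(t, e, g)
            assert stat == pytest.approx(brute_force_logrank(t, e, g))

    def test_permutation_invariance(self, rng):
        t = rng.exponential(3, size=20) + 0.1
        e = rng.integers(0, 2, size=20)
        g = np.repeat([0, 1], 10)
        if e.sum() == 0:
            e[0] = 1
        stat1, _ = logrank(t, e, g)
        perm = rng.permutation(20)
        stat2, _ = logrank(t[perm], e[perm], g[perm])
        assert stat1 == pytest.approx(stat2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank([1, 2], [1, 1], [0, 0])


class TestCox:
    def test_constant_covariate_rejected(self):
        cov = pd.DataFrame({"x": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 0, 1], cov)

    def test_no_events_rejected(self):
        cov = pd.DataFrame({"x": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="events"):
            cox_fit([1, 2, 3, 4], [0, 0, 0, 0], cov)

    def test_complete_separation_flagged(self):
        # the covariate perfectly orders the two events: beta -> +inf
        cov = pd.DataFrame({"x": [1.0, 0.0]})
        with pytest.raises(SeparationError):
            cox_fit([1.0, 2.0], [1, 1], cov)

    def test_recovers_planted_hazard_ratio(self, rng):
        # 95% Wald CI should cover the planted HR in nearly all replicates
        covered = 0
        for _ in range(20):
            n = 400
            x = rng.integers(0, 2, size=n)
            t = rng.exponential(1 / (0.1 * 3.8**x))
            c = rng.uniform(0, 30, size=n)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            res = cox_fit(time, event, pd.DataFrame({"x": x}))
            if res.summary.loc["x", "ci_lower"] < 3.8 < res.summary.loc["x", "ci_upper"]:
                covered += 1
        assert covered >= 16

    def test_backward_elimination_drops_noise_covariate(self, rng):
        n = 300
        x = rng.integers(0, 2, size=n)
        noise = rng.normal(size=n)
        t = rng.exponential(1 / (0.1 * 3.0**x))
        event = np.ones(n, dtype=int)
        res = cox_fit(
            t, event, pd.DataFrame({"x": x, "noise": noise}), backward=True
        )
        assert "noise" in res.dropped
        assert "x" in res.summary.index
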