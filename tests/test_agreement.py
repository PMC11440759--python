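import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stephen.agreement import (
    PairedMetricSample,
    ape,
    bland_altman,
    composition_by_class,
    summarize_mdape,
    tost_equivalence,
    wilcoxon_compare_ape,
)
from stephen.ensemble import ActivityLabel, LabeledPrediction
from stephen.io import MatchedSeries


class TestApe:
    @pytest.mark.parametrize(
        "est,ref,want", [(0.5, 0.4, 0.25), (0.4, 0.4, 0.0), (0.0, 0.4, 1.0)]
    )
    def test_values(self, est, ref, want):
        assert ape(est, ref) == pytest.approx(want)

    def test_nonpositive_referent(self):
        with pytest.raises(ValueError):
            ape(0.5, 0.0)


class TestSummarizeMdape:
    def test_odd_n_median(self):
        sample = PairedMetricSample([1.1, 1.2, 1.3], [1.0, 1.0, 1.0])
        med, _ = summarize_mdape(sample)
        assert med == pytest.approx(0.2)

    def test_constant_sample(self):
        sample = PairedMetricSample([1.15] * 4, [1.0] * 4)
        med, (q1, q3) = summarize_mdape(sample)
        assert (med, q1, q3) == (pytest.approx(0.15),) * 3

    def test_quartiles_match_reference_quantiles(self):
        apes = np.array([0.1, 0.2, 0.3, 0.4])
        sample = PairedMetricSample(1.0 + apes, np.ones(4))
        med, (q1, q3) = summarize_mdape(sample)
        want = np.quantile(apes, [0.25, 0.5, 0.75])
        assert (q1, med, q3) == tuple(pytest.approx(v) for v in want)

    def test_subject_order_invariant(self):
        rng = np.random.default_rng(1)
        est = rng.uniform(0.3, 0.9, 15)
        ref = rng.uniform(0.3, 0.9, 15)
        perm = rng.permutation(15)
        a = summarize_mdape(PairedMetricSample(est, ref))
        b = summarize_mdape(PairedMetricSample(est[perm], ref[perm]))
        assert a == b


class TestBlandAltman:
    def test_degenerate_spread(self):
        ref = np.array([1.0, 2.0, 3.0])
        rep = bland_altman(PairedMetricSample(ref + 2.0, ref))
        assert rep.bias_mean == pytest.approx(2.0)
        assert rep.bias_sd == pytest.approx(0.0)
        assert (rep.loa_low, rep.loa_high) == (pytest.approx(2.0), pytest.approx(2.0))

    def test_exact_proportional_construction(self):
        # d_i = 0.5 * mean_i exactly: est = ref * 5/3 makes d = 0.5 * mean
        ref = np.array([0.3, 0.6, 0.9, 1.2])
        est = ref * 5.0 / 3.0
        rep = bland_altman(PairedMetricSample(est, ref))
        assert rep.prop_bias_slope == pytest.approx(0.5, abs=1e-12)

    def test_ols_matches_closed_form(self):
        rng = np.random.default_rng(7)
        ref = rng.uniform(10, 40, 30)
        est = ref + rng.normal(2.0, 3.0, 30)
        sample = PairedMetricSample(est, ref)
        rep = bland_altman(sample)
        # independent least-squares route: normal equations + t distribution
        x = (est + ref) / 2.0
        d = est - ref
        X = np.column_stack([np.ones(30), x])
        beta = np.linalg.solve(X.T @ X, X.T @ d)
        resid = d - X @ beta
        s2 = resid @ resid / (30 - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        tstat = beta[1] / se
        p = 2 * stats.t.sf(abs(tstat), 30 - 2)
        assert rep.prop_bias_slope == pytest.approx(beta[1], abs=1e-8)
        assert rep.prop_bias_p == pytest.approx(p, abs=1e-8)
        tcrit = stats.t.ppf(0.975, 28)
        assert rep.prop_bias_slope_ci == (
            pytest.approx(beta[1] - tcrit * se, abs=1e-8),
            pytest.approx(beta[1] + tcrit * se, abs=1e-8),
        )
        # ~95% of differences within the limits is checked at larger n
        big_d = rng.normal(1.0, 2.0, 1000)
        big = bland_altman(PairedMetricSample(big_d, np.zeros(1000)))
        frac = np.mean((big_d >= big.loa_low) & (big_d <= big.loa_high))
        assert frac == pytest.approx(0.95, abs=0.02)

    def test_small_n_skips_regression(self):
        with pytest.warns(UserWarning, match="n < 3"):
            rep = bland_altman(PairedMetricSample([1.0, 2.0], [1.0, 1.0]))
        assert rep.prop_bias_slope is None


class TestTostEquivalence:
    def test_boundary_mean_equals_margin(self):
        d = np.array([4.0, 5.0, 6.0, 5.0])  # mean exactly 5
        assert tost_equivalence(d, margin=5.0) == pytest.approx(0.5)

    def test_zero_differences_equivalent(self):
        assert tost_equivalence(np.zeros(30), margin=5.0) == 0.0
        jitter = np.random.default_rng(0).normal(0, 1e-3, 30)
        assert tost_equivalence(jitter, margin=5.0) < 1e-6

    def test_matches_closed_form_t(self):
        rng = np.random.default_rng(2)
        d = rng.normal(1.0, 2.0, 25)
        margin = 5.0
        se = d.std(ddof=1) / np.sqrt(25)
        p_lower = stats.t.sf((d.mean() + margin) / se, 24)
        p_upper = stats.t.cdf((d.mean() - margin) / se, 24)
        assert tost_equivalence(d, margin) == pytest.approx(max(p_lower, p_upper), abs=1e-12)

    def test_far_outside_margin(self):
        rng = np.random.default_rng(3)
        d = rng.normal(50.0, 1.0, 20)
        assert tost_equivalence(d, margin=5.0) > 0.999

    def test_monotone_in_margin(self):
        rng = np.random.default_rng(4)
        d = rng.normal(2.0, 4.0, 15)
        margins = [0.5, 1.0, 2.0, 4.0, 8.0, 16.0]
        ps = [tost_equivalence(d, m) for m in margins]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestWilcoxon:
    def test_identical_samples(self):
        a = [0.1, 0.2, 0.3, 0.2, 0.4]
        assert wilcoxon_compare_ape(a, a) == 1.0

    def test_exact_p_by_sign_enumeration(self):
        rng = np.random.default_rng(5)
        b = rng.uniform(0.2, 0.6, 12)
        a = b - rng.uniform(0.05, 0.15, 12)  # a uniformly below b
        d = a - b
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = np.array(
            [
                sum(r for s, r in zip(signs, ranks) if s)
                for signs in itertools.product([0, 1], repeat=12)
            ]
        )
        p_enum = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
        assert wilcoxon_compare_ape(a, b) == pytest.approx(p_enum, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 1, 10)
        b = rng.uniform(0, 1, 10)
        assert wilcoxon_compare_ape(a, b) == pytest.approx(
            wilcoxon_compare_ape(b, a), abs=1e-12
        )


def _matched_pred(sitting, labels, subject="s1"):
    n = len(sitting)
    ts = pd.date_range("2024-01-01 08:00", periods=n, freq="min")
    matched = MatchedSeries(
        subject,
        pd.DataFrame(
            {
                "steps": 0,
                "heart_rate": 70.0,
                "sitting_s": np.asarray(sitting, dtype=float),
                "standing_s": 60.0 - np.asarray(sitting, dtype=float),
                "stepping_s": 0.0,
            },
            index=ts,
        ),
    )
    labels = np.asarray(labels)
    votes = np.zeros((n, 4), dtype=np.int64)
    votes[np.arange(n), labels] = 1
    pred = LabeledPrediction(subject, ts, labels, votes)
    return matched, pred


S, N = ActivityLabel.SEDENTARY.value, ActivityLabel.MPA.value


class TestComposition:
    def test_constant_sitting(self):
        pair = _matched_pred([60, 60, 60], [S, S, S])
        with pytest.warns(UserWarning, match="non_sedentary"):
            out = composition_by_class([pair])
        assert out["sedentary"]["sitting_s"]["mean"] == pytest.approx(60.0)
        assert "non_sedentary" not in out

    def test_two_subject_pooling(self):
        p1 = _matched_pred([40, 40], [S, S], "a")
        p2 = _matched_pred([50, 50], [S, S], "b")
        with pytest.warns(UserWarning):
            out = composition_by_class([p1, p2])
        assert out["sedentary"]["sitting_s"]["mean"] == pytest.approx(45.0)
        assert out["sedentary"]["sitting_s"]["se"] == pytest.approx(5.0)

    def test_matches_direct_aggregation_and_conserves_time(self):
        rng = np.random.default_rng(8)
        pairs = []
        per_subject_sed = []
        for sid in "abc":
            sitting = rng.uniform(0, 60, 50)
            labels = np.where(rng.random(50) < 0.5, S, N)
            pairs.append(_matched_pred(sitting, labels, sid))
            per_subject_sed.append(sitting[labels == S].mean())
        out = composition_by_class(pairs)
        assert out["sedentary"]["sitting_s"]["mean"] == pytest.approx(
            np.mean(per_subject_sed)
        )
        assert out["sedentary"]["sitting_s"]["se"] == pytest.approx(
            np.std(per_subject_sed, ddof=1) / np.sqrt(3)
        )
        for cls in ("sedentary", "non_sedentary"):
            total = sum(out[cls][p]["mean"] for p in ("sitting_s", "standing_s", "stepping_s"))
            assert total <= 60.0 + 1e-9
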