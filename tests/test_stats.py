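import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from ssritweets.stats import (
    DegenerateVarianceError,
    InsufficientDataError,
    PairedPeriodComparison,
    bh_adjust,
    cohen_kappa,
    compare_periods,
    paired_t,
    paired_t_from_summary,
    percent_agreement,
)


def _bh_oracle(p):
    """Step-up by hand: p(i)*m/i on the sorted values, then a cumulative
    minimum from the largest rank down."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestPairedT:
    def test_hand_computed_example(self):
        t, df, p = paired_t([2, 0, -2, 4])
        assert t == pytest.approx(0.7746, abs=1e-4)
        assert df == 3
        assert np.std([2, 0, -2, 4], ddof=1) == pytest.approx(2.5820, abs=1e-4)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.3, 1.0, 40)
        y = rng.normal(0.0, 1.0, 40)
        t, df, p = paired_t(x - y)
        ref = sps.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)
        assert df == 39

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateVarianceError):
            paired_t([0.0] * 10)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            paired_t([1.0])

    def test_antisymmetry(self):
        d = [1.2, -0.4, 0.9, 2.2, -0.1]
        t1, _, p1 = paired_t(d)
        t2, _, p2 = paired_t([-x for x in d])
        assert t1 == -t2 and p1 == p2


class TestPairedTFromSummary:
    @pytest.mark.parametrize(
        "mean_diff,sd_diff,expected",
        [
            (2.37, 9.72, 3.33),
            (0.94, 10.92, 1.18),
            (-1.3, 6.17, -2.88),
            (0.01, 3.43, 0.04),
        ],
    )
    def test_reported_rows_reproduce(self, mean_diff, sd_diff, expected):
        assert round(paired_t_from_summary(mean_diff, sd_diff, 187), 2) == expected

    def test_zero_mean_gives_zero(self):
        assert paired_t_from_summary(0.0, 3.0, 50) == 0.0

    def test_summary_equals_sample_route(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.4, 2.0, 60)
        t, _, _ = paired_t(d)
        ts = paired_t_from_summary(d.mean(), d.std(ddof=1), d.size)
        assert t == pytest.approx(ts, rel=1e-12)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.5]).tolist() == [0.5]

    def test_step_up_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_dominates_input_and_matches_oracle(self, ps):
        out = bh_adjust(ps)
        assert (out >= np.asarray(ps)).all() and (out <= 1.0).all()
        assert np.allclose(out, _bh_oracle(ps))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.random(15)
        perm = rng.permutation(15)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestAgreement:
    def test_printed_agreement_fraction(self):
        a = np.zeros(4872, dtype=int)
        b = np.zeros(4872, dtype=int)
        b[:4872 - 4537] = 1
        assert round(percent_agreement(a, b), 1) == 93.1

    def test_identical_and_disjoint(self):
        assert percent_agreement([1, 2, 3], [1, 2, 3]) == 100.0
        assert percent_agreement([0, 0], [1, 1]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            percent_agreement([1, 2], [1])


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_hand_computed_confusion_table(self):
        a = [0] * 50 + [1] * 50
        b = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
        assert cohen_kappa(a, b) == pytest.approx(0.6)

    def test_independent_random_labels_near_zero(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 2, 20000)
        b = rng.integers(0, 2, 20000)
        assert abs(cohen_kappa(a, b)) < 0.02

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, 500)
        b = np.where(rng.random(500) < 0.7, a, rng.integers(0, 3, 500))
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), rel=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 3, 200)
        relabel = {0: "x", 1: "y", 2: "z"}
        ra = np.array([relabel[v] for v in a])
        rb = np.array([relabel[v] for v in b])
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(ra, rb), rel=1e-12)

    def test_both_raters_constant_identical_is_undefined(self):
        assert np.isnan(cohen_kappa([1, 1, 1], [1, 1, 1]))


def _matrix(values):
    """values: dict user -> (in_value, unk_value) for feature 'mean_words'."""
    rows = []
    for u, (vi, vu) in values.items():
        rows.append((u, "in_treatment", vi))
        rows.append((u, "unknown_treatment", vu))
    df = pd.DataFrame(rows, columns=["user_id", "period", "mean_words"])
    return df.set_index(["user_id", "period"])


class TestComparePeriods:
    def test_two_user_toy_matrix_matches_hand_computation(self):
        res = compare_periods(_matrix({"a": (10.0, 8.0), "b": (9.0, 8.5)}))
        row = res.iloc[0]
        d = np.array([2.0, 0.5])
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(2))
        assert row["feature"] == "mean_words"
        assert row["n"] == 2 and row["df"] == 1
        assert row["t"] == pytest.approx(t_hand)
        assert row["mean_diff"] == pytest.approx(1.25)

    def test_degenerate_feature_flagged_and_outside_bh_family(self):
        m = _matrix({"a": (9.0, 8.0), "b": (7.0, 6.0), "c": (5.0, 4.0)})
        m["pct_daytime"] = [60.0, 55.0, 70.0, 52.0, 66.0, 61.0]
        res = compare_periods(m)
        by = res.set_index("feature")
        assert by.loc["mean_words", "status"] == "degenerate_variance"
        assert np.isnan(by.loc["mean_words", "p_adj"])
        assert by.loc["pct_daytime", "status"] == "ok"

    def test_missing_values_complete_case_per_feature(self):
        m = _matrix({"a": (10.0, 8.0), "b": (9.0, 8.5), "c": (7.0, 6.0)})
        m["pct_daytime"] = [60.0, 55.0, np.nan, 52.0, 66.0, 61.0]
        res = compare_periods(m).set_index("feature")
        assert res.loc["mean_words", "n"] == 3
        assert res.loc["pct_daytime", "n"] == 2

    def test_all_features_degenerate_raises(self):
        with pytest.raises(InsufficientDataError):
            compare_periods(_matrix({"a": (2.0, 1.0), "b": (3.0, 2.0)}))

    def test_user_permutation_invariance(self):
        rng = np.random.default_rng(12)
        vals = {f"u{i}": (rng.normal(10, 2), rng.normal(9, 2)) for i in range(12)}
        res1 = compare_periods(_matrix(vals))
        shuffled = dict(reversed(list(vals.items())))
        res2 = compare_periods(_matrix(shuffled))
        pd.testing.assert_frame_equal(res1, res2)

    def test_t_sign_matches_mean_diff_and_padj_dominates_praw(self, small_cohort):
        from ssritweets.pipeline import run_frames

        frame, events, _ = small_cohort
        res = run_frames(frame, mention_events=events).results
        ok = res[res["status"] == "ok"]
        assert (np.sign(ok["t"]) == np.sign(ok["mean_diff"])).all()
        assert (ok["p_adj"] >= ok["p_raw"] - 1e-12).all()
        assert (ok["df"] == ok["n"] - 1).all()
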