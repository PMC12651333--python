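"""Detection limits, agreement statistics, Wilson intervals, kappa,
Pearson and Welch — checked against closed forms, published table values,
and an independent library implementation where one exists."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from lfaquant.datasets import (
    BLANK_MEAN,
    BLANK_SD,
    LOW_SD,
    capillary_equivalence_table,
    serum_comparison_table,
)
from lfaquant.stats import (
    agreement_report,
    cohen_kappa,
    contingency_table,
    detection_limits,
    limit_of_blank,
    limit_of_detection,
    pearson_r2,
    percent_agreement,
    welch_ci,
    wilson_ci,
)


class TestDetectionLimits:
    def test_lob_from_summary(self):
        assert limit_of_blank(mean=BLANK_MEAN, sd=BLANK_SD) == pytest.approx(0.829)

    def test_lob_zero_sd(self):
        assert limit_of_blank(mean=0.5, sd=0.0) == 0.5

    def test_lob_monte_carlo_matches_summary(self):
        rng = np.random.default_rng(17)
        blanks = rng.normal(BLANK_MEAN, BLANK_SD, size=20)
        assert limit_of_blank(blanks) == pytest.approx(0.829, abs=0.15)

    def test_lod_from_published_inputs(self):
        lob = limit_of_blank(mean=BLANK_MEAN, sd=BLANK_SD)
        assert limit_of_detection(lob, sd_low=LOW_SD) == pytest.approx(4.9415, abs=1e-6)

    def test_lod_zero_sd_equals_lob(self):
        assert limit_of_detection(0.829, sd_low=0.0) == 0.829

    def test_full_summary_ordering(self):
        rng = np.random.default_rng(3)
        limits = detection_limits(rng.normal(0.5, 0.2, 20), rng.normal(5, 2.5, 20))
        assert limits.lob >= limits.mean_blank
        assert limits.lod >= limits.lob

    def test_single_blank_rejected(self):
        with pytest.raises(ValueError):
            limit_of_blank([0.5])


class TestPercentAgreement:
    def test_serum_table(self):
        overall, per = percent_agreement(serum_comparison_table())
        assert overall == pytest.approx(97.0)
        assert per[0] == pytest.approx(93.3, abs=0.05)
        assert per[1] == pytest.approx(97.4, abs=0.05)
        assert per[2] == pytest.approx(97.8, abs=0.05)

    def test_capillary_table(self):
        overall, _ = percent_agreement(capillary_equivalence_table())
        assert overall == pytest.approx(95.5, abs=0.05)

    def test_identity_table(self):
        overall, per = percent_agreement(np.diag([5, 5, 5]))
        assert overall == 100.0 and per == [100.0, 100.0, 100.0]

    def test_empty_column_reported_missing(self):
        t = np.array([[3, 0, 1], [0, 0, 0], [1, 0, 2]])
        _, per = percent_agreement(t)
        assert per[1] is None

    def test_overall_is_column_weighted_mean_of_per_category(self):
        t = serum_comparison_table()
        overall, per = percent_agreement(t)
        weights = t.sum(axis=0)
        assert overall == pytest.approx(np.average(per, weights=weights))


class TestWilson:
    @pytest.mark.parametrize(
        "successes,n,lo,hi",
        [
            (14, 15, 70.2, 98.8),
            (6, 7, 48.7, 97.4),
            (3, 3, 43.9, 100.0),
            (12, 12, 75.8, 100.0),
            (45, 46, 88.7, 99.6),
        ],
    )
    def test_published_interval_bounds(self, successes, n, lo, hi):
        got_lo, got_hi = wilson_ci(successes, n)
        assert round(100 * got_lo, 1) == lo
        assert round(100 * got_hi, 1) == hi

    def test_zero_successes_lower_bound_zero(self):
        lo, _ = wilson_ci(0, 10)
        assert lo == 0.0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(min_value=1, max_value=500), st.data())
    def test_interval_contains_shrunk_estimate(self, n, data):
        s = data.draw(st.integers(min_value=0, max_value=n))
        lo, hi = wilson_ci(s, n)
        z = 1.959964
        midpoint = (s + z**2 / 2) / (n + z**2)
        assert 0.0 <= lo <= midpoint <= hi <= 1.0


class TestKappa:
    def test_serum_table_unweighted(self):
        assert cohen_kappa(serum_comparison_table()) == pytest.approx(0.951, abs=5e-4)

    def test_perfect_diagonal(self):
        assert cohen_kappa(np.diag([4, 9, 2])) == pytest.approx(1.0)

    def test_chance_only_table(self):
        rows = np.array([2, 3, 5])
        cols = np.array([4, 4, 2])
        table = np.outer(rows, cols)
        assert cohen_kappa(table) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("weights", ["none", "linear", "quadratic"])
    def test_matches_independent_implementation(self, weights):
        rng = np.random.default_rng(11)
        cand = rng.integers(1, 4, size=200)
        ref = np.where(rng.random(200) < 0.7, cand, rng.integers(1, 4, size=200))
        table = contingency_table(cand, ref)
        sk_weights = {"none": None, "linear": "linear", "quadratic": "quadratic"}[weights]
        expected = cohen_kappa_score(cand, ref, weights=sk_weights)
        assert cohen_kappa(table, weights) == pytest.approx(expected, abs=1e-12)

    def test_label_permutation_invariance(self):
        t = serum_comparison_table()
        perm = [2, 0, 1]
        permuted = t[np.ix_(perm, perm)]
        assert cohen_kappa(permuted) == pytest.approx(cohen_kappa(t), abs=1e-12)

    def test_single_category_perfect_table_is_one(self):
        t = np.zeros((3, 3), dtype=int)
        t[1, 1] = 10
        assert cohen_kappa(t) == 1.0


class TestPearsonWelch:
    def test_exact_positive_line(self):
        x = np.arange(10.0)
        r, r2 = pearson_r2(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_exact_negative_line(self):
        x = np.arange(10.0)
        r, _ = pearson_r2(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r2([1, 1, 1], [1, 2, 3])

    def test_identical_samples_ci_centered_at_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        lo, hi = welch_ci(x, x)
        assert lo == pytest.approx(-hi, abs=1e-12)
        assert lo < 0 < hi

    def test_ci_coverage_for_5_unit_shift(self):
        # panels of 25 measured concentrations differing by a true +5 ng/mL
        rng = np.random.default_rng(23)
        hits = 0
        for _ in range(200):
            x = rng.normal(30.0 + 5.0, 2.0, size=25)
            y = rng.normal(30.0, 2.0, size=25)
            lo, hi = welch_ci(x, y)
            hits += lo <= 5.0 <= hi
        assert hits / 200 >= 0.93


class TestAgreementReport:
    def test_report_fields_consistent(self):
        rep = agreement_report(serum_comparison_table())
        assert rep.overall_pct == pytest.approx(97.0)
        assert rep.kappa == pytest.approx(0.951, abs=5e-4)
        for key, (lo, hi) in rep.wilson_cis_pct.items():
            assert 0 <= lo <= hi <= 100
        assert rep.kappa_weighted >= rep.kappa - 1e-9  # near-misses only, off-diagonal adjacent

    def test_summary_text_mentions_overall(self):
        text = agreement_report(capillary_equivalence_table()).summary()
        assert "95.5%" in text
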