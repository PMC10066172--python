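import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from centerfind.stats import (
    bonferroni,
    chi_square_2x2,
    estimate_learning_slope,
    mann_whitney_u,
    transform_response,
)


class TestTransforms:
    def test_sqrt(self):
        assert transform_response([0.25], "sqrt")[0] == 0.5
        assert transform_response([0.0, 1.0], "sqrt") == pytest.approx([0.0, 1.0])

    def test_log_with_offset(self):
        assert transform_response([0.0], "log", log_offset=1.0)[0] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_response([-0.1], "sqrt")


def make_metrics(slopes_by_animal, n_trials=10, intercept=0.2, response="prop"):
    rows = []
    for animal, slope in slopes_by_animal.items():
        for trial in range(1, n_trials + 1):
            val = (intercept + slope * trial) ** 2
            rows.append(
                {
                    "animal_id": animal,
                    "trial_index": trial,
                    "shape": "circle",
                    "prop_on_spot": val,
                    "latency_s": np.exp(intercept + slope * trial) - 1,
                }
            )
    return pd.DataFrame(rows)


class TestLearningSlope:
    def test_exact_linearity_recovered(self):
        df = make_metrics({f"a{i}": 0.03 for i in range(5)})
        s = estimate_learning_slope(df, "circle", "prop_on_spot_sqrt")
        assert s.slope == pytest.approx(0.03, abs=1e-12)
        assert s.se == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_zero_slope(self):
        df = make_metrics({f"a{i}": 0.0 for i in range(4)})
        s = estimate_learning_slope(df, "circle", "prop_on_spot_sqrt")
        assert s.slope == pytest.approx(0.0, abs=1e-12)

    def test_log_latency_slope(self):
        df = make_metrics({f"a{i}": -0.05 for i in range(4)}, intercept=4.0)
        s = estimate_learning_slope(df, "circle", "latency_log")
        assert s.slope == pytest.approx(-0.05, abs=1e-9)

    def test_ci_contains_slope_and_bootstrap(self):
        rng = np.random.default_rng(8)
        df = make_metrics({f"a{i}": 0.02 + rng.normal(0, 0.005) for i in range(12)})
        s = estimate_learning_slope(df, "circle", "prop_on_spot_sqrt",
                                    n_bootstrap=500, seed=1)
        assert s.ci95[0] <= s.slope <= s.ci95[1]
        assert s.bootstrap_ci95[0] < s.slope < s.bootstrap_ci95[1]

    def test_short_series_dropped_with_warning(self):
        df = make_metrics({"a0": 0.03, "a1": 0.03})
        df = df[~((df.animal_id == "a1") & (df.trial_index > 2))]
        with pytest.warns(UserWarning, match="dropped"):
            s = estimate_learning_slope(df, "circle", "prop_on_spot_sqrt")
        assert s.n_animals == 1

    def test_all_dropped_errors(self):
        df = make_metrics({"a0": 0.03}).query("trial_index <= 2")
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                estimate_learning_slope(df, "circle", "prop_on_spot_sqrt")


class TestMannWhitney:
    def test_textbook_exact_case(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1 / 3, abs=1e-12)
        assert r.method == "mann-whitney-exact"

    def test_identical_samples_u_half(self):
        r = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(4.5)  # n1*n2/2

    def test_exact_matches_full_permutation_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n1, n2 = rng.integers(2, 6, size=2)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # no ties
            x, y = pooled[:n1], pooled[n1:]
            r = mann_whitney_u(x, y)
            # oracle: all n! orderings reduce to combinations of positions
            us = []
            ranks = sps.rankdata(np.concatenate([x, y]))
            for comb in itertools.combinations(range(n1 + n2), n1):
                us.append(sum(sorted(ranks)[i] for i in comb) - n1 * (n1 + 1) / 2)
            us = np.array(us)
            u = r.statistic
            p = min(1.0, 2 * min((us <= u).mean(), (us >= u).mean()))
            assert r.p_value == pytest.approx(p, abs=1e-12)

    def test_exact_and_normal_agree_for_moderate_n(self):
        rng = np.random.default_rng(10)
        worst = 0.0
        for _ in range(200):
            x = rng.normal(size=8)
            y = rng.normal(0.5, size=8)
            exact = mann_whitney_u(x, y, exact_max_n=16)
            approx = mann_whitney_u(x, y, exact_max_n=0)
            worst = max(worst, abs(exact.p_value - approx.p_value))
        assert worst < 0.02

    def test_matches_scipy(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=30), rng.normal(0.4, size=25)
        r = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], m=5)[0] == pytest.approx(0.05)
        assert bonferroni([0.5], m=5)[0] == 1.0
        # the family of 5 comparisons: raw 0.0158 -> adjusted 0.079
        assert bonferroni([0.0158], m=5)[0] == pytest.approx(0.079)

    def test_family_size_defaults_to_length(self):
        assert bonferroni([0.01, 0.02]) == pytest.approx([0.02, 0.04])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestChiSquare:
    def test_looming_response_table(self):
        r = chi_square_2x2([[13, 2], [5, 10]])
        assert r.statistic == pytest.approx(8.889, abs=0.001)
        assert r.p_value == pytest.approx(0.00287, abs=0.0002)

    def test_reconstructed_table_unique_up_to_relabeling(self):
        """Brute-force search over all 2x2 tables with row totals 15: the
        tables whose uncorrected statistic rounds to 8.89 form exactly the
        row/column-relabeling orbit of [[13, 2], [5, 10]], so the count
        reconstruction is unique up to which level is called 'present'."""
        hits = set()
        for a in range(16):
            for c in range(16):
                tbl = [[a, 15 - a], [c, 15 - c]]
                try:
                    stat = chi_square_2x2(tbl).statistic
                except ValueError:
                    continue
                if round(stat, 2) == 8.89:
                    hits.add((a, c))
        assert hits == {(13, 5), (5, 13), (10, 2), (2, 10)}
        # majority-present in group 1 / mostly-absent in group 2 with the
        # larger first-cell count picks out [[13, 2], [5, 10]]
        stats = {chi_square_2x2([[a, 15 - a], [c, 15 - c]]).statistic
                 for a, c in hits}
        assert len(stats) == 1  # all relabelings share the statistic

    def test_identical_proportions_zero(self):
        assert chi_square_2x2([[10, 5], [10, 5]]).statistic == 0.0

    def test_transpose_invariant(self):
        t = np.array([[13, 2], [5, 10]])
        assert chi_square_2x2(t).statistic == pytest.approx(
            chi_square_2x2(t.T).statistic
        )

    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            t = rng.integers(1, 40, size=(2, 2))
            r = chi_square_2x2(t)
            ref = sps.chi2_contingency(t, correction=False)
            assert r.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)
            ry = chi_square_2x2(t, continuity_correction=True)
            refy = sps.chi2_contingency(t, correction=True)
            assert ry.statistic == pytest.approx(refy.statistic, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 10]])
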