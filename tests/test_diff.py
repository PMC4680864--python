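"""Reproducibility filter and log-NSAF t-tests against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from nsafq import (
    SimConfig,
    SpectralCountMatrix,
    compute_nsaf,
    differential_test,
    reproducibility_filter,
    simulate_counts,
    summarize_counts,
)
from conftest import brute_force_filter, student_t_p


def _counts_3v3(a, b, n_extra_null=0):
    """One protein of interest plus optional well-behaved fillers."""
    rows = [list(a) + list(b)]
    ids = ["P1"]
    for i in range(n_extra_null):
        rows.append([10 + i] * 6)
        ids.append(f"N{i}")
    df = pd.DataFrame(rows, index=ids,
                      columns=["a1", "a2", "a3", "b1", "b2", "b3"])
    cond = {s: ("A" if s.startswith("a") else "B") for s in df.columns}
    return SpectralCountMatrix(counts=df, conditions=cond,
                               length_aa=pd.Series(200.0, index=df.index))


class TestReproducibilityFilter:
    @pytest.mark.parametrize("a, b, expected", [
        ((2, 2, 1), (0, 0, 0), True),    # present in all of A, total 5
        ((1, 1, 1), (0, 0, 0), False),   # total 3 < 5
        ((5, 5, 0), (0, 0, 4), False),   # no condition fully present
        ((0, 0, 0), (2, 2, 2), True),    # qualifies via B, total 6
        ((1, 1, 1), (1, 1, 2), False),   # neither condition reaches 5
        ((100, 0, 100), (1, 1, 3), True),  # B fully present with total 5
    ])
    def test_rule_on_hand_cases(self, a, b, expected):
        m = _counts_3v3(a, b)
        assert reproducibility_filter(m).loc["P1"] == expected

    def test_scope_all_counts_total_across_samples(self):
        # fully present in A with within-A total 3, grand total 7
        m = _counts_3v3((1, 1, 1), (0, 4, 0))
        assert not reproducibility_filter(m, scope="condition").loc["P1"]
        assert reproducibility_filter(m, scope="all").loc["P1"]

    def test_matches_brute_force_on_random_matrices(self, rng):
        """Exhaustive re-check of the filter rule on 10,000 random 3v3 matrices."""
        groups = {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]}
        n_batches, per_batch = 100, 100  # 10,000 proteins total
        for _ in range(n_batches):
            counts = pd.DataFrame(
                rng.integers(0, 5, size=(per_batch, 6)),
                index=[f"P{i}" for i in range(per_batch)],
                columns=["a1", "a2", "a3", "b1", "b2", "b3"],
            )
            m = SpectralCountMatrix(
                counts=counts,
                conditions={s: ("A" if s.startswith("a") else "B") for s in counts.columns},
                length_aa=pd.Series(100.0, index=counts.index),
            )
            fast = reproducibility_filter(m)
            slow = brute_force_filter(counts, groups)
            pd.testing.assert_series_equal(fast, slow, check_names=False)


class TestDifferentialTest:
    def test_strong_separation_detected(self):
        """Log-NSAF groups around -5 vs -7 give p < 0.01 and direction up_in_a,
        agreeing with the closed-form Student t to 1e-10."""
        a, b = [-5.0, -5.1, -4.9], [-7.0, -7.1, -6.9]
        m = _counts_3v3((1, 1, 1), (1, 1, 1), n_extra_null=1)
        nsaf = compute_nsaf(m)
        nsaf.log_nsaf.loc["P1", ["a1", "a2", "a3"]] = a
        nsaf.log_nsaf.loc["P1", ["b1", "b2", "b3"]] = b
        nsaf.nsaf.loc["P1"] = np.exp(nsaf.log_nsaf.loc["P1"])
        res = differential_test(nsaf, pd.Series(True, index=nsaf.nsaf.index))
        t_ref, p_ref = student_t_p(a, b)
        assert res.loc["P1", "p_value"] == pytest.approx(p_ref, abs=1e-10)
        assert res.loc["P1", "t_stat"] == pytest.approx(t_ref, rel=1e-10)
        assert res.loc["P1", "p_value"] < 0.01
        assert res.loc["P1", "direction"] == "up_in_a"

    def test_p_values_match_closed_form_on_simulation(self):
        """Every tested protein's p agrees with the independent textbook formula."""
        m, _ = simulate_counts(SimConfig(n_proteins=250, depth=8000, seed=8))
        nsaf = compute_nsaf(m)
        mask = reproducibility_filter(m)
        res = differential_test(nsaf, mask)
        a_cols = nsaf.samples_of(nsaf.condition_labels[0])
        b_cols = nsaf.samples_of(nsaf.condition_labels[1])
        for pid in res.index[res["passed_filter"]]:
            _, p_ref = student_t_p(nsaf.log_nsaf.loc[pid, a_cols],
                                   nsaf.log_nsaf.loc[pid, b_cols])
            assert res.loc[pid, "p_value"] == pytest.approx(p_ref, abs=1e-10)

    def test_identical_groups_unchanged_p_one(self):
        m = _counts_3v3((4, 4, 4), (4, 4, 4), n_extra_null=2)
        nsaf = compute_nsaf(m)
        res = differential_test(nsaf, pd.Series(True, index=nsaf.nsaf.index))
        assert res.loc["P1", "p_value"] == 1.0
        assert res.loc["P1", "direction"] == "unchanged"

    def test_ratio_at_least_one_and_direction_consistent(self):
        m, _ = simulate_counts(SimConfig(n_proteins=300, seed=17))
        res = differential_test(compute_nsaf(m), reproducibility_filter(m))
        assert (res["ratio"] >= 1.0).all()
        up_a = res["direction"] == "up_in_a"
        assert (res.loc[up_a, "mean_nsaf_a"] > res.loc[up_a, "mean_nsaf_b"]).all()
        up_b = res["direction"] == "up_in_b"
        assert (res.loc[up_b, "mean_nsaf_b"] > res.loc[up_b, "mean_nsaf_a"]).all()
        # untested proteins carry no statistics
        untested = ~res["passed_filter"]
        assert res.loc[untested, "p_value"].isna().all()
        assert (res.loc[untested, "direction"] == "unchanged").all()

    def test_welch_differs_from_student_under_unequal_variance(self):
        m = _counts_3v3((1, 1, 1), (1, 1, 1), n_extra_null=1)
        nsaf = compute_nsaf(m)
        nsaf.log_nsaf.loc["P1", ["a1", "a2", "a3"]] = [-5.0, -5.5, -4.5]
        nsaf.log_nsaf.loc["P1", ["b1", "b2", "b3"]] = [-6.0, -6.01, -5.99]
        mask = pd.Series(True, index=nsaf.nsaf.index)
        p_student = differential_test(nsaf, mask, equal_var=True).loc["P1", "p_value"]
        p_welch = differential_test(nsaf, mask, equal_var=False).loc["P1", "p_value"]
        assert p_student != pytest.approx(p_welch, rel=1e-6)

    def test_n_diff_monotone_in_alpha(self):
        m, _ = simulate_counts(SimConfig(n_proteins=400, seed=23))
        nsaf = compute_nsaf(m)
        mask = reproducibility_filter(m)
        n_prev = -1
        for alpha in (0.001, 0.01, 0.05, 0.2):
            n = summarize_counts(differential_test(nsaf, mask, alpha=alpha))["n_diff"]
            assert n >= n_prev
            n_prev = n


class TestSummarizeCounts:
    def test_headline_arithmetic(self):
        """1582 identified with 271 differential leaves ~83% unchanged, and
        164 up + 107 down makes 271."""
        res = pd.DataFrame({
            "passed_filter": [True] * 1582,
            "direction": ["up_in_a"] * 164 + ["up_in_b"] * 107 + ["unchanged"] * 1311,
        })
        s = summarize_counts(res)
        assert s["n_diff"] == 271
        assert s["pct_unchanged"] == pytest.approx(100 * (1582 - 271) / 1582)
        assert round(s["pct_unchanged"]) == 83

    def test_empty_input_all_zero(self):
        s = summarize_counts(pd.DataFrame(columns=["passed_filter", "direction"]))
        assert s == {"n_identified": 0, "n_diff": 0, "n_up_a": 0, "n_up_b": 0,
                     "pct_unchanged": 0.0}
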