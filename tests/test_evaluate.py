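"""Exact binomial contest evaluation, enrichment and power design."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vscontest import (ContestOutcome, InputError, binom_tail, design_power,
                       enrichment_curve, evaluate_groups, min_assays,
                       truncation_analysis)


def exact_tail(k, n, p):
    """Independent oracle: exact rational enumeration of P(X >= k)."""
    pr = Fraction(p).limit_denominator(10**9)
    return float(sum(Fraction(math.comb(n, i)) * pr**i * (1 - pr)**(n - i)
                     for i in range(k, n + 1)))


def make_outcome(group_defs, hits):
    """group_defs: {gid: [compound ids in rank order]}"""
    groups = {g: pd.DataFrame({"rank": range(1, len(c) + 1), "compound_id": c})
              for g, c in group_defs.items()}
    return ContestOutcome(groups=groups, hits=set(hits))


class TestBinomTail:
    def test_certain_event(self):
        assert binom_tail(0, 100, 0.3) == 1.0
        assert binom_tail(0, 5, 0.0) == 1.0

    def test_closed_form_half(self):
        # P(X >= 2 | n=10, p=1/2) = 1 - 11/1024
        assert binom_tail(2, 10, 0.5) == pytest.approx(1013 / 1024, rel=1e-12)

    @pytest.mark.parametrize("k,n,p", [
        (2, 12, 0.1), (5, 20, 0.25), (0, 7, 0.9), (7, 7, 0.3),
        (3, 15, 1 / 3), (1, 18, 0.05),
    ])
    def test_matches_exact_enumeration(self, k, n, p):
        assert binom_tail(k, n, p) == pytest.approx(exact_tail(k, n, p),
                                                    rel=1e-10)

    def test_monotone_decreasing_in_k(self):
        vals = [binom_tail(k, 30, 0.2) for k in range(31)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("k,n,p", [(-1, 10, 0.5), (11, 10, 0.5),
                                       (2, 10, 1.5), (2, 10, -0.1)])
    def test_out_of_range_raises(self, k, n, p):
        with pytest.raises(InputError):
            binom_tail(k, n, p)


class TestContestStatistics:
    def test_previous_contest_p_value(self):
        # 2 hits in 55 assays against a pooled rate of 2/600
        assert round(binom_tail(2, 55, 2 / 600), 3) == 0.015

    def test_per_group_p_values_at_pooled_rate(self):
        p0 = 10 / 1991
        assert binom_tail(7, 181, p0) == pytest.approx(4e-5, rel=0.1)
        assert round(binom_tail(2, 181, p0), 1) == 0.2
        assert round(binom_tail(1, 181, p0), 1) == 0.6

    def test_design_probabilities(self):
        p_zero, _ = design_power(0.03, 55)
        assert round(100 * p_zero, 1) == 18.7
        _, p_hit = design_power(0.03, 180)
        assert round(100 * p_hit, 1) == 99.6


class TestEvaluateGroups:
    def test_shared_hits_credited_per_group_counted_once_in_pool(self):
        outcome = make_outcome(
            {"G1": ["a", "b", "c"], "G2": ["a", "d", "e"]}, hits={"a"})
        assert outcome.N == 5  # distinct compounds
        assert outcome.K == 1
        counts = outcome.group_counts().set_index("group")
        assert counts.loc["G1", "k"] == counts.loc["G2", "k"] == 1

    def test_raw_and_corrected_p(self):
        outcome = make_outcome(
            {"G1": list("abcde"), "G2": list("fghij")}, hits={"a", "b"})
        out = evaluate_groups(outcome).set_index("group")
        p0 = 2 / 10
        assert out.loc["G1", "p_raw"] == pytest.approx(binom_tail(2, 5, p0))
        assert out.loc["G1", "p_bonferroni"] == pytest.approx(
            min(1.0, 2 * binom_tail(2, 5, p0)))
        assert out.loc["G2", "p_raw"] == 1.0

    def test_bonferroni_capped_at_one(self):
        outcome = make_outcome({f"G{i}": [f"c{i}{j}" for j in range(4)]
                                for i in range(12)}, hits={"c00"})
        out = evaluate_groups(outcome)
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_zero_hits_degenerate(self):
        outcome = make_outcome({"G1": ["a", "b"]}, hits=set())
        with pytest.warns(UserWarning, match="degenerate"):
            out = evaluate_groups(outcome)
        assert (out["p_raw"] == 1.0).all()

    def test_hit_outside_assayed_lists_rejected(self):
        with pytest.raises(InputError):
            make_outcome({"G1": ["a"]}, hits={"zzz"})

    @staticmethod
    def exact_detection_power(n=181, rate=0.04, null_rate=0.005, n_groups=11,
                              alpha=0.05):
        """Oracle: exact power of the Bonferroni-corrected test for the
        enriched group, marginalizing over its hit count and the pooled
        null hits (disjoint compound lists, so totals just add)."""
        from scipy.stats import binom as B

        n_null = (n_groups - 1) * n
        N = n_groups * n
        power = 0.0
        for k in range(n + 1):
            pk = B.pmf(k, n, rate)
            if pk < 1e-14:
                continue
            for t in range(n_null + 1):
                pt = B.pmf(t, n_null, null_rate)
                if pt < 1e-12:
                    if t > n_null * null_rate:
                        break
                    continue
                if (k + t) == 0:
                    continue
                p0 = (k + t) / N
                if n_groups * binom_tail(k, n, p0) < alpha:
                    power += pk * pt
        return power

    def test_enriched_group_detected_null_groups_spared(self):
        """Contest-level simulation: one 4% group among ten 0.5% groups.

        The detection fraction must be the majority of runs and agree
        with the exactly computed power of the corrected test.
        """
        rng = np.random.default_rng(2718)
        n, n_seeds = 181, 200
        rates = [0.04] + [0.005] * 10
        detected, false_pos = 0, 0
        for _ in range(n_seeds):
            ks = rng.binomial(n, rates)
            groups, hits = {}, set()
            for g, k in enumerate(ks):
                ids = [f"g{g}_{i}" for i in range(n)]
                groups[f"G{g}"] = ids
                hits |= set(ids[:k])
            out = evaluate_groups(make_outcome(groups, hits)).set_index("group")
            if out.loc["G0", "significant"]:
                detected += 1
            false_pos += int(out.drop("G0")["significant"].sum())
        frac = detected / n_seeds
        power = self.exact_detection_power()
        se = math.sqrt(power * (1 - power) / n_seeds)
        assert frac > 0.5
        assert abs(frac - power) < 4 * se
        assert false_pos / (n_seeds * 10) < 0.05 / 10 * 3  # Bonferroni-consistent


class TestEnrichmentCurve:
    def test_front_loaded_hits(self):
        ranked = pd.DataFrame({"rank": range(1, 11),
                               "compound_id": list("abcdefghij")})
        curve = enrichment_curve(ranked, {"a", "b", "c"}, p0=0.3)
        assert curve["cum_hits"].tolist() == [1, 2, 3, 3, 3, 3, 3, 3, 3, 3]
        assert curve["expected"].iloc[-1] == pytest.approx(3.0)
        assert curve.attrs["top_half_hit_fraction"] == 1.0

    def test_no_hits_flat_zero(self):
        ranked = pd.DataFrame({"rank": [1, 2, 3], "compound_id": list("abc")})
        curve = enrichment_curve(ranked, set())
        assert curve["cum_hits"].tolist() == [0, 0, 0]

    def test_unknown_hit_rejected(self):
        ranked = pd.DataFrame({"rank": [1, 2], "compound_id": ["a", "b"]})
        with pytest.raises(InputError):
            enrichment_curve(ranked, {"x"})

    def test_random_placement_matches_expected_line(self):
        """Permutation oracle: mean curve over shuffles equals rank * k/n."""
        n, k, n_shuffles = 40, 6, 400
        rng = np.random.default_rng(99)
        ids = [f"c{i}" for i in range(n)]
        acc = np.zeros(n)
        for _ in range(n_shuffles):
            order = rng.permutation(ids)
            ranked = pd.DataFrame({"rank": range(1, n + 1),
                                   "compound_id": order})
            acc += enrichment_curve(ranked, set(ids[:k]))["cum_hits"].to_numpy()
        mean_curve = acc / n_shuffles
        expected = np.arange(1, n + 1) * k / n
        assert np.max(np.abs(mean_curve - expected)) < 0.25


class TestTruncation:
    def test_full_depth_is_identity(self):
        outcome = make_outcome({"G1": list("abcde"), "G2": list("fghij")},
                               hits={"a", "f"})
        full = evaluate_groups(outcome)
        trunc = truncation_analysis(outcome, 5)
        pd.testing.assert_frame_equal(
            full[["group", "n", "k", "p_raw", "p_bonferroni"]],
            trunc[["group", "n", "k", "p_raw", "p_bonferroni"]])

    def test_truncation_with_front_loaded_hits_shrinks_p(self):
        ids = [f"c{i}" for i in range(20)]
        outcome = make_outcome({"G1": ids, "G2": [f"d{i}" for i in range(20)]},
                               hits=set(ids[:3]))
        full = evaluate_groups(outcome).set_index("group")
        trunc = truncation_analysis(outcome, 5).set_index("group")
        assert trunc.loc["G1", "k"] == 3  # hits all within depth 5
        # direct recomputation oracle at fixed p0
        assert trunc.loc["G1", "p_raw"] == pytest.approx(
            binom_tail(3, 5, outcome.p0))
        assert trunc.loc["G1", "p_raw"] < full.loc["G1", "p_raw"]

    def test_depth_one_without_rank1_hits(self):
        outcome = make_outcome({"G1": ["a", "b"], "G2": ["c", "d"]},
                               hits={"b"})
        trunc = truncation_analysis(outcome, 1)
        assert (trunc["p_raw"] == 1.0).all()

    def test_invalid_depth(self):
        outcome = make_outcome({"G1": ["a", "b"]}, hits={"a"})
        with pytest.raises(InputError):
            truncation_analysis(outcome, 0)


class TestDesignPower:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.001, max_value=0.999),
           st.integers(min_value=0, max_value=500))
    def test_consistency_with_binomial_tail(self, r, n):
        p_zero, p_hit = design_power(r, n)
        assert p_zero + p_hit == pytest.approx(1.0, abs=1e-12)
        if n > 0:
            assert p_hit == pytest.approx(binom_tail(1, n, r), rel=1e-9,
                                          abs=1e-12)

    def test_zero_rate(self):
        assert design_power(0.0, 50) == (1.0, 0.0)

    def test_out_of_range(self):
        with pytest.raises(InputError):
            design_power(1.5, 10)
        with pytest.raises(InputError):
            design_power(0.5, -1)


class TestMinAssays:
    def test_closed_form_example(self):
        assert min_assays(0.5, 0.75) == 2  # 1 - 0.25 = 0.75 exactly

    def test_tiny_detection_probability(self):
        assert min_assays(0.3, 1e-9) == 1

    def test_linear_scan_oracle(self):
        r, q = 0.03, 0.996
        n = 1
        while design_power(r, n)[1] < q:
            n += 1
        assert min_assays(r, q) == n

    def test_degenerate_rate_rejected(self):
        for r in (0.0, 1.0):
            with pytest.raises(InputError):
                min_assays(r, 0.5)
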