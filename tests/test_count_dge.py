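"""Exact two-library count test, FPKM, FDR and DE classification."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dualomics import count_dge as cd


def rational_ac_pmf(i: int, x: int, n1: int, n2: int) -> Fraction:
    """Exact big-rational evaluation of (N2/N1)^i (x+i)!/(x!i!) (1+N2/N1)^-(x+i+1)."""
    q = Fraction(n2, n1)
    return q**i * Fraction(math.factorial(x + i), math.factorial(x) * math.factorial(i)) / (1 + q) ** (x + i + 1)


class TestFpkm:
    @pytest.mark.parametrize(
        "count,total,length,expected",
        [(0, 10**6, 1000, 0.0), (200, 2 * 10**7, 500, 20.0)],
    )
    def test_closed_form(self, count, total, length, expected):
        assert cd.compute_fpkm(count, total, length) == expected

    def test_extended_precision_oracle(self):
        got = cd.compute_fpkm(7, 31_000_000, 1234)
        want = Fraction(7 * 10**9, 31_000_000 * 1234)
        assert got == pytest.approx(float(want), rel=1e-14)

    @pytest.mark.parametrize("count,total,length", [(1, 0, 100), (1, 100, 0), (-1, 100, 100)])
    def test_invalid_inputs(self, count, total, length):
        with pytest.raises(ValueError):
            cd.compute_fpkm(count, total, length)

    @given(
        count=st.integers(0, 10**6),
        total=st.integers(1, 10**8),
        length=st.integers(1, 10**5),
        k=st.integers(1, 50),
    )
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance(self, count, total, length, k):
        a = cd.compute_fpkm(count, total, length)
        b = cd.compute_fpkm(k * count, k * total, length)
        assert a == pytest.approx(b, rel=1e-12)


class TestConditionalPmf:
    def test_equal_libraries_zero_counts(self):
        assert cd.ac_conditional_pmf(0, 0, 10**6, 10**6) == pytest.approx(0.5)

    @pytest.mark.parametrize("x", [0, 1, 10, 100])
    @pytest.mark.parametrize("n1,n2", [(1000, 1000), (1000, 2000), (3000, 1000)])
    def test_normalization(self, x, n1, n2):
        # partial sums converge to 1; the bound scales with the mean x*q
        bound = 200 + 20 * x * max(1, n2 // n1)
        total = np.exp(cd._ac_log_pmf(np.arange(bound), x, n1, n2)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_tail_bound_small_x(self):
        total = np.exp(cd._ac_log_pmf(np.arange(201), 3, 1000, 1000)).sum()
        assert total >= 1 - 1e-12

    def test_exact_rational_oracle(self):
        got = cd.ac_conditional_pmf(2, 5, 1000, 2000)
        assert got == pytest.approx(float(rational_ac_pmf(2, 5, 1000, 2000)), rel=1e-12)

    def test_no_overflow_at_huge_counts(self):
        # direct factorials would overflow; the log-gamma path must not
        v = cd.ac_conditional_pmf(10**6, 10**6, 10**7, 10**7)
        assert 0.0 < v < 1.0


class TestAcPvalue:
    def test_identical_zero_counts(self):
        # doubled lower tail clips to 1 whenever N1 >= N2
        assert cd.ac_pvalue(0, 0, 10**6, 10**6) == 1.0
        assert cd.ac_pvalue(0, 0, 2 * 10**6, 10**6) == 1.0

    def test_balanced_counts_clip_to_one(self):
        assert cd.ac_pvalue(50, 50, 10**6, 10**6) == 1.0

    def test_brute_force_tail_oracle(self):
        # x=10, y=0, equal totals: p = 2 * p(0|10) = 2 * (1/2)^11 = 2^-10
        want = 2 * sum(rational_ac_pmf(i, 10, 10**6, 10**6) for i in range(1))
        assert cd.ac_pvalue(10, 0, 10**6, 10**6) == pytest.approx(float(want), rel=1e-9)

    def test_general_rational_oracle(self):
        x, y, n1, n2 = 4, 11, 1500, 900
        lower = sum(rational_ac_pmf(i, x, n1, n2) for i in range(y + 1))
        upper = 1 - lower + rational_ac_pmf(y, x, n1, n2)
        want = float(min(1, 2 * min(lower, upper)))
        assert cd.ac_pvalue(x, y, n1, n2) == pytest.approx(want, rel=1e-10)

    @pytest.mark.parametrize(
        "x,y,n1,n2", [(7, 19, 1000, 2000), (3, 8, 500, 500), (40, 12, 10**6, 3 * 10**6)]
    )
    def test_swap_consistency(self, x, y, n1, n2):
        """The two conditioning directions carry identical tail information.

        Exact identity: P(Y<=y|x;N1,N2) + P(X<=x|y;N2,N1) = 1. The doubled
        two-sided p-values differ at most by the observed points' pmf mass.
        """
        lower_fwd = float(np.exp(cd._ac_log_pmf(np.arange(y + 1), x, n1, n2)).sum())
        lower_rev = float(np.exp(cd._ac_log_pmf(np.arange(x + 1), y, n2, n1)).sum())
        assert lower_fwd + lower_rev == pytest.approx(1.0, abs=1e-10)
        gap = 2 * (cd.ac_conditional_pmf(y, x, n1, n2) + cd.ac_conditional_pmf(x, y, n2, n1))
        assert abs(cd.ac_pvalue(x, y, n1, n2) - cd.ac_pvalue(y, x, n2, n1)) <= gap + 1e-12

    def test_power_monotone_in_fold_change(self, rng):
        """Rejection at alpha=0.001 is non-decreasing in the planted fold."""
        lam, total, n_rep, alpha = 50.0, 10**6, 400, 1e-3
        rates = []
        for fold in (1, 2, 4, 8):
            x = rng.poisson(lam, n_rep)
            y = rng.poisson(lam * fold, n_rep)
            p = cd.ac_pvalues(x, y, total, total)
            rates.append((p <= alpha).mean())
        assert all(b >= a - 0.02 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]


class TestFdrAdjust:
    def test_single_test_unchanged(self):
        assert cd.fdr_adjust([0.01]).tolist() == [0.01]

    def test_linear_pattern_collapses(self):
        out = cd.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @staticmethod
    def naive_step_up(p):
        """O(n^2) BH oracle: adj at rank r = min over ranks s >= r of p_(s)*n/s."""
        n = len(p)
        order = sorted(range(n), key=lambda i: p[i])
        adj = [0.0] * n
        for rank, i in enumerate(order, start=1):
            candidates = [
                p[order[s - 1]] * n / s for s in range(rank, n + 1)
            ]
            adj[i] = min(1.0, min(candidates))
        return adj

    def test_matches_naive_oracle(self, rng):
        p = rng.uniform(1e-6, 1, 50)
        assert cd.fdr_adjust(p) == pytest.approx(self.naive_step_up(list(p)), rel=1e-12)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=60)
    def test_bounded_by_raw_and_bonferroni(self, p):
        bh = cd.fdr_adjust(p)
        bonf = np.minimum(1.0, np.asarray(p) * len(p))
        assert np.all(bh >= np.asarray(p) - 1e-12)
        assert np.all(bh <= bonf + 1e-12)
        assert np.all(bh <= 1.0)

    def test_by_is_more_conservative_than_bh(self, rng):
        p = rng.uniform(1e-4, 1, 30)
        assert np.all(cd.fdr_adjust(p, "by") >= cd.fdr_adjust(p, "bh") - 1e-12)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1]])
    def test_invalid_pvalues(self, bad):
        with pytest.raises(ValueError):
            cd.fdr_adjust(bad)


class TestClassifyAndBins:
    @pytest.mark.parametrize(
        "fdr,lfc,call",
        [
            (0.0005, 1.5, "up"),
            (0.0005, 0.5, "not_de"),
            (0.001, -1.0, "down"),   # both boundaries inclusive
            (0.002, 3.0, "not_de"),
            (0.001, 1.0, "up"),
        ],
    )
    def test_thresholds(self, fdr, lfc, call):
        assert cd.classify_deg(fdr, lfc) == call

    def test_bin_edges(self):
        df = pd.DataFrame(
            {
                "call": ["up", "up", "up", "down"],
                "log2_ratio": [np.log2(2.0), np.log2(10.0), np.log2(10.5), -np.log2(4.0)],
            }
        )
        bins = cd.fold_change_bins(df)
        lookup = {(r.direction, r.bin): r.count for r in bins.itertuples(index=False)}
        assert lookup[("up", "2-10x")] == 2
        assert lookup[("up", ">10x")] == 1
        assert lookup[("down", "2-10x")] == 1

    def test_bins_match_recount_oracle(self, rng):
        lfc = rng.normal(0, 2.5, 1000)
        call = np.where(np.abs(lfc) < 1, "not_de", np.where(lfc > 0, "up", "down"))
        df = pd.DataFrame({"call": call, "log2_ratio": lfc})
        bins = cd.fold_change_bins(df)
        fold = 2.0 ** np.abs(lfc)
        for r in bins.itertuples(index=False):
            mask = call == r.direction
            if r.bin == "2-10x":
                want = int(((fold >= 2) & (fold <= 10) & mask).sum())
            else:
                want = int(((fold > 10) & mask).sum())
            assert r.count == want
        de_total = int((call != "not_de").sum())
        assert bins["count"].sum() == de_total


class TestRunDge:
    def test_end_to_end_table(self, small_counts):
        out = cd.run_dge(small_counts, n1=10**6, n2=10**6)
        assert list(out.columns) == [
            "gene_id", "fpkm_1", "fpkm_2", "log2_ratio", "p_value", "fdr", "call"
        ]
        # g2: 0 -> 50 must be significant and up; FPKM zero iff count zero
        g2 = out[out["gene_id"] == "g2"].iloc[0]
        assert g2["fpkm_1"] == 0.0 and g2["call"] == "up"
        assert np.all(out["fdr"] >= out["p_value"] - 1e-15)
        for row in out.itertuples(index=False):
            assert row.call == cd.classify_deg(row.fdr, row.log2_ratio)

    def test_totals_summed_from_table(self, small_counts):
        auto = cd.run_dge(small_counts)
        explicit = cd.run_dge(
            small_counts,
            n1=int(small_counts["count_1"].sum()),
            n2=int(small_counts["count_2"].sum()),
        )
        pd.testing.assert_frame_equal(auto, explicit)

    def test_duplicate_gene_ids_rejected(self, small_counts):
        dup = pd.concat([small_counts, small_counts.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="unique"):
            cd.run_dge(dup)

    def test_zero_fpkm_floor_keeps_ratio_finite(self, small_counts):
        out = cd.run_dge(small_counts, n1=10**6, n2=10**6, fpkm_floor=0.001)
        assert np.all(np.isfinite(out["log2_ratio"]))
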