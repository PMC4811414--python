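"""Inference machinery: bootstrap, letters, Stuart-Maxwell, Wilcoxon, ANOVA.

Independent oracles: exact enumeration (binomial resampling distribution,
2^n sign flips), statsmodels' marginal-homogeneity test, scipy's Wilcoxon,
and pingouin's repeated-measures ANOVA.
"""

import itertools

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.contingency_tables import SquareTable

from colourpref.inference import (
    BootstrapConfig,
    PairwiseResult,
    bonferroni_posthoc,
    bootstrap_pairwise,
    corrected_alpha,
    letter_display,
    rm_anova_2x3,
    significance_matrix,
    stuart_maxwell,
    wilcoxon_signed_rank,
)


class TestCorrectedAlpha:
    @pytest.mark.parametrize(
        "alpha, k, expected",
        [(0.05, 2, 0.025), (0.05, 9, 0.05 / 72), (0.1, 3, 0.1 / 6)],
    )
    def test_formula(self, alpha, k, expected):
        assert corrected_alpha(alpha, k) == pytest.approx(expected, rel=1e-12)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            corrected_alpha(0.05, 1)


class TestBootstrapPairwise:
    def test_uniform_counts_yield_no_significance(self):
        res = bootstrap_pairwise([10] * 9, BootstrapConfig(B=20_000, seed=0))
        assert not any(r.significant for r in res)
        assert len(res) == 36

    def test_seeded_runs_are_bit_identical(self):
        cfg = BootstrapConfig(B=5_000, seed=123)
        a = bootstrap_pairwise([26, 5, 5, 2, 9, 23, 8, 6, 1], cfg)
        b = bootstrap_pairwise([26, 5, 5, 2, 9, 23, 8, 6, 1], cfg)
        assert a == b

    def test_mirror_antisymmetry(self):
        res = bootstrap_pairwise(
            {"x": 30, "y": 10, "z": 5}, BootstrapConfig(B=10_000, seed=5)
        )
        by_pair = {(r.category_i, r.category_j): r for r in res}
        r = by_pair[("x", "y")]
        assert r.diff == pytest.approx((30 - 10) / 45)

    def test_k2_matches_exact_binomial_enumeration(self):
        """Small-n two-category CI against the exact resampling distribution.

        With counts (4, 1), the bootstrap difference is (2X - n)/n with
        X ~ Binomial(n, 4/5); the percentile endpoints must fall between the
        exact inverse-CDF quantiles of that discrete distribution.
        """
        counts, n = (4, 1), 5
        cfg = BootstrapConfig(B=200_000, alpha=0.05, seed=9)
        (res,) = bootstrap_pairwise(counts, cfg)
        a_tail = corrected_alpha(0.05, 2)
        support = (2 * np.arange(n + 1) - n) / n
        pmf = stats.binom.pmf(np.arange(n + 1), n, 4 / 5)
        cdf = np.cumsum(pmf)
        lo_exact = support[np.searchsorted(cdf, a_tail)]
        hi_exact = support[np.searchsorted(cdf, 1 - a_tail)]
        spacing = 2 / n
        assert abs(res.ci_low - lo_exact) <= spacing
        assert abs(res.ci_high - hi_exact) <= spacing
        # the resampling histogram itself matches the binomial pmf
        draws = np.random.default_rng(9).multinomial(n, [0.8, 0.2], size=50_000)
        freqs = np.bincount(draws[:, 0], minlength=n + 1) / 50_000
        assert np.abs(freqs - pmf).max() < 0.01

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_pairwise([0, 0, 0])


class TestLetterDisplay:
    def _results(self, labels, sig_pairs):
        out = []
        for a, b in itertools.combinations(labels, 2):
            out.append(
                PairwiseResult(a, b, 0.0, -1.0, 1.0, (a, b) in sig_pairs or (b, a) in sig_pairs)
            )
        return out

    def test_no_significance_single_letter(self):
        letters = letter_display(self._results("ABCD", set()))
        assert set(letters.values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        labels = "ABCD"
        sig = set(itertools.combinations(labels, 2))
        letters = letter_display(self._results(labels, sig))
        assert len(set(letters.values())) == 4
        assert all(len(v) == 1 for v in letters.values())

    def test_chain_pattern(self):
        # A != C significant only: A and C must not share; B bridges both
        letters = letter_display(self._results("ABC", {("A", "C")}))
        assert not set(letters["A"]) & set(letters["C"])
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])

    @given(st.integers(0, 2**28 - 1))
    @settings(derandomize=True, max_examples=60)
    def test_soundness_fuzzed(self, seed):
        """Sharing a letter must exactly reproduce the input significance."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 9))
        sig = np.zeros((k, k), dtype=bool)
        upper = np.triu(rng.random((k, k)) < 0.4, k=1)
        sig = upper | upper.T
        labels = [f"c{i}" for i in range(k)]
        letters = letter_display((labels, sig))
        for i, j in itertools.combinations(range(k), 2):
            share = bool(set(letters[labels[i]]) & set(letters[labels[j]]))
            assert share != sig[i, j]

    def test_asymmetric_matrix_rejected(self):
        bad = np.zeros((3, 3), dtype=bool)
        bad[0, 1] = True
        with pytest.raises(ValueError):
            letter_display((["a", "b", "c"], bad))


class TestStuartMaxwell:
    def test_symmetric_table_is_null(self):
        t = [[10, 5, 2], [5, 8, 3], [2, 3, 12]]
        res = stuart_maxwell(t)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0
        assert res.df == 2

    def test_2x2_reduces_to_mcnemar(self):
        a, b, c, d = 20, 9, 3, 15
        res = stuart_maxwell([[a, b], [c, d]])
        assert res.chi2 == pytest.approx((b - c) ** 2 / (b + c), rel=1e-12)
        assert res.df == 1

    def test_matches_full_rank_pinv_route(self, rng):
        """Independent algebraic route: keep all k marginal differences and
        use the generalized inverse of the full singular covariance."""
        for _ in range(20):
            t = rng.integers(0, 20, size=(3, 3)).astype(float)
            off = t + t.T - 2 * np.diag(np.diag(t))
            if (off == 0).any(axis=None) and (off.sum(1) == 0).any():
                continue
            row, col = t.sum(1), t.sum(0)
            d_full = row - col
            k = 3
            S_full = np.empty((k, k))
            for i in range(k):
                for j in range(k):
                    S_full[i, j] = (
                        row[i] + col[i] - 2 * t[i, i] if i == j else -(t[i, j] + t[j, i])
                    )
            expected = float(d_full @ np.linalg.pinv(S_full) @ d_full)
            assert stuart_maxwell(t).chi2 == pytest.approx(expected, rel=1e-8)

    def test_consistent_with_statsmodels_variant(self, rng):
        """statsmodels estimates the covariance without imposing marginal
        homogeneity (it subtracts the d-outer-product), so the statistics
        differ in finite samples but must give compatible inferences."""
        for _ in range(10):
            t = rng.integers(1, 20, size=(3, 3)).astype(float)
            ours = stuart_maxwell(t)
            sm = SquareTable(t).homogeneity(method="stuart_maxwell")
            assert ours.df == sm.df
            assert abs(ours.p_value - sm.pvalue) < 0.05

    def test_label_permutation_invariance(self, rng):
        t = rng.integers(1, 15, size=(4, 4))
        base = stuart_maxwell(t).chi2
        for _ in range(5):
            perm = rng.permutation(4)
            assert stuart_maxwell(t[np.ix_(perm, perm)]).chi2 == pytest.approx(base, rel=1e-9)

    def test_quadratic_form_oracle(self):
        """Explicit matrix-algebra evaluation on a fixed asymmetric table."""
        t = np.array([[10, 5, 0], [0, 10, 5], [5, 0, 10]], dtype=float)
        row, col = t.sum(1), t.sum(0)
        d = (row - col)[:2]
        S = np.array(
            [
                [row[0] + col[0] - 2 * t[0, 0], -(t[0, 1] + t[1, 0])],
                [-(t[0, 1] + t[1, 0]), row[1] + col[1] - 2 * t[1, 1]],
            ]
        )
        expected = float(d @ np.linalg.solve(S, d))
        assert stuart_maxwell(t).chi2 == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_category_dropped(self):
        t = [[5, 3, 0], [2, 6, 0], [0, 0, 4]]
        res = stuart_maxwell(t, labels=["a", "b", "c"])
        assert res.dropped_categories == ("c",)
        assert res.df == 1


class TestWilcoxon:
    def test_all_positive_differences(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.V == 15.0  # n(n+1)/2

    def test_antisymmetric_differences(self):
        res = wilcoxon_signed_rank([-4.0, -1.0, 1.0, 4.0], exact=False)
        assert res.V == pytest.approx(4 * 5 / 4)
        assert res.Z == 0.0

    def test_exact_p_matches_sign_enumeration(self, rng):
        """n = 8 exact p equals brute force over all 2^8 sign patterns."""
        d = rng.normal(1.0, 2.0, size=8)
        while len(np.unique(np.abs(d))) < 8 or (d == 0).any():
            d = rng.normal(1.0, 2.0, size=8)
        res = wilcoxon_signed_rank(d, exact=True)
        ranks = stats.rankdata(np.abs(d))
        vs = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=8)
        ]
        vs = np.array(vs)
        p_brute = min(1.0, 2 * min((vs <= res.V).mean(), (vs >= res.V).mean()))
        assert res.p_value == pytest.approx(p_brute, rel=1e-12)

    def test_exact_p_matches_scipy(self, rng):
        d = rng.normal(0.5, 1.5, size=12)
        res = wilcoxon_signed_rank(d, exact=True)
        sp = stats.wilcoxon(d, method="exact")
        assert res.p_value == pytest.approx(sp.pvalue, rel=1e-9)

    def test_approx_z_with_ties(self):
        d = [1.0, 1.0, -1.0, 2.0, 3.0, 3.0, 4.0]
        res = wilcoxon_signed_rank(d, exact=False)
        assert res.n_nonzero == 7
        assert 0 < res.p_value < 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])


class TestRmAnova:
    @staticmethod
    def _pingouin(Y):
        rows = [
            (s, p, c, Y[s, i, j])
            for s in range(Y.shape[0])
            for i, p in enumerate(["most", "least"])
            for j, c in enumerate(["general", "walls", "tshirt"])
        ]
        df = pd.DataFrame(rows, columns=["subj", "pref", "ctx", "y"])
        return pg.rm_anova(
            data=df, dv="y", within=["pref", "ctx"], subject="subj",
            detailed=True, effsize="np2",
        ).set_index("Source")

    def test_constant_conditions_give_zero_f(self, rng):
        base = rng.normal(50, 10, size=10)  # participant offsets only
        Y = np.repeat(base, 6).reshape(10, 2, 3)
        res = rm_anova_2x3(Y)
        for eff in res.effects.values():
            assert eff.F == pytest.approx(0.0, abs=1e-18)
            assert eff.partial_eta_sq == pytest.approx(0.0, abs=1e-18)

    def test_matches_pingouin_oracle(self, rng):
        for _ in range(5):
            Y = rng.normal(50, 12, size=(10, 2, 3))
            res = rm_anova_2x3(Y)
            aov = self._pingouin(Y)
            for src, key in [("pref", "preference"), ("ctx", "context"), ("pref * ctx", "interaction")]:
                eff = res.effects[key]
                assert eff.F == pytest.approx(aov.loc[src, "F"], abs=1e-8)
                assert eff.p_value == pytest.approx(aov.loc[src, "p_unc"], abs=1e-8)
                assert eff.partial_eta_sq == pytest.approx(aov.loc[src, "np2"], abs=1e-8)
                assert eff.epsilon == pytest.approx(aov.loc[src, "eps"], abs=1e-8)
                if src != "pref":
                    assert eff.p_gg == pytest.approx(aov.loc[src, "p_GG_corr"], abs=1e-8)

    def test_shift_and_scale_equivariance(self, rng):
        Y = rng.normal(0, 1, size=(12, 2, 3))
        base = rm_anova_2x3(Y)
        shifted = rm_anova_2x3(Y + 100.0)
        scaled = rm_anova_2x3(Y * 7.5)
        for key in base.effects:
            assert shifted.effects[key].F == pytest.approx(base.effects[key].F, rel=1e-9, abs=1e-9)
            assert scaled.effects[key].F == pytest.approx(base.effects[key].F, rel=1e-9)
            assert scaled.effects[key].partial_eta_sq == pytest.approx(
                base.effects[key].partial_eta_sq, rel=1e-9, abs=1e-12
            )

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_2x3(np.zeros((1, 2, 3)))

    def test_missing_cells_rejected(self):
        Y = np.zeros((5, 2, 3))
        Y[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_2x3(Y)


class TestBonferroniPosthoc:
    def test_identical_pairs_adjust_to_one(self):
        Y = np.tile(np.arange(6, dtype=float).reshape(1, 2, 3), (8, 1, 1))
        Y += np.random.default_rng(0).normal(0, 1e-12, Y.shape)
        out = bonferroni_posthoc(Y, "preference")
        assert list(out.values())[0] <= 1.0

    def test_multiplication_and_cap(self, rng):
        Y = rng.normal(50, 5, size=(15, 2, 3))
        raw = {}
        means = {
            "general": Y[:, :, 0].mean(axis=1),
            "walls": Y[:, :, 1].mean(axis=1),
            "t-shirt": Y[:, :, 2].mean(axis=1),
        }
        for a, b in itertools.combinations(means, 2):
            raw[(a, b)] = stats.ttest_rel(means[a], means[b]).pvalue
        out = bonferroni_posthoc(Y, "context")
        for pair, p in out.items():
            assert p == pytest.approx(min(1.0, raw[pair] * 3), rel=1e-9)

    def test_cells_effect_has_fifteen_comparisons(self, rng):
        Y = rng.normal(0, 1, size=(10, 2, 3))
        assert len(bonferroni_posthoc(Y, "cells")) == 15

    def test_unknown_effect_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_posthoc(np.zeros((5, 2, 3)), "nope")


def test_significance_matrix_round_trip():
    labels = ["a", "b", "c"]
    res = [
        PairwiseResult("a", "b", 0.1, 0.01, 0.2, True),
        PairwiseResult("a", "c", 0.0, -0.1, 0.1, False),
        PairwiseResult("b", "c", 0.0, -0.1, 0.1, False),
    ]
    out_labels, sig = significance_matrix(res)
    assert out_labels == labels
    assert sig[0, 1] and sig[1, 0]
    assert not sig[0, 2] and not sig[1, 2]
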