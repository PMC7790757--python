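"""Similarity-protocol statistics: rank tests, supervised PCA, overlap,
shared/specific classification, dSI_max and differential junctions."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from crypticsplice.junction_core import Junction, JunctionPair
from crypticsplice.splice_similarity import (
    classify_shared,
    delta_si_max,
    differential_junctions,
    distance_profile,
    frame_fraction,
    lowp_enrichment,
    overlap_significance,
    overlap_test,
    supervised_pca,
    wilcoxon_per_junction,
)


def _frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"j{i}" for i in range(arr.shape[1])],
    )


class TestWilcoxon:
    def test_complete_separation_matches_exact_tail(self, rng):
        # tie-free complete separation, 5 vs 100: two-sided exact p = 2/C(105,5)
        g = 0.3 + rng.random(5) * 0.01
        c = rng.random(100) * 0.001
        assert wilcoxon_per_junction(g, c) == pytest.approx(2 / math.comb(105, 5))

    def test_same_multiset_gives_central_statistic(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        p = wilcoxon_per_junction(vals, vals[::-1])
        assert p > 0.9

    def test_missing_treated_as_zero(self):
        g = [0.3, np.nan, 0.3]
        c = [np.nan, np.nan, 0.0, 0.0]
        assert wilcoxon_per_junction(g, c) == wilcoxon_per_junction([0.3, 0, 0.3], [0, 0, 0, 0])

    def test_small_groups_raise(self):
        with pytest.raises(ValueError):
            wilcoxon_per_junction([0.3], [0.1, 0.2])


class TestLowPEnrichment:
    def test_strong_enrichment_closed_form(self):
        p = np.concatenate([np.full(500, 0.01), np.full(500, 0.5)])
        assert lowp_enrichment(p) < 1e-10

    def test_no_low_p_gives_one(self):
        assert lowp_enrichment(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_invalid_alpha_raises(self):
        with pytest.raises(ValueError):
            lowp_enrichment([0.5], alpha=1.5)


class TestSupervisedPCA:
    def test_single_perfectly_separating_junction(self):
        si = _frame(np.concatenate([np.full(6, 0.4), np.full(50, 0.01)])[:, None])
        mask = np.zeros(56, bool)
        mask[:6] = True
        res = supervised_pca(si, mask)
        assert res.associated_pcs == ["PC1"]
        assert res.selected_ids == ["j0"]

    def test_planted_junctions_recovered_null_left_behind(self, rng):
        # protocol order: Wilcoxon candidate filter (p < 0.05), then PCA
        n_planted, n_null = 20, 100
        X = rng.normal(0.01, 0.004, size=(106, n_planted + n_null)).clip(0, 1)
        X[:6, :n_planted] = rng.normal(0.3, 0.05, size=(6, n_planted)).clip(0, 1)
        mask = np.zeros(106, bool)
        mask[:6] = True
        si = _frame(X)
        cands = [
            c for c in si.columns
            if wilcoxon_per_junction(si.loc[mask, c], si.loc[~mask, c]) < 0.05
        ]
        res = supervised_pca(si[cands], mask)
        sel = set(res.selected_ids)
        planted = {f"j{i}" for i in range(n_planted)}
        null = {f"j{i}" for i in range(n_planted, n_planted + n_null)}
        assert len(sel & planted) / n_planted >= 0.8
        # only chance-significant candidates can be selected, so the null
        # selection rate is bounded near the candidate alpha of 5%
        assert sel - planted <= set(cands) - planted
        assert len(sel & null) / n_null <= 0.10

    def test_shuffled_labels_rarely_associate(self, rng):
        hits = 0
        for _ in range(30):
            X = rng.normal(0, 1, size=(80, 20))
            mask = np.zeros(80, bool)
            mask[rng.choice(80, 6, replace=False)] = True
            if supervised_pca(_frame(X), mask).associated_pcs:
                hits += 1
        assert hits / 30 <= 0.05

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError):
            supervised_pca(_frame(np.zeros((10, 0))), np.zeros(10, bool))


class TestOverlap:
    def test_empirical_matches_enumeration(self):
        # universe 10, |A| = |B| = 3: exhaustive enumeration oracle
        A = {0, 1, 2}
        for observed in (1, 2, 3):
            exact = sum(
                1 for B in combinations(range(10), 3) if len(A & set(B)) >= observed
            ) / math.comb(10, 3)
            res = overlap_significance(3, 3, observed, 10, n_resamples=20_000, seed=5)
            mc_se = math.sqrt(exact * (1 - exact) / 20_000)
            assert abs(res.empirical_p - exact) <= 3 * mc_se + 1e-4
            assert res.hypergeom_p == pytest.approx(exact, rel=1e-12)

    def test_zero_overlap_tiny_sets_p_near_one(self):
        res = overlap_significance(3, 3, 0, 10_000, n_resamples=500, seed=1)
        assert res.empirical_p > 0.9 and res.hypergeom_p == pytest.approx(1.0)

    def test_expected_value_formula(self):
        res = overlap_significance(211, 179, 110, 5357, n_resamples=10, seed=0)
        assert res.expected == pytest.approx(211 * 179 / 5357)

    def test_universe_too_small_raises(self):
        with pytest.raises(ValueError):
            overlap_test({"a", "b"}, {"c"}, 1)

    def test_seed_reproducible(self):
        r1 = overlap_significance(5, 5, 2, 30, n_resamples=500, seed=9)
        r2 = overlap_significance(5, 5, 2, 30, n_resamples=500, seed=9)
        assert r1.empirical_p == r2.empirical_p


class TestClassifyShared:
    @pytest.fixture
    def setup(self):
        # 40 controls with SI linspace 0..0.2 -> Q95 ~ 0.19, Q75 ~ 0.15
        ctl = np.linspace(0, 0.2, 40)
        groups = pd.Series(
            ["A"] * 2 + ["B"] * 2 + ["control"] * 40,
            index=[f"s{i}" for i in range(44)],
        )
        return ctl, groups

    def _si(self, ctl, a_vals, b_vals):
        col = np.concatenate([a_vals, b_vals, ctl])
        return _frame(col[:, None])

    def test_rules(self, setup):
        ctl, groups = setup
        q95 = np.quantile(ctl, 0.95)
        q75 = np.quantile(ctl, 0.75)

        shared = classify_shared(self._si(ctl, [0.4, 0.1], [0.35, 0.1]), groups, "A", "B", "control")
        assert shared["label"].iloc[0] == "shared"

        a_spec = classify_shared(self._si(ctl, [0.4, 0.1], [0.05, 0.01]), groups, "A", "B", "control")
        assert a_spec["label"].iloc[0] == "A_specific"
        assert a_spec["si_max_b"].iloc[0] < q75

        mid = (q75 + q95) / 2
        nd = classify_shared(self._si(ctl, [0.4, 0.1], [mid, 0.0]), groups, "A", "B", "control")
        assert nd["label"].iloc[0] == "not_determined"

    def test_quantile_columns_reported(self, setup):
        ctl, groups = setup
        out = classify_shared(self._si(ctl, [0.4, 0.1], [0.3, 0.1]), groups, "A", "B", "control")
        assert out["si_q95"].iloc[0] == pytest.approx(np.quantile(ctl, 0.95))
        assert out["si_q75"].iloc[0] == pytest.approx(np.quantile(ctl, 0.75))

    def test_control_group_size_guard(self, setup):
        ctl, groups = setup
        si = self._si(ctl, [0.4, 0.1], [0.3, 0.1])
        with pytest.raises(ValueError, match="control"):
            classify_shared(si, groups.replace("control", "other"), "A", "B", "control")
        with pytest.raises(ValueError, match="quantiles"):
            classify_shared(si.iloc[:10], groups.iloc[:10], "A", "B", "control")


class TestDeltaSIMax:
    @pytest.fixture
    def si(self):
        return _frame([[0.3, 0.2, 0.0], [0.1, 0.2, 0.0], [0.05, 0.2, 0.0]])

    def test_formula(self, si):
        groups = pd.Series(["exp", "ctl", "ctl"], index=si.index)
        out = delta_si_max(si, groups, "exp", "ctl").set_index("junction_id")
        assert out.loc["j0", "delta_si_max"] == pytest.approx((0.3 - 0.1) / 0.1)
        assert out.loc["j1", "delta_si_max"] == pytest.approx(0.0)
        assert math.isnan(out.loc["j2", "delta_si_max"])  # control max 0 sentinel

    def test_defined_values_at_least_minus_one(self, rng):
        si = _frame(rng.random((10, 20)))
        groups = pd.Series(["exp"] * 3 + ["ctl"] * 7, index=si.index)
        out = delta_si_max(si, groups, "exp", "ctl")
        vals = out["delta_si_max"].dropna()
        assert (vals >= -1).all()

    def test_unknown_label_raises(self, si):
        groups = pd.Series(["exp", "ctl", "ctl"], index=si.index)
        with pytest.raises(ValueError, match="unknown"):
            delta_si_max(si, groups, "nope", "ctl")


def _p3(distance):
    s, e = 1000, 1100
    return JunctionPair(
        aberrant=Junction("chr1", s, e + distance, "+"),
        canonical=Junction("chr1", s, e, "+"),
        category="proximal3" if abs(distance) <= 100 else "distant",
        gene_id="g",
        distance=distance,
        side="three_prime",
    )


class TestDistanceAndFrame:
    def test_single_junction_histogram(self):
        prof = distance_profile([_p3(-15)])
        assert prof.counts[-15] == 1 and prof.counts.sum() == 1
        assert prof.frac_upstream_10_30 == 1.0

    def test_out_of_window_goes_to_overflow(self):
        prof = distance_profile([_p3(-15), _p3(-60)], window=50)
        assert prof.counts.sum() == 1 and prof.overflow == 1

    def test_planted_offsets_recovered(self, small_classification):
        prof = distance_profile(small_classification.pairs)
        assert prof.frac_upstream_10_30 >= 0.95

    def test_frame_rules(self):
        out, total, frac = frame_fraction([_p3(-15)])
        assert (out, total) == (0, 1)  # 15 divisible by 3: in frame
        out, total, frac = frame_fraction([_p3(-16)])
        assert (out, total) == (1, 1)
        # uniform offsets over an interval whose length is a multiple of 3
        pairs = [_p3(-d) for d in range(10, 31)]
        out, total, frac = frame_fraction(pairs)
        assert frac == pytest.approx(14 / 21)


class TestDifferentialJunctions:
    def _welch_p(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy import stats

        return 2 * stats.t.sf(abs(t), df)

    def test_clear_difference_selected_and_p_matches_welch(self):
        a, b = [0.30, 0.28, 0.32], [0.05, 0.06, 0.04]
        si = _frame(np.array([a + b]).reshape(6, 1))
        groups = pd.Series(["mut"] * 3 + ["wt"] * 3, index=si.index)
        out = differential_junctions(si, groups, "mut", "wt")
        assert bool(out["selected"].iloc[0])
        assert out["p"].iloc[0] == pytest.approx(self._welch_p(a, b), rel=1e-9)
        assert out["log2fc"].iloc[0] == pytest.approx(np.log2(np.mean(a) / np.mean(b)))

    def test_identical_replicates_not_selected(self):
        si = _frame(np.tile([[0.2], [0.3], [0.25]], (2, 1)))
        groups = pd.Series(["mut"] * 3 + ["wt"] * 3, index=si.index)
        out = differential_junctions(si, groups, "mut", "wt")
        assert not out["selected"].any()

    def test_fold_change_below_threshold_not_selected(self):
        a = [0.190, 0.191, 0.189]
        b = [0.100, 0.101, 0.099]  # ratio 1.9 -> log2 < 1
        si = _frame(np.array(a + b).reshape(6, 1))
        groups = pd.Series(["mut"] * 3 + ["wt"] * 3, index=si.index)
        out = differential_junctions(si, groups, "mut", "wt")
        assert out["p"].iloc[0] < 0.05
        assert not out["selected"].any()

    def test_zero_in_both_groups_skipped(self):
        si = _frame(np.zeros((6, 1)))
        groups = pd.Series(["mut"] * 3 + ["wt"] * 3, index=si.index)
        out = differential_junctions(si, groups, "mut", "wt")
        assert math.isnan(out["p"].iloc[0]) and not out["selected"].any()

    def test_fdr_mode(self, rng):
        X = np.concatenate(
            [rng.normal(0.3, 0.01, (3, 5)), rng.normal(0.05, 0.01, (3, 5))]
        )
        si = _frame(X)
        groups = pd.Series(["mut"] * 3 + ["wt"] * 3, index=si.index)
        out = differential_junctions(si, groups, "mut", "wt", use_fdr=True, fdr_max=0.05)
        assert out["selected"].all()
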