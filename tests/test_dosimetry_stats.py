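"""Caliper volumes, growth trajectories and exact rank statistics."""

import itertools
import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fracptt.dosimetry_stats import (
    CaliperTable,
    bonferroni,
    fit_log_growth,
    growth_trajectories,
    kruskal_wallis,
    mann_whitney_exact,
    score_comparison,
    tumor_volume,
)


def brute_force_mw_p(a, b):
    """Independent oracle: U via pairwise comparisons, p by direct enumeration."""
    a, b = list(a), list(b)
    pooled = a + b
    na, nb = len(a), len(b)

    def u_of(sel):
        ga = [pooled[i] for i in sel]
        gb = [pooled[i] for i in range(na + nb) if i not in sel]
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in ga for y in gb
        )

    mu = na * nb / 2.0
    obs = abs(u_of(frozenset(range(na))) - mu)
    labelings = [frozenset(c) for c in itertools.combinations(range(na + nb), na)]
    hits = sum(1 for s in labelings if abs(u_of(s) - mu) >= obs - 1e-9)
    return hits / len(labelings)


class TestTumorVolume:
    @pytest.mark.parametrize(
        "l, w, v", [(10, 5, 125.0), (4, 4, 32.0), (8.4, 6.2, 161.448)]
    )
    def test_formula(self, l, w, v):
        assert tumor_volume(l, w) == pytest.approx(v)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tumor_volume(0.0, 1.0)

    @given(
        l=st.floats(1.0, 30.0), w=st.floats(1.0, 30.0), eps=st.floats(0.01, 1.0)
    )
    def test_strictly_increasing(self, l, w, eps):
        assert tumor_volume(l + eps, w) > tumor_volume(l, w)
        assert tumor_volume(l, w + eps) > tumor_volume(l, w)


class TestCaliperTable:
    def _frame(self, **over):
        base = dict(
            animal_id=["a1", "a1"], group=["control"] * 2, day=[0, 3],
            length_mm=[8.0, 9.0], width_mm=[6.0, 7.0],
        )
        base.update(over)
        return pd.DataFrame(base)

    def test_swapped_axes_auto_corrected(self, caplog):
        with caplog.at_level(logging.WARNING):
            t = CaliperTable(self._frame(length_mm=[5.0, 9.0], width_mm=[6.0, 7.0]))
        assert (t.df.length_mm >= t.df.width_mm).all()
        assert "swapped" in caplog.text

    def test_duplicate_measurement_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CaliperTable(self._frame(day=[0, 0]))

    def test_csv_round_trip(self, tmp_path):
        t = CaliperTable(self._frame())
        t.to_csv(tmp_path / "c.csv")
        back = CaliperTable.from_csv(tmp_path / "c.csv")
        pd.testing.assert_frame_equal(back.df, t.df)


class TestGrowthTrajectories:
    def test_constant_measurements_give_flat_trajectory(self):
        rows = [dict(animal_id="a", group="control", day=d, length_mm=8.0, width_mm=6.0)
                for d in (0, 3, 7, 14)]
        summary, _ = growth_trajectories(CaliperTable(pd.DataFrame(rows)))
        assert summary["mean"].nunique() == 1
        assert (summary.sd == 0).all()

    def test_normalization_sets_day0_to_one(self):
        rows = [dict(animal_id=f"a{i}", group="mla", day=d,
                     length_mm=8.0 + i + 0.1 * d, width_mm=5.0 + i)
                for i in range(3) for d in (0, 3, 7)]
        summary, per_animal = growth_trajectories(CaliperTable(pd.DataFrame(rows)),
                                                  normalize=True)
        day0 = summary[summary.day == 0]
        assert np.allclose(day0["mean"], 1.0) and np.allclose(day0["sd"], 0.0)

    def test_missing_day0_excluded_with_log(self, caplog):
        rows = [dict(animal_id="a", group="mla", day=d, length_mm=8.0, width_mm=5.0)
                for d in (0, 3)]
        rows += [dict(animal_id="b", group="mla", day=3, length_mm=9.0, width_mm=6.0)]
        with caplog.at_level(logging.WARNING):
            _, per_animal = growth_trajectories(CaliperTable(pd.DataFrame(rows)),
                                                normalize=True)
        assert set(per_animal.animal_id) == {"a"}
        assert "day-0" in caplog.text

    def test_log_slope_recovers_exact_rate(self):
        g = 0.2317
        days = np.array([0, 3, 7, 14], float)
        V = 55.0 * np.exp(g * days)
        assert fit_log_growth(days, V) == pytest.approx(g, abs=1e-9)


class TestMannWhitneyExact:
    def test_complete_separation_n4(self):
        r = mann_whitney_exact([1, 2, 3, 4], [5, 6, 7, 8])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 70)

    def test_identical_multisets_give_p1(self):
        assert mann_whitney_exact([1, 2, 2, 5], [1, 2, 2, 5]).p_value == 1.0

    def test_all_values_tied_gives_p1(self):
        assert mann_whitney_exact([3, 3, 3], [3, 3]).p_value == 1.0

    def test_monotone_transform_invariance(self):
        a = [0.2, 1.7, 2.4, 3.3]
        b = [1.1, 2.9, 4.8, 5.5]
        r1 = mann_whitney_exact(a, b)
        r2 = mann_whitney_exact(np.exp(a), np.exp(b))
        assert r1.p_value == r2.p_value and r1.statistic == r2.statistic

    @given(
        na=st.integers(1, 6),
        nb=st.integers(1, 6),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40)
    def test_matches_scipy_exact_without_ties(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=na), rng.normal(size=nb)
        mine = mann_whitney_exact(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @given(
        na=st.integers(1, 5),
        nb=st.integers(1, 5),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=25)
    def test_matches_enumeration_oracle_with_ties(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, size=na).astype(float)
        b = rng.integers(0, 4, size=nb).astype(float)
        assert mann_whitney_exact(a, b).p_value == pytest.approx(
            brute_force_mw_p(a, b), abs=1e-12
        )

    def test_achieved_size_does_not_exceed_nominal(self, rng):
        """Exact test at n=4 vs 4 under the null: size at 0.05 stays <= 0.05."""
        combs = np.array(list(itertools.combinations(range(8), 4)))
        reps, hits = 10_000, 0
        for _ in range(reps):
            x = rng.standard_normal(8)
            ranks = sps.rankdata(x)
            U = ranks[:4].sum() - 10.0
            U_all = ranks[combs].sum(axis=1) - 10.0
            p = np.mean(np.abs(U_all - 8.0) >= abs(U - 8.0) - 1e-9)
            hits += p <= 0.05
        assert hits / reps <= 0.05

    def test_rejects_empty_or_missing(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])
        with pytest.raises(ValueError):
            mann_whitney_exact([np.nan, 1.0], [2.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        r = kruskal_wallis([[3, 3], [3, 3], [3, 3]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_tie_free_H_matches_direct_computation(self):
        """Ranks 1..6 in three ordered pairs: H = 12/42 * 179/2 - 21 = 4.571."""
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        ref = sps.kruskal([1, 2], [3, 4], [5, 6])
        assert r.statistic == pytest.approx(32.0 / 7.0)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.method == "exact-enumeration"

    def test_exact_p_is_permutation_fraction(self):
        # N=6, sizes (2,2,2): 90 distinct assignments; max H achieved by the
        # fully ordered ones -> p = P(H >= H_obs) from the enumeration
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert 0 < r.p_value < 0.1

    def test_chi2_fallback_for_larger_samples(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=6), rng.normal(size=6), rng.normal(1.0, size=6)]
        r = kruskal_wallis(groups)
        assert r.method == "chi2-approximation"
        ref = sps.kruskal(*groups)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_monotone_transform_invariance(self):
        g = [[0.1, 0.9], [0.5, 2.0], [1.4, 3.0]]
        r1 = kruskal_wallis(g)
        r2 = kruskal_wallis([list(np.log(np.asarray(x) + 1.0)) for x in g])
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestBonferroni:
    @pytest.mark.parametrize("p, m, out", [(0.02, 3, 0.06), (0.9, 2, 1.0), (0.3, 1, 0.3)])
    def test_correction(self, p, m, out):
        assert bonferroni(p, m) == pytest.approx(out)

    def test_domain(self):
        with pytest.raises(ValueError):
            bonferroni(0.0, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestScoreComparison:
    def test_all_maximal_scores_gives_null_kw(self):
        res = score_comparison({g: [3, 3, 3, 3] for g in ("control", "flat", "mla")})
        assert res["kruskal_wallis"].p_value == 1.0

    def test_complete_separation_under_ties(self):
        res = score_comparison({"control": [1, 1, 1, 1], "mla": [3, 3, 3, 3]})
        mu = res["pairwise"]["control_vs_mla"]
        assert mu.p_value == pytest.approx(2 / 70)
        assert mu.p_corrected == pytest.approx(min(1.0, mu.p_value * 1))

    def test_three_group_pairwise_bonferroni_m3(self):
        scores = {"control": [1, 1, 2, 1], "flat": [2, 2, 3, 2], "mla": [3, 3, 3, 2]}
        res = score_comparison(scores)
        assert len(res["pairwise"]) == 3
        for comp in res["pairwise"].values():
            assert comp.p_corrected == pytest.approx(min(1.0, 3 * comp.p_value))

    def test_label_equivariance(self):
        scores = {"control": [1, 2, 1], "flat": [3, 2, 3]}
        res = score_comparison(scores)
        swapped = score_comparison({"control": scores["flat"], "flat": scores["control"]})
        assert res["pairwise"]["control_vs_flat"].p_value == pytest.approx(
            swapped["pairwise"]["control_vs_flat"].p_value
        )

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError):
            score_comparison({"control": [1, 4]})
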