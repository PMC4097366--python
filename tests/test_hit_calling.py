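"""Scoring statistics: normalization, replicate exclusion, lgr, z, hit calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yana.hit_calling import (
    GeneMeasurement,
    ScreenModel,
    call_hits,
    exclude_replicates,
    log_growth_ratio,
    merge_hit_tables,
    normalize_grid,
    score_screen,
)
from yana.screen_io import ColonyGrid, HitRecord, HitTable

from conftest import make_grid


class TestNormalizeGrid:
    def test_constant_plate_normalizes_to_one(self):
        grid = make_grid([200.0] * 10)
        out = normalize_grid(grid)
        assert set(np.unique(out.sizes)) == {0.0, 1.0}

    def test_median_of_nonzero_divides(self):
        out = normalize_grid(make_grid([100.0, 200.0, 300.0, 0.0]))
        assert out.sizes.reshape(-1)[:4].tolist() == [0.5, 1.0, 1.5, 0.0]

    def test_idempotent(self):
        grid = make_grid([3.0, 8.0, 1.0, 12.0, 0.0])
        once = normalize_grid(grid)
        twice = normalize_grid(once)
        np.testing.assert_array_equal(once.sizes, twice.sizes)

    def test_all_zero_plate_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_grid(make_grid([]))


class TestExcludeReplicates:
    def test_tight_quad_fully_retained(self):
        assert exclude_replicates([1.0, 1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0, 1.0]

    def test_single_outlier_removed_when_cv_fixable(self):
        # CV of the full quad is ~0.67; dropping the value farthest from
        # the median (3.0) brings it to ~0.10, under the 0.35 threshold
        assert exclude_replicates([1.0, 1.1, 0.9, 3.0]) == [1.0, 1.1, 0.9]

    def test_broad_spread_not_fixable_by_one_removal(self):
        quad = [1.0, 3.0, 5.0, 7.0]
        assert exclude_replicates(quad) == quad

    def test_fewer_than_three_values_untouched(self):
        assert exclude_replicates([1.0, 9.0]) == [1.0, 9.0]

    def test_at_most_one_value_excluded(self):
        out = exclude_replicates([1.0, 1.0, 4.0, 4.0])
        assert len(out) >= 3


class TestLogGrowthRatio:
    def test_equal_means_give_zero(self):
        assert log_growth_ratio(1.0, 1.0) == 0.0

    def test_halved_induced_growth_gives_ln_two(self):
        assert log_growth_ratio(1.0, 0.5) == pytest.approx(math.log(2))

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    @settings(max_examples=50, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert log_growth_ratio(a, b) == pytest.approx(-log_growth_ratio(b, a))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            log_growth_ratio(0.0, 1.0)


def _population(n, lgr_of=lambda i: 0.0, ind_of=None):
    """n measurements whose lgr is controlled per gene index."""
    out = []
    for i in range(n):
        ind = ind_of(i) if ind_of else math.exp(-lgr_of(i))
        out.append(
            GeneMeasurement(f"g{i:04d}", "wt", [ind] * 4, [1.0] * 4)
        )
    return out


class TestScoreScreen:
    def test_identical_lgr_is_degenerate(self):
        with pytest.raises(ValueError, match="scale"):
            score_screen(_population(30))

    def test_outlier_gene_scores_in_far_tail_as_sl(self):
        rng = np.random.default_rng(0)
        lgrs = dict(enumerate(rng.normal(0, 0.1, 100)))
        lgrs[0] = 0.1 * 8  # ~8 population SDs above the mean
        scores = score_screen(_population(100, lgr_of=lgrs.get))
        row = scores.table.loc["g0000"]
        assert row.z > 5 and row.p < 1e-5
        table = call_hits(scores)
        assert "g0000" in table.genes("wt", "SL")

    def test_population_z_is_robustly_standardized(self):
        from scipy.stats import median_abs_deviation

        rng = np.random.default_rng(1)
        lgrs = dict(enumerate(rng.normal(0.3, 0.2, 200)))
        scores = score_screen(_population(200, lgr_of=lgrs.get))
        assert scores.table.z.median() == pytest.approx(0, abs=1e-12)
        assert median_abs_deviation(scores.table.z, scale="normal") == (
            pytest.approx(1)
        )
        # a gaussian population keeps SD close to 1 as well
        assert scores.table.z.std(ddof=1) == pytest.approx(1, rel=0.15)

    def test_dead_in_both_dropped_dead_induced_capped(self):
        rng = np.random.default_rng(2)
        ms = _population(50, lgr_of=dict(enumerate(rng.normal(0, 0.1, 50))).get)
        ms.append(GeneMeasurement("dead_both", "wt", [0.0] * 4, [0.0] * 4))
        ms.append(GeneMeasurement("dead_induced", "wt", [0.0] * 4, [1.0] * 4))
        scores = score_screen(ms)
        assert scores.dropped == ["dead_both"]
        row = scores.table.loc["dead_induced"]
        assert row.flagged
        assert row.lgr == scores.table.lgr.max()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="scoreable"):
            score_screen(_population(5, lgr_of=lambda i: 0.01 * i))


class TestCallHits:
    @staticmethod
    def _scores(n=100, seed=3):
        rng = np.random.default_rng(seed)
        lgrs = dict(enumerate(rng.normal(0, 0.1, n)))
        return score_screen(_population(n, lgr_of=lgrs.get))

    def test_alpha_bounds(self):
        scores = self._scores()
        for alpha in (0.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                call_hits(scores, alpha)

    def test_sign_splits_sl_from_ss(self):
        scores = self._scores()
        table = call_hits(scores, alpha=0.5)
        z = scores.table.z
        assert all(z[g] > 0 for g in table.genes("wt", "SL"))
        assert all(z[g] < 0 for g in table.genes("wt", "SS"))

    def test_ranked_by_ascending_p(self):
        table = call_hits(self._scores(), alpha=0.5)
        for key, recs in table.lists.items():
            ps = [r.p_value for r in recs]
            assert ps == sorted(ps)

    def test_shrinking_alpha_never_adds_a_hit(self):
        scores = self._scores()
        genes_10 = call_hits(scores, 0.10).all_genes()
        genes_05 = call_hits(scores, 0.05).all_genes()
        genes_01 = call_hits(scores, 0.01).all_genes()
        assert genes_01 <= genes_05 <= genes_10

    def test_tiny_alpha_empties_the_table(self):
        assert len(call_hits(self._scores(), 1e-300)) == 0

    def test_ties_broken_by_abs_z_then_gene_id(self):
        # two genes with identical |z| (hence identical p) on the SL side
        lgrs = {0: 0.5, 1: 0.5, 2: -0.5, 3: -0.5}
        ms = _population(40, lgr_of=lambda i: lgrs.get(i, (i % 7 - 3) * 0.01))
        table = call_hits(score_screen(ms), alpha=0.2)
        sl = table.genes("wt", "SL")
        assert sl[:2] == ["g0000", "g0001"]

    def test_fdr_flag_is_more_conservative(self):
        scores = self._scores()
        raw = call_hits(scores, 0.05).all_genes()
        corrected = call_hits(scores, 0.05, fdr=True).all_genes()
        assert corrected <= raw


class TestMergeHitTables:
    def test_disjoint_lists_add_up(self):
        t1 = HitTable({("wt", "SL"): [HitRecord("a", "wt", "SL", 1),
                                      HitRecord("b", "wt", "SL", 2)]})
        t2 = HitTable({("mut", "SS"): [HitRecord("c", "mut", "SS", 1),
                                       HitRecord("d", "mut", "SS", 2),
                                       HitRecord("e", "mut", "SS", 3)]})
        assert merge_hit_tables(t1, t2) == {"a", "b", "c", "d", "e"}

    def test_union_bounded_by_total_length(self):
        t1 = HitTable({("wt", "SL"): [HitRecord("a", "wt", "SL", 1)],
                       ("wt", "SS"): [HitRecord("a2", "wt", "SS", 1)]})
        t2 = HitTable({("mut", "SL"): [HitRecord("a", "mut", "SL", 1)]})
        merged = merge_hit_tables(t1, t2)
        assert len(merged) == 2 < len(t1) + len(t2)


class TestScreenModel:
    def test_planted_screen_recovered_with_correct_signs(self, small_screen):
        config, grids, strain_map, truth = small_screen
        results = ScreenModel(grids, strain_map, screen="wt").fit()
        sl = set(results.hit_table.genes("wt", "SL"))
        ss = set(results.hit_table.genes("wt", "SS"))
        assert len(sl & config.planted_sl) / len(config.planted_sl) >= 0.95
        assert len(ss & config.planted_ss) / len(config.planted_ss) >= 0.95
        assert not sl & config.planted_ss and not ss & config.planted_sl

    def test_scale_invariance_of_calls(self, small_screen):
        config, grids, strain_map, _ = small_screen
        res = ScreenModel(grids, strain_map, screen="wt").fit()
        scaled = [ColonyGrid(g.plate_id, g.condition, g.day, g.sizes * 17.0)
                  for g in grids]
        res_scaled = ScreenModel(scaled, strain_map, screen="wt").fit()
        assert res.hit_table.lists.keys() == res_scaled.hit_table.lists.keys()
        for key in res.hit_table.lists:
            assert res.hit_table.genes(*key) == res_scaled.hit_table.genes(*key)
        np.testing.assert_allclose(res.table.lgr, res_scaled.table.lgr, atol=1e-12)

    def test_summary_reports_counts(self, small_screen):
        _, grids, strain_map, _ = small_screen
        res = ScreenModel(grids, strain_map, screen="wt").fit()
        text = res.summary()
        assert "genes scored" in text and "400" in text
        assert "SL hits" in text
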