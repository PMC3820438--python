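import numpy as np
import pytest
from scipy.stats import spearmanr

from pi1bench import (
    ExpressionMatrix,
    group_summaries,
    t_statistics,
    s_statistics,
    delta_from_percentile,
    rescale_statistics,
)
from pi1bench.stats_core import GeneSummary, InvalidDesignError


class TestGroupSummaries:
    def test_hand_example(self, tiny_matrix):
        s = group_summaries(tiny_matrix)
        assert s.mean1[0] == 2 and s.mean2[0] == 4
        assert s.var1[0] == 1 and s.var2[0] == 1

    def test_constant_gene(self, tiny_matrix):
        s = group_summaries(tiny_matrix)
        assert s.mean1[1] == 5 and s.mean2[1] == 5
        assert s.var1[1] == 0 and s.var2[1] == 0

    def test_two_sample_groups(self):
        m = ExpressionMatrix(
            values=np.array([[0.0, 0.0, 1.0, 1.0]]),
            gene_ids=np.array(["g"]),
            group=np.array(["x", "x", "y", "y"]),
        )
        s = group_summaries(m)
        assert s.mean1[0] == 0 and s.mean2[0] == 1
        assert s.var1[0] == 0 and s.var2[0] == 0

    def test_single_sample_group_rejected(self):
        with pytest.raises(InvalidDesignError):
            ExpressionMatrix(
                values=np.zeros((1, 3)),
                gene_ids=np.array(["g"]),
                group=np.array(["a", "a", "b"]),
            )


class TestTStatistics:
    def test_hand_value(self, tiny_matrix):
        t = t_statistics(group_summaries(tiny_matrix), 3, 3)
        assert t.values[0] == pytest.approx(-2 / np.sqrt(2 / 3), rel=1e-12)
        assert t.family == "t" and t.delta == 0

    def test_equal_means_zero(self, tiny_matrix):
        t = t_statistics(group_summaries(tiny_matrix), 3, 3)
        assert t.values[1] != t.values[1] or t.values[1] == 0  # NaN or 0

    def test_zero_denominator_flagged(self):
        summ = GeneSummary(
            mean1=np.array([0.0]), mean2=np.array([1.0]),
            var1=np.array([0.0]), var2=np.array([0.0]),
        )
        with pytest.warns(RuntimeWarning):
            t = t_statistics(summ, 3, 3)
        assert np.isnan(t.values[0]) and t.n_flagged == 1


class TestDelta:
    def test_median(self):
        assert delta_from_percentile(np.arange(1.0, 6.0), 50) == 3.0

    def test_linear_interpolation(self):
        # rank 1 + 4*0.9 = 4.6 -> 4 + 0.6*(5-4)
        assert delta_from_percentile(np.arange(1.0, 6.0), 90) == pytest.approx(4.6)

    def test_constant(self):
        for pct in (10, 50, 99):
            assert delta_from_percentile(np.full(7, 2.5), pct) == 2.5

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(0)
        d = rng.gamma(2.0, 1.0, 100)
        pcts = np.linspace(1, 99, 25)
        vals = [delta_from_percentile(d, p) for p in pcts]
        assert np.all(np.diff(vals) >= 0)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            delta_from_percentile(np.array([]), 50)

    def test_nonfinite_excluded(self):
        d = np.array([1.0, 2.0, 3.0, np.nan])
        assert delta_from_percentile(d, 50) == 2.0


class TestSStatistics:
    def test_hand_value(self, tiny_matrix):
        summ = group_summaries(tiny_matrix)
        delta = np.sqrt(2 / 3)
        s = s_statistics(summ, 3, 3, delta)
        assert s.values[0] == pytest.approx(-2 / (2 * np.sqrt(2 / 3)), rel=1e-12)

    def test_delta_zero_equals_t(self, small_dataset):
        summ = group_summaries(small_dataset.data)
        t = t_statistics(summ, 8, 6)
        s = s_statistics(summ, 8, 6, 0.0)
        np.testing.assert_allclose(s.values, t.values, rtol=0, atol=0)

    def test_shrinks_magnitude_keeps_sign(self, small_dataset):
        summ = group_summaries(small_dataset.data)
        t = t_statistics(summ, 8, 6)
        s = s_statistics(summ, 8, 6, 0.5)
        ok = np.isfinite(t.values)
        assert np.all(np.abs(s.values[ok]) <= np.abs(t.values[ok]))
        nz = ok & (t.values != 0)
        assert np.all(np.sign(s.values[nz]) == np.sign(t.values[nz]))


class TestRescale:
    def test_sd_factor_two(self):
        from pi1bench import TestStatisticVector

        s = TestStatisticVector(values=np.array([-1.0, 0.0, 1.0]),
                                denominators=np.ones(3), family="s50", delta=0.1)
        t = TestStatisticVector(values=np.array([-2.0, 0.0, 2.0]),
                                denominators=np.ones(3), family="t")
        r = rescale_statistics(s, t, measure="SD")
        assert r.rescale_factor == pytest.approx(2.0)
        np.testing.assert_allclose(r.values, [-2, 0, 2])

    def test_identity(self, small_dataset):
        summ = group_summaries(small_dataset.data)
        t = t_statistics(summ, 8, 6)
        s = s_statistics(summ, 8, 6, 0.0, family="s50")
        for measure in ("SD", "IQR"):
            r = rescale_statistics(s, t, measure=measure)
            assert r.rescale_factor == pytest.approx(1.0)

    @pytest.mark.parametrize("measure", ["SD", "IQR"])
    def test_spread_matches_t_and_ranks_preserved(self, small_dataset, measure):
        summ = group_summaries(small_dataset.data)
        t = t_statistics(summ, 8, 6)
        s = s_statistics(summ, 8, 6, 0.4, family="s50")
        r = rescale_statistics(s, t, measure=measure)
        if measure == "SD":
            spread = np.std(r.values, ddof=1), np.std(t.values, ddof=1)
        else:
            spread = (np.subtract(*np.percentile(r.values, [75, 25])),
                      np.subtract(*np.percentile(t.values, [75, 25])))
        assert spread[0] == pytest.approx(spread[1], rel=1e-10)
        rho = spearmanr(s.values, r.values).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_zero_spread_error(self):
        from pi1bench import TestStatisticVector

        s = TestStatisticVector(values=np.zeros(5), denominators=np.ones(5),
                                family="s50", delta=0.1)
        t = TestStatisticVector(values=np.arange(5.0), denominators=np.ones(5),
                                family="t")
        with pytest.raises(ValueError):
            rescale_statistics(s, t, measure="SD")


def test_gene_order_equivariance(small_dataset):
    """Permuting gene order of the input permutes all outputs identically."""
    data = small_dataset.data
    rng = np.random.default_rng(3)
    perm = rng.permutation(data.n_genes)
    shuffled = ExpressionMatrix(
        values=data.values[perm], gene_ids=data.gene_ids[perm], group=data.group
    )
    t1 = t_statistics(group_summaries(data), 8, 6)
    t2 = t_statistics(group_summaries(shuffled), 8, 6)
    np.testing.assert_allclose(t2.values, t1.values[perm])
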