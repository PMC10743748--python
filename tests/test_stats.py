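"""Asymmetry statistics: pair differences, paired t, percentiles, summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from ppasym.grid import Cohort
from ppasym.stats import (
    cell_pair_differences,
    difference_matrix,
    hemisphere_summary,
    ks_normality,
    paired_t_test,
    pairwise_summary_table,
    percentile_range,
)

from conftest import make_eye, make_grid


def split_hemisphere_grid(inferior, superior):
    values = np.empty((8, 8))
    values[:4] = inferior
    values[4:] = superior
    return values


class TestCellPairDifferences:
    def test_constant_grid_is_symmetric(self):
        eye = make_eye(fill=50.0)
        diffs = cell_pair_differences(eye, "RNFL")
        assert len(diffs) == 32
        assert all(d == 0.0 for d in diffs.values())

    def test_hemisphere_offset_appears_in_every_pair(self):
        # inferior 46.33, superior 38.76 -> every difference +7.57
        eye = make_eye(values=split_hemisphere_grid(46.33, 38.76))
        diffs = cell_pair_differences(eye, "RNFL")
        assert np.allclose(list(diffs.values()), 46.33 - 38.76)

    def test_local_bump_stays_local(self):
        values = np.full((8, 8), 50.0)
        values[1, 2] += 10.0  # cell 2.3
        diffs = cell_pair_differences(make_eye(values=values), "RNFL")
        assert diffs[(2, 3)] == pytest.approx(10.0)
        assert all(d == 0.0 for a, d in diffs.items() if a != (2, 3))

    def test_missing_layer_named(self):
        with pytest.raises(KeyError, match="GCL"):
            cell_pair_differences(make_eye(layers=("RNFL",)), "GCL")


class TestPairedT:
    def test_zero_mean_difference(self):
        res = paired_t_test([1, -1, 1, -1])
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_frozen_example(self):
        # computed independently from t = mean/(sd/sqrt(n)) with df = 3
        res = paired_t_test([2, 4, 6, 8])
        assert res.t_statistic == pytest.approx(3.872983346207417, rel=1e-12)
        assert res.degrees_of_freedom == 3
        assert res.p_value == pytest.approx(0.030466291662170977, rel=1e-12)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 200))
            d = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 20), size=n)
            ours = paired_t_test(d)
            ref = sps.ttest_1samp(d, 0.0)
            assert ours.t_statistic == pytest.approx(ref.statistic, rel=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 2"):
            paired_t_test([1.0])
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test([3.0, 3.0, 3.0])
        assert paired_t_test([0.0, 0.0, 0.0]).p_value == 1.0

    def test_type_one_error_rate_under_null(self):
        # 300 paired null differences, 1000 replicates: rejection rate ~ alpha
        rng = np.random.default_rng(2024)
        rejections = sum(
            paired_t_test(rng.normal(0.0, 5.0, size=300)).p_value < 0.05
            for _ in range(1000)
        )
        # binomial 99% bounds around 0.05 for 1000 replicates
        assert 0.032 <= rejections / 1000 <= 0.068


class TestKSNormality:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(1).normal(10, 3, size=1000)
        stat, p = ks_normality(x)
        assert 0 <= stat <= 1 and p > 0.05

    def test_skewed_sample_fails(self):
        x = np.exp(np.random.default_rng(2).normal(0, 1, size=1000))
        _, p = ks_normality(x)
        assert p < 0.05

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality([1, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="at least 5"):
            ks_normality([1, 2, 3])


class TestPercentileRange:
    def test_rank_interpolation_closed_form(self):
        r = percentile_range(np.arange(1, 101))
        assert r.p2_5 == pytest.approx(3.475)
        assert r.p97_5 == pytest.approx(97.525)

    def test_constant_sample(self):
        r = percentile_range([7.0, 7.0, 7.0])
        assert r.p2_5 == r.p97_5 == 7.0

    def test_brackets_median_and_covers_95_percent(self):
        x = np.random.default_rng(3).normal(2, 5, size=20000)
        r = percentile_range(x)
        assert r.p2_5 <= np.median(x) <= r.p97_5
        coverage = np.mean((x >= r.p2_5) & (x <= r.p97_5))
        assert coverage == pytest.approx(0.95, abs=0.005)

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            percentile_range([1.0])


class TestHemisphereSummary:
    def test_pooled_mean_arithmetic(self):
        eyes = [
            make_eye("S1", values=split_hemisphere_grid(50.0, 40.0)),
            make_eye("S2", values=split_hemisphere_grid(50.0, 36.0)),
        ]
        inf, sup = hemisphere_summary(Cohort(eyes=eyes), "RNFL")
        assert sup.pooled_mean == pytest.approx(38.0)
        assert inf.pooled_mean == pytest.approx(50.0)
        assert sup.per_eye_means == (40.0, 36.0)

    def test_single_constant_eye_has_zero_sd(self):
        inf, sup = hemisphere_summary(Cohort(eyes=[make_eye()]), "RNFL")
        assert inf.pooled_sd == 0.0 and sup.pooled_sd == 0.0

    def test_pooled_mean_equals_mean_of_per_eye_means(self, reference_cohort):
        inf, sup = hemisphere_summary(reference_cohort, "GCL")
        for s in (inf, sup):
            assert s.pooled_mean == pytest.approx(np.mean(s.per_eye_means), rel=1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hemisphere_summary(Cohort(eyes=[]), "RNFL")


class TestPairwiseSummaryTable:
    def test_symmetric_cohort_all_null(self, symmetric_cohort):
        summaries = pairwise_summary_table(symmetric_cohort, "GCL")
        assert len(summaries) == 32
        assert all(s.mean_diff == 0.0 and not s.significant for s in summaries)
        assert all(s.superior_cell.row == 9 - s.inferior_cell.row for s in summaries)

    def test_fixed_offset_detected_everywhere(self):
        rng = np.random.default_rng(5)
        eyes = []
        for i in range(40):
            values = np.full((8, 8), 50.0) + rng.normal(0, 1.0, size=(8, 8))
            values[:4] += 5.0  # +5 um on every inferior cell
            eyes.append(make_eye(f"S{i}", values=values))
        summaries = pairwise_summary_table(Cohort(eyes=eyes), "RNFL")
        assert all(s.significant for s in summaries)
        assert np.mean([s.mean_diff for s in summaries]) == pytest.approx(5.0, abs=0.5)

    def test_sign_convention_flip(self, reference_cohort):
        # negating every grid's asymmetry negates mean/t and mirrors the range
        diffs = difference_matrix(reference_cohort, "RNFL")
        for j in (0, 17, 31):
            fwd = paired_t_test(diffs[:, j])
            rev = paired_t_test(-diffs[:, j])
            assert rev.mean_diff == pytest.approx(-fwd.mean_diff, rel=1e-12)
            assert rev.t_statistic == pytest.approx(-fwd.t_statistic, rel=1e-12)
            assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-12)
            r_fwd = percentile_range(diffs[:, j])
            r_rev = percentile_range(-diffs[:, j])
            assert r_rev.p2_5 == pytest.approx(-r_fwd.p97_5, rel=1e-12)
            assert r_rev.p97_5 == pytest.approx(-r_fwd.p2_5, rel=1e-12)

    @pytest.mark.parametrize("method", ["holm", "bh"])
    def test_multiplicity_adjustment_is_conservative(self, reference_cohort, method):
        raw = pairwise_summary_table(reference_cohort, "INL", adjust="none")
        adj = pairwise_summary_table(reference_cohort, "INL", adjust=method)
        n_raw = sum(s.significant for s in raw)
        n_adj = sum(s.significant for s in adj)
        assert n_adj <= n_raw

    def test_bad_alpha_rejected(self, symmetric_cohort):
        with pytest.raises(ValueError, match="alpha"):
            pairwise_summary_table(symmetric_cohort, "GCL", alpha=1.5)
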