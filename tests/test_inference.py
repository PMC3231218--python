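"""Sampling segments, the variance-ratio test and the ECDF discriminant."""

import numpy as np
import pytest
from scipy import integrate, special, stats

from holorec import (
    OpticalConfig,
    ComplexField,
    SamplingSegment,
    TargetMask,
    draw_segments,
    ecdf,
    ecdf_null_distribution,
    ecdf_statistic,
    ecdf_test,
    variance_ratio_test,
)
from holorec.inference import lambda_pairs_pooled


def _seg(values, channel="real"):
    return SamplingSegment(np.asarray(values, dtype=float), channel)


def _gauss_seg(rng, n, sd=1.0, mu=0.0, channel="real"):
    return _seg(rng.normal(mu, sd, n), channel)


# ---------------------------------------------------------------------------
# draw_segments
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def masked_field():
    cfg = OpticalConfig(nx=64, ny=64, pixel_pitch_x=9e-6, pixel_pitch_y=9e-6)
    rng = np.random.default_rng(5)
    field = ComplexField(
        rng.standard_normal(cfg.shape) + 1j * rng.standard_normal(cfg.shape), 0.0, cfg
    )
    mask = np.zeros(cfg.shape, bool)
    mask[10:40, 10:40] = True
    return field, TargetMask(mask)


class TestDrawSegments:
    def test_exhaustive_draw_is_permutation(self, masked_field):
        field, mask = masked_field
        seg = draw_segments(field, mask, mask.n_pixels, 1, "real", seed=0)[0]
        np.testing.assert_allclose(
            np.sort(seg.values), np.sort(field.values.real[mask.mask])
        )

    def test_shapes_for_standard_design(self, masked_field):
        field, mask = masked_field
        segs = draw_segments(field, mask, 200, 100, "imaginary", seed=1)
        assert len(segs) == 100
        assert all(s.n == 200 for s in segs)

    def test_reproducible_and_seed_sensitive(self, masked_field):
        field, mask = masked_field
        a = draw_segments(field, mask, 50, 3, "real", seed=9)
        b = draw_segments(field, mask, 50, 3, "real", seed=9)
        c = draw_segments(field, mask, 50, 3, "real", seed=10)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)
        assert not np.array_equal(a[0].values, c[0].values)

    def test_oversized_draw_raises(self, masked_field):
        field, mask = masked_field
        with pytest.raises(ValueError, match="masked pixels"):
            draw_segments(field, mask, mask.n_pixels + 1, 1, "real", seed=0)


# ---------------------------------------------------------------------------
# variance-ratio (F) test
# ---------------------------------------------------------------------------


def _f_cdf_by_quadrature(x, d1, d2):
    """F CDF via numeric integration of the density written from scratch."""

    def pdf(t):
        num = (d1 * t) ** d1 * d2**d2
        den = (d1 * t + d2) ** (d1 + d2)
        return np.sqrt(num / den) / (t * special.beta(d1 / 2, d2 / 2))

    val, _ = integrate.quad(pdf, 0, x, limit=200)
    return val


class TestVarianceRatioTest:
    def test_identical_segments_accept(self):
        rng = np.random.default_rng(0)
        seg = _gauss_seg(rng, 100)
        res = variance_ratio_test(seg, _seg(seg.values.copy()), alpha=0.2)
        assert res.statistic == 1.0
        assert res.accepted
        assert res.acceptance_interval[0] <= 1.0 <= res.acceptance_interval[1]

    def test_variance_ratio_four_rejected(self):
        rng = np.random.default_rng(42)
        ref = _gauss_seg(rng, 200, sd=2.0)
        inp = _gauss_seg(rng, 200, sd=1.0)
        res = variance_ratio_test(ref, inp, alpha=0.01)
        assert res.statistic == pytest.approx(4.0, rel=0.35)
        assert res.decision == "reject_H0"

    def test_analytic_p_matches_quadrature_oracle(self):
        rng = np.random.default_rng(3)
        ref = _gauss_seg(rng, 40, sd=1.4)
        inp = _gauss_seg(rng, 60, sd=1.0)
        res = variance_ratio_test(ref, inp, alpha=0.05)
        cdf = _f_cdf_by_quadrature(res.statistic, ref.n - 1, inp.n - 1)
        expected = 2 * min(cdf, 1 - cdf)
        assert res.p_value == pytest.approx(expected, abs=1e-8)

    def test_monte_carlo_agrees_with_analytic(self):
        rng = np.random.default_rng(8)
        ref = _gauss_seg(rng, 200, sd=1.1)
        inp = _gauss_seg(rng, 200, sd=1.0)
        a = variance_ratio_test(ref, inp, p_mode="analytic")
        b = variance_ratio_test(ref, inp, p_mode="monte_carlo", n_mc=10_000, seed=1)
        assert abs(a.p_value - b.p_value) <= 3 / np.sqrt(10_000)

    def test_degenerate_segment_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            variance_ratio_test(_seg([1.0, 1.0, 1.0]), _seg([1.0, 2.0, 3.0]))

    def test_channel_mismatch_raises(self):
        with pytest.raises(ValueError):
            variance_ratio_test(_seg([1.0, 2.0], "real"), _seg([1.0, 2.0], "imaginary"))

    def test_power_nondecreasing_in_variance_ratio(self):
        rng = np.random.default_rng(11)
        rates = []
        for ratio in (1.0, 2.0, 4.0):
            rejections = 0
            for _ in range(300):
                ref = _gauss_seg(rng, 200, sd=np.sqrt(ratio))
                inp = _gauss_seg(rng, 200, sd=1.0)
                rejections += not variance_ratio_test(ref, inp, alpha=0.01).accepted
            rates.append(rejections / 300)
        assert rates[0] <= rates[1] <= rates[2]


class TestNullCalibration:
    def test_type_i_error_at_nominal_level(self, null_f_results):
        """Two-tailed rejection rate at alpha=0.01 within the exact binomial
        99% interval around 1% over 10,000 equal-variance pairs."""
        rejections = sum(not r.accepted for r in null_f_results)
        n = len(null_f_results)
        lo = stats.binom.ppf(0.005, n, 0.01)
        hi = stats.binom.ppf(0.995, n, 0.01)
        assert lo <= rejections <= hi

    def test_confidence_interval_coverage(self, null_f_results):
        """The variance-ratio confidence interval covers the true ratio (1)
        at 1-alpha, within the binomial band."""
        covered = sum(
            r.ci_variance_ratio[0] < 1.0 < r.ci_variance_ratio[1] for r in null_f_results
        )
        n = len(null_f_results)
        lo = stats.binom.ppf(0.005, n, 0.99)
        hi = stats.binom.ppf(0.995, n, 0.99)
        assert lo <= covered <= hi

    def test_decision_equivalent_to_interval_membership(self, null_f_results):
        for r in null_f_results[:500]:
            inside = r.acceptance_interval[0] <= r.statistic <= r.acceptance_interval[1]
            assert r.accepted == inside


# ---------------------------------------------------------------------------
# ECDF machinery
# ---------------------------------------------------------------------------


class TestEcdf:
    def test_two_point_sample(self):
        np.testing.assert_allclose(
            ecdf([0.0, 1.0], [0.0, 1.0, 2.0, 3.0]), [0.5, 1.0, 1.0, 1.0]
        )

    def test_range_limits(self):
        vals = np.array([2.0, 3.0, 5.0])
        assert ecdf(vals, [1.0])[0] == 0.0
        assert ecdf(vals, [6.0])[0] == 1.0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=37)
        grid = np.sort(rng.normal(size=11))
        got = ecdf(vals, grid)
        want = [np.sum(vals <= u) / vals.size for u in grid]
        np.testing.assert_allclose(got, want)

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            ecdf([], [0.0])
        with pytest.raises(ValueError):
            ecdf([1.0], [])
        with pytest.raises(ValueError):
            ecdf([1.0], [2.0, 1.0])


class TestEcdfStatistic:
    def test_identical_segments_zero(self):
        seg = _seg([0.3, 1.2, -0.5])
        assert ecdf_statistic(seg, _seg(seg.values.copy())) == 0.0

    def test_hand_computed_example(self):
        # ECDFs {0.5,1,1,1} vs {0,0,0.5,1} on pooled grid {0,1,2,3}
        assert ecdf_statistic(_seg([0.0, 1.0]), _seg([2.0, 3.0])) == pytest.approx(0.375)

    def test_bounded_and_symmetric_over_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            a = _gauss_seg(rng, int(rng.integers(2, 30)), sd=rng.uniform(0.5, 2))
            b = _gauss_seg(rng, int(rng.integers(2, 30)), mu=rng.uniform(-1, 1))
            lam = ecdf_statistic(a, b)
            assert 0.0 <= lam <= 1.0
            assert lam == pytest.approx(ecdf_statistic(b, a), abs=1e-15)

    def test_batch_helper_matches_reference_implementation(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=(50, 40))
        b = rng.normal(size=(50, 40))
        batch = lambda_pairs_pooled(a, b)
        loop = [ecdf_statistic(_seg(x), _seg(y)) for x, y in zip(a, b)]
        np.testing.assert_allclose(batch, loop, atol=1e-12)


class TestEcdfTest:
    def test_input_identical_to_pivot(self):
        rng = np.random.default_rng(0)
        refs = [_gauss_seg(rng, 50) for _ in range(21)]
        inp = _seg(refs[0].values.copy())
        res = ecdf_test(refs, inp, alpha=0.05)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert np.all(res.null_statistics >= 0.0)

    def test_extreme_separation_rejected(self):
        rng = np.random.default_rng(4)
        refs = [_gauss_seg(rng, 200) for _ in range(399)]
        inp = _gauss_seg(rng, 200, mu=5.0)  # 5 pooled standard deviations away
        res = ecdf_test(refs, inp, alpha=0.01)
        assert res.decision == "reject_H0"

    def test_too_few_references_raise(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            ecdf_test([_gauss_seg(rng, 20)], _gauss_seg(rng, 20), alpha=0.05)

    def test_null_calibration_rejection_rate(self):
        """With exchangeable reference and input segments the add-one
        p-value is superuniform: over 1000 replicates with fresh
        999-value nulls, the rejection rate at alpha=0.01 sits inside the
        99% binomial band around 1%."""
        rng = np.random.default_rng(31)
        n, k_null, reps = 50, 999, 1000
        rejections = 0
        p_values = []
        for _ in range(reps):
            null = lambda_pairs_pooled(
                rng.standard_normal((k_null, n)), rng.standard_normal((k_null, n))
            )
            pivot = _gauss_seg(rng, n)
            inp = _gauss_seg(rng, n)
            res = ecdf_test([pivot], inp, alpha=0.01, null_statistics=null)
            p_values.append(res.p_value)
            rejections += res.decision == "reject_H0"
        assert min(p_values) >= 1 / (1 + k_null)
        assert max(p_values) <= 1.0
        lo = stats.binom.ppf(0.005, reps, 0.01)
        hi = stats.binom.ppf(0.995, reps, 0.01)
        assert lo <= rejections <= hi

    def test_p_value_lower_bound(self):
        rng = np.random.default_rng(12)
        refs = [_gauss_seg(rng, 30) for _ in range(41)]
        res = ecdf_test(refs, _gauss_seg(rng, 30, mu=10.0), alpha=0.05)
        assert res.p_value >= 1 / (1 + res.null_statistics.size)
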