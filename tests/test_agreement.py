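import numpy as np
import pandas as pd
import pytest

from oracles import icc_a1_pingouin

from gaitvar.agreement import (
    PairedSample,
    agreement_battery,
    bland_altman,
    cv_rms,
    icc_absolute,
    icc_category,
    pearson,
    scale_correlations,
)


class TestIcc:
    def test_matches_library_route_on_random_fixtures(self, rng):
        """ICC(A,1) from the ANOVA mean squares vs pingouin's ICC2."""
        for _ in range(10):
            n = int(rng.integers(5, 40))
            subj = rng.normal(0, 2, n)
            a = subj + rng.normal(0, 1, n)
            b = subj + rng.normal(0.3, 1, n)
            icc, ci = icc_absolute(PairedSample(a, b))
            ref_icc, ref_ci = icc_a1_pingouin(a, b)
            assert icc == pytest.approx(ref_icc, abs=1e-10)
            assert ci[0] == pytest.approx(ref_ci[0], abs=0.005)
            assert ci[1] == pytest.approx(ref_ci[1], abs=0.005)

    def test_duplicated_data_gives_one(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        icc, ci = icc_absolute(PairedSample(a, a.copy()))
        assert icc == 1.0 and ci == (1.0, 1.0)

    def test_independent_noise_near_zero(self, rng):
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        icc, _ = icc_absolute(PairedSample(a, b))
        assert abs(icc) < 0.1

    def test_zero_variance_signalled(self):
        with pytest.warns(UserWarning):
            icc, _ = icc_absolute(PairedSample(np.ones(5), np.ones(5)))
        assert np.isnan(icc)

    def test_consistency_variant_ignores_offset(self, rng):
        subj = rng.normal(0, 2, 30)
        p = PairedSample(subj, subj + 5.0)
        icc_a, _ = icc_absolute(p)
        icc_c, _ = icc_absolute(p, variant="C1")
        assert icc_c == pytest.approx(1.0, abs=1e-12)
        assert icc_a < 0.9  # the constant offset penalises absolute agreement


@pytest.mark.parametrize(
    "value,expected",
    [(0.39, "poor"), (0.40, "fair"), (0.59, "fair"), (0.60, "good"),
     (0.74, "good"), (0.75, "excellent"), (0.95, "excellent"), (-0.2, "poor")],
)
def test_icc_category_thresholds(value, expected):
    assert icc_category(value) == expected


class TestBlandAltman:
    def test_identical_methods(self):
        a = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(PairedSample(a, a.copy()))
        assert ba.bias == 0.0 and (ba.loa_low, ba.loa_high) == (0.0, 0.0)
        np.testing.assert_array_equal(ba.diffs, 0.0)

    def test_loa_closed_form(self):
        ba = bland_altman(PairedSample(np.array([1.0, -1.0]), np.array([0.0, 0.0])))
        assert ba.bias == 0.0
        assert ba.loa_high == pytest.approx(1.96 * np.sqrt(2.0))
        assert ba.loa_low == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_bias_sign_is_a_minus_b(self):
        ba = bland_altman(PairedSample(np.array([2.0, 3.0]), np.array([1.0, 2.0])))
        assert ba.bias == pytest.approx(1.0)

    def test_loa_contains_bias(self, rng):
        p = PairedSample(rng.normal(size=50), rng.normal(size=50))
        ba = bland_altman(p)
        assert ba.loa_low <= ba.bias <= ba.loa_high
        width = ba.loa_high - ba.loa_low
        assert width == pytest.approx(2 * 1.96 * np.std(p.a - p.b, ddof=1))


class TestPearson:
    def test_perfect_correlations(self):
        a = np.array([1.0, 2.0, 4.0])
        assert pearson(PairedSample(a, a))[0] == pytest.approx(1.0)
        assert pearson(PairedSample(a, -a))[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=40)
        r, r2 = pearson(PairedSample(a, b))
        expect = np.cov(a, b, ddof=1)[0, 1] / (np.std(a, ddof=1) * np.std(b, ddof=1))
        assert r == pytest.approx(expect, abs=1e-12)
        assert r2 == pytest.approx(r * r)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            pearson(PairedSample(np.ones(5), np.arange(5.0)))


class TestCvRms:
    def test_identical_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cv_rms(PairedSample(a, a.copy())) == 0.0

    def test_known_cvs(self):
        # pair means of exactly 100 with per-subject CVs of 3% and 4%
        # → √((9+16)/2) ≈ 3.54%
        half = np.array([3.0, 4.0]) * np.sqrt(2.0) / 2.0
        p = PairedSample(100.0 + half, 100.0 - half)
        assert cv_rms(p) == pytest.approx(np.sqrt((9.0 + 16.0) / 2.0))

    def test_scale_invariance(self, rng):
        a = rng.uniform(10, 20, 30)
        b = rng.uniform(10, 20, 30)
        assert cv_rms(PairedSample(a, b)) == pytest.approx(
            cv_rms(PairedSample(10 * a, 10 * b)), rel=1e-12
        )

    def test_zero_mean_pair_excluded(self):
        with pytest.warns(UserWarning):
            out = cv_rms(PairedSample(np.array([1.0, 1.0]), np.array([-1.0, 1.0])))
        assert out == 0.0


class TestScaleCorrelations:
    def test_entropy_equal_to_reference(self, rng):
        ref = rng.normal(size=10)
        mat = np.tile(ref[:, None], (1, 5))
        out = scale_correlations(mat, ref)
        np.testing.assert_allclose(out["r"], 1.0)

    def test_single_scale_consistent_with_pearson(self, rng):
        ref = rng.normal(size=12)
        col = rng.normal(size=12)
        out = scale_correlations(col[:, None], ref)
        assert out["r"][0] == pytest.approx(pearson(PairedSample(col, ref))[0])

    def test_shuffled_subjects_near_zero(self, rng):
        ref = rng.normal(size=500)
        mat = rng.normal(size=(500, 3))
        out = scale_correlations(mat, ref)
        assert np.all(np.abs(out["r"]) < 0.15)

    def test_nan_scales_excluded_pairwise(self, rng):
        ref = rng.normal(size=8)
        mat = np.tile(ref[:, None], (1, 2))
        mat[0, 1] = np.nan
        out = scale_correlations(pd.DataFrame(mat, columns=[1, 2]), ref)
        np.testing.assert_allclose(out["r"], 1.0)


def test_battery_is_subject_order_invariant(rng):
    a, b = rng.normal(size=25), rng.normal(size=25)
    perm = rng.permutation(25)
    r1 = agreement_battery(PairedSample(a, b))
    r2 = agreement_battery(PairedSample(a[perm], b[perm]))
    assert r1.icc == pytest.approx(r2.icc, abs=1e-12)
    assert r1.bias == pytest.approx(r2.bias, abs=1e-12)
    assert r1.cv_rms_pct == pytest.approx(r2.cv_rms_pct, abs=1e-10)
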