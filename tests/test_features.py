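"""Time-series features: hand-computed cases, brute-force oracle agreement,
and invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tinnidyn.diary import QUESTION_CODES
from tinnidyn.features import (
    FEATURE_NAMES,
    TrendDecomposition,
    crossing_points,
    decompose_trend,
    extract_all,
    flat_spots,
    hurst,
    lumpiness,
    nonlinearity,
    spectral_entropy,
    stability,
    trend_linearity_curvature,
    trend_strength,
)

import _oracles as oracle
from conftest import make_diary

series_strategy = st.lists(
    st.floats(min_value=0.0, max_value=100.0, allow_nan=False, width=32),
    min_size=20,
    max_size=30,
).filter(lambda xs: max(xs) > min(xs))


class TestCrossingPoints:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([5, 5, 5, 5], 0),
            ([1, 2, 1, 2, 1], 4),
            ([1, 2, 3, 4, 5], 1),
        ],
    )
    def test_hand_cases(self, x, expected):
        assert crossing_points(x) == expected

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            crossing_points([1.0])

    @given(
        st.lists(
            st.integers(min_value=0, max_value=100), min_size=5, max_size=30
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, xs):
        # integer values keep median comparisons exact under the transform
        x = np.array(xs, dtype=float)
        assert crossing_points(x) == crossing_points(2.0 * x + 7.0)


class TestFlatSpots:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([3.0] * 30, 30),
            ([0, 1] * 5, 1),
            (list(range(1, 101)), 10),
        ],
    )
    def test_hand_cases(self, x, expected):
        assert flat_spots(x) == expected

    @given(
        st.lists(
            st.integers(min_value=0, max_value=100), min_size=20, max_size=30
        ).filter(lambda xs: max(xs) > min(xs))
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, xs):
        # integer-valued series keep bin boundaries exact under the transform
        x = np.array(xs, dtype=float)
        assert flat_spots(x) == flat_spots(2.0 * x + 7.0)


class TestSpectralEntropy:
    def test_noise_is_unforecastable(self):
        rng = np.random.default_rng(42)
        assert spectral_entropy(rng.normal(0, 1, 500)) >= 0.90

    def test_sinusoid_is_concentrated(self):
        t = np.arange(500)
        assert spectral_entropy(np.sin(2 * np.pi * t / 25)) <= 0.35

    def test_bounds_and_constant_error(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            v = spectral_entropy(rng.uniform(0, 100, 40))
            assert 0.0 <= v <= 1.0
        with pytest.raises(ValueError):
            spectral_entropy(np.full(40, 7.0))


class TestHurst:
    def test_iid_noise_near_half(self):
        rng = np.random.default_rng(7)
        vals = [hurst(rng.normal(0, 1, 500)) for _ in range(30)]
        assert abs(np.mean(vals) - 0.5) <= 0.1

    def test_random_walk_strong_memory(self):
        rng = np.random.default_rng(8)
        assert hurst(np.cumsum(rng.normal(0, 1, 500))) >= 0.9

    def test_clamped_to_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            assert 0.0 <= hurst(rng.normal(0, 1, 50)) <= 1.0

    def test_rs_flag_cross_check(self):
        # both estimators call a random walk persistent and noise not
        rng = np.random.default_rng(10)
        rw = np.cumsum(rng.normal(0, 1, 400))
        assert hurst(rw, method="rs") > 0.8
        assert abs(hurst(rng.normal(0, 1, 400), method="rs") - 0.55) < 0.25


class TestWindowFeatures:
    def test_constant_series_zero(self):
        assert lumpiness(np.full(30, 4.0)) == 0.0
        assert stability(np.full(30, 4.0)) == 0.0

    def test_mean_shift_has_stability_not_lumpiness(self):
        x = np.array([0.0] * 10 + [2.0] * 10)
        assert lumpiness(x, standardize=False) == 0.0
        assert stability(x, standardize=False) == pytest.approx(2.0)

    def test_variance_shift_hand_case(self):
        x = np.array([0.0] * 10 + [0.0, 2.0] * 5)
        s2 = np.var([0.0, 2.0] * 5, ddof=1)
        expected = (s2 - 0.0) ** 2 / 2  # sample variance of {0, s2}
        assert lumpiness(x, standardize=False) == pytest.approx(expected)

    def test_short_series_yields_nan(self):
        assert np.isnan(lumpiness(np.arange(19.0)))

    def test_stability_invariant_to_within_window_permutation(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 100, 40)
        xp = x.copy()
        for w in range(4):
            xp[w * 10 : (w + 1) * 10] = rng.permutation(xp[w * 10 : (w + 1) * 10])
        assert stability(x) == pytest.approx(stability(xp), abs=1e-12)


class TestTrendDecomposition:
    def test_linear_series_reproduced(self):
        x = 3.0 * np.arange(84) + 5.0
        d = decompose_trend(x)
        assert np.max(np.abs(d.remainder)) <= 1e-8 * np.ptp(x)
        assert trend_strength(d) == 1.0

    def test_reconstruction_exact(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 100, 60)
        d = decompose_trend(x)
        np.testing.assert_allclose(d.trend + d.remainder, x, rtol=0, atol=1e-12)

    def test_noisy_line_trend_dominates(self):
        rng = np.random.default_rng(13)
        x = np.arange(84.0) + rng.normal(0, 1, 84)
        d = decompose_trend(x)
        assert d.var_trend > 10 * d.var_remainder

    def test_trend_strength_limits(self):
        half = trend_strength(
            TrendDecomposition(
                trend=np.array([0.0, 1.0, 0.0, 1.0]),
                remainder=np.array([1.0, 0.0, 1.0, 0.0]),
            )
        )
        assert half == pytest.approx(0.5)
        # trend fixed at the series mean: all variation is remainder
        x = np.array([1.0, 5.0, 2.0, 4.0, 3.0])
        mean_trend = TrendDecomposition(
            trend=np.full(5, x.mean()), remainder=x - x.mean()
        )
        assert trend_strength(mean_trend) == 0.0
        constant = TrendDecomposition(trend=np.full(5, 3.0), remainder=np.zeros(5))
        assert trend_strength(constant) == 0.0


class TestLinearityCurvature:
    def test_increasing_line(self):
        d = decompose_trend(2.0 * np.arange(30) + 1.0)
        lin, curv = trend_linearity_curvature(d)
        assert lin > 0
        assert abs(curv) <= 1e-8 * np.ptp(d.trend)

    def test_parity_under_time_reversal(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 100, 50)
        lin, curv = trend_linearity_curvature(decompose_trend(x))
        lin_r, curv_r = trend_linearity_curvature(decompose_trend(x[::-1]))
        assert lin_r == pytest.approx(-lin, abs=1e-8)
        assert curv_r == pytest.approx(curv, abs=1e-8)

    def test_symmetric_convex_curvature(self):
        n = 40
        i = np.arange(n, dtype=float)
        x = (i - (n - 1) / 2) ** 2  # symmetric about the index midpoint
        d = decompose_trend(x)
        lin, curv = trend_linearity_curvature(d)
        assert curv > 0
        assert abs(lin) < 0.05 * abs(curv)


class TestNonlinearity:
    def test_linear_ar1_null(self):
        rng = np.random.default_rng(15)
        stats = []
        for _ in range(100):
            e = rng.normal(0, 1, 501)
            x = np.empty(500)
            x[0] = e[0]
            for t in range(1, 500):
                x[t] = 0.5 * x[t - 1] + e[t]
            stats.append(nonlinearity(x))
        assert np.median(stats) <= 0.5

    def test_power_against_nonlinear_ar(self):
        # a sine autoregression has a genuinely nonlinear conditional mean
        rng = np.random.default_rng(16)
        null_stats, alt_stats = [], []
        for _ in range(40):
            e = rng.normal(0, 1, 500)
            z = np.empty(500)
            x = np.empty(500)
            z[0] = x[0] = e[0]
            for t in range(1, 500):
                z[t] = 0.5 * z[t - 1] + e[t]
                x[t] = 1.5 * np.sin(x[t - 1]) + e[t]
            null_stats.append(nonlinearity(z))
            alt_stats.append(nonlinearity(x))
        crit = np.quantile(null_stats, 0.95)
        assert np.median(alt_stats) > crit

    @given(series_strategy)
    @settings(max_examples=30, deadline=None)
    def test_nonnegative(self, xs):
        assert nonlinearity(np.array(xs)) >= 0.0


@pytest.fixture(scope="module")
def short_series():
    rng = np.random.default_rng(99)
    out = [rng.uniform(0, 100, n) for n in (20, 24, 27, 30) for _ in range(3)]
    out.append(np.round(rng.uniform(0, 10, 30)))  # ties
    return out


class TestOracleAgreement:
    """Every feature agrees with a literal brute-force transcription of its
    definition on short series (tolerance 1e-10)."""

    def test_crossing_points(self, short_series):
        for x in short_series:
            assert crossing_points(x) == oracle.oracle_crossing_points(x)

    def test_flat_spots(self, short_series):
        for x in short_series:
            assert flat_spots(x) == oracle.oracle_flat_spots(x)

    def test_spectral_entropy(self, short_series):
        for x in short_series:
            assert spectral_entropy(x) == pytest.approx(
                oracle.oracle_spectral_entropy(x), abs=1e-10
            )

    def test_lumpiness_stability(self, short_series):
        for x in short_series:
            assert lumpiness(x) == pytest.approx(
                oracle.oracle_lumpiness(x), abs=1e-10
            )
            assert stability(x) == pytest.approx(
                oracle.oracle_stability(x), abs=1e-10
            )

    def test_trend_strength(self, short_series):
        for x in short_series:
            d = decompose_trend(x)
            assert trend_strength(d) == pytest.approx(
                oracle.oracle_trend_strength(d.trend, d.remainder), abs=1e-10
            )

    def test_linearity_curvature(self, short_series):
        for x in short_series:
            d = decompose_trend(x)
            lin, curv = trend_linearity_curvature(d)
            olin, ocurv = oracle.oracle_linearity_curvature(d.trend)
            assert lin == pytest.approx(olin, abs=1e-10)
            assert curv == pytest.approx(ocurv, abs=1e-10)

    def test_hurst(self, short_series):
        for x in short_series:
            assert hurst(x) == pytest.approx(oracle.oracle_hurst(x), abs=1e-6)

    def test_nonlinearity(self, short_series):
        for x in short_series:
            assert nonlinearity(x) == pytest.approx(
                oracle.oracle_nonlinearity(x), abs=1e-10
            )


class TestExtractAll:
    def test_complete_diary_100_finite_values(self):
        p = make_diary()
        feats = extract_all(p)
        assert len(feats) == 100
        assert all(np.isfinite(v) for v in feats.values())
        assert set(feats) == {
            f"{q}_{f}" for q in QUESTION_CODES for f in FEATURE_NAMES
        }

    def test_42_day_diary_complete(self):
        p = make_diary(days=range(0, 84, 2))
        feats = extract_all(p)
        assert all(np.isfinite(v) for v in feats.values())

    def test_15_day_diary_gets_sentinels(self):
        p = make_diary(days=range(15))
        feats = extract_all(p)
        for q in QUESTION_CODES:
            for f in ("lumpiness", "stability", "hurst", "nonlinearity"):
                assert np.isnan(feats[f"{q}_{f}"])
            assert np.isfinite(feats[f"{q}_crossing-points"])
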