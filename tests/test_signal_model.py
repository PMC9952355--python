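"""Decay physics, Rician sampling and moments, noise/SNR estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special

from r2cascade import (
    EchoTimes,
    MultiEchoSeries,
    NoiseSpec,
    ParameterMaps,
    add_rician_noise,
    compute_snr,
    estimate_sigma_background,
    rician_first_moment,
    rician_second_moment,
    synthesize_decay,
)
from r2cascade.phantom import make_te_schedule


def rice_moment_quadrature(s, sigma):
    """Independent oracle: direct numerical integration of the Rice density."""
    f = lambda m: m * (m / sigma**2) * np.exp(
        -((m - s) ** 2) / (2 * sigma**2)
    ) * special.ive(0, m * s / sigma**2)
    return integrate.quad(f, 0.0, s + 12 * sigma, limit=200)[0]


class TestSynthesizeDecay:
    def test_zero_decay_identity(self, te12):
        maps = ParameterMaps(np.full((2, 3), 100.0), np.zeros((2, 3)))
        out = synthesize_decay(maps, te12)
        assert np.allclose(out.data, 100.0)

    def test_direct_evaluation(self):
        te = EchoTimes(np.array([0.93, 2.27]))
        maps = ParameterMaps(np.array([[100.0]]), np.array([[500.0]]))
        out = synthesize_decay(maps, te)
        assert out.data[0, 0, 0] == pytest.approx(100 * np.exp(-0.465), rel=1e-12)
        assert out.data[0, 0, 0] == pytest.approx(62.81, abs=0.01)

    def test_echo_ratio_matches_model(self, te12, rng):
        r2 = rng.uniform(45, 956, (4, 4))
        maps = ParameterMaps(np.full((4, 4), 216.6), r2)
        out = synthesize_decay(maps, te12).data
        dte = np.diff(te12.te_s)
        ratio = out[:, :, 1:] / out[:, :, :-1]
        expected = np.exp(-dte[None, None, :] * r2[:, :, None])
        assert np.allclose(ratio, expected, rtol=1e-12)

    def test_schedule_endpoint(self):
        te = make_te_schedule(0.93, 1.34, 12)
        assert te.te_ms[0] == pytest.approx(0.93)
        assert te.te_ms[-1] == pytest.approx(15.67)
        assert len(te) == 12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ParameterMaps(np.ones((2, 2)), np.ones((3, 2)))


class TestRicianNoise:
    def test_zero_sigma_is_identity(self, te12, small_dataset):
        out = add_rician_noise(small_dataset.clean, NoiseSpec(0.0, seed=3))
        assert np.array_equal(out.data, small_dataset.clean.data)

    def test_deterministic_given_seed(self, te12):
        maps = ParameterMaps(np.full((8, 8), 100.0), np.full((8, 8), 300.0))
        clean = synthesize_decay(maps, te12)
        a = add_rician_noise(clean, NoiseSpec(5.0, seed=42))
        b = add_rician_noise(clean, NoiseSpec(5.0, seed=42))
        c = add_rician_noise(clean, NoiseSpec(5.0, seed=43))
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_rayleigh_mean_at_zero_signal(self):
        te = EchoTimes(np.array([1.0, 2.0]))
        n = 1_000_000
        series = MultiEchoSeries(np.zeros((n // 2, 1, 2)), te)
        noisy = add_rician_noise(series, NoiseSpec(5.0, seed=0))
        expected = 5.0 * np.sqrt(np.pi / 2)
        se = 5.0 * np.sqrt((2 - np.pi / 2) / n)
        assert abs(noisy.data.mean() - expected) < 4 * se

    @pytest.mark.parametrize("s", [0.0, 20.0, 100.0])
    def test_first_two_moments_match_theory(self, s):
        te = EchoTimes(np.array([1.0, 2.0]))
        sigma, n = 5.0, 200_000
        series = MultiEchoSeries(np.full((n // 2, 1, 2), s), te)
        draws = add_rician_noise(series, NoiseSpec(sigma, seed=9)).data
        m1, m2 = rician_first_moment(s, sigma), rician_second_moment(s, sigma)
        var = m2 - m1**2
        assert abs(draws.mean() - m1) < 4 * np.sqrt(var / n)
        se2 = np.sqrt((draws**2).var() / n)
        assert abs((draws**2).mean() - m2) < 4 * se2


class TestRicianFirstMoment:
    def test_rayleigh_limit(self):
        assert rician_first_moment(0.0, 3.0) == pytest.approx(
            3.0 * np.sqrt(np.pi / 2), rel=1e-12
        )

    @pytest.mark.parametrize(
        "s,sigma", [(1.0, 1.0), (0.5, 3.0), (5.0, 2.0), (30.0, 1.0), (7.0, 7.0)]
    )
    def test_matches_quadrature(self, s, sigma):
        assert rician_first_moment(s, sigma) == pytest.approx(
            rice_moment_quadrature(s, sigma), abs=1e-6
        )

    def test_high_snr_asymptote(self):
        s, sigma = 50.0, 1.0
        assert rician_first_moment(s, sigma) == pytest.approx(
            np.sqrt(s**2 + sigma**2), rel=1e-3
        )

    def test_stable_at_extreme_snr(self):
        v = rician_first_moment(1000.0, 1.0)
        assert np.isfinite(v) and v == pytest.approx(1000.0005, abs=1e-3)

    @given(
        s=st.floats(0, 50), ds=st.floats(0.01, 5), sigma=st.floats(0.1, 10),
        dsig=st.floats(0.01, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_both_arguments(self, s, ds, sigma, dsig):
        base = rician_first_moment(s, sigma)
        assert rician_first_moment(s + ds, sigma) > base
        assert rician_first_moment(s, sigma + dsig) > base

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            rician_first_moment(-1.0, 1.0)


class TestSigmaEstimation:
    def test_point_eight_factor(self, te12):
        data = np.full((4, 4, 12), 10.0)
        series = MultiEchoSeries(data, te12)
        mask = np.ones((4, 4), dtype=bool)
        assert estimate_sigma_background(series, mask) == pytest.approx(8.0)

    def test_recovers_sigma_on_pure_noise(self, te12):
        sigma = 7.0
        zero = MultiEchoSeries(np.zeros((64, 128, 12)), te12)
        noisy = add_rician_noise(zero, NoiseSpec(sigma, seed=5))
        est = estimate_sigma_background(noisy, np.ones((64, 128), dtype=bool))
        assert est == pytest.approx(sigma, rel=0.02)
        exact = estimate_sigma_background(
            noisy, np.ones((64, 128), dtype=bool), factor=np.sqrt(2 / np.pi)
        )
        assert exact == pytest.approx(sigma, rel=0.01)

    def test_empty_mask_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            estimate_sigma_background(
                small_dataset.noisy, np.zeros((64, 128), dtype=bool)
            )


class TestSnr:
    def test_direct_ratio(self, te12):
        series = MultiEchoSeries(np.full((2, 2, 12), 100.0), te12)
        assert compute_snr(series, np.ones((2, 2), bool), 10.0) == pytest.approx(10.0)

    def test_clinical_ladder_value(self, te12):
        series = MultiEchoSeries(np.full((2, 2, 12), 216.65), te12)
        snr = compute_snr(series, np.ones((2, 2), bool), 7.0)
        assert snr == pytest.approx(30.95, abs=0.01)

    def test_zero_sigma_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            compute_snr(small_dataset.noisy, small_dataset.masks["liver"], 0.0)
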