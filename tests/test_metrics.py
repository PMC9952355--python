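"""Map-quality metrics and paired statistics against brute-force oracles."""

import itertools

import numpy as np
import pytest

from r2cascade.metrics import (
    bland_altman,
    nrmse,
    roi_mean_r2star,
    ssim_global,
    ssim_windowed,
    wilcoxon_signed_rank,
)
from r2cascade.signal_model import ParameterMaps


def nrmse_bruteforce(ref, est, region):
    num = den = 0.0
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            if region[i, j]:
                num += (ref[i, j] - est[i, j]) ** 2
                den += ref[i, j] ** 2
    return (num / den) ** 0.5


def ssim_bruteforce(ref, est, region, k1=0.01, k2=0.03):
    x = [ref[i, j] for i in range(ref.shape[0]) for j in range(ref.shape[1]) if region[i, j]]
    y = [est[i, j] for i in range(est.shape[0]) for j in range(est.shape[1]) if region[i, j]]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    vx = sum((v - mx) ** 2 for v in x) / n
    vy = sum((v - my) ** 2 for v in y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    L = max(x) - min(x)
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    return ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )


class TestNrmse:
    def test_zero_for_identical_maps(self, rng):
        ref = rng.uniform(45, 956, (8, 8))
        assert nrmse(ref, ref) == 0.0

    def test_scaling_identity(self, rng):
        ref = rng.uniform(45, 956, (8, 8))
        assert nrmse(ref, 1.1 * ref) == pytest.approx(0.10, abs=1e-12)

    def test_hand_computed_example(self):
        ref = np.array([[3.0, 4.0]])
        est = np.zeros((1, 2))
        assert nrmse(ref, est) == pytest.approx(1.0)

    def test_matches_bruteforce(self, rng):
        ref = rng.uniform(10, 900, (16, 16))
        est = ref + rng.normal(0, 40, (16, 16))
        region = rng.random((16, 16)) > 0.3
        assert nrmse(ref, est, region) == pytest.approx(
            nrmse_bruteforce(ref, est, region), abs=1e-12
        )

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.zeros((2, 2)), np.ones((2, 2)))


class TestSsim:
    def test_identity_gives_one(self, rng):
        ref = rng.uniform(45, 956, (8, 8))
        assert ssim_global(ref, ref) == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce(self, rng):
        ref = rng.uniform(10, 900, (16, 16))
        est = ref + rng.normal(0, 60, (16, 16))
        region = rng.random((16, 16)) > 0.3
        assert ssim_global(ref, est, region) == pytest.approx(
            ssim_bruteforce(ref, est, region), abs=1e-12
        )

    def test_anticorrelated_hand_example(self):
        ref = np.array([[1.0, 2.0], [3.0, 4.0]])
        est = -ref + 5.0  # matched variance, anti-correlated
        expected = ssim_bruteforce(ref, est, np.ones((2, 2), bool))
        got = ssim_global(ref, est)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got < 1.0

    def test_never_exceeds_one(self, rng):
        for _ in range(50):
            ref = rng.uniform(0, 100, (6, 6))
            est = rng.uniform(0, 100, (6, 6))
            assert ssim_global(ref, est) <= 1.0 + 1e-12

    def test_windowed_variant_agrees_on_identity(self, rng):
        ref = rng.uniform(45, 956, (32, 32))
        assert ssim_windowed(ref, ref) == pytest.approx(1.0, abs=1e-9)


class TestRoiMean:
    def test_constant_map(self):
        maps = ParameterMaps(np.ones((3, 3)), np.full((3, 3), 123.0))
        assert roi_mean_r2star(maps, np.ones((3, 3), bool)) == pytest.approx(123.0)

    def test_two_pixel_mask(self):
        r2 = np.zeros((2, 2))
        r2[0, 0], r2[0, 1] = 100.0, 300.0
        maps = ParameterMaps(np.ones((2, 2)), r2)
        mask = np.zeros((2, 2), bool)
        mask[0, :] = True
        assert roi_mean_r2star(maps, mask) == pytest.approx(200.0)

    def test_empty_mask_rejected(self):
        maps = ParameterMaps(np.ones((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            roi_mean_r2star(maps, np.zeros((2, 2), bool))


class TestBlandAltman:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a)
        assert res.mean_difference == 0.0
        assert res.limits == (0.0, 0.0)

    def test_hand_arithmetic(self):
        res = bland_altman(np.array([1.0, 3.0]), np.array([2.0, 2.0]))
        assert res.mean_difference == pytest.approx(0.0)
        assert res.upper_limit == pytest.approx(1.96 * np.sqrt(2.0))
        assert res.lower_limit == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        ab, ba = bland_altman(a, b), bland_altman(b, a)
        assert ab.mean_difference == pytest.approx(-ba.mean_difference)
        assert ab.upper_limit == pytest.approx(-ba.lower_limit)


def wilcoxon_exact_enumeration(d):
    """Oracle: enumerate all sign assignments of |d| ranks (no ties)."""
    d = np.asarray(d, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    stat = min(w_plus, ranks[d < 0].sum())
    count = 0
    n = len(d)
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, ranks.sum() - w) <= stat:
            count += 1
    return stat, count / 2**n


class TestWilcoxon:
    def test_all_positive_six_pairs(self):
        a = np.array([2.0, 3, 4, 5, 6, 7])
        b = np.zeros(6)
        stat, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(2 / 64)

    def test_matches_enumeration_oracle(self, rng):
        d = rng.normal(0.3, 1.0, 9)
        d = d[d != 0]
        stat, p = wilcoxon_signed_rank(d + 1.0, np.ones_like(d))
        stat_o, p_o = wilcoxon_exact_enumeration(d)
        assert stat == pytest.approx(stat_o)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_shift_invariance(self, rng):
        a, b = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        s1, p1 = wilcoxon_signed_rank(a, b)
        s2, p2 = wilcoxon_signed_rank(a + 5.0, b + 5.0)
        assert (s1, p1) == (s2, p2)

    def test_exact_close_to_normal_approx_at_boundary(self, rng):
        """Exact and approximate branches agree near n = 12."""
        from scipy import stats

        for trial in range(5):
            d = rng.normal(0.5, 1.0, 12)
            _, p_exact = wilcoxon_signed_rank(d + 1.0, np.ones_like(d))
            p_approx = stats.wilcoxon(
                d, correction=True, method="approx"
            ).pvalue
            assert abs(p_exact - p_approx) < 0.02

    def test_identical_pairs_rejected(self):
        a = np.arange(6.0)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(a, a)
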