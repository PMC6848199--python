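import numpy as np
import pytest
from scipy import stats

from geneage import (
    Timeline,
    bridge_covariance,
    joint_band,
    max_modulus_quantile,
    pooled_probs,
    stochastic_order_test,
)
from geneage.distributions import from_counts
from geneage.errors import ValidationError


class TestPooledProbs:
    def test_last_breakpoint_always_dropped(self, tl3):
        a = from_counts("a", [5, 3, 2], tl3)
        p, kept = pooled_probs(a, a)
        assert list(kept) == [1, 2]  # breakpoint 3 has pooled proportion 1
        assert np.allclose(p, [0.5, 0.8])
        assert np.all(p < 1.0)

    def test_weighted_mean_of_curves(self, tl3):
        # equal sizes, C_A = (0.2, 1), C_B = (0.4, 1) at the first breakpoint
        tl2 = Timeline(("A", "B"), (100.0, 0.0))
        a = from_counts("a", [2, 8], tl2)
        b = from_counts("b", [4, 6], tl2)
        p, kept = pooled_probs(a, b)
        assert list(kept) == [1]
        assert p[0] == pytest.approx(0.3)

    def test_pooled_of_identical_inputs_equals_input(self, tl16, rng):
        counts = rng.multinomial(300, np.full(16, 1 / 16))
        a = from_counts("a", counts, tl16)
        p, kept = pooled_probs(a, a)
        assert np.allclose(p, a.cum[kept - 1])

    def test_flat_pooled_stretches_deduplicated(self, tl16):
        young = np.zeros(16, dtype=int)
        young[15] = 100
        old = np.zeros(16, dtype=int)
        old[0] = 100
        p, kept = pooled_probs(from_counts("a", young, tl16), from_counts("b", old, tl16))
        assert list(kept) == [1]
        assert p[0] == pytest.approx(0.5)

    def test_degenerate_pair_rejected(self, tl3):
        a = from_counts("a", [5, 0, 0], tl3)
        with pytest.raises(ValidationError, match="degenerate"):
            pooled_probs(a, a)


class TestBridgeCovariance:
    def test_closed_form_hand_example(self):
        cov = bridge_covariance(np.array([0.25, 0.5, 0.75]))
        expected = [[0.1875, 0.125, 0.0625], [0.125, 0.25, 0.125], [0.0625, 0.125, 0.1875]]
        assert np.allclose(cov.sigma, expected, atol=1e-15)

    def test_single_point_variance(self):
        assert np.allclose(bridge_covariance(np.array([0.5])).sigma, [[0.25]])

    def test_psd_for_random_p_vectors(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 15))
            p = np.sort(rng.uniform(0.01, 0.99, size=m))
            p = np.unique(p)
            sigma = bridge_covariance(p).sigma
            assert np.linalg.eigvalsh(sigma).min() >= -1e-10
            # elementwise closed form
            for i in range(p.size):
                for j in range(p.size):
                    assert sigma[i, j] == pytest.approx(
                        p[min(i, j)] * (1 - p[max(i, j)]), abs=1e-12
                    )

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.0], [0.6, 0.4]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValidationError):
            bridge_covariance(np.array(bad))


class TestMaxModulusQuantile:
    def test_k1_alpha05_matches_normal_quantile(self):
        c = max_modulus_quantile(np.array([[0.21]]), alpha=0.05, n_mc=10**6, seed=0)
        assert abs(c - 1.959964) <= 0.01

    def test_k1_alpha50_matches_normal_quartile(self):
        c = max_modulus_quantile(np.array([[0.25]]), alpha=0.5, n_mc=10**6, seed=0)
        assert abs(c - stats.norm.ppf(0.75)) <= 0.01

    def test_nonincreasing_in_alpha_on_fixed_seed(self):
        sigma = bridge_covariance(np.array([0.2, 0.5, 0.8])).sigma
        cs = [max_modulus_quantile(sigma, alpha=a, n_mc=10**5, seed=7)
              for a in (0.01, 0.05, 0.2, 0.5)]
        assert cs == sorted(cs, reverse=True)

    def test_more_breakpoints_never_cheaper(self):
        c1 = max_modulus_quantile(np.array([[0.25]]), alpha=0.05, n_mc=10**5, seed=3)
        sigma = bridge_covariance(np.linspace(0.1, 0.9, 9)).sigma
        c9 = max_modulus_quantile(sigma, alpha=0.05, n_mc=10**5, seed=3)
        assert c9 >= c1

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues -1, 3
        with pytest.raises(ValidationError, match="positive semidefinite"):
            max_modulus_quantile(bad, n_mc=10**4, seed=0)


class TestJointBand:
    def test_null_pair_band_symmetric_about_zero(self, tl16, rng):
        counts = rng.multinomial(400, np.full(16, 1 / 16))
        a = from_counts("a", counts, tl16)
        b = from_counts("b", counts.copy(), tl16)
        band = joint_band(a, b, alpha=0.05, n_mc=10**4, seed=1)
        assert np.allclose(band.D, 0.0)
        assert np.allclose(band.band_low, -band.band_high)

    def test_width_is_twice_c_alpha_se(self, tl16, rng):
        a = from_counts("a", rng.multinomial(300, np.full(16, 1 / 16)), tl16)
        b = from_counts("b", rng.multinomial(200, np.full(16, 1 / 16)), tl16)
        band = joint_band(a, b, alpha=0.05, n_mc=10**4, seed=2)
        assert np.allclose(band.band_high - band.band_low, 2 * band.c_alpha * band.se)

    def test_scheffe_calibration_is_wider(self, tl16, rng):
        a = from_counts("a", rng.multinomial(300, np.full(16, 1 / 16)), tl16)
        b = from_counts("b", rng.multinomial(200, np.full(16, 1 / 16)), tl16)
        mm = joint_band(a, b, n_mc=10**5, seed=3)
        sch = joint_band(a, b, calibration="scheffe")
        assert sch.c_alpha > mm.c_alpha  # chi-square bound is conservative


class TestStochasticOrderTest:
    def test_maximal_separation_verdict(self, tl16):
        young = np.zeros(16, dtype=int)
        young[15] = 100
        old = np.zeros(16, dtype=int)
        old[0] = 100
        res = stochastic_order_test(
            from_counts("young", young, tl16), from_counts("old", old, tl16),
            n_mc=10**5, seed=4,
        )
        assert res.verdict == "A_younger"
        assert res.p_two_sided <= 0.001

    def test_identical_multisets_no_difference(self, tl16, rng):
        counts = rng.multinomial(150, np.full(16, 1 / 16))
        res = stochastic_order_test(
            from_counts("a", counts, tl16), from_counts("b", counts.copy(), tl16),
            n_mc=10**4, seed=5,
        )
        assert res.verdict == "no_difference"
        assert res.T == 0.0
        assert res.p_two_sided == 1.0

    def test_constructed_crossing_profiles(self):
        tl = Timeline(("A", "B", "C", "D"), (300.0, 200.0, 100.0, 0.0))
        a = from_counts("a", [0, 500, 0, 500], tl)  # C_A = 0, .5, .5, 1
        b = from_counts("b", [250, 0, 500, 250], tl)  # C_B = .25, .25, .75, 1
        res = stochastic_order_test(a, b, n_mc=10**5, seed=6)
        assert res.verdict == "crossing"

    def test_antisymmetry_under_swap(self, tl16, rng):
        pi = np.full(16, 1 / 16)
        a = from_counts("a", rng.multinomial(500, pi), tl16)
        shifted = np.roll(rng.multinomial(500, pi), -2)
        shifted[0] += shifted.sum() - 500  # keep total
        shifted = np.abs(shifted)
        b = from_counts("b", rng.multinomial(500, shifted / shifted.sum()), tl16)
        r_ab = stochastic_order_test(a, b, n_mc=10**5, seed=8)
        r_ba = stochastic_order_test(b, a, n_mc=10**5, seed=8)
        assert np.allclose(r_ab.band.D, -r_ba.band.D)
        assert r_ab.p_two_sided == r_ba.p_two_sided
        swap = {"A_younger": "B_younger", "B_younger": "A_younger"}
        assert r_ba.verdict == swap.get(r_ab.verdict, r_ab.verdict)

    def test_verdict_requires_band_supported_signed_deviation(self, tl16, rng):
        # under the null, whenever p > alpha no breakpoint may exclude zero
        counts = rng.multinomial(300, np.full(16, 1 / 16))
        res = stochastic_order_test(
            from_counts("a", counts, tl16),
            from_counts("b", rng.multinomial(300, np.full(16, 1 / 16)), tl16),
            n_mc=10**4, seed=9,
        )
        excludes = (res.band.band_low > 0) | (res.band.band_high < 0)
        if res.verdict == "no_difference":
            assert res.p_two_sided > res.alpha or not excludes.any()
        else:
            assert excludes.any()
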