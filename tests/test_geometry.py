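"""Spatial misrejoining geometry: kernel, theta, omega, eta, deletion map."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radrepair import (
    GeometryContext,
    ModelParameters,
    deletion_fraction_above,
    deletion_size_bp,
    eta,
    misrepair_fraction_exact,
    misrepair_fraction_from_eta,
    omega,
    p_correct,
    p_intra,
    rejoining_kernel,
    separation_for_deletion_size,
    theta,
)
from radrepair.geometry import (
    deletion_fraction_above_many,
    eta_from_misrepair_fraction,
    pair_distance_pdf,
)


def _uniform_in_sphere(rng, n):
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return v * (rng.random(n) ** (1 / 3))[:, None]


class TestKernel:
    def test_peak_and_decay(self):
        assert rejoining_kernel(0.0, 0.1) == 1.0
        assert rejoining_kernel(5.0, 0.1) < 1e-100

    def test_value_at_one_range(self):
        assert rejoining_kernel(0.1, 0.1) == pytest.approx(math.exp(-0.5))

    def test_monotone_decreasing(self):
        d = np.linspace(0, 1, 100)
        k = rejoining_kernel(d, 0.05)
        assert np.all(np.diff(k) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rejoining_kernel(1.0, 0.0)
        with pytest.raises(ValueError):
            rejoining_kernel(-1.0, 0.1)


class TestPairDistancePdf:
    def test_normalised(self):
        r = np.linspace(0, 2, 20001)
        assert np.trapezoid(pair_distance_pdf(r), r) == pytest.approx(1.0, abs=1e-6)

    def test_matches_empirical_distances(self, rng):
        a = _uniform_in_sphere(rng, 200_000)
        b = _uniform_in_sphere(rng, 200_000)
        d = np.linalg.norm(a - b, axis=1)
        hist, edges = np.histogram(d, bins=40, range=(0, 2), density=True)
        mid = 0.5 * (edges[1:] + edges[:-1])
        assert np.allclose(hist, pair_distance_pdf(mid), atol=0.02)


class TestTheta:
    @pytest.mark.parametrize("sigma", [0.01, 0.04, 0.1, 0.3])
    def test_against_mc_quadrature(self, sigma, rng):
        # brute-force expectation of the kernel over >=1e6 random pairs
        n = 1_200_000
        a = _uniform_in_sphere(rng, n)
        b = _uniform_in_sphere(rng, n)
        z = np.exp(-((a - b) ** 2).sum(axis=1) / (2 * sigma**2))
        mc, se = z.mean(), z.std(ddof=1) / math.sqrt(n)
        assert abs(theta(sigma) - mc) < 3 * se

    def test_large_sigma_limit(self):
        assert theta(50.0) == pytest.approx(1.0, abs=1e-3)

    def test_truncation_monotone(self):
        full = theta(0.05)
        half = theta(0.05, max_separation=0.05)
        assert 0 < half < full
        assert theta(0.05, max_separation=0.0) == 0.0
        assert theta(0.05, max_separation=2.0) == pytest.approx(full)

    def test_invalid(self):
        with pytest.raises(ValueError):
            theta(-0.1)
        with pytest.raises(ValueError):
            theta(0.1, max_separation=-1.0)


class TestOmega:
    def test_large_sigma_no_correction(self, params):
        assert omega(5.0, params=params) == pytest.approx(1.0, abs=1e-9)

    def test_small_sigma_plateau_is_first_constant(self, params):
        assert omega(1e-6, params=params) == pytest.approx(params.geom_A, abs=1e-4)

    @given(sigma=st.floats(1e-3, 1.0))
    def test_positive_and_bounded(self, sigma):
        w = omega(sigma)
        assert 0.0 < w <= 1.0


class TestEta:
    def test_zero_without_other_breaks(self, params):
        assert eta(0, params=params) == 0.0

    def test_first_order_linearity_in_n0(self, params):
        e1 = eta(1e-3, params=params)
        e2 = eta(2e-3, params=params)
        assert e2 == pytest.approx(2 * e1, rel=1e-9)

    def test_monotone_in_n0(self, params):
        vals = [eta(n, params=params) for n in (1, 10, 100, 1000)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_fraction_round_trip(self):
        for e in (0.0, 0.3, 2.5):
            f = misrepair_fraction_from_eta(e)
            assert 0 <= f < 1
            assert eta_from_misrepair_fraction(f) == pytest.approx(e)

    def test_negative_rejected(self, params):
        with pytest.raises(ValueError):
            eta(-1, params=params)


class TestExactMisrepairFraction:
    def test_matches_direct_sampling(self, rng):
        # independent brute-force estimate of E[S/(1+S)] at one setting
        sigma, n_other, n_samp = 0.08, 50, 120_000
        focal = _uniform_in_sphere(rng, n_samp)
        ends = _uniform_in_sphere(rng, n_samp * 2 * n_other).reshape(n_samp, 2 * n_other, 3)
        S = np.exp(-((ends - focal[:, None, :]) ** 2).sum(axis=2) / (2 * sigma**2)).sum(axis=1)
        est = (S / (1 + S)).mean()
        se = (S / (1 + S)).std(ddof=1) / math.sqrt(n_samp)
        assert abs(misrepair_fraction_exact(n_other, sigma) - est) < 3 * se

    def test_closed_form_omega_tracks_exact(self, params):
        # the fitted two-constant form approximates the exact fraction to
        # a few percent over the operating range
        for sigma, n in [(0.02, 100), (0.0428, 100), (0.0428, 1000), (0.1, 100)]:
            f_exact = misrepair_fraction_exact(n, sigma)
            f_closed = misrepair_fraction_from_eta(eta(n, sigma, params=params))
            assert f_closed == pytest.approx(f_exact, rel=0.10)

    def test_zero_field(self):
        assert misrepair_fraction_exact(0, 0.05) == 0.0


class TestPCorrect:
    def test_hr_is_perfect(self, params):
        assert p_correct(5.0, "HR", params) == 1.0

    def test_base_fidelities_at_zero_eta(self, params):
        assert p_correct(0.0, "NHEJ", params) == pytest.approx(0.985)
        assert p_correct(0.0, "MMEJ", params) == pytest.approx(0.465)

    def test_unknown_process(self, params):
        with pytest.raises(ValueError):
            p_correct(0.0, "SSA", params)

    @given(
        e=st.floats(0.0, 1e3),
        mu=st.floats(0.0, 1.0),
        proc=st.sampled_from(["NHEJ", "MMEJ", "HR"]),
    )
    def test_always_a_probability(self, e, mu, proc):
        p = ModelParameters(mu_nhej=mu, mu_mmej=mu)
        assert 0.0 <= p_correct(e, proc, p) <= 1.0


class TestPIntra:
    def test_single_chromosome(self):
        g = GeometryContext(sigma=0.05, n_chromosomes=1)
        assert p_intra(g) == 1.0

    def test_uniform_partner_limit(self):
        # sigma >> R: partner choice uniform over breaks -> 1/n_c
        g = GeometryContext(sigma=40.0, n_chromosomes=8)
        assert p_intra(g) == pytest.approx(1 / 8, rel=1e-3)

    def test_monotone_decreasing_in_chromosome_number(self):
        vals = [
            p_intra(GeometryContext(sigma=0.0428, n_chromosomes=n))
            for n in range(1, 51)
        ]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_human_value_regression(self, params):
        g = GeometryContext(sigma=params.sigma, n_chromosomes=46)
        assert 0.8 < p_intra(g) < 0.9


class TestDeletionSizeMap:
    def test_zero_and_monotone(self):
        assert deletion_size_bp(0.0, 6.1) == 0.0
        r = np.linspace(0, 2, 100)
        s = deletion_size_bp(r, 6.1)
        assert np.all(np.diff(s) > 0)

    def test_chromosome_scale_consistency(self):
        # separation r_c maps onto exactly one mean chromosome length
        g = GeometryContext(sigma=0.05, n_chromosomes=46, genome_gbp=6.1)
        size = deletion_size_bp(g.chromosome_radius, 6.1)
        assert size == pytest.approx(g.mean_chromosome_gbp * 1e9, rel=1e-12)

    def test_round_trip(self):
        r = np.linspace(1e-6, 2.0, 100)
        back = separation_for_deletion_size(deletion_size_bp(r, 6.1), 6.1)
        assert np.allclose(back, r, atol=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            deletion_size_bp(2.5, 6.1)
        with pytest.raises(ValueError):
            deletion_size_bp(-0.1, 6.1)


class TestDeletionFractionAbove:
    def test_limits(self, params):
        g = GeometryContext(sigma=params.sigma)
        assert deletion_fraction_above(0.0, g) == 1.0
        huge = deletion_size_bp(2.0, g.genome_gbp)
        assert deletion_fraction_above(huge, g) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_threshold(self, params):
        g = GeometryContext(sigma=params.sigma)
        sizes = np.logspace(4, 9, 30)
        fracs = [deletion_fraction_above(s, g) for s in sizes]
        assert all(b <= a + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_vectorised_path_matches_quadrature(self, params):
        g = GeometryContext(sigma=params.sigma)
        sizes = np.array([1e5, 1e6, 3e6, 1e7, 1e8])
        many = deletion_fraction_above_many(sizes, g)
        single = np.array([deletion_fraction_above(s, g) for s in sizes])
        assert np.allclose(many, single, atol=2e-5)
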