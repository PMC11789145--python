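"""TI, cycle closure, estimators and structural observables."""

import numpy as np
import pytest

from burnn.analysis import (
    C_CM_PER_PS,
    CycleLeg,
    TISeries,
    block_standard_error,
    bond_power_spectrum,
    count_hbonds,
    cycle_closure,
    exp_averaging,
    harmonic_fep_oracle,
    rdf,
    signed_plane_angle,
    ti_integrate,
    ti_series_from_samples,
)
from burnn.system import Configuration


class TestTI:
    def test_constant_integrand(self):
        lam = np.linspace(0, 1, 7)
        s = TISeries(lam, np.full(7, 3.5), np.zeros(7))
        dG, err = ti_integrate(s)
        assert dG == pytest.approx(3.5) and err == 0.0

    def test_quadratic_integrand_converges(self):
        # means following 3 lam^2 integrate to 1 with O(h^2) trapezoid error
        for n, tol in ((11, 6e-3), (101, 6e-5)):
            lam = np.linspace(0, 1, n)
            s = TISeries(lam, 3 * lam**2, np.zeros(n))
            dG, _ = ti_integrate(s)
            assert abs(dG - 1.0) < tol

    def test_error_propagation_rss(self):
        lam = np.array([0.0, 0.5, 1.0])
        s = TISeries(lam, np.zeros(3), np.array([1.0, 2.0, 1.0]))
        _, err = ti_integrate(s)
        w = np.array([0.25, 0.5, 0.25])
        assert err == pytest.approx(np.sqrt(np.sum((w * s.errors) ** 2)))

    def test_22_point_schedule_accepted(self):
        lam = np.linspace(0, 1, 22)
        s = TISeries(lam, np.zeros(22), np.zeros(22))
        assert ti_integrate(s)[0] == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            ti_integrate(TISeries(np.array([0.0]), np.array([1.0]), np.array([0.0])))

    def test_unsorted_lambdas_rejected(self):
        with pytest.raises(ValueError):
            TISeries(np.array([0.0, 0.5, 0.5]), np.zeros(3), np.zeros(3))

    def test_replica_inverse_variance_combination(self):
        rng = np.random.default_rng(0)
        samples = [[rng.normal(2.0, 1.0, 200), rng.normal(2.0, 1.0, 200)]]
        s = ti_series_from_samples([0.0], samples)
        assert abs(s.means[0] - 2.0) < 0.3
        assert s.errors[0] < block_standard_error(samples[0][0])


class TestHarmonicOracle:
    def test_equal_force_constants_give_zero(self):
        dg, err, exact = harmonic_fep_oracle(800.0, 800.0, n_lambdas=5,
                                             n_steps=4000, seed=1)
        assert exact == 0.0
        assert abs(dg) < 3 * err

    def test_error_scales_with_sampling_length(self):
        _, err_long, _ = harmonic_fep_oracle(500.0, 1500.0, n_lambdas=5,
                                             n_steps=16000, seed=3)
        _, err_short, _ = harmonic_fep_oracle(500.0, 1500.0, n_lambdas=5,
                                              n_steps=8000, seed=3)
        # halving the sampling roughly sqrt(2)-inflates the standard error
        assert 1.0 < err_short / err_long < 2.2


class TestCycleClosure:
    def test_signed_sum(self):
        legs = [CycleLeg("a", 3.0, 0.1), CycleLeg("b", -1.0, 0.1),
                CycleLeg("c", -2.0, 0.1)]
        closure, err = cycle_closure(legs)
        assert closure == pytest.approx(0.0)
        assert err == pytest.approx(np.sqrt(3) * 0.1)

    def test_forward_backward_cancels_exactly(self):
        legs = [CycleLeg("x", 4.2, 0.3, +1), CycleLeg("x", 4.2, 0.3, -1)]
        assert cycle_closure(legs)[0] == 0.0

    def test_open_cycle_detected(self):
        legs = [CycleLeg("a", 1.0, 0.0, +1, start="A", end="B"),
                CycleLeg("b", 1.0, 0.0, +1, start="C", end="A")]
        with pytest.raises(ValueError, match="open cycle"):
            cycle_closure(legs)


class TestExpAveraging:
    def test_agrees_with_ti_on_gaussian_samples(self):
        # independent-estimator cross-check on synthetic linear-coupling data:
        # for Gaussian dH/dl with constant variance both estimators are
        # unbiased for the same dG
        rng = np.random.default_rng(2)
        lam = np.linspace(0, 1, 11)
        true_mean = 5.0 - 4.0 * lam
        samples = [rng.normal(m, 1.5, 4000) for m in true_mean]
        dg_ti, e_ti = ti_integrate(ti_series_from_samples(lam, [[s] for s in samples]))
        dg_exp, e_exp = exp_averaging(lam, samples)
        assert abs(dg_ti - dg_exp) < 3 * np.hypot(e_ti, e_exp) + 0.05


class TestRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(0)
        frames = [Configuration(positions=rng.uniform(0, 3, (120, 3)),
                                box=np.array([3.0, 3, 3])) for _ in range(200)]
        r, g = rdf(frames, np.arange(120), np.arange(120), r_max=1.4, n_bins=14)
        assert np.max(np.abs(g[1:] - 1.0)) < 0.05

    def test_empty_selection_rejected(self):
        frames = [Configuration(positions=np.zeros((2, 3)) + 1,
                                box=np.array([3.0, 3, 3]))]
        with pytest.raises(ValueError):
            rdf(frames, [], [0], 1.0)

    def test_frozen_pair_delta_peak(self):
        d = 0.73
        frames = [Configuration(
            positions=np.array([[1.0, 1, 1], [1.0 + d, 1, 1]]),
            box=np.array([4.0, 4, 4]))]
        r, g = rdf(frames, [0], [1], r_max=1.9, n_bins=19)
        k = np.searchsorted(np.linspace(0, 1.9, 20), d) - 1
        # analytic shell normalization for one pair in one occupied bin
        edges = np.linspace(0, 1.9, 20)
        shell = 4 / 3 * np.pi * (edges[k + 1] ** 3 - edges[k] ** 3)
        expected = 1.0 / (1 * 1 * shell / 64.0)
        assert g[k] == pytest.approx(expected)
        assert np.sum(g > 0) == 1

    def test_integrates_to_n_minus_one(self):
        rng = np.random.default_rng(1)
        n = 60
        frames = [Configuration(positions=rng.uniform(0, 3, (n, 3)),
                                box=np.array([3.0, 3, 3])) for _ in range(150)]
        r, g = rdf(frames, np.arange(n), np.arange(n), r_max=1.5, n_bins=50)
        dr = r[1] - r[0]
        rho = n / 27.0
        count = np.sum(g * rho * 4 * np.pi * r**2 * dr)
        # within the r < L/2 sphere a fraction 4/3 pi (L/2)^3 / L^3 of
        # partners is visible
        visible = (n - 1) * (4 / 3 * np.pi * 1.5**3) / 27.0
        assert count == pytest.approx(visible, rel=0.05)

    def test_r_max_beyond_half_box_rejected(self):
        frames = [Configuration(positions=np.zeros((2, 3)) + 1,
                                box=np.array([3.0, 3, 3]))]
        with pytest.raises(ValueError):
            rdf(frames, [0], [1], r_max=2.0)


class TestHydrogenBonds:
    def _frame(self, positions):
        return [Configuration(positions=np.asarray(positions, float),
                              box=np.array([5.0, 5, 5]))]

    def test_far_pair_not_counted(self):
        frames = self._frame([[1, 1, 1], [1.1, 1, 1], [1.7, 1, 1]])
        counts, _, _ = count_hbonds(frames, [(0, 1)], [2], d_max=0.25)
        assert counts[0] == 0    # H...A = 0.6 nm

    def test_linear_geometry_counted(self):
        frames = self._frame([[1, 1, 1], [1.1, 1, 1], [1.3, 1, 1]])
        counts, hist, mean = count_hbonds(frames, [(0, 1)], [2])
        assert counts[0] == 1 and hist == {1: 1} and mean == 1.0

    def test_three_donors_on_one_acceptor(self):
        a = [2.5, 2.5, 2.5]
        frames_pos = [a]
        donors = []
        for k, direction in enumerate(np.eye(3)):
            h = np.array(a) + 0.2 * direction
            d = np.array(a) + 0.3 * direction
            frames_pos += [d.tolist(), h.tolist()]
            donors.append((1 + 2 * k, 2 + 2 * k))
        counts, _, _ = count_hbonds(self._frame(frames_pos), donors, [0])
        assert counts[0] == 3

    def test_bent_geometry_rejected_by_angle(self):
        # D-H...A at 90 degrees fails the 135-degree criterion
        frames = self._frame([[1, 1, 1], [1.1, 1, 1], [1.1, 1.2, 1]])
        counts, _, _ = count_hbonds(frames, [(0, 1)], [2])
        assert counts[0] == 0


class TestPlaneAngle:
    BOX = np.array([5.0, 5, 5])
    C = np.array([1.0, 1.0, 1.0])
    O = np.array([1.14, 1.0, 1.0])
    H = np.array([1.19, 1.09, 1.0])

    def test_in_plane_same_side_is_zero(self):
        hw = np.array([1.19, 1.18, 1.0])   # in the C-O-H plane, H side
        assert signed_plane_angle(self.C, self.O, self.H, hw, self.BOX) == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn_is_ninety(self):
        u = (self.O - self.C) / np.linalg.norm(self.O - self.C)
        v = np.array([1.19, 1.18, 1.0]) - self.O
        v_perp = v - np.dot(v, u) * u
        hw90 = self.O + np.dot(v, u) * u + np.cross(u, v_perp)
        ang = signed_plane_angle(self.C, self.O, self.H, hw90, self.BOX)
        assert abs(abs(ang) - 90.0) < 1e-9

    def test_mirror_flips_sign(self):
        u = (self.O - self.C) / np.linalg.norm(self.O - self.C)
        v = np.array([1.19, 1.18, 1.0]) - self.O
        v_perp = v - np.dot(v, u) * u
        up = self.O + np.dot(v, u) * u + np.cross(u, v_perp)
        down = self.O + np.dot(v, u) * u - np.cross(u, v_perp)
        a1 = signed_plane_angle(self.C, self.O, self.H, up, self.BOX)
        a2 = signed_plane_angle(self.C, self.O, self.H, down, self.BOX)
        assert a1 == pytest.approx(-a2) and abs(a1) == pytest.approx(90.0)

    def test_collinear_geometry_rejected(self):
        h_collinear = self.O + (self.O - self.C)
        with pytest.raises(ValueError):
            signed_plane_angle(self.C, self.O, h_collinear,
                               np.array([1.2, 1.3, 1.0]), self.BOX)


class TestPowerSpectrum:
    def test_constant_series_zero_power(self):
        wn, spec = bond_power_spectrum(np.full(256, 0.1), 0.001)
        assert np.allclose(spec[1:], 0.0, atol=1e-12)

    def test_sinusoid_peak_in_right_bin(self):
        dt = 0.001
        f = 12.0  # 1/ps
        t = np.arange(1024) * dt
        wn, spec = bond_power_spectrum(0.1 + 0.01 * np.sin(2 * np.pi * f * t), dt)
        peak = wn[np.argmax(spec[1:]) + 1]
        assert abs(peak - f / C_CM_PER_PS) <= (wn[1] - wn[0])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            bond_power_spectrum(np.zeros(32), 0.001)
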