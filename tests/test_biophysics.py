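import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from afdsim.acquisition import AcquisitionScheme, Shell
from afdsim.biophysics import (KERNEL_PARAMS, NOISELESS, CompartmentParams,
                               FibreConfig, NoiseModel, SignalSet,
                               add_rician_noise, analytic_response,
                               compartment_signal, stick_zeppelin,
                               zonal_coefficients)

Z = FibreConfig.single((0.0, 0.0, 1.0))


def single_shell(b, directions):
    return AcquisitionScheme("t", (Shell(b, np.atleast_2d(directions)),), 1)


class TestCompartmentSignal:
    def test_b0_is_exactly_one(self, paper_scheme):
        sig = compartment_signal(CompartmentParams(0.37), Z, paper_scheme)
        np.testing.assert_array_equal(sig.values[:14], 1.0)

    def test_perpendicular_two_exponential_value(self):
        # direct evaluation: S = 0.5 + 0.5 exp(-1.2 * 0.8)
        scheme = single_shell(1200.0, [1.0, 0.0, 0.0])
        params = CompartmentParams(f=0.5, d_par=1.9, d_e_perp=0.8)
        sig = compartment_signal(params, Z, scheme)
        assert sig.values[-1] == pytest.approx(0.5 + 0.5 * np.exp(-0.96),
                                               abs=1e-12)
        assert sig.values[-1] == pytest.approx(0.6914, abs=1e-4)

    @pytest.mark.parametrize("f", [0.2, 0.5, 0.8])
    def test_parallel_signal_is_f_independent(self, f):
        # both compartments share d_par, so S(g ∥ n) = exp(-b d_par)
        scheme = single_shell(6000.0, [0.0, 0.0, 1.0])
        sig = compartment_signal(CompartmentParams(f=f), Z, scheme)
        assert sig.values[-1] == pytest.approx(np.exp(-6 * 1.9), rel=1e-9)

    def test_monotone_nonincreasing_in_b(self, rng):
        for _ in range(5):
            f, de = rng.uniform(0.05, 0.95), rng.uniform(0.0, 1.9)
            c = rng.uniform(-1, 1)
            b = np.linspace(0, 6, 50)
            s = stick_zeppelin(CompartmentParams(f=f, d_e_perp=de), b, c)
            assert np.all(np.diff(s) <= 1e-12)

    def test_rotation_equivariance(self, rng):
        dirs = rng.normal(size=(20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        params = CompartmentParams(f=0.4, d_e_perp=0.6)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            s1 = compartment_signal(
                params, FibreConfig.single(axis),
                single_shell(3000.0, dirs)).values[1:]
            s2 = compartment_signal(
                params, FibreConfig.single(rot @ axis),
                single_shell(3000.0, dirs @ rot.T)).values[1:]
            np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_values_in_unit_interval(self, paper_scheme, rng):
        params = CompartmentParams(f=0.3, d_e_perp=1.1)
        sig = compartment_signal(params, Z, paper_scheme)
        assert np.all(sig.values > 0) and np.all(sig.values <= 1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CompartmentParams(f=1.2)
        with pytest.raises(ValueError):
            CompartmentParams(f=0.3, d_par=1.0, d_e_perp=1.5)
        with pytest.raises(ValueError):
            FibreConfig((((0, 0, 1), 0.6), ((1, 0, 0), 0.6)))

    def test_signal_length_checked(self, paper_scheme):
        with pytest.raises(ValueError):
            SignalSet(paper_scheme, np.ones(7))


class TestRicianNoise:
    def test_noiseless_sentinel_is_identity(self, paper_scheme):
        sig = compartment_signal(KERNEL_PARAMS, Z, paper_scheme)
        assert add_rician_noise(sig, NOISELESS) is sig

    def test_zero_signal_mean_matches_closed_form(self):
        # E[|ε|] at S=0 is σ sqrt(π/2); check within 3 standard errors
        n = 10_000
        scheme = single_shell(1000.0, np.tile([1.0, 0, 0], (n, 1)))
        sig = SignalSet(scheme, np.r_[1.0, np.zeros(n)])
        noisy = add_rician_noise(sig, NoiseModel(20, seed=11))
        sigma = 1 / 20
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt((4 - np.pi) / 2) / np.sqrt(n)
        assert abs(noisy.values[1:].mean() - expected) < 3 * se

    def test_rician_bias_nonnegative(self):
        n = 50_000
        scheme = single_shell(1000.0, np.tile([1.0, 0, 0], (n, 1)))
        sig = SignalSet(scheme, np.r_[1.0, np.full(n, 0.02)])
        noisy = add_rician_noise(sig, NoiseModel(20, seed=5))
        assert noisy.values[1:].mean() >= 0.02

    def test_seed_determinism(self, paper_scheme):
        sig = compartment_signal(KERNEL_PARAMS, Z, paper_scheme)
        a = add_rician_noise(sig, NoiseModel(50, seed=1)).values
        b = add_rician_noise(sig, NoiseModel(50, seed=1)).values
        c = add_rician_noise(sig, NoiseModel(50, seed=2)).values
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(-5)
        with pytest.raises(ValueError):
            NoiseModel(0)


class TestAnalyticResponse:
    def test_b0_shell_has_only_l0(self):
        scheme = AcquisitionScheme(
            "with_b0", (Shell(0.0, np.empty((0, 3))),
                        Shell(1000.0, np.array([[0, 0, 1.0]]))), 0)
        resp = analytic_response(KERNEL_PARAMS, scheme, l_max=8)
        r = resp.zonal(0.0)
        assert r[0] == pytest.approx(np.sqrt(4 * np.pi), rel=1e-10)
        np.testing.assert_allclose(r[1:], 0.0, atol=1e-10)

    def test_isotropic_kernel_has_only_l0(self, paper_scheme):
        iso = CompartmentParams(f=0.0, d_par=1.9, d_e_perp=1.9)
        resp = analytic_response(iso, paper_scheme, l_max=8)
        for b in resp.shells:
            np.testing.assert_allclose(resp.zonal(b)[1:], 0.0, atol=1e-12)

    def test_anisotropy_grows_with_b(self, kernel_response):
        low = kernel_response.zonal(1200.0)
        high = kernel_response.zonal(6000.0)
        assert abs(high[1] / high[0]) > abs(low[1] / low[0])

    def test_quadrature_matches_dense_trapezoid(self):
        # independent oracle: dense trapezoidal quadrature of the same
        # projection integral
        f = lambda c: stick_zeppelin(KERNEL_PARAMS, 3.0, c)
        r = zonal_coefficients(f, 8)
        from scipy.special import eval_legendre
        c = np.linspace(-1, 1, 200_001)
        for i, l in enumerate(range(0, 9, 2)):
            y = np.sqrt((2 * l + 1) / (4 * np.pi)) * eval_legendre(l, c)
            ref = 2 * np.pi * np.trapezoid(f(c) * y, c)
            assert r[i] == pytest.approx(ref, abs=1e-8)

    def test_odd_lmax_rejected(self, paper_scheme):
        with pytest.raises(ValueError):
            analytic_response(KERNEL_PARAMS, paper_scheme, l_max=7)
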