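"""Second-order theory: effective kernels, moments, spectra, information loss."""

import numpy as np
import pytest
from scipy import integrate

from cghawkes import (BinCountSeries, CoarseKernel, HawkesModel,
                      KernelMatrixSpec, autocovariance, bin_events,
                      conditional_moments, coarse_grain,
                      effective_kernels, empirical_autocovariance,
                      information_loss, periodogram, simulate_branching,
                      spectral_density_binned_hawkes,
                      spectral_density_binned_poisson, spectral_density_cg,
                      spectral_density_hawkes_continuous, stationary_mean)


def _ck(matrices, dt=1.0):
    m = np.asarray(matrices, dtype=float)
    if m.ndim == 1:
        m = m[:, None, None]
    return CoarseKernel(d=m.shape[1], dt=dt, matrices=m)


class TestStationaryMean:
    def test_no_excitation(self):
        ck = _ck(np.zeros((1, 2, 2)), dt=2.0)
        assert np.allclose(stationary_mean([1.0, 1.0], ck), [2.0, 2.0])

    def test_symmetric_configuration(self, symmetric_model):
        ck = coarse_grain(symmetric_model.kernel, 1.0, tol=1e-10)
        lam = stationary_mean(symmetric_model.mu, ck)
        assert lam == pytest.approx([10 / 3, 10 / 3], abs=1e-7)

    def test_matches_simulation(self, symmetric_model):
        ck = coarse_grain(symmetric_model.kernel, 1.0, tol=1e-10)
        lam = stationary_mean(symmetric_model.mu, ck)
        means = []
        for s in range(6):
            x = bin_events(simulate_branching(symmetric_model, 1000.0, seed=s), 1.0)
            means.append(x.counts.mean(axis=0))
        means = np.array(means)
        se = means.std(axis=0) / np.sqrt(len(means))
        assert np.all(np.abs(means.mean(axis=0) - lam) < 3 * np.maximum(se, 0.02))

    def test_nonstationary_raises(self):
        ck = _ck([[[1.1]]])
        with pytest.raises(ValueError, match="radius"):
            stationary_mean([1.0], ck)


class TestEffectiveKernels:
    def test_zero_kernel(self):
        ek = effective_kernels(_ck(np.zeros((1, 2, 2))), L=4)
        assert np.allclose(ek.matrices[0], np.eye(2))
        assert np.allclose(ek.matrices[1:], 0.0)

    def test_lag0_geometric(self):
        """phi = a delta_{k0}: Psi_0 = 1/(1-a), Psi_{k>0} = 0."""
        ek = effective_kernels(_ck([0.4]), L=5)
        assert ek.matrices[0, 0, 0] == pytest.approx(1 / 0.6, abs=1e-12)
        assert np.allclose(ek.matrices[1:], 0.0)

    def test_neumann_series_oracle(self):
        """Recursion equals the brute-force convolution series sum_j (Phi^{*j})_k."""
        rng = np.random.default_rng(0)
        Phi = rng.uniform(0, 0.12, size=(4, 2, 2))
        ck = _ck(Phi)
        L = 8
        ek = effective_kernels(ck, L)
        # brute force: accumulate j-fold convolutions
        conv = np.zeros((L + 1, 2, 2))
        conv[0] = np.eye(2)  # j = 0 term
        power = np.zeros((L + 1, 2, 2))
        power[0] = np.eye(2)
        acc = conv.copy()
        for _ in range(60):  # enough terms for 1e-12 decay
            nxt = np.zeros_like(power)
            for k in range(L + 1):
                for j in range(min(k, 3) + 1):
                    nxt[k] += Phi[j] @ power[k - j]
            power = nxt
            acc += power
        assert np.max(np.abs(ek.matrices - acc)) < 1e-10

    def test_sum_is_resolvent(self):
        """sum_n Psi_n ~ (I - A)^{-1}."""
        Phi = np.array([0.3, 0.2, 0.1])
        ek = effective_kernels(_ck(Phi), L=400)
        total = ek.matrices.sum(axis=0)[0, 0]
        assert total == pytest.approx(1 / (1 - 0.6), rel=1e-8)

    def test_singular_phi0_raises(self):
        with pytest.raises(ValueError):
            effective_kernels(_ck([1.0]), L=3)


class TestConditionalMoments:
    def test_poisson_case(self):
        ck = _ck(np.zeros((1, 2, 2)))
        mean, cov = conditional_moments(ck, [1.0, 1.0], np.empty((0, 2)))
        assert np.allclose(mean, [1.0, 1.0])
        assert np.allclose(cov, np.eye(2))

    def test_intra_bin_overdispersion(self):
        """d=1, phi_0=0.5, mu dt=1: mean 2, variance 2/(1-0.5)^2 = 8."""
        ck = _ck([0.5])
        mean, cov = conditional_moments(ck, [1.0], np.empty((0, 1)))
        assert mean[0] == pytest.approx(2.0, abs=1e-12)
        assert cov[0, 0] == pytest.approx(8.0, abs=1e-12)

    def test_lag_one_history(self):
        """Phi_0 = 0, Phi_1 != 0: mean = mu dt + Phi_1 X, Poisson covariance."""
        Phi = np.zeros((2, 2, 2))
        Phi[1] = [[0.2, 0.1], [0.0, 0.3]]
        ck = _ck(Phi)
        mean, cov = conditional_moments(ck, [1.0, 1.0], np.array([[3.0, 0.0]]))
        assert np.allclose(mean, [1.0 + 0.6, 1.0])
        assert np.allclose(cov, np.diag(mean))

    def test_variance_dominates_mean(self, symmetric_model):
        ck = coarse_grain(symmetric_model.kernel, 2.0, tol=1e-10)
        mean, cov = conditional_moments(ck, symmetric_model.mu, np.empty((0, 2)))
        assert np.all(np.diag(cov) > mean)
        assert cov[0, 1] != 0.0  # off-diagonal mass in Phi_0


class TestAutocovariance:
    def test_white_counts(self):
        ek = effective_kernels(_ck(np.zeros((1, 2, 2))), L=5)
        R = autocovariance(ek, [2.0, 3.0], J=3)
        assert np.allclose(R.autocov[0], np.diag([2.0, 3.0]))
        assert np.allclose(R.autocov[1:], 0.0)

    def test_overdispersion(self, symmetric_model):
        ck = coarse_grain(symmetric_model.kernel, 1.0, tol=1e-10)
        lam = stationary_mean(symmetric_model.mu, ck)
        ek = effective_kernels(ck, 200)
        R = autocovariance(ek, lam, J=5)
        assert np.all(np.diag(R.autocov[0]) > lam)
        evals = np.linalg.eigvalsh(R.autocov[0])
        assert np.all(evals > 0)

    def test_matches_simulated_bins(self, symmetric_model):
        """Theory vs empirical autocovariance of long binned-Hawkes runs."""
        dt = 0.25  # small bins: cg theory is a tight approximation
        ck = coarse_grain(symmetric_model.kernel, dt, tol=1e-10)
        lam = stationary_mean(symmetric_model.mu, ck)
        ek = effective_kernels(ck, 300)
        R = autocovariance(ek, lam, J=4)
        emp = []
        for s in range(6):
            x = bin_events(simulate_branching(symmetric_model, 2000.0, seed=40 + s), dt)
            emp.append(empirical_autocovariance(x, 4).autocov)
        emp = np.array(emp)
        se = emp.std(axis=0) / np.sqrt(len(emp))
        assert np.all(np.abs(emp.mean(axis=0) - R.autocov) < 4 * np.maximum(se, 0.01))


class TestSpectra:
    def test_flat_for_white_counts(self):
        ck = _ck(np.zeros((1, 2, 2)))
        F = spectral_density_cg(ck, [2.0, 2.0], np.linspace(-np.pi, np.pi, 11))
        assert np.allclose(F.F, np.eye(2) * 2.0 / (2 * np.pi))

    def test_hermitian_psd_and_symmetry(self, symmetric_model):
        ck = coarse_grain(symmetric_model.kernel, 1.0, tol=1e-10)
        lam = stationary_mean(symmetric_model.mu, ck)
        omega = np.linspace(-np.pi, np.pi, 41)
        F = spectral_density_cg(ck, lam, omega).F
        assert np.allclose(F, np.conj(np.transpose(F, (0, 2, 1))), atol=1e-12)
        assert np.all(np.linalg.eigvalsh(F) > 0)
        Fneg = spectral_density_cg(ck, lam, -omega).F
        assert np.allclose(Fneg, np.conj(F), atol=1e-12)

    def test_fourier_pair_with_autocovariance(self, symmetric_model):
        """int F(w) e^{iwj} dw recovers R_j to 1e-6."""
        ck = coarse_grain(symmetric_model.kernel, 1.0, tol=1e-12)
        lam = stationary_mean(symmetric_model.mu, ck)
        ek = effective_kernels(ck, 400)
        R = autocovariance(ek, lam, J=3)
        omega = np.linspace(-np.pi, np.pi, 2049)
        F = spectral_density_cg(ck, lam, omega).F
        for j in range(4):
            rec = integrate.simpson(F * np.exp(1j * omega * j)[:, None, None],
                                    x=omega, axis=0)
            assert np.max(np.abs(np.real(rec) - R.autocov[j])) < 1e-6

    def test_dc_value_univariate(self):
        """d=1: F(0) = lambda / (2 pi (1 - alpha)^2)."""
        spec = KernelMatrixSpec.exponential([[0.5]], 1.0)
        ck = coarse_grain(spec, 1.0, tol=1e-12)
        lam = stationary_mean([1.0], ck)
        F = spectral_density_cg(ck, lam, [0.0]).F[0, 0, 0]
        assert np.real(F) == pytest.approx(lam[0] / (2 * np.pi * 0.25), rel=1e-7)

    def test_continuous_limit(self, symmetric_model):
        """F_cg(nu dt) -> F_hw(nu) dt as dt -> 0."""
        nu = np.linspace(0.1, 2.0, 9)
        F_hw = spectral_density_hawkes_continuous(symmetric_model, nu).F
        for dt, tol in [(0.1, 0.05), (0.02, 0.002)]:
            ck = coarse_grain(symmetric_model.kernel, dt, tol=1e-12)
            lam = stationary_mean(symmetric_model.mu, ck)
            F_cg = spectral_density_cg(ck, lam, nu * dt).F
            rel = np.max(np.abs(F_cg / dt - F_hw)) / np.max(np.abs(F_hw))
            assert rel < tol

    def test_kernel_transform_quadrature_matches_closed_form(self):
        """Weibull with shape 1 is exponential: the numerically integrated
        transform must match the exponential closed form."""
        from cghawkes.model import _kernel_transform
        nu = np.array([0.0, 0.5, 2.0])
        wb = KernelMatrixSpec.single_family("weibull", [[0.6]],
                                            {"shape": 1.0, "scale": 2.0})
        ex = KernelMatrixSpec.exponential([[0.6]], 0.5)
        assert np.allclose(_kernel_transform(wb, nu), _kernel_transform(ex, nu),
                           atol=1e-8)

    def test_binned_poisson_flat_without_excitation(self):
        mod = HawkesModel(mu=[1.5], kernel=KernelMatrixSpec.exponential([[0.0]], 1.0))
        omega = np.linspace(-np.pi, np.pi, 21)
        dt = 2.0
        Fpo = spectral_density_binned_poisson(mod, dt, omega).F
        Fhw = spectral_density_binned_hawkes(mod, dt, omega).F
        flat = 1.5 * dt / (2 * np.pi)
        assert np.allclose(np.real(Fpo[:, 0, 0]), flat, atol=1e-10)
        assert np.allclose(np.real(Fhw[:, 0, 0]), flat, atol=1e-8)

    def test_binned_hawkes_matches_periodogram(self, symmetric_model):
        """Aliased window-filtered spectrum vs simulation (primary oracle)."""
        dt = 1.0
        omega_grid = np.linspace(-np.pi, np.pi, 41)
        Fth = spectral_density_binned_hawkes(symmetric_model, dt, omega_grid)
        acc = None
        R = 30
        for s in range(R):
            x = bin_events(simulate_branching(symmetric_model, 2000.0, seed=200 + s), dt)
            P = periodogram(x)
            acc = P.F if acc is None else acc + P.F
        acc /= R
        th = np.interp(P.omega, omega_grid, np.real(Fth.F[:, 0, 0]))
        rel = np.abs(np.real(acc[:, 0, 0]) - th) / th
        # periodogram is asymptotically exponential: mean rel error ~ 1/sqrt(R)
        assert np.mean(rel) < 3.0 / np.sqrt(R)


class TestInformationLoss:
    def test_zero_on_identical(self, symmetric_model):
        omega = np.linspace(-np.pi, np.pi, 101)
        ck = coarse_grain(symmetric_model.kernel, 1.0, tol=1e-10)
        lam = stationary_mean(symmetric_model.mu, ck)
        F = spectral_density_cg(ck, lam, omega)
        assert information_loss(F, F) == 0.0

    def test_cg_below_poisson(self, symmetric_model):
        omega = np.linspace(-np.pi, np.pi, 201)
        for dt in (1.0, 2.0):
            Fhw = spectral_density_binned_hawkes(symmetric_model, dt, omega)
            ck = coarse_grain(symmetric_model.kernel, dt, tol=1e-10)
            lam = stationary_mean(symmetric_model.mu, ck)
            Fcg = spectral_density_cg(ck, lam, omega)
            Fpo = spectral_density_binned_poisson(symmetric_model, dt, omega)
            assert information_loss(Fhw, Fcg) < information_loss(Fhw, Fpo)

    def test_grid_mismatch_raises(self, symmetric_model):
        ck = coarse_grain(symmetric_model.kernel, 1.0, tol=1e-10)
        lam = stationary_mean(symmetric_model.mu, ck)
        Fa = spectral_density_cg(ck, lam, np.linspace(-np.pi, np.pi, 11))
        Fb = spectral_density_cg(ck, lam, np.linspace(-np.pi, np.pi, 21))
        with pytest.raises(ValueError):
            information_loss(Fa, Fb)


class TestPeriodogram:
    def test_constant_series_zero_power(self):
        x = BinCountSeries(counts=np.full((64, 1), 5), dt=1.0)
        P = periodogram(x)
        nz = P.omega != 0
        assert np.allclose(np.abs(P.F[nz]), 0.0, atol=1e-12)

    def test_parseval(self):
        rng = np.random.default_rng(5)
        x = BinCountSeries(counts=rng.poisson(4.0, size=(256, 2)), dt=1.0)
        P = periodogram(x)
        tr = np.real(np.trace(P.F, axis1=1, axis2=2))
        var_total = np.sum(np.var(x.counts, axis=0))
        # identity: mean of the periodogram trace = total variance / (2 pi)
        assert np.mean(tr) == pytest.approx(var_total / (2 * np.pi), rel=1e-10)

    def test_white_poisson_flat(self):
        rng = np.random.default_rng(6)
        lam = 3.0
        acc = []
        for _ in range(40):
            x = BinCountSeries(counts=rng.poisson(lam, size=(512, 1)), dt=1.0)
            acc.append(np.real(periodogram(x).F[:, 0, 0]))
        mean_psd = np.mean(acc)
        assert mean_psd == pytest.approx(lam / (2 * np.pi), rel=0.05)
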