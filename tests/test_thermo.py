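"""Inverse Langevin machinery: KM estimation, drift fit, potential, metrics."""

import numpy as np
import pytest

import alphadyn as ad
from alphadyn import thermo
from alphadyn.gsp import normalized_laplacian
from alphadyn.synthetic import LangevinSimSpec
from conftest import random_connected_graph
from test_gsp import dirichlet_pairwise_oracle


def _ou_series(theta=2.0, D=0.5, n=100_000, seed=0):
    z, _ = ad.generate_langevin_series(LangevinSimSpec(
        drift_coefficients=(0, 0, -theta, 0), diffusion=D, n_samples=n,
        seed=seed))
    return thermo.SmoothnessSeries.from_values(z, 0.01)


class TestSamplewiseSmoothness:
    def test_matches_dirichlet_oracle(self, rng):
        W = random_connected_graph(rng, 5)
        L = normalized_laplacian(W).laplacian
        power = rng.random((2, 5, 700)) + 0.1
        series = thermo.samplewise_smoothness(power, [L, L])
        raw = np.array([dirichlet_pairwise_oracle(power[e][:, t], W)
                        for e in range(2) for t in range(700)])
        rebuilt = (raw - raw.mean()) / raw.std()
        assert np.abs(series.values - rebuilt).max() < 1e-8

    def test_standardized_moments(self, rng):
        W = random_connected_graph(rng, 4)
        L = normalized_laplacian(W).laplacian
        power = rng.random((3, 4, 500)) + 0.1
        series = thermo.samplewise_smoothness(power, [L] * 3)
        assert series.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert series.values.std() == pytest.approx(1.0, abs=1e-9)

    def test_nullspace_signal_cannot_standardize(self, rng):
        W = random_connected_graph(rng, 4)
        spec = normalized_laplacian(W)
        x = np.sqrt(spec.degree)  # zero Dirichlet energy at every sample
        power = np.repeat(x[None, :, None], 1200, axis=2)
        with pytest.raises(ValueError, match="zero variance"):
            thermo.samplewise_smoothness(power, [spec.laplacian])

    def test_exclusion_fires_below_validity_floor(self, rng):
        W = random_connected_graph(rng, 4)
        L = normalized_laplacian(W).laplacian
        power = rng.random((1, 4, 999)) + 0.1
        with pytest.raises(thermo.SubjectExcludedError, match="1000"):
            thermo.samplewise_smoothness(power, [L])

    def test_exclusion_counts_only_finite_samples(self, rng):
        W = random_connected_graph(rng, 4)
        L = normalized_laplacian(W).laplacian
        power = rng.random((1, 4, 1100)) + 0.1
        power[0, 0, :200] = np.nan  # 900 finite samples remain
        with pytest.raises(thermo.SubjectExcludedError):
            thermo.samplewise_smoothness(power, [L])


class TestEstimateKM:
    def test_constant_series_has_zero_drift_and_diffusion(self):
        series = thermo.SmoothnessSeries.from_values(np.full(2000, 1.7), 0.01)
        km = thermo.estimate_km(series)
        occ = km.counts > 0
        assert occ.sum() == 1
        assert km.drift[occ][0] == 0.0
        assert km.diffusion[occ][0] == 0.0

    def test_ou_binwise_drift_and_diffusion(self):
        # Binwise drift of an OU path tracks -theta z.  Each bin estimate has
        # binomial-count sampling error SE_k = sqrt(2 D / (n_k dt)); bins are
        # required to sit within 4 SE of the true drift, and the line fitted
        # through the central bins must recover the drift slope within 5%.
        km = thermo.estimate_km(_ou_series(seed=5))
        central = km.valid & (np.abs(km.bin_centers) <= 1.0)
        expect = -2.0 * km.bin_centers[central]
        got = km.drift[central]
        se = np.sqrt(2 * 0.5 / (km.counts[central] * 0.01))
        assert np.all(np.abs(got - expect) < 4 * se)
        slope = np.polyfit(km.bin_centers[central], got, 1)[0]
        assert abs(slope - (-2.0)) / 2.0 < 0.05
        assert abs(np.mean(km.diffusion[km.valid]) - 0.5) / 0.5 < 0.15

    def test_counts_conserve_increments_in_range(self):
        series = _ou_series(n=20_000, seed=9)
        km = thermo.estimate_km(series)
        z = series.values
        lo, hi = np.percentile(z, (2.5, 97.5))
        inside = (z[:-1] >= lo) & (z[:-1] <= hi)
        assert km.counts.sum() == inside.sum()

    def test_twenty_bins_over_central_range(self):
        km = thermo.estimate_km(_ou_series(n=10_000, seed=2))
        assert km.bin_edges.size == 21
        assert np.all(km.valid == (km.counts > 10))


class TestDriftFit:
    def _km(self, centers, drift):
        n = len(centers)
        return thermo.BinnedKM(bin_edges=np.linspace(-1, 1, n + 1),
                               bin_centers=np.asarray(centers, float),
                               counts=np.full(n, 100),
                               drift=np.asarray(drift, float),
                               diffusion=np.full(n, 0.5),
                               valid=np.full(n, True))

    def test_exact_linear_drift(self):
        c = np.linspace(-1.5, 1.5, 12)
        fit = thermo.fit_drift(self._km(c, -2.0 * c))
        a, b, cc, d = fit.coefficients
        assert np.allclose([a, b, cc, d], [0, 0, -2.0, 0], atol=1e-10)

    def test_exact_cubic_drift(self):
        c = np.linspace(-1.5, 1.5, 12)
        fit = thermo.fit_drift(self._km(c, c - c**3))
        a, b, cc, d = fit.coefficients
        assert np.allclose([a, b, cc, d], [-1.0, 0, 1.0, 0], atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        c = np.linspace(-2, 2, 15)
        y = rng.standard_normal(15)
        fit = thermo.fit_drift(self._km(c, y))
        V = np.vander(c, 4)  # columns z^3, z^2, z, 1
        beta = np.linalg.solve(V.T @ V, V.T @ y)
        assert np.allclose(fit.coefficients, beta, atol=1e-9)

    def test_too_few_valid_bins_rejected(self):
        km = self._km(np.linspace(-1, 1, 5), np.zeros(5))
        km.valid[:] = [True, True, True, False, False]
        with pytest.raises(ValueError, match="valid bins"):
            thermo.fit_drift(km)


class TestPotentialAndMetrics:
    def test_linear_drift_gives_harmonic_well(self):
        fit = thermo.DriftFit(coefficients=(0, 0, -1.0, 0), n_bins_used=10,
                              fit_residual=0.0)
        U = thermo.reconstruct_potential(fit)
        z = np.linspace(-2, 2, 9)
        assert np.allclose(U(z), z**2 / 2)
        assert U(0.0) == 0.0

    def test_double_well_shape(self):
        fit = thermo.DriftFit(coefficients=(-1.0, 0, 1.0, 0), n_bins_used=10,
                              fit_residual=0.0)
        U = thermo.reconstruct_potential(fit)
        z = np.linspace(-1.5, 1.5, 7)
        assert np.allclose(U(z), z**4 / 4 - z**2 / 2)
        assert U(1.0) < U(0.0) and U(-1.0) < U(0.0)

    def test_negative_gradient_reproduces_drift(self, rng):
        coeffs = tuple(rng.standard_normal(4))
        fit = thermo.DriftFit(coefficients=coeffs, n_bins_used=8,
                              fit_residual=0.0)
        U = thermo.reconstruct_potential(fit)
        z = np.linspace(-2, 2, 100)
        h = 1e-6
        grad = (U(z + h) - U(z - h)) / (2 * h)
        assert np.abs(-grad - fit(z)).max() < 1e-6

    def test_kappa_sign_convention(self):
        km = TestDriftFit()._km(np.linspace(-1, 1, 10), np.zeros(10))
        fit = thermo.DriftFit(coefficients=(0, 0, -2.0, 0), n_bins_used=10,
                              fit_residual=0.0)
        assert thermo.extract_metrics(fit, km).kappa == 1.0
        anti = thermo.DriftFit(coefficients=(-1.0, 0, 1.0, 0), n_bins_used=10,
                               fit_residual=0.0)
        assert thermo.extract_metrics(anti, km).kappa == -0.5

    def test_no_central_bins_rejected(self):
        km = TestDriftFit()._km(np.linspace(2, 4, 10), np.zeros(10))
        fit = thermo.DriftFit(coefficients=(0, 0, -1.0, 0), n_bins_used=10,
                              fit_residual=0.0)
        with pytest.raises(ValueError, match="central"):
            thermo.extract_metrics(fit, km)


class TestRecovery:
    def test_kappa_increases_with_confinement(self):
        medians = []
        for theta in (0.5, 2.0):
            ks = []
            for seed in range(5):
                z, _ = ad.generate_langevin_series(LangevinSimSpec(
                    drift_coefficients=(0, 0, -theta, 0), diffusion=0.5,
                    n_samples=50_000, seed=seed))
                ks.append(thermo.landscape_from_series(z, 0.01).kappa)
            medians.append(np.median(ks))
        assert medians[1] > medians[0]

    def test_validity_floor_boundary(self):
        vals = np.random.default_rng(0).standard_normal(1000)
        thermo.landscape_from_series(vals, 0.01)  # exactly at the floor: ok
        with pytest.raises(thermo.SubjectExcludedError):
            thermo.landscape_from_series(vals[:999], 0.01)

    def test_subject_pipeline_metrics_finite(self, analyzed_subject):
        tm = analyzed_subject.thermo_metrics
        assert np.isfinite(tm.kappa) and np.isfinite(tm.central_noise)
        assert tm.n_valid >= 1000
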