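"""Graph-spectral descriptors, dynamic summaries, and the 45-feature canon."""

import numpy as np
import pytest

from alphadyn import gsp
from conftest import random_connected_graph


def dirichlet_pairwise_oracle(x, W):
    """0.5 * sum_ij W_ij (x_i/sqrt(d_i) - x_j/sqrt(d_j))^2, coded directly."""
    d = W.sum(axis=1)
    n = len(x)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += W[i, j] * (x[i] / np.sqrt(d[i]) - x[j] / np.sqrt(d[j])) ** 2
    return 0.5 * total


def sampen_bruteforce(series, m, r):
    """O(n^2) template-matching sample entropy, self-matches excluded."""
    n = len(series)
    def count(mm):
        c = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(series[i + k] - series[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c
    b, a = count(m), count(m + 1)
    if a == 0 or b == 0:
        tiny = np.finfo(float).tiny
        return -np.log((a + tiny) / (b + tiny))
    return -np.log(a / b)


class TestLaplacian:
    def test_nullspace_eigenvector(self, rng):
        W = random_connected_graph(rng, 8)
        spec = gsp.normalized_laplacian(W)
        assert spec.frequencies[0] == pytest.approx(0.0, abs=1e-10)
        v = np.sqrt(spec.degree)
        v /= np.linalg.norm(v)
        assert abs(abs(spec.harmonics[:, 0] @ v) - 1.0) < 1e-9

    def test_frequencies_within_normalized_bounds(self, rng):
        for _ in range(5):
            W = random_connected_graph(rng, 10)
            f = gsp.normalized_laplacian(W).frequencies
            assert f.min() > -1e-10 and f.max() < 2 + 1e-10

    def test_complete_graph_closed_form(self):
        W = 1.0 - np.eye(4)
        f = gsp.normalized_laplacian(W).frequencies
        assert np.allclose(f[1:], 4.0 / 3.0)

    def test_zero_degree_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="zero-strength"):
            gsp.normalized_laplacian(W)


class TestTransforms:
    def test_harmonic_maps_to_one_hot(self, rng):
        spec = gsp.normalized_laplacian(random_connected_graph(rng, 6))
        xhat = gsp.gft(spec.harmonics[:, 2], spec)
        expect = np.zeros(6)
        expect[2] = 1.0
        assert np.allclose(np.abs(xhat), expect, atol=1e-10)

    def test_parseval_and_inverse(self, rng):
        spec = gsp.normalized_laplacian(random_connected_graph(rng, 9))
        for _ in range(10):
            x = rng.standard_normal(9)
            xhat = gsp.gft(x, spec)
            assert np.sum(xhat**2) == pytest.approx(np.sum(x**2), abs=1e-10)
            assert np.allclose(spec.harmonics @ xhat, x, atol=1e-10)

    def test_smoothness_identities_and_oracle(self, rng):
        W = random_connected_graph(rng, 7)
        spec = gsp.normalized_laplacian(W)
        # nullspace signal has zero Dirichlet energy
        assert gsp.smoothness(np.sqrt(spec.degree), spec) == pytest.approx(0.0, abs=1e-9)
        # Rayleigh: harmonic i has energy lambda_i
        for i in (1, 3):
            assert gsp.smoothness(spec.harmonics[:, i], spec) == pytest.approx(
                spec.frequencies[i], abs=1e-10)
        for _ in range(5):
            x = rng.standard_normal(7)
            assert gsp.smoothness(x, spec) == pytest.approx(
                dirichlet_pairwise_oracle(x, W), abs=1e-10)

    def test_entropy_limits_and_scale_invariance(self, rng):
        spec = gsp.normalized_laplacian(random_connected_graph(rng, 6))
        assert gsp.spectral_entropy(spec.harmonics[:, 1], spec) == pytest.approx(0.0, abs=1e-10)
        uniform = spec.harmonics.sum(axis=1)  # equal unit coefficient on all modes
        assert gsp.spectral_entropy(uniform, spec) == pytest.approx(np.log(6), abs=1e-10)
        x = rng.standard_normal(6)
        assert gsp.spectral_entropy(x, spec) == pytest.approx(
            gsp.spectral_entropy(-3.7 * x, spec), abs=1e-12)
        assert 0 <= gsp.spectral_entropy(x, spec) <= np.log(6) + 1e-12

    def test_spread_closed_forms_and_oracle(self, rng):
        spec = gsp.normalized_laplacian(random_connected_graph(rng, 6))
        lam = spec.frequencies
        assert gsp.frequency_spread(spec.harmonics[:, 2], spec) == pytest.approx(0.0, abs=1e-9)
        two = spec.harmonics[:, 1] + spec.harmonics[:, 4]
        assert gsp.frequency_spread(two, spec) == pytest.approx(
            abs(lam[4] - lam[1]) / 2, abs=1e-10)
        for _ in range(5):
            x = rng.standard_normal(6)
            xhat = gsp.gft(x, spec)
            p = xhat**2 / np.sum(xhat**2)
            mu = np.sum(p * lam)
            assert gsp.frequency_spread(x, spec) == pytest.approx(
                np.sqrt(np.sum(p * (lam - mu) ** 2)), abs=1e-10)

    def test_zero_signal_rejected(self, rng):
        spec = gsp.normalized_laplacian(random_connected_graph(rng, 5))
        with pytest.raises(ValueError, match="zero signal"):
            gsp.spectral_entropy(np.zeros(5), spec)


class TestSampEn:
    def test_periodic_series_is_regular(self):
        s = np.tile([0.0, 1.0, 0.0, -1.0], 20)
        assert gsp.sampen(s, m=2, r=0.5) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        s = rng.standard_normal(60)
        r = 0.2 * s.std(ddof=1)
        assert gsp.sampen(s, 2, r) == pytest.approx(
            sampen_bruteforce(s, 2, r), abs=1e-12)

    def test_shuffling_does_not_decrease_entropy(self, rng):
        t = np.arange(60)
        s = np.sin(2 * np.pi * t / 12) + 0.05 * rng.standard_normal(60)
        r = 0.2 * s.std(ddof=1)
        ordered = gsp.sampen(s, 2, r)
        shuffled = np.median([gsp.sampen(rng.permutation(s), 2, r)
                              for _ in range(100)])
        assert shuffled >= ordered

    @pytest.mark.parametrize("bad", [{"r": 0.0}, {"r": -1.0}])
    def test_invalid_tolerance_rejected(self, rng, bad):
        with pytest.raises(ValueError):
            gsp.sampen(rng.standard_normal(60), m=2, **bad)


class TestCohortTolerances:
    def _series(self, n_subj, sd, rng, n_ep=60):
        return sd * rng.standard_normal((n_subj, 3, 3, n_ep))

    def test_identical_subjects_recover_fifth_of_sd(self, rng):
        one = rng.standard_normal(60)
        arr = np.broadcast_to(one, (5, 3, 3, 60))
        r = gsp.cohort_tolerances(arr)
        assert np.allclose(r, 0.2 * one.std(ddof=1))

    def test_homogeneity_under_scaling(self, rng):
        arr = self._series(7, 1.0, rng)
        r1 = gsp.cohort_tolerances(arr)
        r2 = gsp.cohort_tolerances(3.0 * arr)
        assert np.allclose(r2, 3.0 * r1)

    def test_median_robust_to_single_outlier(self, rng):
        arr = self._series(5, 1.0, rng)
        spiked = arr.copy()
        spiked[0] *= 1000.0
        r_base = gsp.cohort_tolerances(arr)
        r_spiked = gsp.cohort_tolerances(spiked)
        # the median over 5 subjects moves only between middle order stats
        assert np.all(r_spiked < 10 * r_base)

    def test_zero_median_sd_rejected(self):
        arr = np.zeros((3, 3, 3, 60))
        with pytest.raises(ValueError):
            gsp.cohort_tolerances(arr)


class TestFeatureAssembly:
    def test_canonical_names_and_count(self):
        assert len(gsp.FEATURE_NAMES) == 45
        assert len(set(gsp.FEATURE_NAMES)) == 45
        assert gsp.FEATURE_NAMES[0] == "part0d_smoothness_global"
        assert gsp.FEATURE_NAMES[-1] == "alphapow_spread_sampen"

    def test_constant_epochs_zero_dynamics(self, rng):
        gv = rng.standard_normal((3, 3))
        es = np.repeat(rng.standard_normal((3, 3))[:, :, None], 60, axis=2)
        feats = gsp.extract_features(gv, es, tolerances=np.full((3, 3), 0.1))
        for fam in gsp.FAMILIES:
            for desc in gsp.DESCRIPTORS:
                assert feats[f"{fam}_{desc}_sd"] == pytest.approx(0.0, abs=1e-12)
                assert feats[f"{fam}_{desc}_mafd"] == pytest.approx(0.0, abs=1e-12)

    def test_epoch_mean_matches_recomputation(self, rng):
        gv = rng.standard_normal((3, 3))
        es = rng.standard_normal((3, 3, 60))
        feats = gsp.extract_features(gv, es)
        for i, fam in enumerate(gsp.FAMILIES):
            for j, desc in enumerate(gsp.DESCRIPTORS):
                assert feats[f"{fam}_{desc}_epoch_mean"] == pytest.approx(
                    es[i, j].mean())

    def test_missing_epochs_propagate_to_dynamics(self, rng):
        gv = rng.standard_normal((3, 3))
        es = rng.standard_normal((3, 3, 60))
        es[1, 2, 10] = np.nan
        feats = gsp.extract_features(gv, es)
        assert np.isnan(feats["part1d_spread_sd"])
        assert not np.isnan(feats["part1d_spread_epoch_mean"])

    def test_mafd_definition(self):
        s = np.array([0.0, 1.0, -1.0, 2.0])
        assert gsp.mafd(s) == pytest.approx((1 + 2 + 3) / 3)
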