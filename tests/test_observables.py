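"""Phases, Kuramoto order parameters, turbulence, metastability, FC."""

import numpy as np
import pytest

from hopfpert import observables as obs
from hopfpert.connectome import CouplingMatrix


class TestBandpassPhase:
    TR = 0.72

    def test_in_band_sinusoid_linear_phase(self):
        f = 0.04
        t = np.arange(600) * self.TR
        ts = np.sin(2 * np.pi * f * t)
        ph = obs.bandpass_phase(ts, self.TR)
        slope = np.polyfit(
            np.arange(ph.phases.shape[1]) * self.TR, np.unwrap(ph.phases[0]), 1
        )[0]
        assert np.abs(slope - 2 * np.pi * f) / (2 * np.pi * f) < 0.01

    def test_identical_nodes_identical_phases(self, rng):
        ts = rng.standard_normal(400)
        ph = obs.bandpass_phase(np.vstack([ts, ts]), self.TR)
        np.testing.assert_array_equal(ph.phases[0], ph.phases[1])

    def test_out_of_band_attenuated(self):
        t = np.arange(600) * self.TR
        out_band = np.sin(2 * np.pi * 0.2 * t)
        in_band = np.sin(2 * np.pi * 0.04 * t)
        ph = obs.bandpass_phase(np.vstack([out_band, in_band]), self.TR)
        # filter frequency-response oracle: stop-band RMS well below
        # pass-band; central window avoids the slow high-pass transient
        mid = ph.filtered[:, 150:-150]
        rms = np.sqrt((mid**2).mean(axis=1))
        assert rms[0] < 0.1 * rms[1]

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            obs.bandpass_phase(np.zeros((2, 100)), self.TR, band=(0.01, 0.8))

    def test_phases_in_range(self, rng):
        ph = obs.bandpass_phase(rng.standard_normal((4, 300)), self.TR)
        assert np.all(ph.phases > -np.pi - 1e-12)
        assert np.all(ph.phases <= np.pi + 1e-12)


class TestLocalKuramoto:
    def test_full_synchrony_gives_one(self, rng):
        phases = np.full((5, 20), 0.7)
        w = rng.uniform(0.1, 1.0, size=(5, 5))
        R = obs.local_kuramoto(phases, w)
        np.testing.assert_allclose(R, 1.0, atol=1e-12)

    def test_equally_weighted_antiphase_pair_cancels(self):
        # node sees itself and an antiphase partner with equal weight
        phases = np.array([[0.0], [np.pi]])
        w = np.ones((2, 2))
        R = obs.local_kuramoto(phases, w)
        np.testing.assert_allclose(R, 0.0, atol=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(10, 7))
        w = rng.uniform(0.05, 1.0, size=(10, 10))
        R = obs.local_kuramoto(phases, w)
        for t in range(7):
            for n in range(10):
                acc = sum(
                    w[n, p] * np.exp(1j * phases[p, t]) for p in range(10)
                ) / w[n].sum()
                assert R[n, t] == pytest.approx(abs(acc), abs=1e-12)

    def test_iid_uniform_phases_low_mean_R(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(1000, 5))
        w = np.exp(-0.18 * rng.uniform(0, 100, size=(1000, 1000)))
        w = 0.5 * (w + w.T)
        R = obs.local_kuramoto(phases, w)
        assert 0 < R.mean() < 0.2

    def test_edr_coupling_matrix_restores_self_weight(self, rng):
        # a CouplingMatrix (zero diagonal) must behave like the full EDR
        # kernel with unit self-weight
        d = np.abs(np.subtract.outer(rng.uniform(0, 50, 6), rng.uniform(0, 50, 6)))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        kernel = np.exp(-0.18 * d)
        zero_diag = kernel.copy()
        np.fill_diagonal(zero_diag, 0.0)
        cm = CouplingMatrix(weights=zero_diag, kind="EDR", lambda_decay=0.18)
        phases = rng.uniform(-np.pi, np.pi, size=(6, 4))
        np.testing.assert_allclose(
            obs.local_kuramoto(phases, cm), obs.local_kuramoto(phases, kernel)
        )

    def test_zero_row_sum_rejected(self):
        with pytest.raises(ValueError, match="row sums"):
            obs.local_kuramoto(np.zeros((2, 3)), np.zeros((2, 2)))

    def test_uniform_weights_reduce_to_global(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(8, 10))
        R = obs.local_kuramoto(phases, np.ones((8, 8)))
        gR = obs.global_kuramoto(phases)
        for n in range(8):
            np.testing.assert_allclose(R[n], gR, atol=1e-12)


class TestTurbulenceMetastability:
    def test_constant_field_zero(self):
        assert obs.amplitude_turbulence(np.full((4, 9), 0.3)) == 0.0

    def test_half_zero_half_one_is_half(self):
        R = np.concatenate([np.zeros(50), np.ones(50)]).reshape(10, 10)
        assert obs.amplitude_turbulence(R) == pytest.approx(0.5)

    def test_matches_two_pass_variance_oracle(self, rng):
        R = rng.uniform(0, 1, size=(20, 30))
        direct = np.sqrt(np.mean((R - R.mean()) ** 2))
        assert obs.amplitude_turbulence(R) == pytest.approx(direct, abs=1e-12)

    def test_full_synchrony_metastability_zero(self):
        phases = np.full((6, 11), 1.2)
        gR = obs.global_kuramoto(phases)
        np.testing.assert_allclose(gR, 1.0)
        assert obs.metastability(gR) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_phases_zero_global_order(self):
        phases = np.array([[0.0], [np.pi], [np.pi / 3], [np.pi / 3 + np.pi]])
        assert obs.global_kuramoto(phases)[0] == pytest.approx(0.0, abs=1e-12)

    def test_metastability_matches_sd_oracle(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(12, 40))
        gR = obs.global_kuramoto(phases)
        direct = np.abs(np.exp(1j * phases).mean(axis=0))
        np.testing.assert_allclose(gR, direct)
        assert obs.metastability(gR) == pytest.approx(np.std(direct), abs=1e-12)

    def test_global_phase_rotation_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(9, 25))
        w = rng.uniform(0.1, 1, size=(9, 9))
        shift = 1.234
        D0 = obs.amplitude_turbulence(obs.local_kuramoto(phases, w))
        D1 = obs.amplitude_turbulence(obs.local_kuramoto(phases + shift, w))
        assert D0 == pytest.approx(D1, abs=1e-12)
        M0 = obs.metastability(obs.global_kuramoto(phases))
        M1 = obs.metastability(obs.global_kuramoto(phases + shift))
        assert M0 == pytest.approx(M1, abs=1e-12)


class TestFC:
    def test_identical_nodes_unit_correlation(self, rng):
        ts = rng.standard_normal(100)
        fc = obs.functional_connectivity(np.vstack([ts, ts]))
        assert fc[0, 1] == pytest.approx(1.0)

    def test_sign_flip_anticorrelated(self, rng):
        ts = rng.standard_normal(100)
        fc = obs.functional_connectivity(np.vstack([ts, -ts]))
        assert fc[0, 1] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        ts = rng.standard_normal((6, 200))
        fc = obs.functional_connectivity(ts)
        c = np.cov(ts)
        sd = np.sqrt(np.diag(c))
        np.testing.assert_allclose(fc, c / np.outer(sd, sd), atol=1e-12)
        np.testing.assert_allclose(np.diag(fc), 1.0)
        np.testing.assert_allclose(fc, fc.T)


class TestFCMetrics:
    def test_identical_matrices(self, rng):
        ts = rng.standard_normal((8, 100))
        fc = obs.functional_connectivity(ts)
        fe = obs.fc_metrics(fc, fc)
        assert fe.eFC == 0.0
        assert fe.corrFC == pytest.approx(1.0)
        assert fe.ssimFC == pytest.approx(1.0)

    def test_sign_flipped_anticorrelated(self, rng):
        m = rng.standard_normal((6, 6))
        m = 0.5 * (m + m.T)
        iu = np.triu_indices(6, 1)
        m[iu] -= m[iu].mean()  # zero-mean off-diagonals
        m.T[iu] = m[iu]
        fe = obs.fc_metrics(-m, m)
        assert fe.corrFC == pytest.approx(-1.0)

    def test_eFC_matches_elementwise_oracle(self, rng):
        a = rng.uniform(-1, 1, size=(7, 7))
        b = rng.uniform(-1, 1, size=(7, 7))
        a, b = 0.5 * (a + a.T), 0.5 * (b + b.T)
        fe = obs.fc_metrics(a, b)
        iu = np.triu_indices(7, 1)
        expected_raw = np.sqrt(((a[iu] - b[iu]) ** 2).sum())
        assert fe.eFC_raw == pytest.approx(expected_raw, abs=1e-12)
        assert fe.eFC == pytest.approx(expected_raw / np.sqrt(iu[0].size), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            obs.fc_metrics(np.eye(3), np.eye(4))


class TestScalarErrors:
    @pytest.mark.parametrize(
        "a,b,expected", [(0.2, 0.2, 0.0), (0.19, 0.20, 0.01), (0.20, 0.19, 0.01)]
    )
    def test_absolute_difference(self, a, b, expected):
        assert obs.turbulence_error(a, b) == pytest.approx(expected)
        assert obs.metastability_error(a, b) == pytest.approx(expected)
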