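"""Connectivity metrics: closed-form cases, bias behaviour, invariances."""

import numpy as np
import pytest
from scipy.signal import hilbert

from restspectra.cohort import make_coupled_pair, narrowband_noise
from restspectra.connectivity import (control_metrics, cross_spectrum,
                                      fc_tensor, orth_pow_corr, wpli,
                                      wpli_subsampled)
from restspectra.data import EpochSet
from restspectra.spectral import morlet_transform


def analytic(x):
    return hilbert(np.asarray(x, dtype=float))


class TestCrossSpectrum:
    def test_self_cross_spectrum_is_power(self, rng):
        z = analytic(rng.standard_normal(500))
        x = cross_spectrum(z, z)
        np.testing.assert_allclose(np.imag(x), 0.0, atol=1e-9)
        np.testing.assert_allclose(np.real(x), np.abs(z) ** 2, rtol=1e-12)

    def test_conjugate_symmetry(self, rng):
        zi = analytic(rng.standard_normal(500))
        zj = analytic(rng.standard_normal(500))
        np.testing.assert_allclose(cross_spectrum(zi, zj),
                                   np.conj(cross_spectrum(zj, zi)))

    def test_mean_phase_equals_lag(self):
        lag = 0.7
        a, b = make_coupled_pair(8192, 256.0, 10.0, lag, seed=2)
        x = cross_spectrum(analytic(a), analytic(b))
        assert np.angle(np.mean(x)) == pytest.approx(lag, abs=0.05)


class TestWPLI:
    def test_quarter_cycle_lag_gives_one(self):
        a, b = make_coupled_pair(4096, 256.0, 10.0, np.pi / 2, seed=0)
        assert wpli(cross_spectrum(analytic(a), analytic(b))) > 0.99

    def test_zero_lag_identical_signals_give_zero(self, rng):
        z = analytic(rng.standard_normal(1000))
        assert wpli(cross_spectrum(z, z)) == 0.0

    def test_independent_signals_small(self, rng):
        zi = analytic(rng.standard_normal(1000))
        zj = analytic(rng.standard_normal(1000))
        assert wpli(cross_spectrum(zi, zj)) < 0.1


class TestWPLISubsampled:
    def _epoch_cross(self, rng, n_epochs, n=200):
        out = []
        for _ in range(n_epochs):
            zi = analytic(rng.standard_normal(n))
            zj = analytic(rng.standard_normal(n))
            out.append(cross_spectrum(zi, zj))
        return np.array(out)

    def test_equals_direct_wpli_with_exactly_15_epochs(self, rng):
        x = self._epoch_cross(rng, 15)
        est = wpli_subsampled(x, n_epochs=15, n_reps=5, seed=0)
        assert est == pytest.approx(wpli(x.ravel()), abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        x = self._epoch_cross(rng, 40)
        assert wpli_subsampled(x, seed=9) == wpli_subsampled(x, seed=9)

    def test_too_few_epochs_raise(self, rng):
        x = self._epoch_cross(rng, 10)
        with pytest.raises(ValueError):
            wpli_subsampled(x, n_epochs=15)

    def test_removes_sample_size_bias(self):
        """Under independence the subsampled estimator has the same mean
        whether 15 or 60 epochs are available, while the naive wPLI on
        all epochs shrinks with more data (its small-sample bias)."""
        rng = np.random.default_rng(77)
        sub15, sub60, naive15, naive60 = [], [], [], []
        for _ in range(120):
            x60 = self._epoch_cross(rng, 60, n=40)
            x15 = x60[:15]
            sub15.append(wpli_subsampled(x15, n_reps=20, seed=1))
            sub60.append(wpli_subsampled(x60, n_reps=20, seed=1))
            naive15.append(wpli(x15.ravel()))
            naive60.append(wpli(x60.ravel()))
        gap_sub = abs(np.mean(sub15) - np.mean(sub60))
        gap_naive = abs(np.mean(naive15) - np.mean(naive60))
        assert gap_sub < 0.01
        assert gap_naive > 3 * gap_sub


class TestOrthPowCorr:
    def test_identical_signals_give_zero(self, rng):
        z = analytic(rng.standard_normal(600))
        assert orth_pow_corr(z, z) == 0.0

    def test_independent_signals_small(self, rng):
        zi = analytic(rng.standard_normal(2000))
        zj = analytic(rng.standard_normal(2000))
        assert abs(orth_pow_corr(zi, zj)) < 0.1

    def test_increases_with_injected_envelope_correlation(self):
        """Shared-envelope pairs produce positive values growing with the
        injected envelope correlation."""
        vals = []
        for c in (0.2, 0.5, 0.8):
            acc = []
            for s in range(8):
                a, b = make_coupled_pair(16384, 256.0, 10.0, np.pi / 2,
                                         env_corr=c, seed=s)
                acc.append(orth_pow_corr(analytic(a), analytic(b)))
            vals.append(np.mean(acc))
        assert vals[0] > 0
        assert vals[0] < vals[1] < vals[2]


class TestControlMetrics:
    def test_identical_signals(self, rng):
        z = analytic(rng.standard_normal(500))
        m = control_metrics(z, z)
        assert m["COH"] == pytest.approx(1.0, abs=1e-9)
        assert m["PLV"] == pytest.approx(1.0, abs=1e-9)
        assert m["iCOH"] == pytest.approx(0.0, abs=1e-9)
        assert m["PowCorr"] == pytest.approx(1.0, abs=1e-9)

    def test_quarter_lag_equal_amplitude_makes_coherency_imaginary(self, rng):
        z = analytic(narrowband_noise(4096, 256.0, 10.0, 1.0, rng))
        zl = z * np.exp(-1j * np.pi / 2)
        m = control_metrics(z, zl)
        assert abs(m["iCOH"]) == pytest.approx(m["COH"], abs=1e-9)

    def test_independent_signals_small(self, rng):
        zi = analytic(rng.standard_normal(2000))
        zj = analytic(rng.standard_normal(2000))
        m = control_metrics(zi, zj)
        assert m["COH"] < 0.1 and m["PLV"] < 0.1
        assert abs(m["iCOH"]) < 0.1 and abs(m["PowCorr"]) < 0.1

    def test_zero_power_raises(self):
        with pytest.raises(ValueError):
            control_metrics(np.zeros(10, complex), np.ones(10, complex))


class TestVolumeConductionRobustness:
    def test_common_zero_lag_signal_creates_no_spurious_coupling(self):
        """Two channels sharing only a strong zero-lag common component
        (volume conduction with no true interaction) show large COH/PLV
        but near-zero wPLI and iCOH, which discard zero-lag coupling."""
        rng = np.random.default_rng(5)
        n = 16384
        s1 = narrowband_noise(n, 256.0, 10.0, 1.0, rng)
        s2 = narrowband_noise(n, 256.0, 10.0, 1.0, rng)
        common = narrowband_noise(n, 256.0, 10.0, 1.0, rng)
        za, zb = analytic(s1 + 3 * common), analytic(s2 + 3 * common)

        m = control_metrics(za, zb)
        assert m["COH"] > 0.7
        assert m["PLV"] > 0.7
        assert abs(m["iCOH"]) < 0.1
        assert wpli(cross_spectrum(za, zb)) < 0.15


class TestFCTensor:
    @pytest.fixture(scope="class")
    def wc(self):
        rng = np.random.default_rng(42)
        n, srate = int(2.5 * 256), 256.0
        epochs = []
        for _ in range(16):
            a, b = make_coupled_pair(n, srate, 10.0, np.pi / 2,
                                     seed=int(rng.integers(2 ** 31)))
            c = rng.standard_normal(n)
            epochs.append(np.stack([a + 0.3 * rng.standard_normal(n),
                                    b + 0.3 * rng.standard_normal(n), c]))
        data = np.stack(epochs)
        cond = np.array(["EO"] * 8 + ["EC"] * 8)
        es = EpochSet(data, cond, srate, ["x", "y", "z"])
        return morlet_transform(es)

    def test_shapes_and_ranges(self, wc):
        fc = fc_tensor(wc, n_epochs=8, n_reps=10, seed=0)
        assert fc.values.shape == (3, 27, 2, 6)
        w = fc.metric("wPLI")
        assert np.all((w >= 0) & (w <= 1))
        assert np.all(fc.metric("COH") <= 1 + 1e-9)
        assert np.all(np.abs(fc.metric("orthPowCorr")) <= 1 + 1e-9)

    def test_matches_pairwise_functions(self, wc):
        """The vectorised tensor agrees with the scalar per-pair metrics."""
        fc = fc_tensor(wc, n_epochs=8, n_reps=10, seed=0)
        fi = int(np.argmin(np.abs(fc.freqs - 10.0)))
        sel = wc.condition == "EO"
        c = wc.coeffs[fi][sel]
        zi = c[:, 0, :].ravel()
        zj = c[:, 1, :].ravel()
        m = control_metrics(zi, zj)
        li = 0  # link (0, 1)
        ci = 0  # EO
        for name in ("PowCorr", "COH", "iCOH", "PLV"):
            assert fc.values[li, fi, ci, fc.metrics.index(name)] == \
                pytest.approx(m[name], abs=1e-9)
        assert fc.values[li, fi, ci, fc.metrics.index("orthPowCorr")] == \
            pytest.approx(orth_pow_corr(zi, zj), abs=1e-9)

    def test_coupled_link_dominates_wpli(self, wc):
        fc = fc_tensor(wc, n_epochs=8, n_reps=20, seed=1)
        fi = int(np.argmin(np.abs(fc.freqs - 10.0)))
        w = fc.metric("wPLI")[:, fi, :]
        assert np.all(w[0] > 0.9)           # link (x, y) is coupled
        assert np.all(w[0] > w[1] + 0.3)    # (x, z) and (y, z) are not
        assert np.all(w[0] > w[2] + 0.3)
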