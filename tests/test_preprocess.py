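"""Filtering, resampling, referencing, epoching and inclusion rules."""

import numpy as np
import pytest
from scipy.signal import freqz

from restspectra.data import Block, EpochSet, Recording
from restspectra.preprocess import (average_reference, bandpass_fir,
                                    design_bandpass, epoch, inclusion_check,
                                    largest_bad_neighbourhood, resample)


def make_recording(data, srate=256.0, channels=None, blocks=None):
    channels = channels or [f"ch{i}" for i in range(data.shape[0])]
    if blocks is None:
        dur = data.shape[1] / srate
        blocks = [Block("EO", 0.0, dur)]
    return Recording(data=data, srate=srate, channels=channels, blocks=blocks)


class TestBandpass:
    def test_designed_filter_gains(self):
        """Passband ~1, >=40 dB stopband at 40 Hz, DC removed."""
        srate = 256.0
        h = design_bandpass(1.0, 32.0, 2000, srate)
        w, resp = freqz(h, worN=4096, fs=srate)

        def gain(f):
            return np.abs(resp[np.argmin(np.abs(w - f))])

        assert abs(gain(10.0) - 1.0) < 0.01
        assert gain(40.0) < 10 ** (-40 / 20)
        assert gain(0.0) < 0.01

    def test_impulse_response_symmetric(self):
        h = design_bandpass(1.0, 32.0, 2000, 256.0)
        np.testing.assert_allclose(h, h[::-1], atol=1e-15)

    def test_zero_phase_on_sine(self):
        """A 10 Hz sine passes with unit gain and no phase shift."""
        srate = 256.0
        t = np.arange(int(34 * srate)) / srate
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        rec = make_recording(x, srate, blocks=[Block("EO", 0.0, 34.0)])
        out = bandpass_fir(rec, pad=2.0)
        mid = slice(int(10 * srate), int(24 * srate))
        np.testing.assert_allclose(out.data[0, mid], x[0, mid], atol=0.02)

    def test_dc_offset_removed(self):
        srate = 256.0
        x = np.full((1, int(34 * srate)), 100.0)
        rec = make_recording(x, srate, blocks=[Block("EO", 0.0, 34.0)])
        out = bandpass_fir(rec)
        mid = slice(int(10 * srate), int(24 * srate))
        assert np.max(np.abs(out.data[0, mid])) < 1.0

    def test_short_block_raises(self):
        srate = 256.0
        x = np.zeros((1, int(2 * srate)))  # 2 s + 4 s pad < 7.8 s kernel
        rec = make_recording(x, srate, blocks=[Block("EO", 0.0, 2.0)])
        with pytest.raises(ValueError, match="block"):
            bandpass_fir(rec, order=2000, pad=2.0)


class TestResample:
    def test_rate_and_length(self):
        rng = np.random.default_rng(0)
        rec = make_recording(rng.standard_normal((2, 2048 * 30)), 2048.0)
        out = resample(rec, 1000.0)
        assert out.srate == 1000.0
        assert out.data.shape[1] == 30000

    def test_identity_when_same_rate(self):
        rec = make_recording(np.ones((1, 256)), 256.0)
        out = resample(rec, 256.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_low_frequency_sine_survives(self):
        srate = 2048.0
        t = np.arange(int(10 * srate)) / srate
        rec = make_recording(np.sin(2 * np.pi * 5 * t)[None, :], srate)
        out = resample(rec, 1000.0)
        mid = out.data[0, 1000:-1000]
        amp = np.sqrt(2.0) * np.std(mid)
        assert abs(amp - 1.0) < 0.01


class TestReference:
    def test_channel_mean_is_zero_and_idempotent(self, rng):
        data = rng.standard_normal((4, 3, 100)) + 5.0
        es = EpochSet(data, np.array(["EO"] * 4), 100.0, ["a", "b", "c"])
        ref = average_reference(es)
        assert np.max(np.abs(ref.data.mean(axis=1))) < 1e-10
        again = average_reference(ref)
        np.testing.assert_allclose(again.data, ref.data, atol=1e-12)

    def test_two_channel_antisymmetric_unchanged(self):
        data = np.stack([np.ones((2, 10)), -np.ones((2, 10))], axis=1)
        es = EpochSet(data, np.array(["EO"] * 2), 10.0, ["a", "b"])
        np.testing.assert_allclose(average_reference(es).data, data)


class TestEpoch:
    def test_counts_in_clean_blocks(self):
        srate = 100.0
        blocks = [Block("EO", 0.0, 60.0), Block("EC", 60.0, 60.0)]
        rec = make_recording(np.zeros((1, 12000)), srate, blocks=blocks)
        es = epoch(rec, 2.5)
        assert (es.condition == "EO").sum() == 24
        assert (es.condition == "EC").sum() == 24

    def test_mask_shifts_epochs(self):
        srate = 100.0
        rec = make_recording(np.zeros((1, 3000)), srate,
                             blocks=[Block("EO", 0.0, 30.0)])
        es = epoch(rec, 2.5, artifact_mask=[(0.0, 5.0)])
        assert es.n_epochs == 10

    def test_full_mask_yields_empty_with_warning(self):
        rec = make_recording(np.zeros((1, 1000)), 100.0)
        with pytest.warns(UserWarning):
            es = epoch(rec, 2.5, artifact_mask=[(0.0, 10.0)])
        assert es.n_epochs == 0

    def test_epochs_reproduce_samples_exactly(self, rng):
        srate = 100.0
        data = rng.standard_normal((2, 1000))
        rec = make_recording(data, srate, blocks=[Block("EO", 0.0, 10.0)])
        es = epoch(rec, 2.5)
        recon = np.concatenate(list(es.data), axis=1)
        np.testing.assert_array_equal(recon, data)

    def test_no_epoch_spans_block_boundary(self):
        srate = 100.0
        blocks = [Block("EO", 0.0, 3.0), Block("EC", 3.0, 3.0)]
        rec = make_recording(np.zeros((1, 600)), srate, blocks=blocks)
        es = epoch(rec, 2.5)
        # each 3 s block fits one 2.5 s epoch; the 0.5 s tails are dropped
        assert es.n_epochs == 2
        assert list(es.condition) == ["EO", "EC"]


class TestInclusion:
    @pytest.mark.parametrize("n_eo,n_ec,usable,adj,ics,good,included,reason", [
        (14, 20, 61, 0, 0, 61, False, "epochs"),
        (20, 20, 50, 0, 0, 61, False, "channels"),
        (20, 20, 61, 4, 0, 61, False, "channels"),
        (20, 20, 61, 0, 4, 40, True, None),     # 40 - 4 = 36 >= 35
        (20, 20, 61, 0, 10, 40, False, "components"),
        (15, 15, 51, 3, 0, 61, True, None),     # all thresholds exactly met
    ])
    def test_criteria(self, n_eo, n_ec, usable, adj, ics, good, included,
                      reason):
        data = np.zeros((max(n_eo + n_ec, 1), 2, 10))
        cond = np.array(["EO"] * n_eo + ["EC"] * n_ec)
        es = EpochSet(data[: len(cond)], cond, 100.0, ["a", "b"])
        rep = inclusion_check(es, usable, adj, ics, good)
        assert rep.included is included
        if reason:
            assert reason in rep.reasons

    def test_pure_function(self):
        es = EpochSet(np.zeros((30, 2, 10)), np.array(["EO"] * 15 + ["EC"] * 15),
                      100.0, ["a", "b"])
        r1 = inclusion_check(es, 61, 0, 0, 61)
        r2 = inclusion_check(es, 61, 0, 0, 61)
        assert r1.to_dict() == r2.to_dict()

    def test_negative_counts_raise(self):
        es = EpochSet(np.zeros((1, 2, 10)), np.array(["EO"]), 100.0, ["a", "b"])
        with pytest.raises(ValueError):
            inclusion_check(es, -1, 0, 0, 61)


def test_largest_bad_neighbourhood_counts_contiguous_patch():
    names = ["a", "b", "c", "d"]
    pos = np.array([[0, 0, 0], [0.03, 0, 0], [0.06, 0, 0], [0.5, 0, 0]])
    assert largest_bad_neighbourhood(["a", "b", "d"], pos, names) == 2
    assert largest_bad_neighbourhood([], pos, names) == 0
    assert largest_bad_neighbourhood(["d"], pos, names) == 1
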