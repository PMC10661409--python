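"""Re-referencing, filtering, artifact rejection and epoching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegdx.core import CHANNELS_10_20, EEGRecording
from eegdx.preprocess import (PreprocessConfig, bandpass, make_epochs,
                              reject_windows, rereference)


def _rec(data, fs=500.0, labels=None):
    data = np.asarray(data, dtype=float)
    labels = labels or tuple(f"ch{i}" for i in range(data.shape[0]))
    return EEGRecording(data=data, fs=fs, channel_labels=labels,
                        subject_id="S1", group="CN")


class TestRereference:
    def test_zero_reference_is_identity_on_scalp(self):
        scalp = np.random.default_rng(0).standard_normal((2, 100))
        data = np.vstack([scalp, np.zeros((2, 100))])
        rec = _rec(data, labels=("c1", "c2", "A1", "A2"))
        out = rereference(rec)
        assert np.allclose(out.data, scalp)
        assert out.channel_labels == ("c1", "c2")

    def test_constant_reference_subtracts_mean(self):
        s = np.arange(50, dtype=float)
        data = np.vstack([s, np.full(50, 2.0), np.full(50, 4.0)])
        rec = _rec(data, labels=("c1", "A1", "A2"))
        out = rereference(rec)
        assert np.allclose(out.data[0], s - 3.0)

    def test_full_montage_drops_to_19_channels(self):
        data = np.random.default_rng(1).standard_normal((21, 100))
        rec = _rec(data, labels=CHANNELS_10_20 + ("A1", "A2"))
        out = rereference(rec)
        assert out.n_channels == 19
        assert out.reference == "A1-A2"

    def test_missing_references_is_identity_with_notice(self):
        data = np.random.default_rng(2).standard_normal((3, 100))
        rec = _rec(data)
        out = rereference(rec)
        assert out is rec

    def test_single_reference_is_ambiguous(self):
        data = np.zeros((2, 100))
        rec = _rec(data, labels=("c1", "A1"))
        with pytest.raises(ValueError, match="ambiguous"):
            rereference(rec)


class TestBandpass:
    def test_response_matches_designed_transfer_function(self):
        # Oracle: the zero-phase (forward-backward) gain is |H(f)|^2 of
        # the designed Butterworth SOS cascade.
        from scipy import signal as sps
        fs, t = 500.0, np.arange(0, 10, 1 / 500.0)
        cfg = PreprocessConfig()
        sos = sps.butter(cfg.filter_order, [cfg.low_hz, cfg.high_hz],
                         btype="bandpass", fs=fs, output="sos")
        for freq in (60.0, 10.0):
            rec = _rec(np.sin(2 * np.pi * freq * t)[None, :], fs=fs)
            out = bandpass(rec, cfg)
            # steady-state section only (edge transients excluded)
            mid = slice(2000, -2000)
            ratio = np.sqrt((out.data[0, mid] ** 2).mean()
                            / (rec.data[0, mid] ** 2).mean())
            _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
            expected = np.abs(h[0]) ** 2
            assert ratio == pytest.approx(expected, abs=0.02)
        # qualitatively: 10 Hz passes essentially unchanged, 60 Hz is
        # strongly attenuated
        assert np.abs(sps.sosfreqz(sos, worN=[10.0], fs=fs)[1][0]) ** 2 \
            == pytest.approx(1.0, abs=0.05)
        assert np.abs(sps.sosfreqz(sos, worN=[60.0], fs=fs)[1][0]) ** 2 < 0.25

    def test_zero_in_zero_out(self):
        rec = _rec(np.zeros((2, 1000)))
        out = bandpass(rec, PreprocessConfig())
        assert np.allclose(out.data, 0.0)
        assert out.n_samples == rec.n_samples

    def test_low_rate_violates_nyquist(self):
        rec = _rec(np.zeros((1, 1000)), fs=80.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, PreprocessConfig())


class TestRejectWindows:
    def test_constant_channels_keep_everything(self):
        rec = _rec(np.ones((3, 5000)))
        out, mask = reject_windows(rec, PreprocessConfig())
        assert not mask.any()
        assert out.n_samples == rec.n_samples

    def test_single_hot_window_excised(self):
        fs = 500.0
        rng = np.random.default_rng(3)
        data = rng.standard_normal((2, 5000))  # SD ~1, well under 17
        # inflate window 4 (samples 1000:1250) on channel 1 to SD ~20
        data[1, 1000:1250] = 20.0 * rng.standard_normal(250)
        rec = _rec(data, fs=fs)
        out, mask = reject_windows(rec, PreprocessConfig())
        assert mask.tolist().count(True) == 1 and mask[4]
        assert out.n_samples == 5000 - 250
        # remaining data is the original with that window cut out
        expected = np.concatenate([data[:, :1000], data[:, 1250:]], axis=1)
        assert np.array_equal(out.data, expected)

    def test_huge_threshold_is_vacuous(self):
        rng = np.random.default_rng(4)
        rec = _rec(rng.standard_normal((2, 5000)))
        cfg = PreprocessConfig().copy_with(artifact_sd_threshold=1e12)
        out, mask = reject_windows(rec, cfg)
        assert not mask.any()
        assert np.array_equal(out.data, rec.data)

    def test_rejection_is_idempotent(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((2, 5000))
        data[0, 2000:2250] = 25.0 * rng.standard_normal(250)
        rec = _rec(data)
        once, _ = reject_windows(rec, PreprocessConfig())
        twice, mask2 = reject_windows(once, PreprocessConfig())
        assert not mask2.any()
        assert np.array_equal(once.data, twice.data)


class TestMakeEpochs:
    def test_minute_at_500hz_gives_29_epochs(self):
        rec = _rec(np.zeros((2, 30000)))
        eps = make_epochs(rec, PreprocessConfig())
        assert len(eps) == 29

    @pytest.mark.parametrize("seconds,expected", [(4.0, 1), (5.0, 1),
                                                  (6.0, 2), (3.9, 0)])
    def test_boundary_epoch_counts(self, seconds, expected):
        rec = _rec(np.zeros((1, int(seconds * 500))))
        assert len(make_epochs(rec, PreprocessConfig())) == expected

    def test_epoch_provenance_and_grid(self):
        rec = _rec(np.arange(30000, dtype=float)[None, :])
        eps = make_epochs(rec, PreprocessConfig())
        for k, ep in enumerate(eps):
            assert ep.epoch_index == k
            assert ep.data[0, 0] == k * 1000  # 50% overlap of 2000 samples

    @given(n_samples=st.integers(100, 20000),
           epoch_s=st.floats(0.5, 5.0),
           overlap=st.floats(0.0, 0.9))
    @settings(max_examples=50, deadline=None)
    def test_count_formula_matches_enumeration(self, n_samples, epoch_s,
                                               overlap):
        fs = 100.0
        cfg = PreprocessConfig().copy_with(epoch_length_s=epoch_s,
                                           overlap_fraction=overlap)
        rec = _rec(np.zeros((1, n_samples)), fs=fs)
        eps = make_epochs(rec, cfg)
        L = int(round(epoch_s * fs))
        step = max(1, int(round(L * (1 - overlap))))
        starts = [s for s in range(0, n_samples, step) if s + L <= n_samples
                  and s % step == 0]
        assert len(eps) == len(starts)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig().copy_with(overlap_fraction=1.0).validate()
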