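"""Readers/writers, bandpass filter, segmentation, z-scoring."""

import numpy as np
import pytest

import eegclassify as eeg
from eegclassify import preprocess
from eegclassify.edf import EDFFormatError, edf_quantization_step
from eegclassify.preprocess import (TextFormatError, n_epochs_expected,
                                    read_concat_text, write_concat_text)


@pytest.fixture(scope="module")
def rec_250():
    params = eeg.SynthParams(fs=250.0, duration=20.0, n_channels=19,
                             channel_names=eeg.synth.DATASET1_CHANNELS)
    return eeg.gen_recording(params, "sub01", "control", seed=11)


class TestEdfIO:
    def test_round_trip_within_quantization(self, rec_250, tmp_path):
        path = tmp_path / "sub01.edf"
        eeg.write_edf(rec_250, path)
        back = eeg.read_edf(path)
        assert back.fs == 250.0
        assert back.channel_names == rec_250.channel_names
        step = edf_quantization_step(rec_250.data)
        err = np.abs(back.data - rec_250.data[:, :back.n_samples]).max()
        assert err <= 1.5 * step

    def test_reads_19_channels_at_250hz(self, rec_250, tmp_path):
        path = tmp_path / "x.edf"
        eeg.write_edf(rec_250, path)
        back = eeg.read_edf(path)
        assert back.n_channels == 19
        assert back.fs == 250.0
        assert back.subject_id == "x"  # filename stem

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.edf"
        path.write_bytes(b"")
        with pytest.raises(EDFFormatError):
            eeg.read_edf(path)

    def test_garbage_file_is_format_error(self, tmp_path):
        path = tmp_path / "bad.edf"
        path.write_bytes(b"not an edf file at all" * 30)
        with pytest.raises(EDFFormatError):
            eeg.read_edf(path)


class TestConcatText:
    def test_round_trip_exact(self, tmp_path):
        params = eeg.SynthParams(duration=5.0)
        rec = eeg.gen_recording(params, "m1", "patient", seed=2)
        path = tmp_path / "m1.txt"
        write_concat_text(rec, path)
        back = read_concat_text(path, rec.n_channels, rec.fs,
                                channel_names=rec.channel_names)
        np.testing.assert_allclose(back.data, rec.data, rtol=1e-9)

    def test_dataset2_geometry(self, tmp_path):
        data = np.arange(16 * 7680, dtype=float)
        path = tmp_path / "d2.txt"
        np.savetxt(path, data)
        rec = read_concat_text(path, 16, 128.0)
        assert rec.data.shape == (16, 7680)

    def test_channel_blocks_are_contiguous(self, tmp_path):
        path = tmp_path / "tiny.txt"
        path.write_text("\n".join(str(v) for v in range(1, 10)))
        rec = read_concat_text(path, 3, 10.0)
        np.testing.assert_array_equal(rec.data[0], [1, 2, 3])
        np.testing.assert_array_equal(rec.data[1], [4, 5, 6])
        np.testing.assert_array_equal(rec.data[2], [7, 8, 9])

    def test_indivisible_count_is_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("\n".join(str(v) for v in range(10)))
        with pytest.raises(TextFormatError):
            read_concat_text(path, 3, 10.0)

    def test_non_numeric_token_is_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1\n2\nbanana\n4\n5\n6\n")
        with pytest.raises(TextFormatError):
            read_concat_text(path, 3, 10.0)


class TestBandpass:
    def _sine(self, freq, fs=250.0, dur=10.0):
        t = np.arange(int(fs * dur)) / fs
        data = np.sin(2 * np.pi * freq * t)[None, :]
        return eeg.Recording("s", "control", fs, ["Cz"], data)

    def test_stopband_attenuation_60hz(self):
        rec = self._sine(60.0)
        out = eeg.bandpass(rec, 0.5, 50.0)
        mid = slice(500, -500)  # ignore filter edge transients
        assert np.sqrt(np.mean(out.data[0, mid] ** 2)) <= 0.1 * np.sqrt(
            np.mean(rec.data[0, mid] ** 2))

    def test_passband_preserved_10hz(self):
        rec = self._sine(10.0)
        out = eeg.bandpass(rec, 0.5, 50.0)
        mid = slice(500, -500)
        rms_in = np.sqrt(np.mean(rec.data[0, mid] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, mid] ** 2))
        assert abs(rms_out - rms_in) <= 0.05 * rms_in

    def test_zero_in_zero_out(self):
        rec = eeg.Recording("s", "control", 250.0, ["Cz"],
                            np.zeros((1, 2500)))
        out = eeg.bandpass(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_linearity(self, rng):
        x = rng.standard_normal((2, 2500))
        y = rng.standard_normal((2, 2500))
        mk = lambda d: eeg.Recording("s", "control", 250.0, ["a", "b"], d)
        fa = eeg.bandpass(mk(x)).data
        fb = eeg.bandpass(mk(y)).data
        fab = eeg.bandpass(mk(3.0 * x - 2.0 * y)).data
        np.testing.assert_allclose(fab, 3.0 * fa - 2.0 * fb, rtol=1e-8,
                                   atol=1e-8)

    def test_above_nyquist_rejected(self, rec_250):
        with pytest.raises(ValueError):
            eeg.bandpass(rec_250, 0.5, 130.0)


class TestSegment:
    def test_epoch_sample_counts(self, rec_250):
        ep = eeg.segment(rec_250, 6.0, 2.0)
        assert ep.n_samples == 1500  # 6 s at 250 Hz
        assert ep.n_channels == 19

    def test_window_count_formula(self):
        params = eeg.SynthParams(fs=128.0, duration=60.0)
        rec = eeg.gen_recording(params, "s", "control", seed=1)
        ep = eeg.segment(rec, 6.0, 2.0)
        assert rec.n_samples == 7680
        assert ep.n_epochs == (7680 - 768) // 512 + 1 == 14

    def test_exact_one_window(self):
        rec = eeg.Recording("s", "control", 100.0, ["Cz"],
                            np.random.default_rng(0).normal(size=(1, 600)))
        ep = eeg.segment(rec, 6.0, 2.0)
        assert ep.n_epochs == 1
        np.testing.assert_array_equal(ep.data[0, 0], rec.data[0])

    def test_short_recording_warns_and_empties(self):
        rec = eeg.Recording("s", "control", 100.0, ["Cz"],
                            np.zeros((1, 100)))
        with pytest.warns(UserWarning):
            ep = eeg.segment(rec, 6.0, 2.0)
        assert ep.n_epochs == 0

    def test_half_open_zero_based_windows(self):
        data = np.arange(20, dtype=float)[None, :]
        rec = eeg.Recording("s", "control", 1.0, ["Cz"], data)
        ep = eeg.segment(rec, 6.0, 2.0)  # L=6, S=4
        np.testing.assert_array_equal(ep.data[0, 0], np.arange(0, 6))
        np.testing.assert_array_equal(ep.data[1, 0], np.arange(4, 10))

    def test_cohort_epoch_count_matches_closed_form(self, small_cohort):
        ep = eeg.segment_cohort(small_cohort, 6.0, 2.0)
        expected = sum(n_epochs_expected(r.n_samples, r.fs, 6.0, 2.0)
                       for r in small_cohort)
        assert ep.n_epochs == expected

    def test_invalid_overlap_rejected(self, rec_250):
        with pytest.raises(ValueError):
            eeg.segment(rec_250, 2.0, 2.0)


class TestZscore:
    def test_standardizes_each_channel(self, small_cohort):
        ep = eeg.segment(small_cohort[0], 6.0, 2.0)
        z = eeg.zscore_epochs(ep)
        np.testing.assert_allclose(z.data.mean(axis=-1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.data.std(axis=-1), 1.0, atol=1e-10)

    def test_constant_channel_unchanged(self):
        data = np.full((1, 1, 100), 7.0)
        ep = eeg.EpochSet(data, 100.0, ["Cz"], ["s"], ["control"], 1.0, 0.0)
        z = eeg.zscore_epochs(ep)
        np.testing.assert_array_equal(z.data, data)

    def test_idempotent(self, small_cohort):
        ep = eeg.segment(small_cohort[0], 6.0, 2.0)
        once = eeg.zscore_epochs(ep)
        twice = eeg.zscore_epochs(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)


class TestManifest:
    def test_cohort_save_load_round_trip(self, tmp_path, small_cohort):
        manifest = eeg.save_cohort(small_cohort[:3], tmp_path / "c",
                                   fmt="text")
        back = eeg.load_cohort(manifest, n_channels=16, fs=128.0)
        assert [r.subject_id for r in back] == \
            [r.subject_id for r in small_cohort[:3]]
        assert [r.label for r in back] == \
            [r.label for r in small_cohort[:3]]
        np.testing.assert_allclose(back[0].data, small_cohort[0].data,
                                   rtol=1e-9)

    def test_manifest_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("subject_id,path\na,b\n")
        with pytest.raises(ValueError):
            preprocess.read_manifest(p)
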