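import numpy as np
import pytest

from heartprint.fiducials import FiducialSet
from heartprint.records import (EcgRecord, preprocess, read_csv, read_manifest,
                                read_wfdb, resample_record, write_csv,
                                write_wfdb)

FS = 500.0


def _record(samples, fs=FS, fids=None):
    return EcgRecord("s000", "1", "i", fs, np.asarray(samples, float),
                     truth_fiducials=fids)


class TestEcgRecord:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            _record([1.0, 2.0], fs=0.0)
        with pytest.raises(ValueError):
            _record([])
        with pytest.raises(ValueError):
            _record([1.0, np.nan])

    def test_truth_fiducials_must_be_in_range(self):
        with pytest.raises(ValueError):
            _record(np.zeros(100), fids=FiducialSet(r_peaks=np.array([150])))

    def test_duration(self):
        assert _record(np.zeros(10_000)).duration_s == 20.0


class TestWfdbIO:
    def test_round_trip(self, tmp_path):
        rec = _record(np.sin(np.arange(1000) / 30.0))
        write_wfdb(rec, tmp_path / "s000_1")
        back = read_wfdb(tmp_path / "s000_1", lead="i")
        assert back.fs == FS
        assert len(back) == 1000
        assert back.subject_id == "s000" and back.session_id == "1"
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-3)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_wfdb(tmp_path / "absent")

    def test_unknown_lead(self, tmp_path):
        write_wfdb(_record(np.zeros(64)), tmp_path / "r")
        with pytest.raises(ValueError, match="lead"):
            read_wfdb(tmp_path / "r", lead="v5")

    def test_manifest_overrides_identity(self, tmp_path):
        write_wfdb(_record(np.zeros(64)), tmp_path / "rec07")
        (tmp_path / "manifest.txt").write_text("rec07 subjA 3\n")
        manifest = read_manifest(tmp_path / "manifest.txt")
        rec = read_wfdb(tmp_path / "rec07", manifest=manifest)
        assert (rec.subject_id, rec.session_id) == ("subjA", "3")


class TestCsvIO:
    def test_round_trip_and_duration(self, tmp_path):
        rec = _record(np.linspace(-1, 1, 5000))
        write_csv(rec, tmp_path / "s000_1.csv")
        back = read_csv(tmp_path / "s000_1.csv", fs=1000.0)
        assert back.duration_s == 5.0
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-6)

    def test_header_skipped_when_flagged(self, tmp_path):
        (tmp_path / "x_1.csv").write_text("amplitude\n0.1\n0.2\n")
        rec = read_csv(tmp_path / "x_1.csv", fs=100.0, has_header=True)
        assert len(rec) == 2

    def test_nan_cites_row(self, tmp_path):
        (tmp_path / "x_1.csv").write_text("0.1\nNaN\n0.3\n")
        with pytest.raises(ValueError, match=":2"):
            read_csv(tmp_path / "x_1.csv", fs=100.0)

    def test_non_numeric_rejected(self, tmp_path):
        (tmp_path / "x_1.csv").write_text("0.1\nabc\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_csv(tmp_path / "x_1.csv", fs=100.0)


class TestPreprocess:
    def test_constant_signal_removed(self):
        out = preprocess(_record(np.full(4000, 2.5)))
        assert np.abs(out.samples).max() < 1e-6

    def test_passband_tones_retained(self):
        # DFT oracle: 1 Hz and 25 Hz amplitudes before vs after 0.5-40 Hz
        t = np.arange(20_000) / FS
        x = np.sin(2 * np.pi * 1.0 * t) + 0.5 * np.sin(2 * np.pi * 25.0 * t)
        out = preprocess(_record(x), 0.5, 40.0)
        spec_in = np.abs(np.fft.rfft(x)) / len(t)
        spec_out = np.abs(np.fft.rfft(out.samples)) / len(t)
        freqs = np.fft.rfftfreq(len(t), 1 / FS)
        for f0 in (1.0, 25.0):
            k = np.argmin(np.abs(freqs - f0))
            assert spec_out[k] == pytest.approx(spec_in[k], rel=0.15)

    def test_zero_phase_exact_for_symmetric_bump(self):
        # an isolated symmetric bump must not move at all under the
        # forward-backward filter
        t = np.arange(4000) / FS
        x = np.exp(-((t - 4.0) ** 2) / (2 * 0.012 ** 2))
        out = preprocess(_record(x))
        assert int(np.argmax(out.samples)) == int(np.argmax(x))

    def test_r_apex_shift_at_most_one_sample(self, clean_records):
        # full PQRST morphology: asymmetric Q/S neighbors may move the
        # smoothed apex by one sample, never more
        rec = clean_records[0]
        out = preprocess(rec)
        for r in rec.truth_fiducials.r_peaks[2:-2]:
            lo, hi = r - 10, r + 11
            assert abs(int(np.argmax(out.samples[lo:hi])) + lo - r) <= 1

    def test_idempotent_for_in_band_tone(self):
        # a tone far from both cutoffs passes the filter untouched, so a
        # second pass reproduces the first almost exactly
        t = np.arange(30_000) / FS
        once = preprocess(_record(np.sin(2 * np.pi * 6.0 * t)))
        twice = preprocess(once)
        span = once.samples.max() - once.samples.min()
        # the 0.5 Hz high-pass edge transient decays over ~15 s; compare
        # the interior beyond it
        core = slice(8000, -8000)
        assert np.abs(twice.samples[core] - once.samples[core]).max() \
            < 1e-6 * span

    def test_second_pass_changes_little_on_ecg(self, clean_records):
        once = preprocess(clean_records[0])
        twice = preprocess(once)
        span = once.samples.max() - once.samples.min()
        assert np.abs(twice.samples - once.samples).max() < 0.02 * span

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess(_record(np.zeros(100)), 0.5, 300.0)


class TestResample:
    def test_halving(self):
        fids = FiducialSet(r_peaks=np.array([1000]))
        rec = EcgRecord("s", "1", "i", 1000.0, np.zeros(10_000),
                        truth_fiducials=fids)
        out = resample_record(rec, 500.0)
        assert len(out) == 5000 and out.fs == 500.0
        assert out.truth_fiducials.r_peaks[0] == 500

    def test_identity(self, clean_records):
        assert resample_record(clean_records[0], FS) is clean_records[0]

    def test_band_limited_round_trip(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 7.0 * t)
        back = resample_record(resample_record(_record(x), 250.0), FS)
        core = slice(200, -200)  # ignore filter edges
        assert np.abs(back.samples[core] - x[core]).max() < 1e-2
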