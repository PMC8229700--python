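import numpy as np
import pytest

from heartprint.fiducials import FiducialSet
from heartprint.records import EcgRecord
from heartprint.segmentation import (SegmentSet, augment_to_count,
                                     blind_segments, normalize_lengths,
                                     pp_segments, r_centered_segments,
                                     resample_to_length, rr_segments)

FS = 500.0


def _record(n=10_000, fs=FS, subject="s0"):
    rng = np.random.default_rng(1)
    return EcgRecord(subject, "1", "i", fs, rng.normal(size=n))


class TestBlind:
    @pytest.mark.parametrize("window_s,expected", [(2.0, 10), (3.0, 6)])
    def test_counts_for_20s_record(self, window_s, expected):
        segs = blind_segments(_record(), window_s)
        assert len(segs) == expected
        assert all(len(s) == round(window_s * FS) for s in segs)

    def test_record_shorter_than_window_is_empty(self):
        assert len(blind_segments(_record(n=200), 0.5)) == 0

    def test_windows_are_consecutive_nonoverlapping(self):
        rec = _record()
        segs = blind_segments(rec, 1.0)
        starts = [s.origin[1] for s in segs]
        assert starts == list(range(0, 10_000 - 499, 500))


class TestRCentered:
    def test_centering_convention(self):
        rec = _record(n=20_000, fs=1000.0)
        fids = FiducialSet(r_peaks=np.array([10_000]))
        seg = r_centered_segments(rec, fids, 0.5)[0]
        assert seg.origin[1] == 9750 and len(seg) == 500
        np.testing.assert_array_equal(seg.samples, rec.samples[9750:10250])

    def test_boundary_windows_dropped(self):
        rec = _record(n=20_000, fs=1000.0)
        fids = FiducialSet(r_peaks=np.array([100, 10_000, 19_900]))
        segs = r_centered_segments(rec, fids, 0.5)
        assert len(segs) == 1

    def test_half_second_at_500hz_gives_250_samples(self):
        fids = FiducialSet(r_peaks=np.array([1000, 2000, 3000]))
        segs = r_centered_segments(_record(), fids, 0.5)
        assert all(len(s) == 250 for s in segs)


class TestIntervalSchemes:
    def test_rr_lengths(self):
        fids = FiducialSet(r_peaks=np.array([500, 1500, 2400]))
        segs = rr_segments(_record(), fids)
        assert [len(s) for s in segs] == [1000, 900]

    def test_single_fiducial_gives_empty(self):
        assert len(rr_segments(_record(), FiducialSet(r_peaks=np.array([500])))) == 0

    def test_rr_lengths_telescope(self):
        r = np.array([300, 900, 1700, 2900, 4100])
        segs = rr_segments(_record(), FiducialSet(r_peaks=r))
        assert sum(len(s) for s in segs) == r[-1] - r[0]

    def test_pp_uses_p_peaks(self):
        fids = FiducialSet(r_peaks=np.array([500, 1500]),
                           p_peaks=np.array([420, 1430]))
        segs = pp_segments(_record(), fids)
        assert len(segs) == 1 and len(segs[0]) == 1010


class TestResampleToLength:
    def test_endpoints_preserved(self):
        seg = rr_segments(_record(), FiducialSet(r_peaks=np.array([0, 900])))[0]
        out = resample_to_length(seg, 500)
        assert len(out) == 500
        assert out.samples[0] == seg.samples[0]
        assert out.samples[-1] == seg.samples[-1]

    def test_identity_when_length_matches(self):
        seg = blind_segments(_record(), 1.0)[0]
        assert resample_to_length(seg, 500) is seg

    def test_linear_ramp_stays_linear(self):
        rec = EcgRecord("s0", "1", "i", FS, np.linspace(0.0, 1.0, 900))
        seg = blind_segments(rec, 900 / FS)[0]
        out = resample_to_length(seg, 400)
        np.testing.assert_allclose(out.samples, np.linspace(0.0, 1.0, 400),
                                   atol=1e-9)

    def test_normalize_to_median_length(self):
        fids = FiducialSet(r_peaks=np.array([0, 900, 1900, 3100]))
        segs = normalize_lengths(rr_segments(_record(), fids))
        assert {len(s) for s in segs} == {1000}


class TestAugmentation:
    def _set(self, counts):
        rng = np.random.default_rng(0)
        segs = []
        for subject, n in counts.items():
            for _ in range(n):
                rec = EcgRecord(subject, "1", "i", FS, rng.normal(size=250))
                segs.extend(blind_segments(rec, 0.5))
        return SegmentSet(segs)

    def test_topped_up_counts_and_provenance(self):
        segset = self._set({"a": 40, "b": 100})
        out = augment_to_count(segset, target_count=100, k=10, seed=3)
        counts = out.counts()
        assert counts["a"] == 100 and counts["b"] == 100
        originals = {"a": [s for s in segset if s.subject_id == "a"]}
        for s in out:
            if s.sources is not None:
                assert len(s.sources) == 10
                expected = np.mean(
                    [originals["a"][i].samples for i in s.sources], axis=0)
                np.testing.assert_array_equal(s.samples, expected)

    def test_identical_originals_average_to_themselves(self):
        base = np.ones(250)
        segs = [EcgRecord("a", "1", "i", FS, base) for _ in range(3)]
        segset = SegmentSet([blind_segments(r, 0.5)[0] for r in segs])
        out = augment_to_count(segset, target_count=10, k=10, seed=0)
        for s in out:
            np.testing.assert_array_equal(s.samples, base)

    def test_originals_untouched_and_deterministic(self):
        segset = self._set({"a": 5})
        a = augment_to_count(segset, 20, 3, seed=9)
        b = augment_to_count(segset, 20, 3, seed=9)
        assert len(a) == 20
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.samples, s2.samples)
        # the 5 originals appear unchanged
        for orig, aug in zip(segset, a):
            assert orig is aug

    def test_mixed_lengths_rejected(self):
        rng = np.random.default_rng(0)
        recs = [EcgRecord("a", "1", "i", FS, rng.normal(size=n))
                for n in (250, 300)]
        segs = SegmentSet([blind_segments(r, r.duration_s)[0] for r in recs])
        with pytest.raises(ValueError, match="equal-length"):
            augment_to_count(segs, 10, 2, seed=0)
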