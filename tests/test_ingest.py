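import numpy as np
import pandas as pd
import pytest

from actipheno.ingest import (
    EpochSeries,
    FilterSpec,
    RawTriaxialSeries,
    drop_missing_days,
    pim_from_raw,
    read_epoch_csv,
    write_epoch_csv,
)


def _series(counts, **kw):
    return EpochSeries(counts=np.asarray(counts, dtype=float), **kw)


class TestEpochCsv:
    def test_identity_read(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text("subject_id,timestamp,count\ns1,2000-01-03T00:00:00,0\n"
                     "s1,2000-01-03T00:01:00,5\ns1,2000-01-03T00:02:00,2\n")
        s = read_epoch_csv(p)
        assert list(s.counts) == [0, 5, 2]
        assert s.subject_id == "s1"

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="no epochs"):
            read_epoch_csv(p)

    def test_negative_count_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("subject_id,timestamp,count\ns1,2000-01-03T00:00:00,3\n"
                     "s1,2000-01-03T00:01:00,-1\n")
        with pytest.raises(ValueError, match="line 3"):
            read_epoch_csv(p)

    def test_malformed_count_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("subject_id,timestamp,count\ns1,2000-01-03T00:00:00,oops\n")
        with pytest.raises(ValueError, match="line 2"):
            read_epoch_csv(p)

    def test_haukeland_dialect_single_column(self, tmp_path):
        p = tmp_path / "h.txt"
        p.write_text("0\n12\n3.5\n")
        s = read_epoch_csv(p, dialect="haukeland", subject_id="h1")
        assert list(s.counts) == [0, 12, 3.5]

    def test_roundtrip_byte_identical(self, tmp_path):
        rng = np.random.default_rng(42)
        counts = np.round(rng.gamma(2, 50, size=1440), 3)
        s = _series(counts, subject_id="rt")
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_epoch_csv(s, p1)
        write_epoch_csv(read_epoch_csv(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestPim:
    def test_all_zero_raw(self):
        raw = RawTriaxialSeries(np.zeros(1200), np.zeros(1200), np.zeros(1200))
        out = pim_from_raw(raw, FilterSpec())
        assert len(out) == 2
        assert np.allclose(out.counts, 0, atol=1e-9)

    def test_per_second_max_sum_bypass(self):
        # each second's 10 magnitudes are a permutation of 0.1..1.0, so
        # each per-second max is 1.0 and the minute count is 60
        rng = np.random.default_rng(0)
        mags = np.concatenate([rng.permutation(np.arange(1, 11) / 10) for _ in range(60)])
        raw = RawTriaxialSeries(mags, np.zeros_like(mags), np.zeros_like(mags))
        out = pim_from_raw(raw, band=None)
        assert out.counts == pytest.approx([60.0])

    def test_permutation_within_second_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2, 0.1, size=1800)
        raw = RawTriaxialSeries(x, np.zeros_like(x), np.zeros_like(x))
        base = pim_from_raw(raw, band=None).counts
        xp = x.reshape(-1, 10).copy()
        for row in xp:
            rng.shuffle(row)
        permuted = RawTriaxialSeries(xp.ravel(), np.zeros(1800), np.zeros(1800))
        assert pim_from_raw(permuted, band=None).counts == pytest.approx(list(base))

    def test_epoch_count_is_floor_of_minutes(self):
        n = 10 * 60 * 2 + 371  # 2 min + leftover samples at 10 Hz
        raw = RawTriaxialSeries(np.ones(n), np.zeros(n), np.zeros(n))
        assert len(pim_from_raw(raw, band=None)) == 2

    def test_scaling_monotonicity_bypass(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2, 0.1, size=1200)
        raw = RawTriaxialSeries(x, x / 2, x / 3)
        scaled = RawTriaxialSeries(3 * x, 3 * x / 2, 3 * x / 3)
        a = pim_from_raw(raw, band=None).counts
        b = pim_from_raw(scaled, band=None).counts
        assert b == pytest.approx(list(3 * a))

    def test_too_short_errors(self):
        raw = RawTriaxialSeries(np.ones(300), np.ones(300), np.ones(300))
        with pytest.raises(ValueError, match="shorter than one full epoch"):
            pim_from_raw(raw, band=None)

    def test_band_above_nyquist_errors(self):
        raw = RawTriaxialSeries(np.ones(1200), np.ones(1200), np.ones(1200))
        with pytest.raises(ValueError, match="Nyquist"):
            pim_from_raw(raw, FilterSpec(low_hz=0.5, high_hz=6.0))


class TestDayHandling:
    def test_drop_all_zero_day(self):
        days = np.ones((3, 1440)) * 5
        days[1] = 0
        out = drop_missing_days(_series(days.ravel()))
        assert out.n_days == 2
        assert np.all(out.counts == 5)

    def test_no_zero_day_is_identity(self):
        s = _series(np.ones(2 * 1440))
        assert np.array_equal(drop_missing_days(s).counts, s.counts)

    def test_planted_zero_days_removed_exactly(self):
        rng = np.random.default_rng(7)
        days = rng.gamma(2, 30, size=(10, 1440))
        planted = [2, 5, 6]
        days[planted] = 0.0
        out = drop_missing_days(_series(days.ravel()))
        assert out.n_days == 7

    def test_idempotent(self):
        days = np.ones((4, 1440))
        days[0] = 0
        once = drop_missing_days(_series(days.ravel()))
        twice = drop_missing_days(once)
        assert np.array_equal(once.counts, twice.counts)

    def test_all_days_zero_errors(self):
        with pytest.raises(ValueError, match="no valid days"):
            drop_missing_days(_series(np.zeros(1440)))

    def test_trim_partial_days(self):
        # record starting 23:00 with 2 full days after the partial lead
        s = _series(np.arange(60 + 2 * 1440 + 100),
                    start_time=pd.Timestamp("2000-01-03 23:00:00"))
        t = s.trim_partial_days()
        assert t.n_days == 2
        assert t.counts[0] == 60  # first epoch of the first full day
        assert (t.start_time - t.start_time.normalize()).total_seconds() == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _series([1.0, -2.0])
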