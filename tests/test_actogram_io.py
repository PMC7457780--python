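"""Monitor-file parsing, re-binning and light annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from noctura import (
    ActivitySeries,
    LightRegime,
    annotate_light,
    read_dam_monitor,
    rebin,
    write_dam_file,
    write_tidy_csv,
)
from noctura.actogram_io import ActogramParseError

from conftest import LD, T0, dam_row, make_ld_series, make_series


class TestDamParsing:
    def test_two_row_fixture_hand_parsed(self, dam_writer):
        path = dam_writer([dam_row(1, "09:00:00", 1, 3),
                           dam_row(2, "09:30:00", 1, 5)])
        series = read_dam_monitor(path, dialect="dam42")
        assert len(series) == 32
        s = series[0]
        assert s.fly_id == "M1C01"
        assert list(s.counts) == [3, 5]
        assert s.bin_minutes == 30
        assert s.t0 == pd.Timestamp("2017-08-08 09:00:00")
        assert all(list(q.counts) == [0, 0] for q in series[1:])

    def test_bad_status_row_dropped_and_logged(self, dam_writer, caplog):
        path = dam_writer([
            dam_row(1, "09:00:00", 1, 3),
            dam_row(2, "09:30:00", 51, 99),  # monitor error code
            dam_row(3, "10:00:00", 1, 5),
        ])
        with caplog.at_level("WARNING"):
            series = read_dam_monitor(path, dialect="dam42")
        assert 99 not in series[0].counts
        assert list(series[0].counts) == [3, 5]  # bad bin absent
        assert any("status 51" in r.message for r in caplog.records)

    def test_interior_drop_zero_filled_on_regular_grid(self, dam_writer, caplog):
        # 30-min grid established by neighbours: the dropped bin leaves a
        # gap that is zero-filled and logged
        rows = [dam_row(1, "09:00:00", 1, 1),
                dam_row(2, "09:30:00", 1, 2),
                dam_row(3, "10:00:00", 51, 99),
                dam_row(4, "10:30:00", 1, 4),
                dam_row(5, "11:00:00", 1, 5)]
        path = dam_writer(rows)
        with caplog.at_level("WARNING"):
            series = read_dam_monitor(path, dialect="dam42")
        assert list(series[0].counts) == [1, 2, 0, 4, 5]
        assert any("zero-filled" in r.message for r in caplog.records)

    def test_wrong_field_count_names_line(self, dam_writer):
        path = dam_writer([dam_row(1, "09:00:00", 1, 3),
                           "1\t8 Aug 17\t09:30:00\t1\t0"])
        with pytest.raises(ActogramParseError, match="line 2"):
            read_dam_monitor(path, dialect="dam42")

    def test_non_monotone_timestamps_rejected(self, dam_writer):
        path = dam_writer([dam_row(1, "10:00:00", 1, 3),
                           dam_row(2, "09:00:00", 1, 5)])
        with pytest.raises(ActogramParseError, match="monotone"):
            read_dam_monitor(path, dialect="dam42")

    def test_zero_valid_rows_is_an_error(self, dam_writer):
        path = dam_writer([dam_row(1, "09:00:00", 51, 3)])
        with pytest.raises(ActogramParseError, match="no records"):
            read_dam_monitor(path, dialect="dam42")

    def test_monitor_id_from_filename(self, dam_writer):
        path = dam_writer([dam_row(1, "09:00:00", 1, 1),
                           dam_row(2, "09:30:00", 1, 1)], name="Monitor7.txt")
        series = read_dam_monitor(path, dialect="dam42")
        assert series[0].fly_id == "M7C01"


class TestTidyCsv:
    def test_single_fly_zeros_identity_parse(self, tmp_path):
        df = pd.DataFrame({
            "fly_id": "f1",
            "datetime": pd.date_range(T0, periods=10, freq="30min"),
            "count": 0,
        })
        path = tmp_path / "tidy.csv"
        df.to_csv(path, index=False)
        (s,) = read_dam_monitor(path, dialect="tidy_csv")
        assert s.n_bins == 10 and s.counts.sum() == 0
        assert s.bin_minutes == 30

    def test_round_trip_preserves_series(self, tmp_path, rng):
        s = make_ld_series(rng.poisson(5, size=48), bin_minutes=30)
        path = tmp_path / "rt.csv"
        write_tidy_csv([s], path)
        (back,) = read_dam_monitor(path, dialect="tidy_csv")
        assert back.fly_id == s.fly_id
        assert back.t0 == s.t0
        assert back.bin_minutes == s.bin_minutes
        np.testing.assert_array_equal(back.counts, s.counts)
        np.testing.assert_array_equal(back.light_flags, s.light_flags)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"fly_id": ["a"], "count": [1]}).to_csv(path, index=False)
        with pytest.raises(ActogramParseError, match="missing columns"):
            read_dam_monitor(path, dialect="tidy_csv")


class TestDamWriter:
    def test_dam_round_trip(self, tmp_path, rng):
        counts = rng.poisson(4, size=(3, 48))
        series = [
            make_series(counts[i], bin_minutes=30, fly_id=f"M1C{i+1:02d}")
            for i in range(3)
        ]
        path = tmp_path / "Monitor1.txt"
        write_dam_file(series, path)
        back = read_dam_monitor(path, dialect="dam42")
        for i in range(3):
            np.testing.assert_array_equal(back[i].counts, counts[i])


class TestRebin:
    def test_sum_conservation(self):
        s = make_series(np.ones(60, dtype=int), bin_minutes=1)
        out = rebin(s, 30)
        assert list(out.counts) == [30, 30]
        assert out.bin_minutes == 30

    def test_identity(self):
        s = make_series([1, 2, 3], bin_minutes=30)
        out = rebin(s, 30)
        np.testing.assert_array_equal(out.counts, s.counts)

    def test_trailing_partial_window_dropped(self, caplog):
        s = make_series(np.ones(61, dtype=int), bin_minutes=1)
        with caplog.at_level("WARNING"):
            out = rebin(s, 30)
        assert out.n_bins == 2
        assert any("dropping 1 trailing" in r.message for r in caplog.records)

    def test_non_multiple_target_rejected(self):
        s = make_series([1, 2, 3], bin_minutes=30)
        with pytest.raises(ValueError, match="multiple"):
            rebin(s, 45)

    @given(
        factors=st.tuples(st.sampled_from([2, 3, 5, 6]),
                          st.sampled_from([2, 4])),
        n_days=st.integers(min_value=1, max_value=3),
    )
    def test_rebin_composes_and_conserves(self, factors, n_days):
        a, b = factors
        rng = np.random.default_rng(1)
        s = make_series(rng.poisson(2, size=n_days * 1440), bin_minutes=1)
        two_step = rebin(rebin(s, a), a * b)
        one_step = rebin(s, a * b)
        np.testing.assert_array_equal(two_step.counts, one_step.counts)
        assert one_step.counts.sum() == s.counts.sum()  # widths divide a day


class TestAnnotateLight:
    def test_ld_12_12_labels(self):
        s = make_series(np.ones(24, dtype=int), bin_minutes=60)
        out = annotate_light(s, LD)
        assert list(out.light_flags[:12]) == ["L"] * 12
        assert list(out.light_flags[12:]) == ["D"] * 12

    def test_subjective_projection_after_dd_start(self):
        dd_start = T0 + pd.Timedelta(days=1)
        regime = LightRegime(8.0, 12.0, dd_start=dd_start)
        s = make_series(np.ones(48, dtype=int), bin_minutes=60)
        out = annotate_light(s, regime)
        assert list(out.light_flags[:12]) == ["L"] * 12
        assert list(out.light_flags[24:36]) == ["subjL"] * 12
        assert list(out.light_flags[36:]) == ["subjD"] * 12

    def test_zero_photoperiod_without_history_rejected(self):
        s = make_series(np.ones(24, dtype=int), bin_minutes=60)
        with pytest.raises(ValueError, match="no subjective reference"):
            annotate_light(s, LightRegime(8.0, 0.0))

    def test_bin_straddling_transition_advises_rebin(self):
        t0 = T0 + pd.Timedelta(minutes=45)  # 90-min bins now cross ZT12
        s = make_series(np.ones(16, dtype=int), bin_minutes=90, t0=t0)
        with pytest.raises(ValueError, match="re-bin"):
            annotate_light(s, LD)

    def test_validation_catches_bad_series(self):
        with pytest.raises(ValueError):
            make_series([], bin_minutes=30)
        with pytest.raises(ValueError):
            make_series([-1, 2], bin_minutes=30)
        with pytest.raises(ValueError):
            make_series([1, 2], bin_minutes=7)  # 7 does not divide 1440
        with pytest.raises(ValueError):
            ActivitySeries("f", T0, 30, np.array([1, 2]),
                           light_flags=np.array(["L"], dtype=object))
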