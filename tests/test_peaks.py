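"""Peak-list reading, referencing, assembly and missingness filtering."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsqcmelt.peaks import (
    PeakRecord,
    PeakTableError,
    assemble_series,
    filter_missing,
    parse_sparky_assignment,
    read_peak_table,
    reference_to_tsp,
    temperature_from_filename,
    write_peak_table,
)

TSV_HEADER = (
    "residue_index\tresidue_type\ttemperature_K\tdelta_H_ppm\t"
    "delta_N_ppm\tintensity\n"
)


class TestReadPeakTable:
    def test_tsv_row_maps_fields_directly(self):
        text = TSV_HEADER + "134\tQ\t303\t8.12\t119.4\t1.0e6\n"
        (rec,) = read_peak_table(io.StringIO(text))
        assert rec == PeakRecord(134, "Q", 303.0, 8.12, 119.4, 1.0e6)

    def test_empty_file_with_header_gives_empty_list(self):
        assert read_peak_table(io.StringIO(TSV_HEADER)) == []

    def test_comments_and_blank_lines_skipped(self):
        text = "# comment\n" + TSV_HEADER + "\n1\tA\t295\t8.0\t120\t1\n"
        assert len(read_peak_table(io.StringIO(text))) == 1

    def test_missing_header_column_named_in_error(self):
        bad = TSV_HEADER.replace("\tintensity", "")
        with pytest.raises(PeakTableError, match="intensity"):
            read_peak_table(io.StringIO(bad + "1\tA\t295\t8.0\t120\n"))

    def test_bad_row_reports_line_number(self):
        text = TSV_HEADER + "1\tA\t295\t8.0\t120\t1e6\nnope\tA\tX\t..\t..\t..\n"
        with pytest.raises(PeakTableError, match="line 3"):
            read_peak_table(io.StringIO(text))

    def test_validation_rejects_out_of_range_values(self):
        text = TSV_HEADER + "1\tA\t30\t8.0\t120\t1e6\n"  # Celsius slip
        with pytest.raises(PeakTableError, match="temperature"):
            read_peak_table(io.StringIO(text))
        # and can be explicitly disabled
        assert len(read_peak_table(io.StringIO(text), validate=False)) == 1

    def test_residue_offset_applied_on_read(self):
        text = TSV_HEADER + "7\tS\t295\t8.0\t120\t1e6\n"
        (rec,) = read_peak_table(io.StringIO(text), residue_offset=6)
        assert rec.residue_index == 13

    def test_sparky_line_matches_tsv_record(self):
        sparky = "      Assignment   w1   w2  Data Height\nQ134N-H 119.4 8.12 1.0e6\n"
        (rec,) = read_peak_table(
            io.StringIO(sparky), "sparky", temperature=303.0
        )
        assert rec == PeakRecord(134, "Q", 303.0, 8.12, 119.4, 1.0e6)

    def test_sparky_requires_temperature(self):
        with pytest.raises(ValueError, match="temperature"):
            read_peak_table(io.StringIO("Q1N-H 119 8 1\n"), "sparky")

    def test_unparsable_assignment_reports_line(self):
        with pytest.raises(PeakTableError, match="line 1"):
            read_peak_table(
                io.StringIO("134Q 119.4 8.12 1e6\n"), "sparky", temperature=300
            )


@pytest.mark.parametrize(
    "label, expected",
    [("Q134N-H", ("Q", 134)), ("G4N-H", ("G", 4)), ("W58NE1-HE1", ("W", 58))],
)
def test_parse_sparky_assignment(label, expected):
    assert parse_sparky_assignment(label) == expected


def test_temperature_from_filename():
    assert temperature_from_filename("wt_gcsf_303K.list") == 303.0
    assert temperature_from_filename("run_295.5K.list") == 295.5
    with pytest.raises(PeakTableError):
        temperature_from_filename("peaks.list")


@settings(max_examples=30, derandomize=True)
@given(
    dialect=st.sampled_from(["tsv", "sparky"]),
    records=st.lists(
        st.builds(
            PeakRecord,
            residue_index=st.integers(1, 200),
            residue_type=st.sampled_from("ACDQGW"),
            temperature=st.just(303.0),
            delta_h=st.floats(0.0, 11.0, allow_nan=False),
            delta_n=st.floats(100.0, 135.0, allow_nan=False),
            intensity=st.floats(0.0, 1e8, allow_nan=False),
        ),
        min_size=1,
        max_size=20,
        unique_by=lambda r: r.residue_index,
    ),
)
def test_write_read_round_trip_is_bit_exact(dialect, records):
    buf = io.StringIO()
    write_peak_table(records, buf, dialect)
    buf.seek(0)
    back = read_peak_table(buf, dialect, temperature=303.0)
    assert back == records


class TestReferencing:
    def test_zero_offset_is_identity(self):
        recs = [PeakRecord(1, "A", 295.0, 8.12, 119.4, 1.0)]
        out, offsets = reference_to_tsp(recs, 0.0)
        assert out == recs and offsets == (0.0, 0.0)

    def test_proton_offset_subtracted(self):
        recs = [PeakRecord(1, "A", 295.0, 8.12, 119.4, 1.0)]
        (out,), _ = reference_to_tsp(recs, 0.02, indirect_nitrogen=False)
        assert out.delta_h == pytest.approx(8.10)
        assert out.delta_n == 119.4

    def test_indirect_nitrogen_matches_hand_computation(self):
        # rescaling the reference frequency by (1 + o*1e-6) moves every
        # ppm value by (delta - o) / (1 + o*1e-6)
        o = 0.02
        recs = [PeakRecord(1, "A", 295.0, 8.12, 119.4, 1.0)]
        (out,), offsets = reference_to_tsp(recs, o)
        expected_n = (119.4 - o) / (1 + o * 1e-6)
        assert out.delta_n == pytest.approx(expected_n, abs=1e-12)
        assert out.delta_n == pytest.approx(119.38, abs=1e-4)  # first order
        assert offsets == (o, o)

    def test_non_finite_offset_rejected(self):
        with pytest.raises(ValueError):
            reference_to_tsp([], math.nan)


class TestAssembleSeries:
    def test_complete_series_has_no_missing(self, small_series):
        assert small_series.residues == [1, 2, 3]
        assert len(small_series.temperatures) == 4
        assert all(small_series.missing_count(r) == 0 for r in [1, 2, 3])

    def test_absent_record_counts_missing(self):
        recs = [
            PeakRecord(1, "A", t, 8.0, 120.0, 1.0) for t in (295.0, 297.0)
        ] + [PeakRecord(2, "A", 295.0, 8.5, 121.0, 1.0)]
        series = assemble_series(recs)
        assert series.missing_count(1) == 0
        assert series.missing_count(2) == 1
        assert series.get(2, 297.0) is None

    def test_order_invariance(self):
        recs = [
            PeakRecord(r, "A", t, 8.0 + r * 0.1, 120.0, float(r * t))
            for r in (1, 2, 3)
            for t in (295.0, 297.0, 299.0)
        ]
        rng = np.random.default_rng(0)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        a = assemble_series(recs)
        b = assemble_series(shuffled)
        assert a.temperatures == b.temperatures
        assert list(a.iter_records()) == list(b.iter_records())

    def test_exact_duplicates_warn_and_collapse(self):
        rec = PeakRecord(1, "A", 295.0, 8.0, 120.0, 1.0)
        with pytest.warns(UserWarning, match="duplicate"):
            series = assemble_series([rec, rec])
        assert len(series) == 1

    def test_conflicting_duplicates_error(self):
        a = PeakRecord(1, "A", 295.0, 8.0, 120.0, 1.0)
        b = PeakRecord(1, "A", 295.0, 8.1, 120.0, 1.0)
        with pytest.raises(PeakTableError, match="conflicting"):
            assemble_series([a, b])


class TestFilterMissing:
    @staticmethod
    def _series_with_missing(n_missing):
        temps = [295.0 + 2 * k for k in range(15)]
        recs = [PeakRecord(1, "A", t, 8.0, 120.0, 1.0) for t in temps]
        recs += [
            PeakRecord(2, "A", t, 8.5, 121.0, 1.0)
            for t in temps[: len(temps) - n_missing]
        ]
        return assemble_series(recs)

    def test_four_missing_of_fifteen_removed(self):
        series = filter_missing(self._series_with_missing(4), 3)
        assert series.residues == [1]

    def test_exactly_three_missing_retained(self):
        series = filter_missing(self._series_with_missing(3), 3)
        assert series.residues == [1, 2]

    def test_complete_series_unchanged(self, small_series):
        assert filter_missing(small_series, 3).residues == [1, 2, 3]

    def test_idempotent_and_monotone(self):
        base = self._series_with_missing(4)
        once = filter_missing(base, 3)
        assert filter_missing(once, 3).residues == once.residues
        # raising max_missing never removes a residue retained lower
        lenient = filter_missing(base, 10)
        assert set(once.residues) <= set(lenient.residues)
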