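"""Transient container, tidy-table I/O and marker extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ojipstress.errors import (
    CoverageError,
    DegenerateTransientError,
    EmptyInputError,
    TableFormatError,
    TableParseError,
)
from ojipstress.synthetic_data import default_presets, generate_transient, time_grid
from ojipstress.transients import (
    MARKER_TIMES,
    FluorescenceTransient,
    MarkerSet,
    extract_markers,
    read_transients,
    transients_to_frame,
    write_transients,
)


def make_transient(times, values, sample_id="s1", **meta):
    kwargs = dict(strain="GM", treatment="MT", replicate=1)
    kwargs.update(meta)
    return FluorescenceTransient(sample_id=sample_id, times=times, values=values, **kwargs)


class TestContainer:
    def test_validates_time_span_and_positivity(self):
        good_t = np.geomspace(2e-5, 1.0, 50)
        make_transient(good_t, np.linspace(500, 1250, 50))  # ok
        with pytest.raises(ValueError, match="20 us"):
            make_transient(np.geomspace(1e-4, 1.0, 50), np.ones(50))
        with pytest.raises(ValueError, match="1 s"):
            make_transient(np.geomspace(2e-5, 0.5, 50), np.ones(50))
        with pytest.raises(ValueError, match="positive"):
            make_transient(good_t, np.r_[-1.0, np.ones(49)])
        with pytest.raises(ValueError, match="increasing"):
            make_transient(good_t[::-1], np.ones(50))
        with pytest.raises(ValueError, match="5 time points"):
            make_transient([2e-5, 1e-3, 1.0], [1, 2, 3.0])

    def test_marker_set_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            MarkerSet(0.0, 1, 2, 3, 4)
        m = MarkerSet(1, 2, 3, 4, 5)
        assert m.is_monotone()
        assert not MarkerSet(1, 4, 3, 4, 5).is_monotone()


class TestTableIO:
    def test_groups_rows_into_per_sample_transients(self, tmp_path):
        presets = default_presets()
        transients = [generate_transient(p, seed=3, replicate=1) for p in presets[:2]]
        path = tmp_path / "transients.csv"
        write_transients(transients, path)
        back = read_transients(path)
        assert len(back) == 2
        assert all(len(t) == 120 for t in back)

    def test_write_read_round_trip_is_bit_identical(self, tmp_path):
        p = default_presets()[0]
        original = [generate_transient(p, seed=9, replicate=r) for r in (1, 2)]
        path = tmp_path / "t.csv"
        write_transients(original, path)
        back = read_transients(path)
        for a, b in zip(original, back):
            assert a.sample_id == b.sample_id and a.replicate == b.replicate
            np.testing.assert_array_equal(a.times, b.times)
            np.testing.assert_array_equal(a.values, b.values)

    def test_tab_delimited_accepted(self, tmp_path):
        p = default_presets()[0]
        t = [generate_transient(p, seed=1, replicate=1)]
        path = tmp_path / "t.tsv"
        write_transients(t, path, delimiter="\t")
        assert len(read_transients(path)) == 1

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,strain,treatment,replicate,time_s\ns1,GM,MT,1,0.1\n")
        with pytest.raises(TableFormatError, match="fluorescence"):
            read_transients(path)

    def test_nan_time_cited_with_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sample_id,strain,treatment,replicate,time_s,fluorescence\n"
            "s1,GM,MT,1,2e-05,500\n"
            "s1,GM,MT,1,NaN,600\n"
        )
        with pytest.raises(TableParseError, match="row 3"):
            read_transients(path)

    def test_empty_file_raises_empty_input(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("sample_id,strain,treatment,replicate,time_s,fluorescence\n")
        with pytest.raises(EmptyInputError):
            read_transients(path)
        path.write_text("")
        with pytest.raises(EmptyInputError):
            read_transients(path)


class TestExtractMarkers:
    def test_exact_grid_returns_sampled_values(self):
        times = np.array([2e-5, 3e-4, 2e-3, 3e-2, 1.0])
        values = np.array([500.0, 668.75, 837.5, 1100.0, 1250.0])
        m = extract_markers(make_transient(times, values))
        assert m.as_tuple() == tuple(values)

    def test_noise_free_generator_markers_recovered(self, presets):
        from dataclasses import replace

        for preset in presets.values():
            clean = replace(preset, noise_cv=0.0, replicate_sd=0.0)
            m = extract_markers(generate_transient(clean, seed=5, replicate=1))
            for got, want in zip(m.as_tuple(), preset.markers.as_tuple()):
                assert got == pytest.approx(want, rel=1e-9)

    def test_constant_trace_is_degenerate(self):
        times = np.geomspace(2e-5, 1.0, 40)
        with pytest.raises(DegenerateTransientError):
            extract_markers(make_transient(times, np.full(40, 1000.0)))

    def test_marker_time_outside_range_raises_coverage_error(self):
        # F_K at 300 us cannot be bracketed if sampling jumps over it —
        # construct a transient legal per the container but sparse in between
        times = np.array([2e-5, 2.5e-5, 0.5, 0.75, 1.0])
        values = np.array([500.0, 510.0, 1200.0, 1240.0, 1250.0])
        m = extract_markers(make_transient(times, values))  # interpolation still covers
        assert m.f_m == 1250.0
        # now an actually uncovered marker: first sample after 300 us is impossible
        # by the container invariant, so coverage errors surface via a doctored grid
        t = make_transient(times, values)
        object.__setattr__(t, "times", np.array([3e-4, 2e-3, 3e-2, 0.5, 1.0]))
        with pytest.raises(CoverageError):
            extract_markers(t)

    def test_early_maximum_warns(self):
        times = np.geomspace(2e-5, 1.0, 60)
        values = np.where(times < 0.01, 500 + 5e4 * times, 1000.0)
        with pytest.warns(UserWarning, match="100 ms"):
            extract_markers(make_transient(times, np.maximum.accumulate(values)))

    def test_invariant_under_redundant_collinear_insertion(self):
        times = time_grid(60)
        logt = np.log10(times)
        values = 500 + 750 * (logt - logt[0]) / (logt[-1] - logt[0])  # monotone
        base = extract_markers(make_transient(times, values))
        # insert midpoints (collinear in log-time) between every other pair
        mid_log = (logt[:-1] + logt[1:]) / 2
        t2 = np.sort(np.r_[times, 10.0**mid_log])
        v2 = np.interp(np.log10(t2), logt, values)
        dense = extract_markers(make_transient(t2, v2))
        for a, b in zip(base.as_tuple(), dense.as_tuple()):
            assert a == pytest.approx(b, rel=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 50.0), min_size=19, max_size=19), st.floats(100.0, 5000.0))
    def test_monotone_trace_yields_ordered_markers(self, increments, f0):
        times = time_grid(20)
        values = f0 + np.r_[0.0, np.cumsum(increments)]
        import warnings as _warnings

        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", UserWarning)  # early plateaus are fine here
                m = extract_markers(make_transient(times, values))
        except DegenerateTransientError:
            assert np.allclose(values, values[0])
            return
        assert m.f_o <= m.f_k <= m.f_j <= m.f_i <= m.f_m
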