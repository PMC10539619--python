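"""Conversion to the recording model, CSV dialect and NIX/HDF5 export."""

import h5py
import numpy as np
import pytest

from dapsysio import (
    ConverterConfig,
    InvariantViolation,
    PageKind,
    assemble_waveform,
    convert,
    csv_text,
    export_csv,
    export_nix_h5,
    generate_csv_reference,
    resolve_stream,
    RecordingModel,
)

from conftest import make_file, stream, text_page, wf_regular


def two_page_file(gap_samples=1.0, dt=1e-3):
    """Two 3-sample regular pages; second starts gap_samples*dt after the
    first ends (gap 1.0 means seamless continuation)."""
    t1 = (2 + gap_samples) * dt
    pages = [
        wf_regular(1, 0.0, dt, [1.0, 2.0, 3.0]),
        wf_regular(2, t1, dt, [4.0, 5.0, 6.0]),
    ]
    return make_file(pages, [stream(1, "Sig", PageKind.WAVEFORM, [1, 2])])


def config(**kw):
    return ConverterConfig(continuous_paths=["Sig"], **kw)


class TestConvertMerging:
    def test_contiguous_pages_merge_into_one_trace(self):
        model = convert(two_page_file(gap_samples=1.0), config())
        assert len(model.traces) == 1
        trace = model.traces[0]
        assert trace.samples.shape == (6,)
        assert trace.is_regular
        assert trace.start_time_s == 0.0

    def test_gap_beyond_tolerance_starts_new_trace(self):
        model = convert(two_page_file(gap_samples=5.0), config())
        assert len(model.traces) == 2
        assert [t.samples.shape[0] for t in model.traces] == [3, 3]
        assert model.traces[0].name != model.traces[1].name

    def test_half_interval_jitter_still_merges(self):
        model = convert(two_page_file(gap_samples=1.4), config())
        assert len(model.traces) == 1

    def test_interval_mismatch_never_merges(self):
        f = two_page_file(gap_samples=1.0)
        f.pages[2].interval = 2e-3
        model = convert(f, config())
        assert len(model.traces) == 2

    def test_bad_tolerance_rejected(self):
        with pytest.raises(InvariantViolation):
            ConverterConfig(merge_gap_tolerance=1.5)


class TestConvertSession:
    @pytest.fixture()
    def model(self, small_session):
        _, file, _ = small_session
        return convert(file, ConverterConfig.discover(file))

    def test_spike_and_event_partition(self, small_session, model):
        _, file, truth = small_session
        assert len(model.spikes) == 2
        for series in model.spikes:
            times = truth.spike_times[series.track_name]
            np.testing.assert_array_equal(series.entered_times_s, times[:, 0])
            np.testing.assert_array_equal(series.recognized_times_s, times[:, 1])
        assert len(model.events) == 1
        np.testing.assert_array_equal(model.events[0].times_s, truth.comment_times)
        assert len(model.events[0].labels) == truth.comment_times.shape[0]

    def test_comment_splits_vanish_after_merge(self, small_session, model):
        """Page cuts induced by comments are seams, not real gaps."""
        _, file, truth = small_session
        assert len(model.traces) == 1
        assert model.traces[0].samples.shape[0] == truth.total_samples

    def test_conversion_is_lossless_over_samples(self, small_session, model):
        _, file, _ = small_session
        slab = assemble_waveform(file, resolve_stream(file, "Continuous Recording"))
        got = np.concatenate([t.samples for t in model.traces])
        np.testing.assert_array_equal(got, slab.amplitudes)

    def test_provenance_carries_footer(self, small_session, model):
        _, file, _ = small_session
        assert file.footer.version_string in model.provenance


class TestCsvDialect:
    def test_waveform_formatting(self):
        f = make_file(
            [wf_regular(1, 1.5, 0.5, [0.25])],
            [stream(1, "S", PageKind.WAVEFORM, [1])],
        )
        assert csv_text(f, "S") == "1.500000,0.250000\n"

    def test_text_half_even_rounding(self):
        f = make_file(
            [text_page(1, "cold", 0.33335)], [stream(1, "S", PageKind.TEXT, [1])]
        )
        assert csv_text(f, "S") == "0.3334,cold\n"

    def test_text_with_separator_is_quoted(self):
        f = make_file(
            [text_page(1, 'a,b "c"', 1.0)], [stream(1, "S", PageKind.TEXT, [1])]
        )
        assert csv_text(f, "S") == '1.0000,"a,b ""c"""\n'

    def test_matches_independent_reference(self, small_session):
        _, file, _ = small_session
        for path in ["Continuous Recording", "Comments", "Tracks/Track 1"]:
            assert csv_text(file, path) == generate_csv_reference(file, path)

    def test_reparse_never_deviates_beyond_rounding_bound(self, small_session):
        _, file, _ = small_session
        slab = assemble_waveform(file, resolve_stream(file, "Continuous Recording"))
        rows = csv_text(file, "Continuous Recording").splitlines()
        parsed = np.array([[float(a), float(b)] for a, b in (r.split(",") for r in rows)])
        assert np.abs(parsed[:, 0] - slab.timestamps).max() <= 5e-7
        assert np.abs(parsed[:, 1] - slab.amplitudes.astype(np.float64)).max() <= 5e-7

    def test_export_csv_writes_file(self, small_session, tmp_path):
        _, file, _ = small_session
        out = tmp_path / "cont.csv"
        export_csv(file, "Continuous Recording", str(out))
        assert out.read_text() == csv_text(file, "Continuous Recording")


class TestNixExport:
    def test_empty_model(self, tmp_path):
        path = tmp_path / "empty.nix.h5"
        export_nix_h5(RecordingModel(provenance="empty test"), str(path))
        with h5py.File(path) as h:
            assert h.attrs["format"] == "nix"
            assert list(h["data"].keys()) == ["recording"]
            assert list(h["data/recording/data_arrays"].keys()) == []

    def test_array_count_and_bitwise_readback(self, small_session, tmp_path):
        _, file, truth = small_session
        model = convert(file, ConverterConfig.discover(file))
        path = tmp_path / "session.nix.h5"
        export_nix_h5(model, str(path))
        with h5py.File(path) as h:
            arrays = h["data/recording/data_arrays"]
            assert len(arrays) == len(model.traces) + len(model.events) + len(model.spikes)
            g = arrays["Continuous Recording"]
            np.testing.assert_array_equal(g["data"][:], model.traces[0].samples)
            d1 = g["dimensions/1"]
            assert d1.attrs["dimension_type"] == "sample"
            assert d1.attrs["unit"] == "s"
            assert d1.attrs["sampling_interval"] == model.traces[0].sampling_interval_s
            sp = arrays["Track 1"]
            np.testing.assert_array_equal(
                sp["data"][:, 0], truth.spike_times["Track 1"][:, 0]
            )
            assert h["metadata/recording"].attrs["provenance"] == model.provenance

    def test_repeated_export_is_byte_identical(self, small_session, tmp_path):
        _, file, _ = small_session
        model = convert(file, ConverterConfig.discover(file))
        a, b = tmp_path / "a.h5", tmp_path / "b.h5"
        export_nix_h5(model, str(a))
        export_nix_h5(model, str(b))
        assert a.read_bytes() == b.read_bytes()
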