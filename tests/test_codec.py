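"""Binary codec: round-trips, strict parsing, typed failure modes."""

import struct

import numpy as np
import pytest

from dapsysio import (
    BadMagic,
    DanglingPageRef,
    DuplicateId,
    InvariantViolation,
    LengthMismatch,
    PageKind,
    TrailingData,
    TruncatedFile,
    UnknownPageKind,
    files_equal,
    read_file,
    write_file,
)
from dapsysio.codec import ByteCursor, _Writer, _write_entry, _write_page
from dapsysio.model import FileHeader
from dapsysio.codec import parse_text_page, parse_waveform_page

from conftest import make_file, stream, text_page, wf_irregular, wf_regular


def raw_serialize(pages, root, footer="v"):
    """Serialize without invariant validation (for forging malformed files)."""
    body = _Writer()
    for p in pages:
        _write_page(body, p)
    tail = _Writer()
    _write_entry(tail, root)
    tail.string(footer)
    header = bytearray(FileHeader.MAGIC + b"\x00" * 60)
    struct.pack_into("<Q", header, 8, 64 + len(body.buf))
    return bytes(header) + bytes(body.buf) + bytes(tail.buf)


@pytest.fixture
def mixed_file():
    pages = [
        wf_regular(1, 0.0, 1e-3, np.arange(5)),
        text_page(2, "heat stimulus", 0.005),
        wf_regular(3, 0.005, 1e-3, np.arange(5, 9)),
        wf_irregular(4, [0.1, 0.2, 0.3], [1.0, 2.0, 3.0]),
        text_page(5, "Track1", 3.0001, 3.0, reference=4),
    ]
    return make_file(
        pages,
        children=[
            stream(1, "Continuous Recording", PageKind.WAVEFORM, [1, 3]),
            stream(2, "Comments", PageKind.TEXT, [2]),
            stream(3, "Irregular", PageKind.WAVEFORM, [4]),
            stream(4, "Track 1", PageKind.TEXT, [5]),
        ],
    )


class TestRoundTrip:
    def test_identity(self, mixed_file):
        assert files_equal(read_file(write_file(mixed_file)), mixed_file)

    def test_write_read_write_is_byte_identical(self, mixed_file):
        data = write_file(mixed_file)
        assert write_file(read_file(data)) == data

    def test_minimal_empty_file(self):
        f = make_file()
        back = read_file(write_file(f))
        assert files_equal(back, f)
        assert back.pages == {}
        assert back.toc_root.children == []
        assert back.footer.version_string == "test footer v1"

    def test_interleaved_page_order_preserved(self, mixed_file):
        back = read_file(write_file(mixed_file))
        assert list(back.pages.keys()) == list(mixed_file.pages.keys())

    def test_session_fixture_roundtrip(self, small_session):
        _, file, _ = small_session
        data = write_file(file)
        assert files_equal(read_file(data), file)
        assert write_file(read_file(data)) == data


class TestRegularPages:
    def test_regular_page_keeps_single_timestamp(self):
        f = make_file(
            [wf_regular(1, 0.0, 1e-4, np.zeros(1000))],
            [stream(1, "S", PageKind.WAVEFORM, [1])],
        )
        page = read_file(write_file(f)).pages[1]
        assert page.is_regular
        assert page.timestamps.shape == (1,)
        assert page.n_samples == 1000
        assert page.interval == 1e-4


class TestPageParsers:
    def test_regular_decode(self):
        w = _Writer()
        _write_page(w, wf_regular(9, 0.0, 1e-4, np.arange(5)))
        page = parse_waveform_page(ByteCursor(bytes(w.buf)))
        assert page.timestamps.tolist() == [0.0]
        assert page.interval == 1e-4
        assert page.amplitudes.tolist() == [0.0, 1.0, 2.0, 3.0, 4.0]

    def test_irregular_decode(self):
        w = _Writer()
        _write_page(w, wf_irregular(9, [0.1, 0.2, 0.3], [1, 2, 3]))
        page = parse_waveform_page(ByteCursor(bytes(w.buf)))
        assert page.interval is None
        assert page.timestamps.tolist() == [0.1, 0.2, 0.3]
        assert page.amplitudes.shape == (3,)

    def test_irregular_length_mismatch(self):
        # forge: 3 timestamps but 2 amplitudes
        w = _Writer()
        w.u32(9)
        w.u8(1)  # WAVEFORM tag
        w.u32(0xFFFFFFFF)
        w.u8(0)  # irregular
        w.u32(3)
        w.array(np.array([0.1, 0.2, 0.3]))
        w.u32(2)
        w.array(np.array([1.0, 2.0], dtype=np.float32))
        with pytest.raises(LengthMismatch):
            parse_waveform_page(ByteCursor(bytes(w.buf)))

    @pytest.mark.parametrize(
        "text,ts_a,ts_b,expect_comment",
        [
            ("heat stimulus", 12.5, 12.5, True),
            ("Track1", 3.0001, 3.0, False),
            ("", 0.0, 0.0, True),
        ],
    )
    def test_text_page_semantics(self, text, ts_a, ts_b, expect_comment):
        w = _Writer()
        _write_page(w, text_page(9, text, ts_a, ts_b))
        page = parse_text_page(ByteCursor(bytes(w.buf)))
        assert page.text == text
        assert page.timestamp_a == ts_a
        assert page.timestamp_b == ts_b
        assert page.is_comment is expect_comment


class TestStrictErrors:
    def test_bad_magic(self, mixed_file):
        data = bytearray(write_file(mixed_file))
        data[:4] = b"XXXX"
        with pytest.raises(BadMagic):
            read_file(bytes(data))

    def test_unknown_page_kind(self, mixed_file):
        data = bytearray(write_file(mixed_file))
        data[64 + 4] = 0x7F  # kind tag of the first page
        with pytest.raises(UnknownPageKind):
            read_file(bytes(data))

    def test_dangling_page_ref(self):
        root = make_file([wf_regular(1, 0.0, 1e-3, [1.0])]).toc_root
        root.children = [stream(1, "S", PageKind.WAVEFORM, [999])]
        data = raw_serialize([wf_regular(1, 0.0, 1e-3, [1.0])], root)
        with pytest.raises(DanglingPageRef):
            read_file(data)

    def test_duplicate_page_id(self):
        pages = [wf_regular(1, 0.0, 1e-3, [1.0]), wf_regular(1, 0.1, 1e-3, [2.0])]
        from dapsysio.model import Folder

        data = raw_serialize(pages, Folder(id=5, name="Root"))
        with pytest.raises(DuplicateId):
            read_file(data)

    def test_trailing_bytes_rejected(self, mixed_file):
        with pytest.raises(TrailingData):
            read_file(write_file(mixed_file) + b"\x00")

    def test_truncation_at_every_byte(self, mixed_file):
        """Any prefix of a valid file fails loudly, never parses partially."""
        data = write_file(mixed_file)
        for cut in range(len(data)):
            with pytest.raises(TruncatedFile):
                read_file(data[:cut])


class TestWriteValidation:
    def test_regular_page_with_many_timestamps(self):
        page = wf_regular(1, 0.0, 1e-3, [1.0, 2.0])
        page.timestamps = np.array([0.0, 1e-3])
        f = make_file([page], [stream(1, "S", PageKind.WAVEFORM, [1])])
        with pytest.raises(InvariantViolation):
            write_file(f)

    def test_kind_mismatch_between_stream_and_page(self):
        from dapsysio import KindMismatch

        f = make_file(
            [wf_regular(1, 0.0, 1e-3, [1.0])],
            [stream(1, "S", PageKind.TEXT, [1])],
        )
        with pytest.raises(KindMismatch):
            write_file(f)

    def test_dangling_stream_ref(self):
        f = make_file([], [stream(1, "S", PageKind.WAVEFORM, [42])])
        with pytest.raises(DanglingPageRef):
            write_file(f)
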