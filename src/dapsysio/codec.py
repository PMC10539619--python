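"""Bit-exact binary codec for the reference dialect.

On-disk layout (all integers little-endian; documented byte-level in
``docs/format.md``):

* header — 64 bytes: magic ``b"DPSY"``, 4 reserved bytes, u64 absolute file
  offset of the ToC, zero padding.
* pages — consecutive page records filling ``[64, toc_offset)``.
* ToC — one recursively serialized root folder entry.
* footer — a length-prefixed version string; nothing may follow it.

Strings are u32-byte-count-prefixed Latin-1.  Parsing is strict: any
malformation raises a typed :class:`~dapsysio.errors.FormatError`, never a
partial structure.
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import (
    BadMagic,
    DuplicateId,
    EncodingError,
    InvariantViolation,
    LengthMismatch,
    TrailingData,
    TruncatedFile,
    UnknownPageKind,
)
from .model import (
    NO_REFERENCE,
    DapsysFile,
    FileFooter,
    FileHeader,
    Folder,
    Page,
    PageHeader,
    PageKind,
    Stream,
    TextPage,
    TocEntry,
    WaveformPage,
)

_ENCODING = "latin-1"
_TOC_OFFSET_AT = 8  # u64 pointer inside the 64-byte header

_KIND_TAGS = {1: PageKind.WAVEFORM, 2: PageKind.TEXT}
_KIND_BYTES = {v: k for k, v in _KIND_TAGS.items()}

_ENTRY_FOLDER = 1
_ENTRY_STREAM = 2

_REGULAR = 1
_IRREGULAR = 0


class ByteCursor:
    """Forward-only reader over a byte buffer with truncation checking."""

    def __init__(self, data: bytes, pos: int = 0):
        self.data = data
        self.pos = pos

    def read_exact(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise TruncatedFile(
                f"need {n} bytes at offset {self.pos}, only "
                f"{len(self.data) - self.pos} remain"
            )
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def u8(self) -> int:
        return self.read_exact(1)[0]

    def u32(self) -> int:
        return struct.unpack("<I", self.read_exact(4))[0]

    def u64(self) -> int:
        return struct.unpack("<Q", self.read_exact(8))[0]

    def f64(self) -> float:
        return struct.unpack("<d", self.read_exact(8))[0]

    def array(self, dtype: np.dtype, count: int) -> np.ndarray:
        dtype = np.dtype(dtype)
        raw = self.read_exact(dtype.itemsize * count)
        # copy so the array does not pin the whole source buffer
        return np.frombuffer(raw, dtype=dtype).copy()

    def string(self) -> str:
        n = self.u32()
        raw = self.read_exact(n)
        try:
            return raw.decode(_ENCODING)
        except UnicodeDecodeError as exc:  # pragma: no cover - latin-1 total
            raise EncodingError(str(exc)) from exc


class _Writer:
    def __init__(self) -> None:
        self.buf = bytearray()

    def bytes_(self, b: bytes) -> None:
        self.buf += b

    def u8(self, v: int) -> None:
        self.buf += struct.pack("<B", v)

    def u32(self, v: int) -> None:
        self.buf += struct.pack("<I", v)

    def u64(self, v: int) -> None:
        self.buf += struct.pack("<Q", v)

    def f64(self, v: float) -> None:
        self.buf += struct.pack("<d", v)

    def array(self, arr: np.ndarray) -> None:
        self.buf += arr.tobytes()

    def string(self, s: str) -> None:
        try:
            raw = s.encode(_ENCODING)
        except UnicodeEncodeError as exc:
            raise EncodingError(f"string not representable in Latin-1: {s!r}") from exc
        self.u32(len(raw))
        self.buf += raw


# ---------------------------------------------------------------------------
# pages


def _parse_page_header(cursor: ByteCursor) -> PageHeader:
    page_id = cursor.u32()
    tag = cursor.u8()
    kind = _KIND_TAGS.get(tag)
    if kind is None:
        raise UnknownPageKind(f"page {page_id}: unknown kind tag {tag:#x}")
    ref = cursor.u32()
    return PageHeader(id=page_id, kind=kind, reference_id=None if ref == NO_REFERENCE else ref)


def parse_waveform_page(cursor: ByteCursor, header: PageHeader | None = None) -> WaveformPage:
    """Decode a waveform page at the cursor.

    When ``header`` is None the shared page header (id, kind tag, reference)
    is consumed first.
    """
    if header is None:
        header = _parse_page_header(cursor)
    flag = cursor.u8()
    if flag == _REGULAR:
        t0 = cursor.f64()
        interval = cursor.f64()
        n = cursor.u32()
        amplitudes = cursor.array(np.dtype("<f4"), n)
        return WaveformPage(
            header=header,
            amplitudes=amplitudes,
            timestamps=np.array([t0], dtype=np.float64),
            interval=interval,
        )
    if flag == _IRREGULAR:
        n_ts = cursor.u32()
        timestamps = cursor.array(np.dtype("<f8"), n_ts)
        n_amp = cursor.u32()
        amplitudes = cursor.array(np.dtype("<f4"), n_amp)
        if n_ts != n_amp:
            raise LengthMismatch(
                f"page {header.id}: {n_ts} timestamps but {n_amp} amplitudes"
            )
        return WaveformPage(header=header, amplitudes=amplitudes, timestamps=timestamps)
    raise UnknownPageKind(f"page {header.id}: bad sampling flag {flag:#x}")


def parse_text_page(cursor: ByteCursor, header: PageHeader | None = None) -> TextPage:
    """Decode a text page (comment or sorted spike) at the cursor."""
    if header is None:
        header = _parse_page_header(cursor)
    text = cursor.string()
    ts_a = cursor.f64()
    ts_b = cursor.f64()
    return TextPage(header=header, text=text, timestamp_a=ts_a, timestamp_b=ts_b)


def _write_page(w: _Writer, page: Page) -> None:
    h = page.header
    w.u32(h.id)
    w.u8(_KIND_BYTES[h.kind])
    w.u32(NO_REFERENCE if h.reference_id is None else h.reference_id)
    if isinstance(page, WaveformPage):
        if page.is_regular:
            w.u8(_REGULAR)
            w.f64(page.t0)
            w.f64(float(page.interval))
            w.u32(page.n_samples)
            w.array(page.amplitudes.astype("<f4", copy=False))
        else:
            w.u8(_IRREGULAR)
            w.u32(page.timestamps.shape[0])
            w.array(page.timestamps.astype("<f8", copy=False))
            w.u32(page.n_samples)
            w.array(page.amplitudes.astype("<f4", copy=False))
    else:
        w.string(page.text)
        w.f64(page.timestamp_a)
        w.f64(page.timestamp_b)


# ---------------------------------------------------------------------------
# ToC


def _parse_entry(cursor: ByteCursor) -> TocEntry:
    entry_id = cursor.u32()
    name = cursor.string()
    entry_type = cursor.u8()
    if entry_type == _ENTRY_FOLDER:
        n = cursor.u32()
        children = [_parse_entry(cursor) for _ in range(n)]
        return Folder(id=entry_id, name=name, children=children)
    if entry_type == _ENTRY_STREAM:
        tag = cursor.u8()
        stream_type = _KIND_TAGS.get(tag)
        if stream_type is None:
            raise UnknownPageKind(f"stream {name!r}: unknown stream type tag {tag:#x}")
        n_pages = cursor.u32()
        page_ids = cursor.array(np.dtype("<u4"), n_pages)
        plot_config = cursor.read_exact(Stream.PLOT_CONFIG_SIZE)
        return Stream(
            id=entry_id,
            name=name,
            stream_type=stream_type,
            page_ids=page_ids,
            plot_config=plot_config,
        )
    raise UnknownPageKind(f"entry {name!r}: unknown entry type {entry_type:#x}")


def _write_entry(w: _Writer, entry: TocEntry) -> None:
    w.u32(entry.id)
    w.string(entry.name)
    if isinstance(entry, Folder):
        w.u8(_ENTRY_FOLDER)
        w.u32(len(entry.children))
        for child in entry.children:
            _write_entry(w, child)
    elif isinstance(entry, Stream):
        w.u8(_ENTRY_STREAM)
        w.u8(_KIND_BYTES[entry.stream_type])
        w.u32(entry.page_ids.shape[0])
        w.array(entry.page_ids.astype("<u4", copy=False))
        w.bytes_(entry.plot_config)
    else:  # pragma: no cover
        raise InvariantViolation(f"unknown entry class {type(entry).__name__}")


# ---------------------------------------------------------------------------
# whole files


def read_file(source: bytes) -> DapsysFile:
    """Parse a complete file in the reference dialect.

    The four sections are consumed strictly in order: header, pages, ToC,
    footer.  All model invariants (page-id uniqueness, stream/page kind
    agreement, resolvable references) are enforced before returning.
    """
    cursor = ByteCursor(bytes(source))
    raw_header = cursor.read_exact(FileHeader.SIZE)
    if raw_header[:4] != FileHeader.MAGIC:
        raise BadMagic(f"expected magic {FileHeader.MAGIC!r}, got {raw_header[:4]!r}")
    toc_offset = struct.unpack_from("<Q", raw_header, _TOC_OFFSET_AT)[0]
    if toc_offset < FileHeader.SIZE:
        raise TruncatedFile(f"ToC offset {toc_offset} points inside the header")
    if toc_offset > len(cursor.data):
        raise TruncatedFile(
            f"ToC offset {toc_offset} beyond end of file ({len(cursor.data)} bytes)"
        )

    pages: dict[int, Page] = {}
    while cursor.pos < toc_offset:
        header = _parse_page_header(cursor)
        if header.kind is PageKind.WAVEFORM:
            page: Page = parse_waveform_page(cursor, header)
        else:
            page = parse_text_page(cursor, header)
        if cursor.pos > toc_offset:
            raise TruncatedFile(
                f"page {header.id} runs past the ToC offset ({toc_offset})"
            )
        if header.id in pages:
            raise DuplicateId(f"duplicate page id {header.id}")
        pages[header.id] = page

    root = _parse_entry(cursor)
    if not isinstance(root, Folder):
        raise InvariantViolation("ToC root entry is not a folder")
    footer = FileFooter(version_string=cursor.string())
    if cursor.pos != len(cursor.data):
        raise TrailingData(
            f"{len(cursor.data) - cursor.pos} bytes after the footer"
        )

    f = DapsysFile(
        header=FileHeader(raw=raw_header), pages=pages, toc_root=root, footer=footer
    )
    f.validate()
    return f


def write_file(file: DapsysFile) -> bytes:
    """Serialize to the reference dialect.

    Pages are emitted in the iteration order of ``file.pages`` (the fixture
    generator and ``read_file`` both produce recording order).  Output parses
    back to an equal structure and is byte-identical under
    ``write ∘ read ∘ write``.
    """
    file.validate()

    body = _Writer()
    for page in file.pages.values():
        _write_page(body, page)
    toc_offset = FileHeader.SIZE + len(body.buf)

    tail = _Writer()
    _write_entry(tail, file.toc_root)
    tail.string(file.footer.version_string)

    raw = bytearray(file.header.raw or (FileHeader.MAGIC + b"\x00" * (FileHeader.SIZE - 4)))
    struct.pack_into("<Q", raw, _TOC_OFFSET_AT, toc_offset)
    return bytes(raw) + bytes(body.buf) + bytes(tail.buf)
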