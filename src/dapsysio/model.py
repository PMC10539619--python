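"""In-memory model of a DAPSYS-style recording file.

A file is flat: a fixed-size header, a sequence of data *pages* (discontinuous
chunks of waveform samples or text annotations, each with a file-unique id),
a table of contents (ToC) organizing pages into a folder/stream hierarchy, and
a footer carrying the version string of the acquisition program.

Waveform pages hold f32 amplitudes with f64 timestamps in seconds; regularly
sampled pages store only the first timestamp plus a fixed sampling interval.
Text pages hold a string and two f64 timestamps: equal timestamps mark a
comment entered during the recording, distinct timestamps mark a sorted spike
whose second timestamp is the automatically recognized spike time.
"""

from __future__ import annotations

import enum
import struct
from dataclasses import dataclass, field
from typing import Iterator, NewType, Optional, Union

import numpy as np

from .errors import DanglingPageRef, DuplicateId, InvariantViolation, KindMismatch

PageId = NewType("PageId", int)
EntryId = NewType("EntryId", int)

#: Sentinel used on disk for an absent ``reference_id``.
NO_REFERENCE = 0xFFFFFFFF


class PageKind(enum.Enum):
    """Discriminator for the two page payload layouts."""

    WAVEFORM = 1
    TEXT = 2


def _f64_bits_equal(a: float, b: float) -> bool:
    # bitwise f64 comparison: distinguishes timestamps that compare == under
    # IEEE semantics but differ in representation (and treats NaN==NaN).
    return struct.pack("<d", a) == struct.pack("<d", b)


@dataclass(frozen=True)
class FileHeader:
    """Fixed 64-byte header; only the magic tag and ToC pointer matter."""

    raw: bytes = b""

    SIZE = 64
    MAGIC = b"DPSY"

    def __post_init__(self) -> None:
        if self.raw and len(self.raw) != self.SIZE:
            raise InvariantViolation(
                f"header must be exactly {self.SIZE} bytes, got {len(self.raw)}"
            )

    @property
    def magic(self) -> bytes:
        return (self.raw or self.MAGIC)[:4]


@dataclass(frozen=True)
class PageHeader:
    """Metadata common to all pages: id, kind tag, optional page reference."""

    id: int
    kind: PageKind
    reference_id: Optional[int] = None


@dataclass
class WaveformPage:
    """A chunk of sampled signal.

    ``interval is None`` means irregular sampling: one timestamp per
    amplitude, strictly increasing.  ``interval`` set means regular sampling:
    ``timestamps`` holds only the first sample time and the remaining times
    are implied by the interval.
    """

    header: PageHeader
    amplitudes: np.ndarray  # f32
    timestamps: np.ndarray  # f64, seconds
    interval: Optional[float] = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float32)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)

    @property
    def is_regular(self) -> bool:
        return self.interval is not None

    @property
    def n_samples(self) -> int:
        return int(self.amplitudes.shape[0])

    @property
    def t0(self) -> float:
        return float(self.timestamps[0])

    def validate(self) -> None:
        if self.header.kind is not PageKind.WAVEFORM:
            raise InvariantViolation(f"page {self.header.id}: kind tag is not WAVEFORM")
        if self.n_samples < 1:
            raise InvariantViolation(f"page {self.header.id}: empty amplitude array")
        if self.is_regular:
            if self.timestamps.shape[0] != 1:
                raise InvariantViolation(
                    f"page {self.header.id}: regular page must store exactly one "
                    f"timestamp, got {self.timestamps.shape[0]}"
                )
            if not self.interval > 0:
                raise InvariantViolation(
                    f"page {self.header.id}: sampling interval must be > 0"
                )
        else:
            if self.timestamps.shape[0] != self.amplitudes.shape[0]:
                raise InvariantViolation(
                    f"page {self.header.id}: {self.timestamps.shape[0]} timestamps "
                    f"vs {self.amplitudes.shape[0]} amplitudes"
                )
            if self.timestamps.shape[0] > 1 and not np.all(np.diff(self.timestamps) > 0):
                raise InvariantViolation(
                    f"page {self.header.id}: irregular timestamps not strictly increasing"
                )


@dataclass
class TextPage:
    """A comment or a sorted spike.

    ``timestamp_a`` is the primary (entered) time.  For comments
    ``timestamp_b`` is bit-identical to it; for sorted spikes it carries the
    automatically recognized spike time and differs.
    """

    header: PageHeader
    text: str
    timestamp_a: float
    timestamp_b: float

    @property
    def is_comment(self) -> bool:
        return _f64_bits_equal(self.timestamp_a, self.timestamp_b)

    def validate(self) -> None:
        if self.header.kind is not PageKind.TEXT:
            raise InvariantViolation(f"page {self.header.id}: kind tag is not TEXT")
        if not self.timestamp_a >= 0:
            raise InvariantViolation(f"page {self.header.id}: negative timestamp")


Page = Union[WaveformPage, TextPage]


@dataclass
class TocEntry:
    """Common fields of ToC elements: an id (namespace unrelated to page ids)
    and a non-empty display name."""

    id: int
    name: str

    def validate(self) -> None:
        if not self.name:
            raise InvariantViolation(f"ToC entry {self.id}: empty name")


@dataclass
class Stream(TocEntry):
    """A leaf of the ToC: an ordered array of page ids of one kind, plus the
    opaque plot configuration used by the acquisition GUI."""

    stream_type: PageKind = PageKind.WAVEFORM
    page_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint32))
    plot_config: bytes = b"\x00" * 32

    PLOT_CONFIG_SIZE = 32

    def __post_init__(self) -> None:
        self.page_ids = np.asarray(self.page_ids, dtype=np.uint32)

    def validate(self) -> None:
        super().validate()
        if len(self.plot_config) != self.PLOT_CONFIG_SIZE:
            raise InvariantViolation(
                f"stream {self.name!r}: plot_config must be "
                f"{self.PLOT_CONFIG_SIZE} bytes"
            )


@dataclass
class Folder(TocEntry):
    """An inner node of the ToC with named, order-preserving children and
    dictionary-like (case-insensitive) access to them."""

    children: list[TocEntry] = field(default_factory=list)

    def __getitem__(self, name: str) -> TocEntry:
        matches = [c for c in self.children if c.name.lower() == name.lower()]
        if not matches:
            raise KeyError(name)
        if len(matches) > 1:
            raise KeyError(f"ambiguous child name {name!r}")
        return matches[0]

    def __contains__(self, name: str) -> bool:
        return any(c.name.lower() == name.lower() for c in self.children)

    def __iter__(self) -> Iterator[TocEntry]:
        return iter(self.children)

    def keys(self) -> list[str]:
        return [c.name for c in self.children]

    def walk(self) -> Iterator[tuple[tuple[str, ...], TocEntry]]:
        """Yield ``(path_segments, entry)`` depth-first over the subtree."""
        for child in self.children:
            yield (child.name,), child
            if isinstance(child, Folder):
                for path, entry in child.walk():
                    yield (child.name, *path), entry


@dataclass(frozen=True)
class FileFooter:
    """Trailer after the ToC: program version and serial number string."""

    version_string: str = ""


@dataclass
class DapsysFile:
    """A complete parsed file: flat page store plus the ToC view onto it."""

    header: FileHeader = field(default_factory=FileHeader)
    pages: dict[int, Page] = field(default_factory=dict)
    toc_root: Folder = field(default_factory=lambda: Folder(id=0, name="Root"))
    footer: FileFooter = field(default_factory=FileFooter)

    def streams(self) -> Iterator[tuple[tuple[str, ...], Stream]]:
        for path, entry in self.toc_root.walk():
            if isinstance(entry, Stream):
                yield path, entry

    def validate(self) -> None:
        """Check every model invariant; raise on the first violation.

        Applied symmetrically by the reader (after parsing) and the writer
        (before serializing).
        """
        for pid, page in self.pages.items():
            if page.header.id != pid:
                raise InvariantViolation(f"page store key {pid} != page id {page.header.id}")
            page.validate()
            ref = page.header.reference_id
            if ref is not None and ref not in self.pages:
                raise DanglingPageRef(f"page {pid} references absent page {ref}")

        seen_entry_ids: set[int] = set()
        seen_names: set[int] = set()  # id() of entries, to detect shared children

        def check_entry(entry: TocEntry) -> None:
            entry.validate()
            if entry.id in seen_entry_ids:
                raise DuplicateId(f"duplicate ToC entry id {entry.id}")
            seen_entry_ids.add(entry.id)
            if id(entry) in seen_names:
                raise InvariantViolation(f"entry {entry.name!r} appears under two parents")
            seen_names.add(id(entry))
            if isinstance(entry, Folder):
                for child in entry.children:
                    check_entry(child)
            elif isinstance(entry, Stream):
                for pid in entry.page_ids.tolist():
                    page = self.pages.get(pid)
                    if page is None:
                        raise DanglingPageRef(
                            f"stream {entry.name!r} cites absent page id {pid}"
                        )
                    if page.header.kind is not entry.stream_type:
                        raise KindMismatch(
                            f"stream {entry.name!r} ({entry.stream_type.name}) cites "
                            f"{page.header.kind.name} page {pid}"
                        )

        check_entry(self.toc_root)
        if not isinstance(self.toc_root, Folder):
            raise InvariantViolation("ToC root must be a folder")


def _arrays_bitwise_equal(a: np.ndarray, b: np.ndarray) -> bool:
    return a.shape == b.shape and a.tobytes() == b.tobytes()


def pages_equal(a: Page, b: Page) -> bool:
    """Field-by-field page equality; floats compared bitwise."""
    if type(a) is not type(b) or a.header != b.header:
        return False
    if isinstance(a, WaveformPage):
        assert isinstance(b, WaveformPage)
        if (a.interval is None) != (b.interval is None):
            return False
        if a.interval is not None and not _f64_bits_equal(a.interval, b.interval):
            return False
        return _arrays_bitwise_equal(a.amplitudes, b.amplitudes) and _arrays_bitwise_equal(
            a.timestamps, b.timestamps
        )
    assert isinstance(a, TextPage) and isinstance(b, TextPage)
    return (
        a.text == b.text
        and _f64_bits_equal(a.timestamp_a, b.timestamp_a)
        and _f64_bits_equal(a.timestamp_b, b.timestamp_b)
    )


def entries_equal(a: TocEntry, b: TocEntry) -> bool:
    """Recursive ToC equality preserving child and page order."""
    if type(a) is not type(b) or a.id != b.id or a.name != b.name:
        return False
    if isinstance(a, Folder):
        assert isinstance(b, Folder)
        return len(a.children) == len(b.children) and all(
            entries_equal(x, y) for x, y in zip(a.children, b.children)
        )
    assert isinstance(a, Stream) and isinstance(b, Stream)
    return (
        a.stream_type is b.stream_type
        and a.plot_config == b.plot_config
        and _arrays_bitwise_equal(a.page_ids, b.page_ids)
    )


def _header_raw_masked(raw: bytes) -> bytes:
    # bytes 8..16 hold the codec-owned ToC offset pointer; it is derived
    # data recomputed on every write, not part of the logical model
    return raw[:8] + b"\x00" * 8 + raw[16:]


def files_equal(a: DapsysFile, b: DapsysFile) -> bool:
    """Structural equality of two files (used by round-trip checks)."""
    if (
        a.header.raw
        and b.header.raw
        and _header_raw_masked(a.header.raw) != _header_raw_masked(b.header.raw)
    ):
        return False
    if a.footer != b.footer:
        return False
    if list(a.pages.keys()) != list(b.pages.keys()):
        return False
    if not all(pages_equal(a.pages[k], b.pages[k]) for k in a.pages):
        return False
    return entries_equal(a.toc_root, b.toc_root)
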