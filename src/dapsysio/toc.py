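"""Navigation of the ToC tree and assembly of per-stream data.

A recording's continuous signal is stored as many discontinuous waveform
pages; this module concatenates them (expanding regularly sampled pages into
explicit per-sample timestamps) into flat slabs, and exposes the aligned
comment/spike view of text streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

from .errors import AmbiguousPath, DanglingPageRef, KindMismatch, NotFound, NotRegular
from .model import DapsysFile, Folder, PageKind, Stream, TextPage, TocEntry, WaveformPage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StreamPath:
    """A case-insensitive path of display names from the ToC root.

    Whitespace is significant (stream names may legitimately end in spaces);
    matching lowercases only.
    """

    segments: tuple[str, ...]

    SEPARATOR = "/"

    @classmethod
    def of(cls, path: Union["StreamPath", str, Iterable[str]]) -> "StreamPath":
        """Coerce a ``"Folder/Stream"`` string or a segment sequence."""
        if isinstance(path, StreamPath):
            return path
        if isinstance(path, str):
            segments = tuple(s for s in path.split(cls.SEPARATOR) if s != "")
            return cls(segments)
        return cls(tuple(path))

    def __str__(self) -> str:
        return self.SEPARATOR.join(self.segments)


def resolve(root: Folder, path: Union[StreamPath, str, Iterable[str]]) -> TocEntry:
    """Resolve a path to its unique ToC entry.

    The empty path resolves to ``root`` itself.  Duplicate sibling names are
    reported as :class:`AmbiguousPath` at resolve time.
    """
    path = StreamPath.of(path)
    entry: TocEntry = root
    for depth, segment in enumerate(path.segments):
        if not isinstance(entry, Folder):
            raise NotFound(
                f"{'/'.join(path.segments[:depth])!r} is a stream, cannot descend "
                f"into {segment!r}"
            )
        matches = [c for c in entry.children if c.name.lower() == segment.lower()]
        if not matches:
            raise NotFound(f"no entry {segment!r} under {entry.name!r}")
        if len(matches) > 1:
            raise AmbiguousPath(
                f"{len(matches)} siblings named {segment!r} under {entry.name!r}"
            )
        entry = matches[0]
    return entry


def resolve_stream(file: DapsysFile, path, kind: PageKind | None = None) -> Stream:
    """Resolve a path and require a stream (optionally of a given kind)."""
    entry = resolve(file.toc_root, path)
    if not isinstance(entry, Stream):
        raise KindMismatch(f"{path!s} is a folder, not a stream")
    if kind is not None and entry.stream_type is not kind:
        raise KindMismatch(
            f"{path!s} is a {entry.stream_type.name} stream, expected {kind.name}"
        )
    return entry


def expand_regular_timestamps(page: WaveformPage) -> np.ndarray:
    """Explicit per-sample timestamps of a regularly sampled page.

    Uses the closed form ``t0 + k*dt`` rather than iterative accumulation so
    no drift accumulates over long pages; each timestamp carries at most two
    correctly rounded operations of error.
    """
    if not page.is_regular:
        raise NotRegular(f"page {page.header.id} has per-sample timestamps")
    n = page.n_samples
    return page.t0 + np.arange(n, dtype=np.float64) * float(page.interval)


def page_timestamps(page: WaveformPage) -> np.ndarray:
    """Per-sample timestamps regardless of sampling mode."""
    return expand_regular_timestamps(page) if page.is_regular else page.timestamps


@dataclass
class WaveformSlab:
    """Concatenation of one waveform stream's pages in stream order."""

    timestamps: np.ndarray  # f64 seconds
    amplitudes: np.ndarray  # f32
    page_boundaries: np.ndarray  # index where each source page begins

    def __len__(self) -> int:
        return int(self.amplitudes.shape[0])


@dataclass
class TextSlab:
    """Aligned view of one text stream's pages in stream order."""

    texts: list[str]
    timestamps_a: np.ndarray
    timestamps_b: np.ndarray
    is_comment: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.texts)


def stream_pages(file: DapsysFile, stream: Stream, kind: PageKind):
    """Pages of ``stream`` in page_ids order, kind-checked (helper)."""
    if stream.stream_type is not kind:
        raise KindMismatch(
            f"stream {stream.name!r} is {stream.stream_type.name}, expected {kind.name}"
        )
    pages = []
    for pid in stream.page_ids.tolist():
        if pid not in file.pages:
            raise DanglingPageRef(f"stream {stream.name!r} cites absent page id {pid}")
        page = file.pages[pid]
        if page.header.kind is not kind:
            raise KindMismatch(
                f"stream {stream.name!r} cites {page.header.kind.name} page {pid}"
            )
        pages.append(page)
    return pages


def assemble_waveform(file: DapsysFile, stream: Stream) -> WaveformSlab:
    """Concatenate all waveform pages of a stream into one slab.

    Pages are taken in ``page_ids`` order; out-of-order timestamps across
    page boundaries are tolerated with a warning (files are observed, not
    guaranteed, to store pages in recording order).
    """
    pages: list[WaveformPage] = stream_pages(file, stream, PageKind.WAVEFORM)
    if not pages:
        empty_idx = np.empty(0, dtype=np.intp)
        return WaveformSlab(
            timestamps=np.empty(0, dtype=np.float64),
            amplitudes=np.empty(0, dtype=np.float32),
            page_boundaries=empty_idx,
        )
    ts_parts = [page_timestamps(p) for p in pages]
    boundaries = np.cumsum([0] + [p.n_samples for p in pages[:-1]], dtype=np.intp)
    timestamps = np.concatenate(ts_parts)
    if np.any(np.diff(timestamps) < 0):
        logger.warning(
            "stream %r: assembled timestamps are not non-decreasing "
            "(pages stored out of recording order)",
            stream.name,
        )
    return WaveformSlab(
        timestamps=timestamps,
        amplitudes=np.concatenate([p.amplitudes for p in pages]),
        page_boundaries=boundaries,
    )


def assemble_text(file: DapsysFile, stream: Stream) -> TextSlab:
    """Aligned arrays over a text stream's pages in ``page_ids`` order.

    ``is_comment[i]`` applies the equal-timestamp rule: a text page whose two
    timestamps are bit-identical is a comment, otherwise a sorted spike.
    """
    pages: list[TextPage] = stream_pages(file, stream, PageKind.TEXT)
    return TextSlab(
        texts=[p.text for p in pages],
        timestamps_a=np.array([p.timestamp_a for p in pages], dtype=np.float64),
        timestamps_b=np.array([p.timestamp_b for p in pages], dtype=np.float64),
        is_comment=np.array([p.is_comment for p in pages], dtype=bool),
    )
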