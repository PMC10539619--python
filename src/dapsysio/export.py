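"""Conversion to a generic recording model and export to NIX/HDF5 and CSV.

The recording model is a library-neutral container with three entity types:

* :class:`ContinuousTrace` — a stretch of regularly (start + interval) or
  irregularly (explicit times) sampled signal;
* :class:`EventSeries` — labelled time points (experimenter comments);
* :class:`SpikeSeries` — per-track sorted spikes with both the entered and
  the automatically recognized timestamps.

Because different experimental set-ups produce different ToC structures,
there is no universal conversion; a :class:`ConverterConfig` names which
streams play which role (with :meth:`ConverterConfig.discover` as a
heuristic default).

Exports:

* ``export_nix_h5`` writes one HDF5 file following the NIX data-model layout
  (``/data/<block>/data_arrays/<name>`` groups holding a ``data`` dataset
  plus a ``dimensions`` subtree; provenance under ``/metadata``);
* ``export_csv`` writes the fixed-precision CSV dialect: waveform rows
  ``t,v`` at 6 decimals on both columns, text rows ``t,text`` at 4 decimals.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import h5py
import numpy as np

from .errors import InvariantViolation, IOFailure, KindMismatch
from .model import DapsysFile, Folder, PageKind, Stream, WaveformPage
from .precision import format_fixed
from .toc import (
    StreamPath,
    assemble_text,
    assemble_waveform,
    resolve,
    resolve_stream,
    stream_pages,
)

PathLike = Union[StreamPath, str, Sequence[str]]


@dataclass
class ContinuousTrace:
    """A gap-free stretch of signal."""

    name: str
    start_time_s: float
    samples: np.ndarray  # f32
    sampling_interval_s: Optional[float] = None  # None => irregular
    times_s: Optional[np.ndarray] = None  # per-sample times when irregular

    @property
    def is_regular(self) -> bool:
        return self.sampling_interval_s is not None

    def timestamps(self) -> np.ndarray:
        if self.is_regular:
            n = self.samples.shape[0]
            return self.start_time_s + np.arange(n, dtype=np.float64) * float(
                self.sampling_interval_s
            )
        return self.times_s


@dataclass
class EventSeries:
    """Labelled time points, sorted by time."""

    name: str
    times_s: np.ndarray
    labels: list[str]


@dataclass
class SpikeSeries:
    """One track of sorted spikes."""

    track_name: str
    entered_times_s: np.ndarray
    recognized_times_s: np.ndarray


@dataclass
class RecordingModel:
    """Converted recording: traces + events + spikes with provenance."""

    traces: list[ContinuousTrace] = field(default_factory=list)
    events: list[EventSeries] = field(default_factory=list)
    spikes: list[SpikeSeries] = field(default_factory=list)
    provenance: str = "dapsysio"


@dataclass
class ConverterConfig:
    """Which ToC streams feed which recording-model entity.

    ``merge_gap_tolerance`` is the fraction of one sampling interval by which
    a following page's start may deviate from the seamless continuation time
    and still be merged into the running trace.
    """

    continuous_paths: list[StreamPath] = field(default_factory=list)
    comment_paths: list[StreamPath] = field(default_factory=list)
    track_folder_paths: list[StreamPath] = field(default_factory=list)
    merge_gap_tolerance: float = 0.5

    def __post_init__(self) -> None:
        self.continuous_paths = [StreamPath.of(p) for p in self.continuous_paths]
        self.comment_paths = [StreamPath.of(p) for p in self.comment_paths]
        self.track_folder_paths = [StreamPath.of(p) for p in self.track_folder_paths]
        if not 0 < self.merge_gap_tolerance < 1:
            raise InvariantViolation("merge_gap_tolerance must lie in (0, 1)")

    @classmethod
    def discover(cls, file: DapsysFile) -> "ConverterConfig":
        """Heuristic config: waveform streams become traces; text streams
        containing any sorted spike become tracks, the rest comments."""
        continuous: list[StreamPath] = []
        comments: list[StreamPath] = []
        tracks: list[StreamPath] = []
        track_parents: set[tuple[str, ...]] = set()
        for path, stream in file.streams():
            p = StreamPath(path)
            if stream.stream_type is PageKind.WAVEFORM:
                continuous.append(p)
            else:
                slab = assemble_text(file, stream)
                if len(slab) and not slab.is_comment.all():
                    track_parents.add(path[:-1])
                else:
                    comments.append(p)
        for parent in sorted(track_parents):
            tracks.append(StreamPath(parent))
        return cls(
            continuous_paths=continuous,
            comment_paths=comments,
            track_folder_paths=tracks,
        )


def _bits(x: float) -> bytes:
    return struct.pack("<d", float(x))


def _traces_from_stream(
    file: DapsysFile, path: StreamPath, tolerance: float
) -> list[ContinuousTrace]:
    stream = resolve_stream(file, path, PageKind.WAVEFORM)
    pages: list[WaveformPage] = stream_pages(file, stream, PageKind.WAVEFORM)
    base = str(path)

    traces: list[ContinuousTrace] = []
    run: list[WaveformPage] = []  # current mergeable run of regular pages

    def flush_run() -> None:
        if not run:
            return
        samples = np.concatenate([p.amplitudes for p in run])
        traces.append(
            ContinuousTrace(
                name=base,
                start_time_s=run[0].t0,
                samples=samples,
                sampling_interval_s=float(run[0].interval),
            )
        )
        run.clear()

    for page in pages:
        if not page.is_regular:
            flush_run()
            traces.append(
                ContinuousTrace(
                    name=base,
                    start_time_s=page.t0,
                    samples=page.amplitudes.copy(),
                    times_s=page.timestamps.copy(),
                )
            )
            continue
        if run:
            dt = float(run[0].interval)
            n_run = sum(p.n_samples for p in run)
            seamless = run[0].t0 + n_run * dt
            if _bits(page.interval) == _bits(dt) and abs(page.t0 - seamless) <= (
                tolerance * dt
            ):
                run.append(page)
                continue
            flush_run()
        run.append(page)
    flush_run()

    if len(traces) > 1:
        for i, tr in enumerate(traces):
            tr.name = f"{base} [{i}]"
    return traces


def convert(file: DapsysFile, config: ConverterConfig) -> RecordingModel:
    """Convert the configured streams into a :class:`RecordingModel`.

    Consecutive regular waveform pages are merged into one trace when their
    intervals agree bitwise and the next page starts within
    ``merge_gap_tolerance`` of the seamless continuation time; comment-induced
    page splits therefore disappear, while real gaps start a new trace.
    """
    model = RecordingModel(
        provenance=f"{file.footer.version_string} | dapsysio stream-path converter"
    )
    for path in config.continuous_paths:
        model.traces.extend(_traces_from_stream(file, path, config.merge_gap_tolerance))
    for path in config.comment_paths:
        stream = resolve_stream(file, path, PageKind.TEXT)
        slab = assemble_text(file, stream)
        keep = slab.is_comment
        times = slab.timestamps_a[keep]
        labels = [t for t, c in zip(slab.texts, keep) if c]
        order = np.argsort(times, kind="stable")
        model.events.append(
            EventSeries(
                name=str(path),
                times_s=times[order],
                labels=[labels[i] for i in order],
            )
        )
    for folder_path in config.track_folder_paths:
        folder = resolve(file.toc_root, folder_path)
        if not isinstance(folder, Folder):
            raise KindMismatch(f"{folder_path!s} is a stream, expected a folder")
        for child in folder:
            if not isinstance(child, Stream) or child.stream_type is not PageKind.TEXT:
                continue
            slab = assemble_text(file, child)
            keep = ~slab.is_comment
            model.spikes.append(
                SpikeSeries(
                    track_name=child.name,
                    entered_times_s=slab.timestamps_a[keep],
                    recognized_times_s=slab.timestamps_b[keep],
                )
            )
    return model


# ---------------------------------------------------------------------------
# CSV dialect

WAVEFORM_DECIMALS = 6
TEXT_DECIMALS = 4


def _csv_escape(text: str) -> str:
    if any(ch in text for ch in ',"\n\r'):
        return '"' + text.replace('"', '""') + '"'
    return text


def csv_text(file: DapsysFile, stream_path: PathLike, header: bool = False) -> str:
    """Render one stream as CSV dialect text (LF line endings).

    Waveform streams: ``timestamp,value`` rows, both columns at 6 decimals.
    Text streams: ``timestamp,text`` rows, timestamp at 4 decimals (the
    recognized spike time for sorted spikes, the entry time for comments),
    text double-quoted per RFC 4180 only when it contains a separator.
    """
    path = StreamPath.of(stream_path)
    stream = resolve_stream(file, path)
    lines: list[str] = []
    if stream.stream_type is PageKind.WAVEFORM:
        if header:
            lines.append("timestamp,value")
        slab = assemble_waveform(file, stream)
        lines.extend(
            f"{format_fixed(t, WAVEFORM_DECIMALS)},{format_fixed(v, WAVEFORM_DECIMALS)}"
            for t, v in zip(slab.timestamps.tolist(), slab.amplitudes.tolist())
        )
    else:
        if header:
            lines.append("timestamp,text")
        slab = assemble_text(file, stream)
        lines.extend(
            f"{format_fixed(t, TEXT_DECIMALS)},{_csv_escape(s)}"
            for t, s in zip(slab.timestamps_b.tolist(), slab.texts)
        )
    return "\n".join(lines) + ("\n" if lines else "")


def export_csv(
    file: DapsysFile, stream_path: PathLike, path: str, header: bool = False
) -> str:
    """Write one stream's CSV export to ``path``; returns the path."""
    text = csv_text(file, stream_path, header=header)
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    except OSError as exc:
        raise IOFailure(f"cannot write CSV to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# NIX-structured HDF5

_NIX_VERSION = (1, 2, 1)
_FIXED_TIME = "1970-01-01T00:00:00"  # fixed so repeated exports are identical


def _entity_id(*parts: str) -> str:
    digest = hashlib.md5("/".join(parts).encode("utf-8")).hexdigest()
    return f"{digest[:8]}-{digest[8:12]}-{digest[12:16]}-{digest[16:20]}-{digest[20:32]}"


def _nix_entity(parent: h5py.Group, key: str, name: str, type_: str) -> h5py.Group:
    g = parent.create_group(key)
    g.attrs["name"] = name
    g.attrs["type"] = type_
    g.attrs["entity_id"] = _entity_id(parent.name, name)
    g.attrs["created_at"] = _FIXED_TIME
    g.attrs["updated_at"] = _FIXED_TIME
    return g


def export_nix_h5(model: RecordingModel, path: str) -> str:
    """Serialize a :class:`RecordingModel` as a NIX-structured HDF5 file.

    One block holds one data array per trace, event series and spike series:
    traces as f32 arrays with a sampled (regular) or range (irregular) time
    dimension in seconds; events as f64 times with their labels on a set
    dimension; spikes as an ``(n, 2)`` f64 array of entered/recognized times.
    The source file's footer string is stored as metadata.  All ids and
    timestamps are deterministic so identical models export identical bytes.
    """
    str_dt = h5py.string_dtype(encoding="utf-8")
    # group/attr creation order is fixed by insertion; no HDF5 object times
    try:
        fh = h5py.File(path, "w", track_order=True)
    except OSError as exc:
        raise IOFailure(f"cannot create HDF5 file {path}: {exc}") from exc
    with fh:
        fh.attrs["format"] = "nix"
        fh.attrs["version"] = np.asarray(_NIX_VERSION, dtype=np.int32)
        fh.attrs["created_at"] = _FIXED_TIME
        fh.attrs["updated_at"] = _FIXED_TIME
        fh.attrs["id"] = _entity_id("file", model.provenance)

        data = fh.create_group("data")
        block = _nix_entity(data, "recording", "recording", "dapsysio.recording")
        arrays = block.create_group("data_arrays")
        for sub in ("sources", "tags", "multi_tags", "groups"):
            block.create_group(sub)

        def da(name: str, type_: str) -> h5py.Group:
            key = name.replace("/", ".")
            return _nix_entity(arrays, key, name, type_)

        for trace in model.traces:
            g = da(trace.name, "dapsysio.trace")
            g.create_dataset("data", data=trace.samples.astype("<f4"), track_times=False)
            dims = g.create_group("dimensions")
            d1 = dims.create_group("1")
            if trace.is_regular:
                d1.attrs["dimension_type"] = "sample"
                d1.attrs["sampling_interval"] = float(trace.sampling_interval_s)
                d1.attrs["offset"] = float(trace.start_time_s)
            else:
                d1.attrs["dimension_type"] = "range"
                d1.create_dataset(
                    "ticks", data=trace.times_s.astype("<f8"), track_times=False
                )
            d1.attrs["unit"] = "s"

        for ev in model.events:
            g = da(ev.name, "dapsysio.events")
            g.attrs["unit"] = "s"
            g.create_dataset("data", data=ev.times_s.astype("<f8"), track_times=False)
            d1 = g.create_group("dimensions").create_group("1")
            d1.attrs["dimension_type"] = "set"
            d1.create_dataset("labels", data=ev.labels, dtype=str_dt, track_times=False)

        for sp in model.spikes:
            g = da(sp.track_name, "dapsysio.spikes")
            g.attrs["unit"] = "s"
            stacked = np.column_stack(
                [sp.entered_times_s, sp.recognized_times_s]
            ).astype("<f8")
            g.create_dataset("data", data=stacked, track_times=False)
            dims = g.create_group("dimensions")
            dims.create_group("1").attrs["dimension_type"] = "set"
            d2 = dims.create_group("2")
            d2.attrs["dimension_type"] = "set"
            d2.create_dataset(
                "labels",
                data=["entered_time", "recognized_time"],
                dtype=str_dt,
                track_times=False,
            )

        meta = fh.create_group("metadata")
        section = _nix_entity(meta, "recording", "recording", "dapsysio.session")
        section.attrs["provenance"] = model.provenance
    return path
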