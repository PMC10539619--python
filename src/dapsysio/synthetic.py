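"""Deterministic generator of microneurography-like recording fixtures.

A generated session mimics what the acquisition program writes during a
human single-fiber recording: one regularly sampled continuous signal split
across many waveform pages, comments typed by the experimenter (each comment
flushes the current waveform page and starts a new one), and per-track
sorted-spike text streams whose second timestamp carries the automatically
recognized spike time.

All randomness derives from one master seed through named
``numpy.random.SeedSequence`` spawns, so adding a new consumer never silently
changes existing fixtures, and the same seed always yields a byte-identical
file.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np

from .errors import InvalidSpec
from .model import (
    DapsysFile,
    FileFooter,
    FileHeader,
    Folder,
    Page,
    PageHeader,
    PageKind,
    Stream,
    TextPage,
    WaveformPage,
)
from .toc import StreamPath, assemble_text, assemble_waveform, resolve_stream

_COMMENT_VOCAB = (
    "heat stimulus",
    "cold stimulus",
    "brush stroke",
    "electrical stimulus on",
    "electrical stimulus off",
    "pressure applied",
)

_FOOTER = "DAPSYS-like reference dialect, dapsysio synthetic session v1.0, SN 0000042"

CONTINUOUS_STREAM = "Continuous Recording"
COMMENT_STREAM = "Comments"
TRACK_FOLDER = "Tracks"


@dataclass(frozen=True)
class SessionSpec:
    """Conditions of one synthetic recording session.

    Defaults describe a short but realistically sized microneurography
    protocol: 100 s of a 10 kHz continuous channel (1e6 samples), a handful
    of experimenter comments and two sorted-spike tracks.
    """

    duration_s: float = 100.0
    sample_rate_hz: float = 10_000.0
    n_comments: int = 5
    n_spike_tracks: int = 2
    spikes_per_track: int = 50
    page_target_samples: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise InvalidSpec("duration_s must be > 0")
        if not self.sample_rate_hz > 0:
            raise InvalidSpec("sample_rate_hz must be > 0")
        if self.page_target_samples < 1:
            raise InvalidSpec("page_target_samples must be >= 1")
        if min(self.n_comments, self.n_spike_tracks, self.spikes_per_track) < 0:
            raise InvalidSpec("counts must be >= 0")
        if self.total_samples < 1:
            raise InvalidSpec("session too short for one sample")

    @property
    def total_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz


@dataclass
class GroundTruth:
    """Bookkeeping of everything the generator put into a session."""

    total_samples: int
    comment_times: np.ndarray  # sorted, seconds
    spike_times: dict[str, np.ndarray]  # track name -> (n, 2) [entered, recognized]
    page_count_by_kind: dict[str, int]
    continuous_pages: int = 0
    template_page_ids: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_samples": self.total_samples,
                "comment_times": self.comment_times.tolist(),
                "spike_times": {k: v.tolist() for k, v in self.spike_times.items()},
                "page_count_by_kind": self.page_count_by_kind,
                "continuous_pages": self.continuous_pages,
                "template_page_ids": self.template_page_ids,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            total_samples=d["total_samples"],
            comment_times=np.asarray(d["comment_times"], dtype=np.float64),
            spike_times={
                k: np.asarray(v, dtype=np.float64).reshape(-1, 2)
                for k, v in d["spike_times"].items()
            },
            page_count_by_kind=d["page_count_by_kind"],
            continuous_pages=d["continuous_pages"],
            template_page_ids=d["template_page_ids"],
        )


def _spike_template(fs: float) -> np.ndarray:
    """Biphasic extracellular spike shape, ~3 ms, unit peak amplitude."""
    n = max(5, int(round(0.003 * fs)) | 1)
    t = np.linspace(-1.0, 1.0, n)
    shape = np.sin(2.0 * np.pi * t) * np.hanning(n)
    peak = np.abs(shape).max()
    return (shape / peak if peak > 0 else shape).astype(np.float32)


def _draw_comments(
    rng: np.random.Generator, spec: SessionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Comment times uniform over (0, duration), sorted, plus split indices.

    A comment at time ``t`` cuts the continuous signal before the first
    sample with ``k*dt >= t``.  Draws are repeated (deterministically) until
    every comment induces its own interior split, so n comments always yield
    n+1 waveform pages.
    """
    total = spec.total_samples
    if spec.n_comments == 0:
        return np.empty(0, dtype=np.float64), np.empty(0, dtype=np.int64)
    if spec.n_comments > total - 1:
        raise InvalidSpec(
            f"{spec.n_comments} comments cannot each split {total} samples"
        )
    for _ in range(1000):
        times = np.sort(rng.uniform(0.0, spec.duration_s, size=spec.n_comments))
        idx = np.ceil(times * spec.sample_rate_hz).astype(np.int64)
        if idx[0] >= 1 and idx[-1] <= total - 1 and np.all(np.diff(idx) > 0):
            return times, idx
    raise InvalidSpec("could not place distinct comment split points")  # pragma: no cover


def generate_session(spec: SessionSpec) -> tuple[DapsysFile, GroundTruth]:
    """Build a complete in-memory session plus its ground truth.

    The continuous stream is cut into regular waveform pages of at most
    ``page_target_samples`` samples, with an additional cut at every comment
    time (the comment's text page is stored between the two waveform pages,
    reproducing how the acquisition program interleaves pages in recording
    order).  Spike tracks live under a ``Tracks`` folder; each spike page
    references its track's waveform template page.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_noise, rng_comments, rng_spikes, rng_plot = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    fs = spec.sample_rate_hz
    dt = spec.dt
    total = spec.total_samples

    # --- spike trains -------------------------------------------------------
    track_names = [f"Track {i + 1}" for i in range(spec.n_spike_tracks)]
    spike_times: dict[str, np.ndarray] = {}
    for name in track_names:
        entered = np.sort(
            rng_spikes.uniform(2.0 * dt, spec.duration_s, size=spec.spikes_per_track)
        )
        recognized = entered - dt  # recognition precedes the manual entry time
        spike_times[name] = np.column_stack([entered, recognized])

    # --- continuous signal: slow sinusoid + noise + spike transients --------
    t = np.arange(total, dtype=np.float64) * dt
    signal = np.sin(2.0 * np.pi * 1.5 * t) + 0.2 * rng_noise.standard_normal(total)
    template = _spike_template(fs)
    half = len(template) // 2
    for name in track_names:
        centers = np.round(spike_times[name][:, 1] * fs).astype(np.int64)
        for c in centers:
            lo, hi = max(0, c - half), min(total, c + half + 1)
            signal[lo:hi] += 3.0 * template[lo - (c - half) : hi - (c - half)]
    signal = signal.astype(np.float32)

    # --- comments -----------------------------------------------------------
    comment_times, split_idx = _draw_comments(rng_comments, spec)
    comment_texts = [
        f"{_COMMENT_VOCAB[i % len(_COMMENT_VOCAB)]} #{i + 1}"
        for i in range(spec.n_comments)
    ]

    # --- pages in recording order ------------------------------------------
    # events: (time, tiebreak, builder) — text pages sort before the waveform
    # page that starts at the same instant.
    events: list[tuple[float, int, object]] = []

    cuts = np.concatenate([[0], split_idx, [total]])
    wf_segments: list[tuple[int, int]] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        start = int(a)
        while start < b:
            stop = min(start + spec.page_target_samples, int(b))
            wf_segments.append((start, stop))
            start = stop
    for start, stop in wf_segments:
        events.append((start * dt, 1, ("wf", start, stop)))
    for time, text in zip(comment_times, comment_texts):
        events.append((float(time), 0, ("comment", text, float(time))))
    for name in track_names:
        for entered, recognized in spike_times[name]:
            events.append((float(entered), 0, ("spike", name, float(entered), float(recognized))))
    events.sort(key=lambda e: (e[0], e[1]))

    pages: dict[int, Page] = {}
    next_id = 1
    template_ids: dict[str, int] = {}
    for name in track_names:  # templates first: they predate the recording
        pages[next_id] = WaveformPage(
            header=PageHeader(id=next_id, kind=PageKind.WAVEFORM),
            amplitudes=template,
            timestamps=np.array([0.0]),
            interval=dt,
        )
        template_ids[name] = next_id
        next_id += 1

    continuous_ids: list[int] = []
    comment_ids: list[int] = []
    track_ids: dict[str, list[int]] = {name: [] for name in track_names}
    for _, _, payload in events:
        if payload[0] == "wf":
            _, start, stop = payload
            pages[next_id] = WaveformPage(
                header=PageHeader(id=next_id, kind=PageKind.WAVEFORM),
                amplitudes=signal[start:stop],
                timestamps=np.array([start * dt]),
                interval=dt,
            )
            continuous_ids.append(next_id)
        elif payload[0] == "comment":
            _, text, time = payload
            pages[next_id] = TextPage(
                header=PageHeader(id=next_id, kind=PageKind.TEXT),
                text=text,
                timestamp_a=time,
                timestamp_b=time,
            )
            comment_ids.append(next_id)
        else:
            _, name, entered, recognized = payload
            pages[next_id] = TextPage(
                header=PageHeader(
                    id=next_id, kind=PageKind.TEXT, reference_id=template_ids[name]
                ),
                text=name,
                timestamp_a=entered,
                timestamp_b=recognized,
            )
            track_ids[name].append(next_id)
        next_id += 1

    # --- ToC ----------------------------------------------------------------
    def plot_config() -> bytes:
        return rng_plot.bytes(Stream.PLOT_CONFIG_SIZE)

    eid = itertools.count(1)
    track_streams = [
        Stream(
            id=0,  # placeholder, assigned below in document order
            name=name,
            stream_type=PageKind.TEXT,
            page_ids=np.asarray(track_ids[name], dtype=np.uint32),
            plot_config=plot_config(),
        )
        for name in track_names
    ]
    root = Folder(
        id=0,
        name="Root",
        children=[
            Stream(
                id=0,
                name=CONTINUOUS_STREAM,
                stream_type=PageKind.WAVEFORM,
                page_ids=np.asarray(continuous_ids, dtype=np.uint32),
                plot_config=plot_config(),
            ),
            Stream(
                id=0,
                name=COMMENT_STREAM,
                stream_type=PageKind.TEXT,
                page_ids=np.asarray(comment_ids, dtype=np.uint32),
                plot_config=plot_config(),
            ),
            Folder(id=0, name=TRACK_FOLDER, children=list(track_streams)),
        ],
    )
    root.id = next(eid)
    for _, entry in root.walk():
        entry.id = next(eid)

    file = DapsysFile(
        header=FileHeader(
            raw=FileHeader.MAGIC + b"\x00" * (FileHeader.SIZE - len(FileHeader.MAGIC))
        ),
        pages=pages,
        toc_root=root,
        footer=FileFooter(version_string=_FOOTER),
    )
    file.validate()

    n_text = spec.n_comments + spec.n_spike_tracks * spec.spikes_per_track
    truth = GroundTruth(
        total_samples=total,
        comment_times=comment_times.astype(np.float64),
        spike_times=spike_times,
        page_count_by_kind={
            "waveform": len(continuous_ids) + len(template_ids),
            "text": n_text,
        },
        continuous_pages=len(continuous_ids),
        template_page_ids=template_ids,
    )
    return file, truth


def generate_csv_reference(file: DapsysFile, stream_path, header: bool = False) -> str:
    """Expected CSV text for a stream, built independently of the exporter.

    Formats with ``decimal`` arithmetic (half-even on the shortest decimal
    representation): waveform rows carry 6 decimals on both columns, text
    rows 4 decimals on the timestamp.  Serves as the expectation that
    :func:`dapsysio.export.export_csv` and the verifier are tested against.
    """
    path = StreamPath.of(stream_path)
    stream = resolve_stream(file, path)
    lines: list[str] = []
    if stream.stream_type is PageKind.WAVEFORM:
        if header:
            lines.append("timestamp,value")
        slab = assemble_waveform(file, stream)
        q6 = Decimal("0.000001")
        for ts, amp in zip(slab.timestamps.tolist(), slab.amplitudes.tolist()):
            ts_d = Decimal(repr(ts)).quantize(q6, rounding=ROUND_HALF_EVEN)
            amp_d = Decimal(repr(amp)).quantize(q6, rounding=ROUND_HALF_EVEN)
            lines.append(f"{ts_d:f},{amp_d:f}")
    else:
        if header:
            lines.append("timestamp,text")
        slab = assemble_text(file, stream)
        q4 = Decimal("0.0001")
        for ts, text in zip(slab.timestamps_b.tolist(), slab.texts):
            ts_d = Decimal(repr(ts)).quantize(q4, rounding=ROUND_HALF_EVEN)
            if any(ch in text for ch in ',"\n\r'):
                text = '"' + text.replace('"', '""') + '"'
            lines.append(f"{ts_d:f},{text}")
    return "\n".join(lines) + ("\n" if lines else "")
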