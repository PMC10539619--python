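import numpy as np
import pytest

from dapsysio import (
    DapsysFile,
    FileFooter,
    Folder,
    PageHeader,
    PageKind,
    SessionSpec,
    Stream,
    TextPage,
    WaveformPage,
    generate_session,
)


def wf_regular(page_id, t0, dt, amplitudes, reference=None):
    return WaveformPage(
        header=PageHeader(id=page_id, kind=PageKind.WAVEFORM, reference_id=reference),
        amplitudes=np.asarray(amplitudes, dtype=np.float32),
        timestamps=np.array([t0], dtype=np.float64),
        interval=dt,
    )


def wf_irregular(page_id, timestamps, amplitudes):
    return WaveformPage(
        header=PageHeader(id=page_id, kind=PageKind.WAVEFORM),
        amplitudes=np.asarray(amplitudes, dtype=np.float32),
        timestamps=np.asarray(timestamps, dtype=np.float64),
    )


def text_page(page_id, text, ts_a, ts_b=None, reference=None):
    return TextPage(
        header=PageHeader(id=page_id, kind=PageKind.TEXT, reference_id=reference),
        text=text,
        timestamp_a=ts_a,
        timestamp_b=ts_a if ts_b is None else ts_b,
    )


def make_file(pages=(), children=(), footer="test footer v1"):
    """Assemble a small valid file from pages and root children."""
    return DapsysFile(
        pages={p.header.id: p for p in pages},
        toc_root=Folder(id=100, name="Root", children=list(children)),
        footer=FileFooter(version_string=footer),
    )


def stream(entry_id, name, kind, page_ids):
    return Stream(
        id=entry_id,
        name=name,
        stream_type=kind,
        page_ids=np.asarray(page_ids, dtype=np.uint32),
    )


@pytest.fixture(scope="session")
def small_session():
    """A short but fully featured session: comments, two spike tracks."""
    spec = SessionSpec(
        duration_s=1.0,
        sample_rate_hz=1000.0,
        n_comments=3,
        n_spike_tracks=2,
        spikes_per_track=10,
        page_target_samples=10_000,
        seed=7,
    )
    file, truth = generate_session(spec)
    return spec, file, truth
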