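"""Rounding-aware verification of binary values against CSV exports.

The CSV dialect prints waveform timestamps and amplitudes with 6 decimals
and text timestamps with 4, so a naive comparison against the binary values
flags nothing but rounding residue.  The verifier therefore supports two
modes:

* ``rounded`` — round the binary values to the CSV precision first (f32
  amplitudes promoted to f64), then require agreement to within the f64
  machine epsilon; a faithful export verifies with zero differences.
* ``raw`` — compare the unrounded binary values; differences are then the
  rounding residue itself, bounded by half an ulp of the printed precision
  (5e-7 at 6 decimals, 5e-5 at 4).

Texts are compared exactly in both modes.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import CsvParseError, RowCountMismatch
from .model import DapsysFile, PageKind
from .precision import round_fixed
from .toc import StreamPath, assemble_text, assemble_waveform, resolve_stream

#: The f64 machine epsilon (gap between 1.0 and the next representable f64).
EPSILON = float(np.finfo(np.float64).eps)

WAVEFORM_DECIMALS = 6
TEXT_DECIMALS = 4

_HEADERS = {("timestamp", "value"), ("timestamp", "text")}


def float_equal(a: float, b: float) -> bool:
    """Equality under the epsilon rule: ``|a - b| <= eps(f64)``.

    NaN inputs always compare unequal.
    """
    if math.isnan(a) or math.isnan(b):
        return False
    return abs(a - b) <= EPSILON


@dataclass
class ComparisonReport:
    """Tally of one stream-vs-CSV comparison."""

    n_compared: int = 0
    n_different: int = 0
    max_abs_difference: float = 0.0
    text_mismatches: int = 0

    @property
    def ok(self) -> bool:
        return self.n_different == 0 and self.text_mismatches == 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_compared": self.n_compared,
                "n_different": self.n_different,
                "max_abs_difference": self.max_abs_difference,
                "text_mismatches": self.text_mismatches,
            },
            indent=2,
        )


def _rows(text: str) -> list[list[str]]:
    rows = list(csv.reader(io.StringIO(text)))
    if rows and tuple(rows[0]) in _HEADERS:
        rows = rows[1:]
    return rows


def _parse_waveform_csv(text: str) -> tuple[np.ndarray, np.ndarray]:
    rows = _rows(text)
    ts = np.empty(len(rows), dtype=np.float64)
    vals = np.empty(len(rows), dtype=np.float64)
    for i, row in enumerate(rows):
        if len(row) != 2:
            raise CsvParseError(f"row {i + 1}: expected 2 columns, got {len(row)}")
        try:
            ts[i] = float(row[0])
            vals[i] = float(row[1])
        except ValueError as exc:
            raise CsvParseError(f"row {i + 1}: {exc}") from exc
    return ts, vals


def _parse_text_csv(text: str) -> tuple[np.ndarray, list[str]]:
    rows = _rows(text)
    ts = np.empty(len(rows), dtype=np.float64)
    texts: list[str] = []
    for i, row in enumerate(rows):
        if len(row) != 2:
            raise CsvParseError(f"row {i + 1}: expected 2 columns, got {len(row)}")
        try:
            ts[i] = float(row[0])
        except ValueError as exc:
            raise CsvParseError(f"row {i + 1}: {exc}") from exc
        texts.append(row[1])
    return ts, texts


def _tally(report: ComparisonReport, binary: np.ndarray, parsed: np.ndarray) -> None:
    diff = np.abs(binary - parsed)
    unequal = ~(diff <= EPSILON)  # NaN diffs count as unequal
    report.n_compared += int(binary.shape[0])
    report.n_different += int(unequal.sum())
    if unequal.any():
        worst = float(np.nanmax(diff[unequal]))
        report.max_abs_difference = max(report.max_abs_difference, worst)


def compare_stream_to_csv(
    file: DapsysFile,
    stream_path,
    csv_text: str,
    mode: str = "rounded",
) -> ComparisonReport:
    """Compare one stream's binary values against a CSV export of it.

    Comparison is strictly positional: row *i* of the CSV is compared with
    sample *i* of the assembled stream; a count mismatch is an error, not a
    difference.  ``mode`` selects whether binary values are rounded to the
    CSV precision first (``"rounded"``) or taken as stored (``"raw"``).
    """
    if mode not in ("rounded", "raw"):
        raise ValueError(f"mode must be 'rounded' or 'raw', got {mode!r}")
    path = StreamPath.of(stream_path)
    stream = resolve_stream(file, path)
    report = ComparisonReport()

    if stream.stream_type is PageKind.WAVEFORM:
        slab = assemble_waveform(file, stream)
        ts_csv, val_csv = _parse_waveform_csv(csv_text)
        if ts_csv.shape[0] != len(slab):
            raise RowCountMismatch(
                f"{ts_csv.shape[0]} CSV rows vs {len(slab)} binary samples"
            )
        ts_bin = slab.timestamps
        val_bin = slab.amplitudes.astype(np.float64)  # f32 promoted to f64
        if mode == "rounded":
            p = WAVEFORM_DECIMALS
            ts_bin = np.array([round_fixed(x, p) for x in ts_bin.tolist()])
            val_bin = np.array([round_fixed(x, p) for x in val_bin.tolist()])
        _tally(report, ts_bin, ts_csv)
        _tally(report, val_bin, val_csv)
    else:
        slab = assemble_text(file, stream)
        ts_csv, texts_csv = _parse_text_csv(csv_text)
        if ts_csv.shape[0] != len(slab):
            raise RowCountMismatch(
                f"{ts_csv.shape[0]} CSV rows vs {len(slab)} binary text pages"
            )
        ts_bin = slab.timestamps_b
        if mode == "rounded":
            ts_bin = np.array([round_fixed(x, TEXT_DECIMALS) for x in ts_bin.tolist()])
        if len(slab):
            _tally(report, ts_bin, ts_csv)
        report.text_mismatches += sum(
            1 for a, b in zip(slab.texts, texts_csv) if a != b
        )
    return report
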