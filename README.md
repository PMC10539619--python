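# dapsysio

Reader, writer, converter and verifier for DAPSYS-style binary
electrophysiology recordings.

DAPSYS ("Data Acquisition Processor System") is a proprietary
neurophysiological acquisition program used, among other places, in
microneurography labs recording single peripheral-nerve-fiber activity in
awake humans. Its files lock the data into the vendor's software: the only
built-in escape hatch is a manual per-stream CSV export that is slow,
inflates file size several-fold, and truncates every value to a fixed number
of decimals. `dapsysio` gives labs and pipeline authors direct, scriptable
access to recordings in this style of format, plus lossless export to
NIX-structured HDF5 for interchange with the wider electrophysiology
ecosystem.

## The file model

A file is flat and splits into four parts:

1. **Header** — fixed 64 bytes; nothing in it is needed to read the data.
2. **Data pages** — discontinuous chunks, each with a file-unique id, written
   in the order they occur during the recording. *Waveform pages* hold f32
   amplitudes with f64 timestamps in seconds; regularly sampled pages store
   only the first timestamp `t0` plus the sampling interval `Δt`, so sample
   `k` lives at `t0 + k·Δt`. *Text pages* hold a string and two f64
   timestamps: equal ⇒ a comment typed during the recording, distinct ⇒ a
   sorted spike whose second timestamp is the automatically recognized spike
   time. Entering a comment closes the current waveform page, appends the
   text page, and starts a new waveform page.
3. **Table of contents** — folders and streams (ordered arrays of page ids)
   defining the hierarchy shown in the acquisition GUI.
4. **Footer** — the program version / serial-number string.

The exact byte layout of the reference dialect implemented here is specified
in [`docs/format.md`](docs/format.md); the scientific and design notes live
in [`docs/methods.md`](docs/methods.md).

Because real recordings contain patient data and cannot be redistributed,
the package ships a deterministic generator of microneurography-like
sessions (continuous channel + comments + sorted-spike tracks) used as
fixtures by the entire test suite.

## Worked example

Generate a 10 s, 10 kHz synthetic session with 3 comments and two
20-spike tracks, inspect it, export the continuous stream to CSV and verify
the export against the binary values:

```console
$ dapsysio generate demo.dps --seed 42 --duration 10 --sample-rate 10000 \
      --comments 3 --tracks 2 --spikes-per-track 20
{
  "file": "demo.dps",
  "ground_truth": "demo.dps.gt.json",
  "bytes": 402594,
  "total_samples": 100000,
  "pages": { "waveform": 6, "text": 43 }
}

$ dapsysio inspect demo.dps
Root/
  Continuous Recording  [waveform, 4 pages, 100000 samples]
  Comments  [text, 3 pages]
  Tracks/
    Track 1  [text, 20 pages]
    Track 2  [text, 20 pages]
pages: 6 waveform, 43 text
footer: DAPSYS-like reference dialect, dapsysio synthetic session v1.0, SN 0000042

$ dapsysio export demo.dps --format csv --stream "Continuous Recording"
demo.Continuous_Recording.csv
$ head -3 demo.Continuous_Recording.csv
0.000000,0.083666
0.000100,0.122058
0.000200,0.007643
```

The 3 comments cut the continuous channel into 4 waveform pages; the 6
waveform pages are those 4 plus one spike-template page per track, and the
43 text pages are 3 comments + 2×20 spikes. The CSV prints both columns at
6 decimals (text streams print timestamps at 4 decimals).

Verification compares binary values with the CSV positionally. In
`rounded` mode the binary values are first rounded to the CSV precision, so
a faithful export shows zero differences; in `raw` mode the differences are
the rounding residue itself, bounded by half an ulp of the printed grid:

```console
$ dapsysio verify demo.dps "Continuous Recording" demo.Continuous_Recording.csv
{
  "n_compared": 200000,
  "n_different": 0,
  "max_abs_difference": 0.0,
  "text_mismatches": 0
}
$ dapsysio verify --mode raw demo.dps "Continuous Recording" demo.Continuous_Recording.csv
{
  "n_compared": 200000,
  "n_different": 133465,
  "max_abs_difference": 4.999961853435764e-07,
  "text_mismatches": 0
}
```

`dapsysio export --format nix demo.dps` writes `demo.nix.h5`, a
NIX-structured HDF5 file with one data array per continuous trace, comment
series and spike track (the CSV export above is 1 850 017 bytes for a
402 594-byte source — a 4.6× inflation the HDF5 export avoids).

The same functionality is available as a library:

```python
import dapsysio as dio

file = dio.read_file(open("demo.dps", "rb").read())
slab = dio.assemble_waveform(file, dio.resolve_stream(file, "Continuous Recording"))
model = dio.convert(file, dio.ConverterConfig.discover(file))
dio.export_nix_h5(model, "demo.nix.h5")
```

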