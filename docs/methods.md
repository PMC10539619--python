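# Methods and design notes

## Scope and model

`dapsysio` implements a complete round-trip toolchain for a DAPSYS-style
recording format: an in-memory model (flat page store + ToC tree), a
bit-exact binary codec for the reference dialect in `docs/format.md`,
stream assembly, conversion to a generic trace/event/spike recording model
with NIX-structured HDF5 and fixed-precision CSV exports, a rounding-aware
verifier, and a synthetic session generator that makes every layer testable
without access to real (patient-derived, non-shareable) recordings.

The logical model is the published structure of the format: four sections
(header, pages, ToC, footer); waveform pages with f32 amplitudes and f64
second-valued timestamps, regular pages compressed to `(t0, Δt)`; text pages
whose equal/distinct timestamp pair distinguishes comments from sorted
spikes; streams as ordered page-id arrays. The byte-level realization
(little-endian, length-prefixed Latin-1 strings, tag values, the u64 ToC
pointer in the header, the `0xFFFFFFFF` absent-reference sentinel) is a
dialect choice of this package: the originating acquisition software runs on
x86 Windows, which motivates little-endian and a single-byte-charset string
encoding. The codec is strictly fail-fast; there are no recovery heuristics,
because a silently half-read recording is worse than a typed error.

## Timestamp expansion

Regular pages are expanded with the closed form `t0 + k·Δt` (vectorized
`arange(n)·Δt + t0`), never by iterative accumulation: the closed form keeps
every timestamp within two correctly rounded operations of the true value,
so no drift accumulates over million-sample pages. This matters because CSV
verification compares timestamps at 6 decimals. Consecutive expanded
differences equal `Δt` to within a couple of float spacings *of the
timestamp magnitude* — the tightest bound any binary floating-point scheme
can offer once `t0 ≫ Δt`.

## Trace merging

Converting a waveform stream produces one `ContinuousTrace` per *gap-free
run* of regular pages, not one per page: a following page is merged when its
interval matches bitwise and its `t0` lies within `merge_gap_tolerance`
(default 0.5, as a fraction of Δt) of the seamless continuation time
`t0_run + n_run·Δt`. Comment-induced page cuts are seams, not gaps, and
disappear; genuine acquisition pauses exceed half a sample interval and
start a new trace. Irregular pages are never merged. The default of half an
interval is the largest tolerance that can never bridge a missing sample.

## CSV dialect and rounding

The export dialect prints waveform rows as `timestamp,value` with **exactly
6 decimals** on both columns and text rows as `timestamp,text` with **4
decimals** (comments use their entry time; sorted spikes the recognized
spike time), LF line endings, no header by default, RFC 4180 quoting only
when the text contains a separator. Rounding is **half-even applied to the
shortest decimal representation** of the value — the number a user actually
reads — so `0.33335` prints as `0.3334` at 4 decimals. Implemented with
`decimal.Decimal(repr(x)).quantize(...)`; the verifier's rounding goes
through the same helper, which makes self-verification exact by
construction.

## Verification

`compare_stream_to_csv` is strictly positional (row *i* against sample *i*;
count mismatches are errors, not differences) and counts every float
comparison, the number of unequal pairs, the maximum absolute difference
over unequal pairs, and exact text mismatches. Float equality uses the f64
machine epsilon (≈2.22·10⁻¹⁶) as the tolerance; f32 amplitudes are promoted
to f64 first; NaNs never compare equal. Two modes:

* `rounded` — binary values rounded to the CSV precision first. A faithful
  export verifies with zero differences; any nonzero count indicates a codec
  or exporter defect.
* `raw` — binary values as stored. Differences are then pure rounding
  residue, bounded by half an ulp of the printed grid: 5·10⁻⁷ at 6 decimals,
  5·10⁻⁵ at 4. On million-sample fixtures the measured raw maximum sits at
  ≈5·10⁻⁷, comfortably under the 10⁻⁵ scale that fixed 6-decimal exports can
  introduce into downstream analyses — the quantitative argument for reading
  the binary directly instead of round-tripping through CSV.

## NIX-structured HDF5 export

`export_nix_h5` writes the NIX data-model layout directly with `h5py`: root
attributes (`format="nix"`, version), one block under `/data` containing a
`data_arrays` group with one array per trace/event-series/spike-track, each
holding a `data` dataset plus a `dimensions` subtree (sampled dimension with
`sampling_interval`/`offset` in seconds for regular traces, range dimension
with explicit ticks for irregular ones, set dimensions with labels for
events and for the entered/recognized spike-time columns), and provenance
(the source file's footer string) under `/metadata`. Entity ids are
content-derived (MD5-based UUID strings) and all `created_at` stamps are
fixed, so exporting the same model twice yields byte-identical files —
convenient for caching and regression diffs. Regular traces store only
`(t0, Δt)` plus raw f32 samples, which is why the HDF5 file stays within a
few percent of the binary source size while the CSV export inflates it more
than four-fold.

## Synthetic sessions

`generate_session` emulates a microneurography protocol: one continuous
channel (default 100 s at 10 kHz — a realistic single-fiber session length
and rate), experimenter comments, and per-track sorted spikes.

* The signal is a 1.5 Hz unit sinusoid (slow physiological modulation) plus
  Gaussian noise (σ = 0.2) plus a biphasic ~3 ms spike transient (amplitude
  3) at every recognized spike time, giving plausible morphology for visual
  QC. These statistical details are a fixture choice, not a claim about real
  nerve recordings: real microneurography data has non-stationary noise,
  drifting spike shapes and stimulation artifacts that the generator does
  not model, so passing tests demonstrate correctness of the *format
  toolchain*, not of any physiological analysis.
* Comment times are uniform over (0, duration), sorted, and redrawn
  (deterministically) until each induces its own interior page split, so *n*
  comments always yield *n*+1 waveform pages — the interleaving rule the
  format follows. Comment splitting takes precedence over the
  `page_target_samples` size limit.
* Recognized spike time = entered time − one sample interval, making the
  two timestamps of spike pages robustly distinct.
* Each track gets a small waveform template page, referenced by its spike
  pages via `reference_id`; the reader never relies on this.
* All randomness flows from one master seed through named
  `SeedSequence.spawn` children (signal noise, comments, spikes, plot
  configs), so the same seed is byte-reproducible and adding a consumer
  never silently reshuffles existing fixtures.

## Numerical and degenerate-input choices

* Page-id uniqueness, stream/page kind agreement, resolvable references and
  regular-page shape are enforced symmetrically on read and write.
* Empty streams assemble to empty slabs; an empty file (no pages, empty
  root folder) is valid.
* Out-of-order page timestamps are tolerated on read with a logged warning
  (recording order is an observation about the originating software, not a
  format guarantee); path resolution is case-insensitive, does not trim
  whitespace, and reports duplicate sibling names as an error at resolve
  time rather than at parse time.
* `is_comment` compares the two f64 timestamps bitwise, not via `==`, so
  the comment/spike partition is stable under any value including signed
  zeros.

## Problem sizes

The test suite and the acceptance script size their fixtures to what the
guarantees actually require: codec round-trip properties run on hundreds of
randomized small sessions (tens of pages, ≤ a few thousand samples), while
precision and size-ratio measurements use one million-sample session
(100 s × 10 kHz), the scale at which rounding residue and the ≥4× CSV
inflation are meaningfully exercised.

## Known limitations

* The reference dialect realizes the documented logical model; it is not a
  byte-level clone of any proprietary file, so it cannot open real DAPSYS
  recordings as-is. The model/dialect layering is the designed extension
  point for adding a real-world dialect.
* No compression or encryption (the emulated format has none), no in-place
  editing, no streaming of files larger than memory, no NWB export, and no
  spike re-sorting or signal processing — the package assembles what the
  file stores.
* The NIX export targets the NIX layout conventions; it is written with
  h5py and validated structurally (readable by any HDF5 tool), not against
  the NIX reference implementation.
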