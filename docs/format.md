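# Reference binary dialect — normative byte layout

This document is normative for `dapsysio.codec`: the writer emits exactly
this layout and the reader accepts nothing else. It is a concrete
realization of the DAPSYS-style logical file model (flat page store +
hierarchical ToC); the byte-level choices (endianness, field order, tag
values, string encoding) are fixed by this dialect. The codec is layered so
that a second dialect matching some other byte layout can be added without
touching the in-memory model.

All integers and floats are **little-endian**. `u8/u32/u64` are unsigned
integers, `f32/f64` IEEE-754 binary32/binary64.

**String** := `u32 byte_count` followed by `byte_count` bytes of **Latin-1**
text.

## 1. Header (64 bytes)

| offset | size | content                                      |
|-------:|-----:|----------------------------------------------|
| 0      | 4    | magic `44 50 53 59` (`"DPSY"`)               |
| 4      | 4    | reserved, zero                               |
| 8      | 8    | `u64` absolute file offset of the ToC section |
| 16     | 48   | opaque padding, zero on write, ignored on read |

Apart from the magic and the ToC pointer, header content is never needed to
parse the file.

## 2. Pages (offsets 64 … toc_offset)

Consecutive page records, written in recording order. Every page starts
with the shared page header:

| field        | type | notes                                             |
|--------------|------|---------------------------------------------------|
| id           | u32  | unique within the file                            |
| kind         | u8   | `1` = waveform, `2` = text; anything else is an error |
| reference_id | u32  | id of another page; `0xFFFFFFFF` = absent         |

**Waveform page** (kind 1):

| field      | type        | notes                                   |
|------------|-------------|-----------------------------------------|
| regular    | u8          | `1` = regular sampling, `0` = irregular |
| *if regular:* |          |                                         |
| t0         | f64         | timestamp of the first sample, seconds  |
| interval   | f64         | sampling interval, seconds, > 0         |
| n          | u32         | sample count, ≥ 1                       |
| amplitudes | f32 × n     | signal values                           |
| *if irregular:* |        |                                         |
| n_ts       | u32         |                                         |
| timestamps | f64 × n_ts  | strictly increasing, seconds            |
| n_amp      | u32         | must equal n_ts                         |
| amplitudes | f32 × n_amp |                                         |

**Text page** (kind 2):

| field       | type   | notes                                           |
|-------------|--------|-------------------------------------------------|
| text        | String |                                                 |
| timestamp_a | f64    | entry time, seconds, ≥ 0                        |
| timestamp_b | f64    | bit-equal to `timestamp_a` ⇒ comment; otherwise the automatically recognized spike time |

## 3. Table of contents (at toc_offset)

One recursively serialized entry; the root must be a folder.

Common entry fields:

| field      | type   | notes                                  |
|------------|--------|----------------------------------------|
| entry_id   | u32    | namespace unrelated to page ids        |
| name       | String | non-empty display name                 |
| entry_type | u8     | `1` = folder, `2` = stream             |

**Folder** (entry_type 1): `u32 n_children`, then `n_children` entries.

**Stream** (entry_type 2):

| field       | type    | notes                                 |
|-------------|---------|----------------------------------------|
| stream_type | u8      | `1` = waveform, `2` = text             |
| n_pages     | u32     |                                        |
| page_ids    | u32 × n | ordered; every id must exist and match stream_type |
| plot_config | 32 bytes| opaque GUI plot configuration          |

## 4. Footer

One String holding the program version and serial number. The file ends
immediately after it; trailing bytes are a parse error.

## Strictness

Parsing is fail-fast with typed errors: truncation anywhere raises
`TruncatedFile` (never a partial structure), unknown tags raise
`UnknownPageKind`, a wrong magic raises `BadMagic`, unresolvable or
kind-mismatched page references raise `DanglingPageRef`/`KindMismatch`, and
duplicate page or entry ids raise `DuplicateId`.
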