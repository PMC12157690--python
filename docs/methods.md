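# Methods

## The rewrite procedure

Every read is treated as a 5'-anchored concatenation
`UMI(u) + linker(l) + insert`, with `u ≥ 0` and `l ≥ 0` supplied by the
user (they describe the library chemistry; the tool cannot infer them).
The transformation is pure string arithmetic on one record at a time:

- `umi_first = false`: output is `barcode + UMI + insert`.
- `umi_first = true` (requires `u > 0`): output is `UMI + barcode + insert`.
- In both cases the `l` linker bases after the UMI, and their qualities,
  are deleted.

Qualities partition exactly as the sequence does. Inserted barcode bases
receive a constant fill quality; UMI and insert bases keep their sequenced
qualities. Headers (id and comment) pass through untouched. The output
length identity `len(out) = len(in) + len(barcode) − l` holds for every
emitted record and is asserted throughout the test suite.

Assumptions worth stating plainly:

- The UMI and linker sit at **fixed offsets**. The linker is removed by
  position and length, never by sequence matching; reads whose linker has
  indels will be mis-decomposed. Adapter-style fuzzy trimming is a
  different tool's job (e.g. cutadapt/fastp) and is deliberately out of
  scope.
- One invocation processes **one** FASTQ file. In the motivating use case
  (a paired-end plate assay whose mate 2 carries the UMI) only that mate
  needs rewriting; mate pairing is the caller's responsibility.
- The same machinery inserts synthetic UMIs or any arbitrary sequence —
  the barcode parameter accepts any string over the IUPAC alphabet,
  including the empty string (a no-op insertion).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `barcode` | `CATATAC` | sequence inserted into every read; 7 bases, giving CB field positions 1–7 in default mode |
| `umi_length` (`-u`) | 0 | 5' bases treated as the UMI |
| `linker_length` (`-l`) | 0 | bases after the UMI to delete |
| `umi_first` | off | keep the UMI at the 5' end, insert the barcode after it |
| `fill_quality` (`-q`) | `I` | quality for inserted bases; `I` is Phred 40 in the +33 encoding, chosen so synthetic bases are never removed by downstream quality filters |
| `short_read_policy` | `fail` | reads shorter than `u+l` abort the run; `skip` drops and counts them instead |

Failing on short reads is the default because silently emitting a read
whose CB/UMI fields are mis-aligned corrupts the geometry every downstream
tool is configured with; the skip policy exists for libraries with a known
tail of fragmented reads and reports the exact count dropped.

## FASTQ handling

The reader enforces strict 4-line records: a header starting `@`, the
sequence, a separator starting `+`, and a quality line of equal length.
Wrapped (multi-line) FASTQ is rejected as a parse error — modern sequencer
output is strictly 4-line, and accepting wrapping would mask corrupt input.
Parse errors carry the line number (header/separator faults), the read id
(length mismatches), or the ordinal of the last complete record
(truncation), so a fault in a multi-gigabyte stream is locatable.

Input compression is detected from the gzip magic bytes `0x1f 0x8b`, not
the filename, so gzip data arriving on standard input decompresses
transparently. Output is gzip-compressed when the destination path ends in
`.gz`, overridable either way; gzip output uses a fixed mtime and no
embedded filename so identical record streams are byte-identical, which
makes equivalence checks (and caching) exact.

Quality strings are never decoded: only the length invariant is enforced,
making the tool agnostic to the Phred encoding. The `+` separator's
optional repeated title is accepted on input and always written as a bare
`+`. Header comments are preserved; a tab between id and comment is
re-serialized as a single space (the conventional separator).

Both reader and transformation are single-pass generators: peak memory is
bounded by one record regardless of file size, and runtime is linear in
the number of bases.

## The synthetic-data generator

`generate_fixture` emulates a plate-based read-2 structure: a random UMI,
one **fixed** linker sequence per fixture set (as in a real library prep),
and a random insert. Defaults are an 8-base UMI, a 6-base linker, and
insert lengths of 20–80 bases — so the synthetic barcode (7) + UMI (8) +
linker (6) span 21 bases, the 5' technical region of the motivating
STORM-seq use case. Qualities are uniform over `#`..`I`, the plausible
Phred+33 band. A requested number of deliberately short reads
(length < `u+l`) exercises the error paths, and a sidecar truth table
records each read's decomposition.

What the generator does *not* emulate: sequencing error models, base
composition bias, PCR duplicates, or quality profiles correlated with
position. Passing tests therefore demonstrate that the string rewrite is
exactly correct for any read conforming to the declared structure — which
is the tool's whole contract — but say nothing about biological analyses
downstream of the aligner.

## Verification design

Two independent routes to every expected value:

- An **oracle** in the test suite rebuilds the expected output character by
  character from (position, class) tuples — a different construction from
  the engine's slicing. Engine and oracle must agree byte-for-byte on
  1,000 seeded fixture reads per mode, plus derandomized property tests
  over random reads, barcodes, and geometries.
- The hand-written FASTQ parser is cross-checked against Biopython's
  `FastqGeneralIterator` on a generated fixture.

Problem sizes in the suite and acceptance script (hundreds to tens of
thousands of reads) were chosen as the smallest sets that exercise every
mode, error path, and I/O route with non-trivial variety; the rewrite is
deterministic, so larger inputs add running time, not information.

## Known limitations

- No paired-file synchronized iteration; no FASTA, BAM/CRAM.
- Insertion only at the 5' region (before or after the UMI); no 3'-end
  insertion.
- The sequence alphabet of reads is not validated (any non-whitespace
  characters stream through); only the *barcode* is restricted to IUPAC
  codes.
- No multi-threading: the pass is I/O-bound and O(n) single-threaded.
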