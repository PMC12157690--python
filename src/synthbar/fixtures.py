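"""Seeded synthetic-FASTQ generator with a ground-truth decomposition.

Emits reads built as ``UMI(u) + linker(l) + insert`` — the structure of a
STORM-seq read 2 (an in-read UMI and technical linker but no cell barcode)
— along with a sidecar truth table recording each read's decomposition.
Defaults mirror that geometry: an 8-base UMI and a 6-base linker, so that a
7-base synthetic barcode plus UMI plus linker spans 21 bases, with insert
lengths of 20-80 bases.  A requested number of deliberately short reads
(total length < u + l) exercises the short-read error paths.

The linker is one fixed sequence per fixture set, as it is in a real
library prep.  Qualities are drawn uniformly from ``'#'``..``'I'``, the
plausible Phred+33 band.  Identical parameters and seed reproduce
byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .fastq_io import FastqRecord, open_fastq_sink

_BASES = "ACGT"
_QUAL_ALPHABET = "".join(chr(c) for c in range(ord("#"), ord("I") + 1))

TRUTH_COLUMNS = ("read_id", "umi", "linker", "insert", "is_short")


@dataclass(frozen=True)
class FixtureTruth:
    """Ground-truth decomposition of one generated read.

    For a regular read, ``umi + linker + insert`` equals the read sequence.
    ``is_short`` marks reads deliberately generated shorter than ``u + l``,
    whose decomposition fields are empty.
    """

    read_id: str
    umi: str
    linker: str
    insert: str
    is_short: bool


def generate_fixture(
    n_reads: int,
    u: int = 8,
    l: int = 6,
    insert_length_range: Tuple[int, int] = (20, 80),
    n_short: int = 0,
    seed: int = 0,
) -> Tuple[List[FastqRecord], List[FixtureTruth]]:
    """Generate ``n_reads`` synthetic reads with known structure.

    Parameters
    ----------
    n_reads:
        Total records to emit.
    u, l:
        UMI and linker lengths of the simulated library.
    insert_length_range:
        Inclusive ``(low, high)`` bounds for the random insert length.
    n_short:
        How many of the reads are generated with total length < ``u + l``
        (requires ``u + l >= 2`` so a non-empty short read exists).
    seed:
        Seed for the pseudo-random generator; fixes the output bytes.

    Returns
    -------
    (records, truths)
        Parallel lists in emission order; read ids are unique within the
        fixture.

    Raises
    ------
    ValueError
        On inconsistent parameters, before any output is produced.
    """
    lo, hi = insert_length_range
    if n_reads < 0 or n_short < 0:
        raise ValueError("n_reads and n_short must be >= 0")
    if n_short > n_reads:
        raise ValueError(f"n_short ({n_short}) exceeds n_reads ({n_reads})")
    if u < 0 or l < 0:
        raise ValueError("u and l must be >= 0")
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid insert_length_range ({lo}, {hi})")
    if n_short > 0 and u + l < 2:
        raise ValueError("short reads require u + l >= 2")

    rng = random.Random(seed)
    linker_seq = "".join(rng.choice(_BASES) for _ in range(l))
    short_positions = frozenset(rng.sample(range(n_reads), n_short))

    records: List[FastqRecord] = []
    truths: List[FixtureTruth] = []
    for i in range(n_reads):
        read_id = f"synthread_{i + 1:06d}"
        if i in short_positions:
            length = rng.randint(1, u + l - 1)
            seq = "".join(rng.choice(_BASES) for _ in range(length))
            truth = FixtureTruth(read_id, "", "", "", True)
        else:
            umi = "".join(rng.choice(_BASES) for _ in range(u))
            insert = "".join(
                rng.choice(_BASES) for _ in range(rng.randint(lo, hi))
            )
            seq = umi + linker_seq + insert
            truth = FixtureTruth(read_id, umi, linker_seq, insert, False)
        qual = "".join(rng.choice(_QUAL_ALPHABET) for _ in range(len(seq)))
        records.append(FastqRecord(id=read_id, sequence=seq, quality=qual))
        truths.append(truth)
    return records, truths


def write_fixture(
    records: Sequence[FastqRecord],
    truths: Sequence[FixtureTruth],
    fastq_path: str,
    truth_path: Optional[str] = None,
    compress: Optional[bool] = None,
) -> None:
    """Write a generated fixture to a FASTQ file and an optional TSV truth table."""
    with open_fastq_sink(fastq_path, compress=compress) as sink:
        for record in records:
            sink.write(record)
    if truth_path is not None:
        with open(truth_path, "w", encoding="ascii") as handle:
            handle.write("\t".join(TRUTH_COLUMNS) + "\n")
            for t in truths:
                handle.write(
                    f"{t.read_id}\t{t.umi}\t{t.linker}\t{t.insert}\t"
                    f"{int(t.is_short)}\n"
                )
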