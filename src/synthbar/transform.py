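"""Read-structure rewrite engine.

A plate-based scRNA-seq read (e.g. STORM-seq read 2) decomposes, from the
5' end, into an optional UMI of ``u`` bases, an optional linker/spacer of
``l`` bases, and the cDNA insert.  The engine rewrites that structure in a
single deterministic pass so a barcode-expecting aligner can consume it:

==============================  =============================================
mode (parameters)               output layout
==============================  =============================================
prepend        (u=0, l=0)       barcode + read
umi-first      (u>0, l=0)       UMI + barcode + insert-and-rest
linker-removal (l>0)            barcode + UMI + insert   (linker dropped)
combined       (u>0, l>0)       UMI + barcode + insert   (linker dropped)
==============================  =============================================

The linker is identified by length and fixed position (immediately after
the UMI), never by sequence matching, which keeps the rewrite alignment-free
and O(n).  Inserted barcode bases receive a synthetic fill quality
(default ``'I'``, Phred 40 in the +33 encoding) so they are never removed by
downstream quality filters; UMI bases keep their original, sequenced
qualities.  The same machinery inserts synthetic UMIs or any arbitrary
IUPAC sequence — the barcode parameter *is* the arbitrary sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple

from .errors import BarcodeError, ShortReadError
from .fastq_io import FastqRecord

#: IUPAC nucleotide one-letter codes, including ambiguity codes and U.
IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")

DEFAULT_BARCODE = "CATATAC"
DEFAULT_FILL_QUALITY = "I"

SHORT_READ_POLICIES = ("fail", "skip")


def validate_barcode(barcode: str) -> str:
    """Normalize a barcode to uppercase, enforcing the IUPAC alphabet.

    Any length and composition over the IUPAC nucleotide codes is accepted,
    including the empty string (a degenerate no-op insertion).

    Raises
    ------
    BarcodeError
        Listing every offending character if any falls outside the IUPAC
        set (e.g. digits or ``-``).
    """
    normalized = barcode.upper()
    bad = [c for c in dict.fromkeys(normalized) if c not in IUPAC_CODES]
    if bad:
        listing = ", ".join(repr(c) for c in bad)
        raise BarcodeError(
            f"barcode '{barcode}' contains non-IUPAC characters: {listing}"
        )
    return normalized


@dataclass(frozen=True)
class ReadStructureSpec:
    """Parameters of the read-structure rewrite.

    Attributes
    ----------
    barcode:
        Synthetic sequence to insert (IUPAC codes, any length, may be
        empty).  Normalized to uppercase on construction.
    umi_length:
        Number of 5' bases treated as the UMI (``0`` = no UMI).
    linker_length:
        Number of bases immediately after the UMI to remove (``0`` = none).
    umi_first:
        When true the UMI stays at the 5' end and the barcode is inserted
        after it; requires ``umi_length > 0``.  When false the barcode goes
        to the 5' end.
    fill_quality:
        Single printable ASCII character (``'!'``..``'~'``) assigned to
        every inserted barcode base.
    short_read_policy:
        ``"fail"`` raises on reads shorter than ``umi_length +
        linker_length``; ``"skip"`` drops and counts them.
    """

    barcode: str = DEFAULT_BARCODE
    umi_length: int = 0
    linker_length: int = 0
    umi_first: bool = False
    fill_quality: str = DEFAULT_FILL_QUALITY
    short_read_policy: str = "fail"

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcode", validate_barcode(self.barcode))
        if self.umi_length < 0:
            raise ValueError("umi_length must be >= 0")
        if self.linker_length < 0:
            raise ValueError("linker_length must be >= 0")
        if self.umi_first and self.umi_length == 0:
            raise ValueError("umi_first requires umi_length > 0")
        if len(self.fill_quality) != 1 or not ("!" <= self.fill_quality <= "~"):
            raise ValueError(
                "fill_quality must be a single printable ASCII character "
                "in the Phred+33 range '!'..'~'"
            )
        if self.short_read_policy not in SHORT_READ_POLICIES:
            raise ValueError(
                f"short_read_policy must be one of {SHORT_READ_POLICIES}"
            )

    @property
    def min_read_length(self) -> int:
        return self.umi_length + self.linker_length


@dataclass
class TransformResult:
    """Per-run record accounting: ``records_in == records_out + records_skipped``."""

    records_in: int = 0
    records_out: int = 0
    records_skipped: int = 0


def transform_record(
    record: FastqRecord, spec: ReadStructureSpec
) -> Optional[FastqRecord]:
    """Rewrite one read; return the new record, or ``None`` to skip it.

    The sequence decomposes as UMI = first ``umi_length`` bases, linker =
    next ``linker_length`` bases, rest = remainder; qualities partition
    identically.  Linker bases and their qualities are always discarded.
    The header (id and comment) is unchanged.  The output length is
    ``len(in) + len(barcode) - linker_length``.

    Raises
    ------
    ShortReadError
        When the read is shorter than ``umi_length + linker_length`` and
        the policy is ``"fail"``.
    """
    u = spec.umi_length
    l = spec.linker_length
    seq = record.sequence
    if len(seq) < u + l:
        if spec.short_read_policy == "skip":
            return None
        raise ShortReadError(
            f"read '{record.id}' has length {len(seq)} < umi_length + "
            f"linker_length = {u + l}"
        )
    qual = record.quality
    fill = spec.fill_quality * len(spec.barcode)
    umi_seq, rest_seq = seq[:u], seq[u + l:]
    umi_qual, rest_qual = qual[:u], qual[u + l:]
    if spec.umi_first:
        out_seq = umi_seq + spec.barcode + rest_seq
        out_qual = umi_qual + fill + rest_qual
    else:
        out_seq = spec.barcode + umi_seq + rest_seq
        out_qual = fill + umi_qual + rest_qual
    return FastqRecord(
        id=record.id, sequence=out_seq, quality=out_qual, comment=record.comment
    )


def transform_stream(
    records: Iterator[FastqRecord], spec: ReadStructureSpec
) -> Tuple[Iterator[FastqRecord], TransformResult]:
    """Apply :func:`transform_record` lazily over a record stream.

    Returns the transformed iterator together with a live
    :class:`TransformResult`; the counts are final once the iterator is
    exhausted.  Order is preserved and each record is processed exactly
    once with constant memory.  A fatal short read is re-raised with the
    failing record's 1-based ordinal prepended.
    """
    result = TransformResult()

    def _generate() -> Iterator[FastqRecord]:
        for ordinal, record in enumerate(records, start=1):
            result.records_in += 1
            try:
                out = transform_record(record, spec)
            except ShortReadError as exc:
                raise ShortReadError(f"record {ordinal}: {exc}") from None
            if out is None:
                result.records_skipped += 1
            else:
                result.records_out += 1
                yield out

    return _generate(), result
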