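"""Streaming FASTQ reader and writer.

Reads strict 4-line FASTQ records from plain or gzip-compressed files or
from standard input, and writes them back out, optionally gzip-compressed.
Compression of the *input* is detected from the gzip magic bytes
(``0x1f 0x8b``) rather than the filename, so compressed data arriving on a
pipe is decompressed transparently.  Output compression follows the ``.gz``
suffix of the destination path unless explicitly overridden.

The reader is a single-pass generator: memory use is bounded by the size of
one record, never by the size of the file.  Multi-line (wrapped) FASTQ is
rejected as a parse error; every modern sequencer emits strictly 4-line
records and wrapped input almost always indicates corruption.

Quality strings are carried through verbatim.  Only the length invariant
(``len(sequence) == len(quality)``) is enforced; scores are never decoded,
so the module is agnostic to the Phred encoding.
"""

from __future__ import annotations

import gzip
import io
import re
import sys
from dataclasses import dataclass
from typing import Iterator, Optional

from .errors import FastqIoError, FastqParseError

GZIP_MAGIC = b"\x1f\x8b"

_WHITESPACE = re.compile(r"\s")

STDIO_TOKEN = "-"


@dataclass(frozen=True, slots=True)
class FastqRecord:
    """One sequencing read.

    Attributes
    ----------
    id:
        Read identifier: the header text after ``@`` up to the first
        whitespace character.  Must be non-empty.
    sequence:
        Nucleotide string.  Any non-whitespace characters are accepted;
        the alphabet is not validated.
    quality:
        ASCII-encoded per-base quality string, same length as ``sequence``.
        Phred+33 by convention but never interpreted.
    comment:
        Optional remainder of the header line (after the first whitespace),
        preserved verbatim on output.  ``None`` when the header carries no
        comment.
    """

    id: str
    sequence: str
    quality: str
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FastqParseError("FASTQ record has an empty identifier")
        if len(self.sequence) != len(self.quality):
            raise FastqParseError(
                f"read '{self.id}': sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )
        if _WHITESPACE.search(self.sequence) or _WHITESPACE.search(self.quality):
            raise FastqParseError(
                f"read '{self.id}': sequence/quality contains whitespace"
            )

    @property
    def header(self) -> str:
        """The full header line content (without the leading ``@``)."""
        if self.comment is None:
            return self.id
        return f"{self.id} {self.comment}"


def _open_text_source(path: str) -> tuple[io.TextIOBase, bool]:
    """Open ``path`` (or stdin for ``'-'``) as text, sniffing gzip content.

    Returns the text handle and whether it may be closed outright (false
    when the wrapper sits directly on ``sys.stdin``, which must survive).
    """
    is_stdin = path == STDIO_TOKEN
    if is_stdin:
        raw: io.BufferedIOBase = sys.stdin.buffer
    else:
        try:
            raw = open(path, "rb")
        except OSError as exc:
            raise FastqIoError(
                f"cannot open FASTQ input '{path}': {exc.strerror or exc}"
            ) from None
    if not isinstance(raw, io.BufferedReader):
        raw = io.BufferedReader(raw)  # type: ignore[arg-type]
    try:
        head = raw.peek(2)[:2]
    except OSError as exc:  # e.g. reading from a closed descriptor
        raise FastqIoError(f"cannot read from '{path}': {exc}") from None
    if head == GZIP_MAGIC:
        # GzipFile.close() leaves an externally supplied fileobj open,
        # so closing the wrapper never closes real stdin
        stream: io.IOBase = gzip.GzipFile(fileobj=raw, mode="rb")
        return io.TextIOWrapper(stream, encoding="latin-1", newline=""), True
    return io.TextIOWrapper(raw, encoding="latin-1", newline=""), not is_stdin


def open_fastq_source(path: str) -> Iterator[FastqRecord]:
    """Iterate over FASTQ records from a file path or ``'-'`` (stdin).

    Gzip input is detected by content, so both plain and compressed data
    work from files and pipes alike.  Records are yielded in file order in
    a single pass with bounded memory.

    Raises
    ------
    FastqIoError
        If the path does not exist or cannot be read.
    FastqParseError
        On a truncated record (fewer than 4 lines at EOF), a header line
        not starting with ``@``, a separator line not starting with ``+``
        (both reported with their line number), or a sequence/quality
        length mismatch (reported with the read id).
    """
    handle, closeable = _open_text_source(path)
    n_complete = 0
    line_no = 0
    try:
        while True:
            header = handle.readline()
            if header == "":
                break
            line_no += 1
            header_line_no = line_no
            seq_line = handle.readline()
            plus_line = handle.readline()
            qual_line = handle.readline()
            if qual_line == "":
                raise FastqParseError(
                    f"truncated FASTQ record at end of input after record "
                    f"{n_complete} (record starting at line {header_line_no} "
                    f"has fewer than 4 lines)"
                )
            line_no += 3
            if not header.startswith("@"):
                raise FastqParseError(
                    f"line {header_line_no}: expected a header starting with "
                    f"'@', got {header.rstrip()!r} (wrapped multi-line FASTQ "
                    f"is not supported)"
                )
            if not plus_line.startswith("+"):
                raise FastqParseError(
                    f"line {header_line_no + 2}: expected a separator line "
                    f"starting with '+', got {plus_line.rstrip()!r} (wrapped "
                    f"multi-line FASTQ is not supported)"
                )
            full_header = header[1:].rstrip("\r\n")
            read_id, comment = _split_header(full_header)
            if not read_id:
                raise FastqParseError(
                    f"line {header_line_no}: empty read identifier"
                )
            sequence = seq_line.rstrip("\r\n")
            quality = qual_line.rstrip("\r\n")
            if len(sequence) != len(quality):
                raise FastqParseError(
                    f"read '{read_id}' (line {header_line_no}): sequence "
                    f"length {len(sequence)} != quality length {len(quality)}"
                )
            yield FastqRecord(
                id=read_id, sequence=sequence, quality=quality, comment=comment
            )
            n_complete += 1
    finally:
        if closeable:
            handle.close()
        else:
            # detach so the wrapper's GC never closes real stdin
            try:
                handle.detach()
            except ValueError:
                pass


def _split_header(full_header: str) -> tuple[str, Optional[str]]:
    """Split header content into (id, comment) at the first whitespace."""
    m = _WHITESPACE.search(full_header)
    if m is None:
        return full_header, None
    return full_header[: m.start()], full_header[m.end():]


class FastqWriter:
    """Write FASTQ records as strict 4-line blocks.

    The separator line is always emitted as a bare ``+``.  Use as a context
    manager, or call :meth:`close` explicitly.  Writing to ``'-'`` targets
    standard output, which is flushed but never closed.
    """

    def __init__(self, path: str, compress: Optional[bool] = None) -> None:
        self._path = path
        self._is_stdout = path == STDIO_TOKEN
        if compress is None:
            compress = (not self._is_stdout) and path.endswith(".gz")
        self.compress = compress
        if self._is_stdout:
            base: io.BufferedIOBase = sys.stdout.buffer
        else:
            try:
                base = open(path, "wb")
            except OSError as exc:
                raise FastqIoError(
                    f"cannot open FASTQ output '{path}': {exc.strerror or exc}"
                ) from None
        self._base = base
        if compress:
            # fixed mtime and no embedded filename keep identical record
            # streams byte-identical across paths and runs
            stream: io.IOBase = gzip.GzipFile(
                filename="", fileobj=base, mode="wb", mtime=0
            )
        else:
            stream = base  # type: ignore[assignment]
        self._handle = io.TextIOWrapper(stream, encoding="latin-1", newline="")

    def write(self, record: FastqRecord) -> None:
        self._handle.write(
            f"@{record.header}\n{record.sequence}\n+\n{record.quality}\n"
        )

    def close(self) -> None:
        self._handle.flush()
        inner = self._handle.detach()
        if self.compress:
            inner.close()  # finalize the gzip trailer; the base stays open
        if self._is_stdout:
            self._base.flush()  # stdout is flushed, never closed
        else:
            self._base.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc_info: object) -> None:
        self.close()


def open_fastq_sink(path: str, compress: Optional[bool] = None) -> FastqWriter:
    """Open a FASTQ writer for a file path or ``'-'`` (stdout).

    ``compress=None`` selects gzip automatically when ``path`` ends in
    ``.gz`` (stdout defaults to uncompressed); ``True``/``False`` force it.
    """
    return FastqWriter(path, compress=compress)
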