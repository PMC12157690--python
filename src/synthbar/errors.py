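"""Exception hierarchy.

Every error a pipeline run can hit maps onto one of three classes so the
command-line layer can translate it into a stable exit status:

* usage problems (bad flag combinations)           -> exit 1
* I/O and FASTQ parse problems                     -> exit 2
* data problems (bad barcode, read too short)      -> exit 3
"""


class SynthbarError(Exception):
    """Base class for all errors raised by this package."""


class UsageError(SynthbarError):
    """Invalid combination of options (e.g. --umi-first without a UMI length)."""


class FastqIoError(SynthbarError):
    """Input file missing/unreadable or output destination unwritable."""


class FastqParseError(SynthbarError):
    """Malformed FASTQ: bad header/separator, truncated record, or a
    sequence/quality length mismatch."""


class BarcodeError(SynthbarError):
    """Barcode contains characters outside the IUPAC nucleotide alphabet."""


class ShortReadError(SynthbarError):
    """A read is shorter than umi_length + linker_length under the
    fail-on-short policy."""
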