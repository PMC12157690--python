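"""Shared fixtures and the independent transformation oracle.

The oracle rebuilds the expected output read character by character from
(position, class) tuples — a deliberately different construction from the
engine's slicing — so agreement between the two is informative.
"""

from __future__ import annotations

from typing import Optional, Tuple

import pytest

from synthbar import FastqRecord, generate_fixture


def oracle_transform(
    seq: str,
    qual: str,
    *,
    barcode: str,
    u: int,
    l: int,
    umi_first: bool,
    fill: str,
) -> Optional[Tuple[str, str]]:
    """Naive reference rewrite; returns (sequence, quality) or None if short."""
    if len(seq) < u + l:
        return None
    umi = [(seq[i], qual[i]) for i in range(u)]
    rest = [(seq[i], qual[i]) for i in range(u + l, len(seq))]
    inserted = [(base, fill) for base in barcode.upper()]
    if umi_first:
        parts = umi + inserted + rest
    else:
        parts = inserted + umi + rest
    return "".join(p[0] for p in parts), "".join(p[1] for p in parts)


#: The four documented rewrite modes as (umi_length, linker_length, umi_first).
MODE_PARAMS = {
    "prepend": (0, 0, False),
    "umi_first": (8, 0, True),
    "linker_removal": (8, 6, False),
    "combined": (8, 6, True),
}


@pytest.fixture(scope="session")
def storm_fixture():
    """100 STORM-seq-like reads (u=8, l=6), 7 of them deliberately short."""
    return generate_fixture(
        n_reads=100, u=8, l=6, insert_length_range=(20, 60), n_short=7, seed=42
    )


@pytest.fixture
def tiny_records():
    return [
        FastqRecord(id="r1", sequence="ACGT", quality="FFFF"),
        FastqRecord(id="r2", sequence="TTGGCCAA", quality="IIIIIIII", comment="1:N:0"),
        FastqRecord(id="r3", sequence="", quality=""),
    ]
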