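"""Coordinate conventions and size formatting.

All genomic coordinates exposed by this package are 1-based inclusive,
matching the convention of the published Pp02 positions that the allele
geometry is anchored to. BED output is 0-based half-open; the conversion
lives here and nowhere else.

Two length conventions coexist in the source material and both are kept
explicit:

* ``span_length`` -- inclusive span ``end - start + 1``; this is how the
  ~9.5 kb deletion length (25,855,441..25,864,957 -> 9,517 bp) is
  reported.
* ``distance`` -- plain difference ``end - start``; this is how the
  ~2.4 Mb LD interval between boundary SNPs (24,277,038 / 26,628,544 ->
  2,351,506 bp) is reported.

Gel-estimate style band sizes are formatted in kb with *truncation* to
one decimal (1,761 bp -> "1.7"), whereas Mb-scale interval lengths use
ordinary rounding (2,351,506 bp -> "2.4").
"""

from __future__ import annotations

import math


def one_based_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> BED 0-based half-open."""
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based interval ({start}, {end})")
    return start - 1, end


def bed_to_one_based(start: int, end: int) -> tuple[int, int]:
    """BED 0-based half-open interval -> 1-based inclusive."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid BED interval ({start}, {end})")
    return start + 1, end


def span_length(start: int, end: int) -> int:
    """Inclusive length of a 1-based interval (both endpoints counted)."""
    if end < start:
        raise ValueError("end < start")
    return end - start + 1


def distance(start: int, end: int) -> int:
    """Distance between two coordinates (end - start)."""
    if end < start:
        raise ValueError("end < start")
    return end - start


def format_kb(bp: int | float) -> str:
    """Band size in kb, truncated to one decimal (gel-estimate style)."""
    return f"{math.floor(bp / 100.0) / 10.0:.1f}"


def format_mb(bp: int | float) -> str:
    """Interval length in Mb, rounded to one decimal."""
    return f"{bp / 1e6:.1f}"
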