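"""Breakpoint discovery from long-read alignments.

Consumes SAM records (alignment itself is out of scope) and emulates
the manual long-read analysis of the locus: alignments are first
filtered on mapping quality (records with mapQ >= 40 are accepted, the
published inclusion rule), then clipped-read endpoints are clustered
into breakpoint candidates and paired into insertion or deletion calls.

An insertion shows up as a pile of right-clipped records ending at the
insertion point next to a pile of left-clipped records starting just
after it; reads spanning the whole insert additionally carry a linked
supplementary alignment, and the unaligned middle of such reads
measures the insert length directly. A deletion shows up either as a
long deletion CIGAR operation or as a split read pair whose reference
gap equals the deleted interval while the read coordinates stay
contiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pysam

__all__ = [
    "ClipCluster",
    "SVCall",
    "filter_alignments",
    "detect_breakpoints",
    "call_sv",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 40
DEFAULT_MIN_CLIP = 200
DEFAULT_CLUSTER_WINDOW = 100
DEFAULT_MIN_READS = 3
_MIN_DEL_CIGAR = 50  # deletion CIGAR ops at least this long are SV signals
_MAX_READ_GAP = 30  # split pair: read-coordinate gap tolerated for a deletion


def filter_alignments(
    records: Sequence[pysam.AlignedSegment], min_mapq: int = DEFAULT_MIN_MAPQ
) -> tuple[list[pysam.AlignedSegment], int]:
    """Keep records with mapQ >= ``min_mapq`` (primary and supplementary
    alike). Returns (kept records, dropped count); records whose CIGAR
    cannot be interpreted are skipped with a log entry."""
    kept: list[pysam.AlignedSegment] = []
    dropped = 0
    for rec in records:
        try:
            if rec.is_unmapped or rec.cigartuples is None:
                raise ValueError("unmapped or missing CIGAR")
            _ = rec.infer_read_length()
        except (ValueError, TypeError) as exc:
            logger.warning("skipping malformed record %s: %s", rec.query_name, exc)
            dropped += 1
            continue
        if rec.mapping_quality >= min_mapq:
            kept.append(rec)
        else:
            dropped += 1
    return kept, dropped


def _clips(rec: pysam.AlignedSegment) -> tuple[int, int]:
    """(left, right) clip lengths; soft and hard clips both count."""
    ct = rec.cigartuples
    left = ct[0][1] if ct[0][0] in (4, 5) else 0
    right = ct[-1][1] if ct[-1][0] in (4, 5) else 0
    return left, right


@dataclass(frozen=True)
class ClipCluster:
    """A pile-up of clip endpoints marking a putative breakpoint."""

    position: int  # 1-based median endpoint
    side: str  # "left": clip precedes the alignment; "right": clip follows it
    n_reads: int
    mean_clip: float
    read_names: tuple[str, ...]


def _cluster_positions(signals: list[tuple[int, int, str]], window: int, side: str) -> list[ClipCluster]:
    if not signals:
        return []
    signals.sort()
    clusters: list[list[tuple[int, int, str]]] = [[signals[0]]]
    for sig in signals[1:]:
        if sig[0] - clusters[-1][-1][0] <= window:
            clusters[-1].append(sig)
        else:
            clusters.append([sig])
    out = []
    for cl in clusters:
        pos = int(np.median([s[0] for s in cl]))
        out.append(
            ClipCluster(pos, side, len(cl), float(np.mean([s[1] for s in cl])),
                        tuple(s[2] for s in cl))
        )
    return out


def detect_breakpoints(
    records: Sequence[pysam.AlignedSegment],
    min_clip: int = DEFAULT_MIN_CLIP,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
) -> list[ClipCluster]:
    """Cluster clipped-alignment endpoints into breakpoint candidates.

    A right clip marks the last aligned reference base; a left clip
    marks the first. Endpoints of the same side within
    ``cluster_window`` bp merge; the cluster position is the median
    endpoint.
    """
    if min_clip < 50:
        raise ValueError("min_clip must be >= 50")
    lefts: list[tuple[int, int, str]] = []
    rights: list[tuple[int, int, str]] = []
    for rec in records:
        lc, rc = _clips(rec)
        if lc >= min_clip:
            lefts.append((rec.reference_start + 1, lc, rec.query_name))
        if rc >= min_clip:
            rights.append((rec.reference_end, rc, rec.query_name))
    return _cluster_positions(rights, cluster_window, "right") + _cluster_positions(
        lefts, cluster_window, "left"
    )


@dataclass(frozen=True)
class SVCall:
    """An insertion or deletion call with its read support."""

    type: str  # "insertion" | "deletion"
    position: int  # insertion: ref base before which the insert sits; deletion: start
    end: int | None  # deletion end (None for insertions)
    size: int  # bp
    n_support: int
    size_is_lower_bound: bool = False

    def __post_init__(self) -> None:
        if self.type == "deletion" and (self.end is None or self.end <= self.position):
            raise ValueError("deletion end must exceed start")

    @property
    def interval(self) -> tuple[int, int]:
        if self.type != "deletion":
            raise ValueError("interval defined for deletions only")
        return self.position, self.end  # type: ignore[return-value]


def _split_pairs(records: Sequence[pysam.AlignedSegment]):
    """Group primary/supplementary segments of the same read, ordered by
    reference start."""
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    for rec in records:
        by_name.setdefault(rec.query_name, []).append(rec)
    for name, segs in by_name.items():
        if len(segs) == 2:
            segs.sort(key=lambda r: r.reference_start)
            yield name, segs[0], segs[1]


def call_sv(
    clusters: Sequence[ClipCluster],
    records: Sequence[pysam.AlignedSegment],
    min_reads: int = DEFAULT_MIN_READS,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
) -> list[SVCall]:
    """Pair breakpoint clusters and split/deletion-CIGAR evidence into
    insertion and deletion calls.

    Insertions: a right-clip cluster at P adjacent to a left-clip
    cluster at ~P+1. The size is the median unaligned middle of reads
    split across the insert (read length minus both aligned segments);
    when no read spans the insert, the longest one-sided clip only
    bounds the size from below and the call carries
    ``size_is_lower_bound``.

    Deletions: split pairs with contiguous read coordinates but a
    reference gap, or deletion CIGAR operations; the call interval is
    the median gap. Calls require ``min_reads`` supporting reads.
    """
    calls: list[SVCall] = []

    # --- deletion evidence ------------------------------------------------
    del_signals: list[tuple[int, int, str]] = []  # (start, end) 1-based inclusive
    for rec in records:
        ref = rec.reference_start  # 0-based walker
        for op, ln in rec.cigartuples or []:
            if op in (0, 7, 8):  # M/=/X
                ref += ln
            elif op == 2:  # D
                if ln >= _MIN_DEL_CIGAR:
                    del_signals.append((ref + 1, ref + ln, rec.query_name))
                ref += ln
            elif op == 3:  # N
                ref += ln
    ins_pair_sizes: dict[int, list[int]] = {}
    for name, a, b in _split_pairs(records):
        ref_gap = b.reference_start - a.reference_end  # bases skipped on the reference
        read_len = a.infer_read_length()
        aligned = a.query_alignment_length + b.query_alignment_length
        read_gap = read_len - aligned
        if ref_gap > cluster_window and read_gap <= _MAX_READ_GAP:
            del_signals.append((a.reference_end + 1, b.reference_start, name))
        elif abs(ref_gap) <= cluster_window and read_gap > _MAX_READ_GAP:
            # insert-spanning split read: unaligned middle measures the insert
            ins_pair_sizes.setdefault(a.reference_end, []).append(read_gap)

    if del_signals:
        del_signals.sort()
        groups: list[list[tuple[int, int, str]]] = [[del_signals[0]]]
        for sig in del_signals[1:]:
            if sig[0] - groups[-1][-1][0] <= cluster_window:
                groups[-1].append(sig)
            else:
                groups.append([sig])
        for g in groups:
            support = len({s[2] for s in g})
            if support < min_reads:
                continue
            start = int(np.median([s[0] for s in g]))
            end = int(np.median([s[1] for s in g]))
            calls.append(SVCall("deletion", start, end, end - start + 1, support))

    # --- insertion evidence -----------------------------------------------
    rights = [c for c in clusters if c.side == "right"]
    lefts = [c for c in clusters if c.side == "left"]
    used_left: set[int] = set()
    for rc in rights:
        mate = None
        for li, lc in enumerate(lefts):
            if li in used_left:
                continue
            if abs(lc.position - (rc.position + 1)) <= cluster_window:
                mate = (li, lc)
                break
        if mate is None:
            continue
        li, lc = mate
        used_left.add(li)
        names = set(rc.read_names) | set(lc.read_names)
        if len(names) < min_reads:
            continue
        position = int(round((rc.position + 1 + lc.position) / 2))
        spans: list[int] = []
        for anchor, sizes in ins_pair_sizes.items():
            if abs((anchor) - rc.position) <= cluster_window:
                spans.extend(sizes)
        if spans:
            size = int(np.median(spans))
            lower = False
        else:
            size = int(max(rc.mean_clip, lc.mean_clip))
            lower = True
        calls.append(SVCall("insertion", position, None, size, len(names), lower))
    return sorted(calls, key=lambda c: c.position)
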