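"""Structural-allele model for the miR172d (double-flower *di*) locus.

The locus carries a single-exon primary transcript with an embedded
~119 nt miRNA precursor. Loss of the precursor — by a transposon-style
insertion into the transcribed region or by a deletion removing the
whole gene — is recessive: only genotypes with no intact copy show the
double-flower phenotype. This module represents the reference locus and
its structural alleles, builds allele haplotypes with an invertible
reference<->haplotype coordinate map, derives the junction windows that
short-read genotyping matches against, scans coding sequences for
miR172 recognition sites, and recovers allele geometry from a pairwise
alignment of a haplotype against the reference.

Coordinates are 1-based inclusive throughout (see :mod:`petalotype.coords`).
An insertion's ``position`` is the first reference base displaced
rightward by the insert, i.e. the insert is placed immediately *before*
that base; for an insertion at transcript offset +k this equals
``tss + k``, matching the published arithmetic ("+297" at
25,860,117 + 297 = 25,860,414).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp, seq_to_array

__all__ = [
    "LocusModel",
    "StructuralAllele",
    "JunctionSet",
    "SiteHit",
    "InferredVariant",
    "apply_allele",
    "junctions",
    "find_mir172_target_site",
    "infer_structural_change",
]


@dataclass(frozen=True)
class LocusModel:
    """Reference sequence plus transcript-unit annotation.

    Attributes
    ----------
    sequence
        Reference DNA of the locus (upper-case ACGTN).
    tss
        1-based transcription start coordinate.
    transcript_interval
        1-based inclusive span of the (intronless) primary transcript.
    premirna_interval
        1-based inclusive span of the miRNA precursor, inside the
        transcript.
    """

    sequence: str
    tss: int
    transcript_interval: tuple[int, int]
    premirna_interval: tuple[int, int]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        ts, te = self.transcript_interval
        ps, pe = self.premirna_interval
        if not (1 <= ts <= te <= n):
            raise ValueError(f"transcript_interval {self.transcript_interval} outside [1, {n}]")
        if not (ts <= ps <= pe <= te):
            raise ValueError("premirna_interval must lie inside transcript_interval")
        if self.tss != ts:
            raise ValueError("tss must equal the transcript start")

    @property
    def transcript_length(self) -> int:
        return self.transcript_interval[1] - self.transcript_interval[0] + 1

    @property
    def premirna_length(self) -> int:
        return self.premirna_interval[1] - self.premirna_interval[0] + 1

    @property
    def transcript_sequence(self) -> str:
        ts, te = self.transcript_interval
        return self.sequence[ts - 1 : te]

    @property
    def premirna_sequence(self) -> str:
        ps, pe = self.premirna_interval
        return self.sequence[ps - 1 : pe]


@dataclass(frozen=True)
class StructuralAllele:
    """An insertion, deletion or reference allele at the locus.

    ``position`` (insertions) is the reference base before which the
    insert sits; ``interval`` (deletions) is the 1-based inclusive
    deleted span.
    """

    label: str
    kind: str  # "insertion" | "deletion" | "reference"
    position: int | None = None
    interval: tuple[int, int] | None = None
    inserted_sequence: str = ""

    def __post_init__(self) -> None:
        if self.kind == "insertion":
            if not self.inserted_sequence:
                raise ValueError(f"allele {self.label!r}: insertion requires a non-empty inserted_sequence")
            if self.position is None or self.position < 1:
                raise ValueError(f"allele {self.label!r}: insertion requires a 1-based position")
        elif self.kind == "deletion":
            if self.interval is None:
                raise ValueError(f"allele {self.label!r}: deletion requires an interval")
            s, e = self.interval
            if e < s or s < 1:
                raise ValueError(f"allele {self.label!r}: deletion interval must satisfy 1 <= start <= end")
        elif self.kind == "reference":
            if self.position is not None or self.interval is not None or self.inserted_sequence:
                raise ValueError("reference allele carries no coordinates or sequence")
        else:
            raise ValueError(f"unknown allele kind {self.kind!r}")

    @classmethod
    def insertion(cls, label: str, position: int, inserted_sequence: str) -> "StructuralAllele":
        return cls(label=label, kind="insertion", position=position, inserted_sequence=inserted_sequence.upper())

    @classmethod
    def deletion(cls, label: str, start: int, end: int) -> "StructuralAllele":
        return cls(label=label, kind="deletion", interval=(start, end))

    @classmethod
    def reference(cls, label: str = "wt") -> "StructuralAllele":
        return cls(label=label, kind="reference")

    @property
    def size(self) -> int:
        """Inserted/deleted length in bp (0 for the reference allele)."""
        if self.kind == "insertion":
            return len(self.inserted_sequence)
        if self.kind == "deletion":
            s, e = self.interval  # type: ignore[misc]
            return e - s + 1
        return 0


class CoordinateMap:
    """Monotone, invertible-outside-the-variant map ref<->haplotype.

    Positions are 1-based. Reference positions removed by a deletion map
    to ``None``; haplotype positions inside an insert map to ``None``.
    """

    def __init__(self, allele: StructuralAllele, ref_length: int) -> None:
        self._allele = allele
        self._ref_length = ref_length
        if allele.kind == "insertion":
            self._pivot = allele.position  # first ref base shifted right
            self._shift = len(allele.inserted_sequence)
        elif allele.kind == "deletion":
            self._del_start, self._del_end = allele.interval  # type: ignore[misc]
            self._shift = -(self._del_end - self._del_start + 1)
        else:
            self._shift = 0

    def ref_to_hap(self, pos: int) -> int | None:
        if not 1 <= pos <= self._ref_length:
            raise ValueError(f"reference position {pos} out of range")
        a = self._allele
        if a.kind == "reference":
            return pos
        if a.kind == "insertion":
            return pos if pos < self._pivot else pos + self._shift
        if self._del_start <= pos <= self._del_end:
            return None
        return pos if pos < self._del_start else pos + self._shift

    def hap_to_ref(self, pos: int) -> int | None:
        a = self._allele
        hap_len = self._ref_length + (self._shift if a.kind != "reference" else 0)
        if not 1 <= pos <= hap_len:
            raise ValueError(f"haplotype position {pos} out of range")
        if a.kind == "reference":
            return pos
        if a.kind == "insertion":
            if pos < self._pivot:
                return pos
            if pos < self._pivot + self._shift:
                return None  # inside the insert
            return pos - self._shift
        return pos if pos < self._del_start else pos - self._shift


def apply_allele(locus: LocusModel, allele: StructuralAllele) -> tuple[str, CoordinateMap]:
    """Build the haplotype sequence carrying ``allele`` plus its coordinate map.

    Length bookkeeping: ``len(hap) == len(ref) + insert`` for insertions
    and ``len(ref) - deleted`` for deletions.
    """
    seq = locus.sequence
    n = len(seq)
    if allele.kind == "reference":
        return seq, CoordinateMap(allele, n)
    if allele.kind == "insertion":
        p = allele.position
        if not 2 <= p <= n:  # insert strictly inside the locus
            raise ValueError(f"insertion position {p} outside locus interior [2, {n}]")
        hap = seq[: p - 1] + allele.inserted_sequence + seq[p - 1 :]
        return hap, CoordinateMap(allele, n)
    s, e = allele.interval  # type: ignore[misc]
    if s <= 1 or e >= n:
        raise ValueError(f"deletion ({s}, {e}) touches the locus edge [1, {n}]")
    hap = seq[: s - 1] + seq[e:]
    return hap, CoordinateMap(allele, n)


@dataclass(frozen=True)
class JunctionSet:
    """Breakpoint-centred sequence windows for one allele.

    ``wt_junctions`` holds one window per wild-type breakpoint spanned
    by the variant (one for an insertion, two for a deletion);
    ``variant_junctions`` holds the novel-adjacency windows (insertion
    left/right, or the single deletion fusion). Every window has length
    ``2 * flank`` and is centred on its breakpoint.
    """

    label: str
    wt_junctions: tuple[str, ...]
    variant_junctions: tuple[str, ...]
    flank: int
    breakpoints: tuple[int, ...]  # reference coordinate left of each breakpoint

    @property
    def n_wt_breakpoints(self) -> int:
        return len(self.wt_junctions)


def junctions(locus: LocusModel, allele: StructuralAllele, flank: int = 50) -> JunctionSet:
    """Derive the wild-type and variant junction windows for an allele.

    For an insertion before reference base P:
      wt window      = ref[P-flank .. P+flank-1]
      left junction  = ref[P-flank .. P-1] + insert[:flank]
      right junction = insert[-flank:] + ref[P .. P+flank-1]
    For a deletion [s, e]:
      wt windows = one centred on each breakpoint (s-1|s and e|e+1)
      fusion     = ref[s-flank .. s-1] + ref[e+1 .. e+flank]
    """
    if flank < 15:
        raise ValueError("flank must be >= 15")
    seq = locus.sequence
    n = len(seq)
    if allele.kind == "reference":
        raise ValueError("junctions are defined for variant alleles only")
    if allele.kind == "insertion":
        p = allele.position
        ins = allele.inserted_sequence
        if len(ins) < flank:
            raise ValueError(f"flank {flank} exceeds insert length {len(ins)}")
        if p - 1 - flank < 0 or p - 1 + flank > n:
            raise ValueError("flank larger than available reference sequence")
        wt = seq[p - 1 - flank : p - 1 + flank]
        left = seq[p - 1 - flank : p - 1] + ins[:flank]
        right = ins[-flank:] + seq[p - 1 : p - 1 + flank]
        return JunctionSet(allele.label, (wt,), (left, right), flank, (p - 1,))
    s, e = allele.interval  # type: ignore[misc]
    if s - 1 - flank < 0 or e + flank > n:
        raise ValueError("flank larger than available reference sequence")
    wt_left = seq[s - 1 - flank : s - 1 + flank]
    wt_right = seq[e - flank : e + flank]
    fusion = seq[s - 1 - flank : s - 1] + seq[e : e + flank]
    return JunctionSet(allele.label, (wt_left, wt_right), (fusion,), flank, (s - 1, e))


@dataclass(frozen=True)
class SiteHit:
    """A candidate miR172 recognition site on a coding sequence."""

    position: int  # 1-based start of the site on the cds
    mismatches: int
    mismatch_offsets: tuple[int, ...]  # 0-based offsets within the site


def find_mir172_target_site(cds: str, mature_mirna: str, max_mismatch: int = 3) -> list[SiteHit]:
    """Scan a coding sequence for near-complementary miR172 binding sites.

    The recognition site on the mRNA is the reverse complement of the
    mature miRNA. All windows with at most ``max_mismatch`` mismatches
    are ranked; the hit(s) with the minimal mismatch count are returned
    together with their per-position mismatch offsets, so a variant cds
    can be flagged as altering the site. ``N`` never matches.
    """
    if not cds:
        raise ValueError("empty cds")
    if not 19 <= len(mature_mirna) <= 24:
        raise ValueError("mature miRNA length must be 19-24 nt")
    cds = cds.upper().replace("U", "T")
    site = revcomp(mature_mirna.upper().replace("U", "T"))
    k = len(site)
    if len(cds) < k:
        return []
    best: list[SiteHit] = []
    best_mm = max_mismatch + 1
    for i in range(len(cds) - k + 1):
        window = cds[i : i + k]
        offsets = tuple(
            j for j, (a, b) in enumerate(zip(window, site)) if a != b or a == "N" or b == "N"
        )
        mm = len(offsets)
        if mm < best_mm:
            best = [SiteHit(i + 1, mm, offsets)]
            best_mm = mm
        elif mm == best_mm and mm <= max_mismatch:
            best.append(SiteHit(i + 1, mm, offsets))
    return best if best_mm <= max_mismatch else []


@dataclass(frozen=True)
class InferredVariant:
    """A structural difference recovered from a pairwise alignment."""

    kind: str  # "insertion" | "deletion"
    position: int  # insertion: ref base before which insert sits; deletion: start
    length: int

    @property
    def interval(self) -> tuple[int, int]:
        if self.kind != "deletion":
            raise ValueError("interval is defined for deletions")
        return self.position, self.position + self.length - 1


def _common_prefix_len(a: np.ndarray, b: np.ndarray) -> int:
    n = min(len(a), len(b))
    neq = np.flatnonzero(a[:n] != b[:n])
    return int(neq[0]) if neq.size else n


def infer_structural_change(reference: str, haplotype: str) -> InferredVariant | None:
    """Recover insertion/deletion geometry from a pairwise diff of a
    haplotype against the reference.

    The two sequences are anchored on their longest common prefix and
    suffix; for a haplotype differing from the reference by a single
    clean indel this recovers the variant length exactly and its
    left-aligned placement (identical to the planted position whenever
    the breakpoint flanks are non-repetitive). Returns None for
    identical sequences; sequences differing by more than one indel
    (or by substitutions) are rejected.
    """
    ref = seq_to_array(reference)
    hap = seq_to_array(haplotype)
    if len(ref) == len(hap):
        if (ref == hap).all():
            return None
        raise ValueError("sequences differ by substitutions, not a single indel")
    size = abs(len(hap) - len(ref))
    prefix = _common_prefix_len(ref, hap)
    suffix = _common_prefix_len(ref[::-1], hap[::-1])
    if prefix + suffix < min(len(ref), len(hap)):
        raise ValueError("sequences differ by more than a single indel")
    # left-align: the indel starts right after the unambiguous shared prefix
    pos = min(prefix, min(len(ref), len(hap)) - suffix)
    if len(hap) > len(ref):
        return InferredVariant("insertion", pos + 1, size)
    return InferredVariant("deletion", pos + 1, size)
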