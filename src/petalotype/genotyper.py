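"""Sequence-based structural-allele genotyping from short reads.

Reads are classified against breakpoint-centred junction windows
(:class:`petalotype.alleles.JunctionSet`): a read *supports wild type*
at a breakpoint when it aligns contiguously across the breakpoint with
enough matched bases on each side; it *supports a variant* when it does
so across one of the allele's novel junctions (insertion left/right
flank or deletion fusion); it is *truncated* when it matches one
wild-type flank but its continuation mismatches the reference beyond
the breakpoint. Truncated reads are the primary discovery signal in
the underlying method while junction-spanning reads are the control;
accordingly a truncated pile-up only counts toward an allele when at
least one variant-junction read corroborates it, and otherwise raises
the conflicting-evidence flag.

Diploid calls require a minimum mean locus coverage (default 10x,
mirroring the ">10x" inclusion rule of the source analysis) and
read-support thresholds that are design choices exposed in
:class:`Thresholds`.

The matching engine is exact under the substitution error model: a
k-mer seed (k=15) shared between read and window proposes alignment
offsets which are verified directly, and a vectorised exhaustive
ungapped scan covers every remaining offset, so seeding can only
accelerate, never change, a classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._seq import revcomp, seq_to_array
from .alleles import JunctionSet

__all__ = [
    "Thresholds",
    "Classification",
    "ReadEvidence",
    "GenotypeCall",
    "classify_read",
    "genotype_sample",
    "genotype_panel",
    "check_recessive_cosegregation",
    "CosegregationReport",
]

K = 15  # seed k-mer size
_MIN_EXT = 5  # bases beyond a breakpoint needed to judge truncation
_TRUNC_MAX_MATCH = 0.5  # extension match fraction below which a read is truncated


@dataclass(frozen=True)
class Thresholds:
    """Read-support and coverage thresholds for diploid calling."""

    min_overlap: int = 20  # matched bases required on each side of a breakpoint
    max_mismatch_rate: float = 0.05  # per aligned base
    min_support: int = 3  # reads to declare an allele present
    max_contra: int = 1  # tolerated contradicting reads for a homozygous call
    min_coverage: float = 10.0  # mean locus fold coverage ("> 10x")

    def __post_init__(self) -> None:
        if self.min_overlap < 15:
            raise ValueError("min_overlap must be >= 15")


class Classification(NamedTuple):
    """Outcome of classifying one read against one allele's junction set."""

    category: str  # "wt" | "variant" | "truncated" | "uninformative"
    wt_breakpoints: tuple[int, ...] = ()  # indices of supported wt breakpoints
    variant_window: int | None = None


def _half_match_totals(read_arr: np.ndarray, half_arr: np.ndarray) -> np.ndarray:
    """Matched-base count of the read against one window half, for every
    ungapped offset (row r corresponds to read base 0 sitting at
    half-window coordinate r - len(read))."""
    lr, lh = len(read_arr), len(half_arr)
    padded = np.zeros(lh + 2 * lr, dtype=np.uint8)
    padded[lr : lr + lh] = half_arr
    views = np.lib.stride_tricks.sliding_window_view(padded, lr)
    return (views == read_arr).sum(axis=1)


def _scan(read_arr: np.ndarray, win_arr: np.ndarray, flank: int,
          min_overlap: int, rate: float) -> tuple[bool, bool]:
    """Exhaustive ungapped scan of a read against one window.

    Returns (supported, truncated): *supported* iff some offset has
    >= min_overlap matched bases on each side of the window centre and
    an overall mismatch rate within budget; *truncated* iff some offset
    matches one flank cleanly but the read's continuation past the
    breakpoint (>= 5 aligned bases) matches at < 50%.

    The per-side matched counts at every offset of the full window are
    assembled from two independent scans of the window halves (the
    breakpoint sits exactly at the window centre), which keeps the
    whole computation to two vectorised equality passes.
    """
    lr, lw = len(read_arr), len(win_arr)
    # left/right matched counts per full-window offset, via the two halves
    tl = _half_match_totals(read_arr, win_arr[:flank])
    tr = _half_match_totals(read_arr, win_arr[flank:])
    pad = np.zeros(lw - flank, dtype=tl.dtype)
    left = np.concatenate([tl, pad])
    right = np.concatenate([np.zeros(flank, dtype=tr.dtype), tr])
    rows = lw + lr + 1
    w0 = np.arange(rows) - lr  # window coordinate of read base 0
    total = left + right
    ov_start = np.maximum(0, w0)
    ov_end = np.minimum(lw, w0 + lr)
    aligned = np.clip(ov_end - ov_start, 0, None)
    mism = aligned - total
    supported = bool(np.any((left >= min_overlap) & (right >= min_overlap) & (mism <= rate * aligned)))
    left_ext = np.clip(np.minimum(flank, ov_end) - ov_start, 0, None)
    right_ext = np.clip(ov_end - np.maximum(flank, ov_start), 0, None)
    left_clean = (left >= min_overlap) & (left_ext - left <= rate * left_ext)
    right_clean = (right >= min_overlap) & (right_ext - right <= rate * right_ext)
    trunc = bool(
        np.any(left_clean & (right_ext >= _MIN_EXT) & (right < _TRUNC_MAX_MATCH * right_ext))
        or np.any(right_clean & (left_ext >= _MIN_EXT) & (left < _TRUNC_MAX_MATCH * left_ext))
    )
    return supported, trunc


def classify_read(read: str, junction_set: JunctionSet, min_overlap: int = 20,
                  max_mismatch_rate: float = 0.05) -> Classification:
    """Classify one read against one allele's junction windows.

    Both the read and its reverse complement are tested. Priority:
    variant support > wild-type support > truncation. A read shorter
    than ``2 * min_overlap`` is uninformative (not an error).
    """
    if min_overlap < 15:
        raise ValueError("min_overlap must be >= 15")
    if len(read) < 2 * min_overlap:
        return Classification("uninformative")
    flank = junction_set.flank
    orientations = (seq_to_array(read), seq_to_array(revcomp(read)))
    for j, window in enumerate(junction_set.variant_junctions):
        win_arr = seq_to_array(window)
        for arr in orientations:
            supported, _ = _scan(arr, win_arr, flank, min_overlap, max_mismatch_rate)
            if supported:
                return Classification("variant", variant_window=j)
    wt_hits: list[int] = []
    truncated = False
    for b, window in enumerate(junction_set.wt_junctions):
        win_arr = seq_to_array(window)
        for arr in orientations:
            supported, trunc = _scan(arr, win_arr, flank, min_overlap, max_mismatch_rate)
            if supported:
                wt_hits.append(b)
                break
            truncated = truncated or trunc
    if wt_hits:
        return Classification("wt", wt_breakpoints=tuple(sorted(set(wt_hits))))
    if truncated:
        return Classification("truncated")
    return Classification("uninformative")


@dataclass
class ReadEvidence:
    """Per-allele read-evidence tallies for one sample."""

    allele: str
    supports_wt_by_breakpoint: list[int]  # one count per wt breakpoint
    truncated_wt: int = 0
    supports_variant: int = 0
    uninformative: int = 0

    @property
    def supports_wt(self) -> int:
        """Wild-type presence support: the weakest breakpoint governs
        (a deletion needs both of its breakpoints covered)."""
        return min(self.supports_wt_by_breakpoint)


@dataclass(frozen=True)
class GenotypeCall:
    """Diploid call over {wt, variant alleles} with its evidence."""

    sample_id: str
    genotype: tuple[str, str] | None  # None = no-call
    evidence: dict[str, ReadEvidence]
    mean_coverage: float
    flags: tuple[str, ...] = ()

    @property
    def is_call(self) -> bool:
        return self.genotype is not None


# ---------------------------------------------------------------------------
# k-mer machinery (speed only; classification itself is exact)


def _kmer_codes(enc: np.ndarray) -> np.ndarray:
    """Rolling k-mer integer codes for a (n_reads, read_len) base-index matrix."""
    if enc.shape[1] < K:
        return np.empty((enc.shape[0], 0), dtype=np.int64)
    powers = (4 ** np.arange(K - 1, -1, -1)).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc.astype(np.int64), K, axis=1)
    return windows @ powers


def _encode_matrix(reads: Sequence[str]) -> np.ndarray:
    lens = {len(r) for r in reads}
    assert len(lens) == 1
    buf = "".join(reads)
    arr = seq_to_array(buf).reshape(len(reads), lens.pop())
    code = np.full(256, 0, dtype=np.int64)  # non-ACGT folded onto A: only affects seeding
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    return code[arr]


_KMER_CACHE: dict[JunctionSet, np.ndarray] = {}


def _window_kmers(junction_set: JunctionSet) -> np.ndarray:
    cached = _KMER_CACHE.get(junction_set)
    if cached is not None:
        return cached
    seqs = list(junction_set.wt_junctions) + list(junction_set.variant_junctions)
    seqs += [revcomp(s) for s in seqs]
    codes: list[np.ndarray] = []
    for s in seqs:
        enc = _encode_matrix([s])
        codes.append(_kmer_codes(enc).ravel())
    kmers = np.unique(np.concatenate(codes))
    if len(_KMER_CACHE) > 64:
        _KMER_CACHE.clear()
    _KMER_CACHE[junction_set] = kmers
    return kmers


def _prescreen(reads: Sequence[str], junction_sets: Sequence[JunctionSet]) -> dict[int, list[int]]:
    """Map read index -> junction-set indices sharing at least one exact
    15-mer (either strand) with the read. Reads absent from the map
    cannot be classified as anything but uninformative by the seeded
    engine and are skipped."""
    per_set = [_window_kmers(js) for js in junction_sets]
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r), []).append(i)
    hits: dict[int, list[int]] = {}
    for length, idxs in by_len.items():
        if length < K:
            continue
        enc = _encode_matrix([reads[i] for i in idxs])
        codes = _kmer_codes(enc)
        flat = codes.ravel()
        # one pass against the union, then resolve sets per candidate read
        union = np.unique(np.concatenate(per_set))
        pos = np.searchsorted(union, flat)
        found = union[np.minimum(pos, len(union) - 1)] == flat
        candidates = np.flatnonzero(found.reshape(codes.shape).any(axis=1))
        for local in candidates:
            read_codes = codes[local]
            sets = []
            for s, kmers in enumerate(per_set):
                p = np.searchsorted(kmers, read_codes)
                if (kmers[np.minimum(p, len(kmers) - 1)] == read_codes).any():
                    sets.append(s)
            if sets:
                hits[idxs[int(local)]] = sets
    return hits


# ---------------------------------------------------------------------------
# diploid calling


def _empty_evidence(junction_sets: Sequence[JunctionSet]) -> dict[str, ReadEvidence]:
    return {
        js.label: ReadEvidence(js.label, [0] * js.n_wt_breakpoints)
        for js in junction_sets
    }


def genotype_sample(
    sample_id: str,
    reads: Iterable,
    junction_sets: Sequence[JunctionSet],
    thresholds: Thresholds = Thresholds(),
    locus_length: int | None = None,
) -> GenotypeCall:
    """Call the diploid genotype of one sample from its reads.

    An allele is *present* when its variant-junction support reaches
    ``min_support`` (truncated reads top up the count only when at
    least one junction-spanning read corroborates the allele). Wild
    type fills the remaining slot(s) when every relevant breakpoint
    shows contiguous wild-type coverage. Conflicting or insufficient
    evidence yields a no-call with an explanatory flag — never a forced
    genotype.
    """
    if not junction_sets:
        raise ValueError("need at least one junction set")
    seqs = [r.sequence if hasattr(r, "sequence") else str(r) for r in reads]
    evidence = _empty_evidence(junction_sets)
    coverage = (sum(len(s) for s in seqs) / locus_length) if locus_length else float("inf")
    flags: list[str] = []
    if locus_length and coverage < thresholds.min_coverage:
        return GenotypeCall(sample_id, None, evidence, coverage, ("low-coverage",))

    hits = _prescreen(seqs, junction_sets)
    n_classified_sets = {js.label: 0 for js in junction_sets}
    for i, set_indices in hits.items():
        for s in set_indices:
            js = junction_sets[s]
            cls = classify_read(seqs[i], js, thresholds.min_overlap, thresholds.max_mismatch_rate)
            ev = evidence[js.label]
            n_classified_sets[js.label] += 1
            if cls.category == "variant":
                ev.supports_variant += 1
            elif cls.category == "wt":
                for b in cls.wt_breakpoints:
                    ev.supports_wt_by_breakpoint[b] += 1
            elif cls.category == "truncated":
                ev.truncated_wt += 1
            else:
                ev.uninformative += 1

    t = thresholds
    present: list[str] = []
    for js in junction_sets:
        ev = evidence[js.label]
        support = ev.supports_variant
        if support >= 1:
            support += ev.truncated_wt  # truncation corroborated by junction reads
        if support >= t.min_support:
            present.append(js.label)
        elif ev.truncated_wt >= t.min_support and ev.supports_variant == 0:
            flags.append("conflicting-evidence")

    genotype: tuple[str, str] | None = None
    if len(present) > 2:
        flags.append("conflicting-evidence")
    elif len(present) == 2:
        genotype = (present[0], present[1])
    elif len(present) == 1:
        label = present[0]
        wt_here = evidence[label].supports_wt
        if wt_here >= t.min_support:
            genotype = ("wt", label)
        elif wt_here <= t.max_contra:
            genotype = (label, label)
        else:
            flags.append("conflicting-evidence")
    else:
        wt_everywhere = min(evidence[js.label].supports_wt for js in junction_sets)
        contra = max(evidence[js.label].supports_variant for js in junction_sets)
        if wt_everywhere >= t.min_support and contra <= t.max_contra:
            genotype = ("wt", "wt")
        else:
            flags.append("conflicting-evidence")
    return GenotypeCall(sample_id, genotype, evidence, coverage, tuple(dict.fromkeys(flags)))


def genotype_panel(
    sample_reads: Sequence[tuple[str, Iterable]],
    junction_sets: Sequence[JunctionSet],
    thresholds: Thresholds = Thresholds(),
    locus_length: int | None = None,
) -> list[GenotypeCall]:
    """Genotype every sample of a panel. Duplicate sample ids are an error."""
    seen: set[str] = set()
    calls: list[GenotypeCall] = []
    for sid, reads in sample_reads:
        if sid in seen:
            raise ValueError(f"duplicate sample id {sid!r}")
        seen.add(sid)
        calls.append(genotype_sample(sid, reads, junction_sets, thresholds, locus_length))
    return calls


def calls_to_frame(calls: Sequence[GenotypeCall]):
    """Tabular view of a panel's calls (one row per sample)."""
    import pandas as pd

    rows = []
    for c in calls:
        gt = "/".join(c.genotype) if c.genotype else "no-call"
        row = {
            "sample": c.sample_id,
            "genotype": gt,
            "mean_coverage": round(c.mean_coverage, 2) if c.mean_coverage != float("inf") else "",
            "flags": ";".join(c.flags),
        }
        for label, ev in c.evidence.items():
            row[f"{label}_variant_reads"] = ev.supports_variant
            row[f"{label}_wt_reads"] = ev.supports_wt
            row[f"{label}_truncated_reads"] = ev.truncated_wt
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CosegregationReport:
    """Consistency of calls with the recessive double-flower model."""

    double_with_wt: tuple[str, ...]  # double-flower samples carrying wt, unexplained
    single_with_variant: tuple[str, ...]  # single-flower samples with no wt allele
    n_consistent: int
    n_no_call: int

    @property
    def n_inconsistent(self) -> int:
        return len(self.double_with_wt) + len(self.single_with_variant)


def check_recessive_cosegregation(
    calls: Sequence[GenotypeCall],
    phenotypes: dict[str, str],
    dominant_carriers: set[str] = frozenset(),
) -> CosegregationReport:
    """Flag samples whose genotype contradicts the recessive model.

    A double-flower sample carrying a wild-type allele is inconsistent
    unless it is a known carrier of a dominant double-flower allele at
    another locus; a single-flower sample homozygous or compound
    heterozygous for variant alleles is always inconsistent.
    """
    double_wt: list[str] = []
    single_var: list[str] = []
    consistent = 0
    no_call = 0
    for c in calls:
        pheno = phenotypes[c.sample_id]
        if pheno not in ("single", "double"):
            raise ValueError(f"{c.sample_id}: phenotype must be 'single' or 'double'")
        if c.genotype is None:
            no_call += 1
            continue
        has_wt = "wt" in c.genotype
        if pheno == "double" and has_wt and c.sample_id not in dominant_carriers:
            double_wt.append(c.sample_id)
        elif pheno == "single" and not has_wt:
            single_var.append(c.sample_id)
        else:
            consistent += 1
    return CosegregationReport(tuple(double_wt), tuple(single_var), consistent, no_call)
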