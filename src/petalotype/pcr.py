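"""In-silico PCR: primer-site search, amplicon prediction and per-genotype
gel band patterns.

The diagnostic assays modelled here are presence/absence assays on
locus-specific primers, so annealing is exact-match by default
(``max_mismatch=0``) and products are capped at a long-range-PCR
``max_len`` of 10 kb. Product length is measured 5'-end to 5'-end
inclusive, and an insertion inside an amplicon grows the product by
exactly the insert length (wild-type 563 bp -> 1,761 bp with a 1,198 bp
insert, -> 5,555 bp with a 4,992 bp insert).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp, seq_to_array
from .alleles import LocusModel, StructuralAllele, apply_allele
from .coords import format_kb

__all__ = [
    "Primer",
    "PrimerSite",
    "AmpliconPrediction",
    "find_primer_sites",
    "predict_amplicons",
    "genotype_gel_pattern",
]

DEFAULT_MAX_LEN = 10_000


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3'."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not 15 <= len(seq) <= 35:
            raise ValueError(f"primer {self.name!r}: length must be 15-35 nt, got {len(seq)}")
        if set(seq) - set("ACGT"):
            raise ValueError(f"primer {self.name!r}: ambiguous bases not allowed")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerSite:
    """An annealing site; ``position`` is the 1-based template coordinate
    of the primer's 5' end (leftmost base for forward hits, rightmost
    for reverse hits)."""

    position: int
    strand: str  # "+" | "-"
    mismatches: int


def _hamming_hits(template_arr: np.ndarray, probe: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(0-based leftmost position, mismatch count) of all windows within budget."""
    p = seq_to_array(probe)
    k = len(p)
    if len(template_arr) < k:
        return []
    if max_mismatch == 0:
        # exact: string search is fastest and unambiguous
        tpl = template_arr.tobytes()
        probe_b = probe.encode()
        out = []
        i = tpl.find(probe_b)
        while i != -1:
            out.append((i, 0))
            i = tpl.find(probe_b, i + 1)
        return out
    windows = np.lib.stride_tricks.sliding_window_view(template_arr, k)
    mm = (windows != p).sum(axis=1)
    return [(int(i), int(mm[i])) for i in np.flatnonzero(mm <= max_mismatch)]


def find_primer_sites(template: str, primer: Primer, max_mismatch: int = 0) -> list[PrimerSite]:
    """All annealing sites of a primer on a template, both strands.

    Forward hits are occurrences of the primer sequence; reverse hits
    are occurrences of its reverse complement (the reported position is
    then the rightmost template base, the primer's 5' end).
    """
    if not template:
        raise ValueError("empty template")
    arr = seq_to_array(template)
    sites = [PrimerSite(i + 1, "+", mm) for i, mm in _hamming_hits(arr, primer.sequence, max_mismatch)]
    k = len(primer)
    sites += [
        PrimerSite(i + k, "-", mm)
        for i, mm in _hamming_hits(arr, revcomp(primer.sequence), max_mismatch)
    ]
    return sorted(sites, key=lambda s: (s.position, s.strand))


@dataclass(frozen=True)
class AmpliconPrediction:
    """Predicted products of one primer pair on one template allele."""

    forward: Primer
    reverse: Primer
    template_label: str
    products: tuple[int, ...]  # lengths in bp, sorted; empty = no amplification

    @property
    def bands_kb(self) -> tuple[str, ...]:
        """Gel-estimate style sizes (kb, truncated to one decimal)."""
        return tuple(format_kb(p) for p in self.products)


def predict_amplicons(template: str, forward: Primer, reverse: Primer,
                      max_len: int = DEFAULT_MAX_LEN, max_mismatch: int = 0,
                      template_label: str = "template") -> AmpliconPrediction:
    """Predict PCR products: every (forward-strand fwd hit, reverse-strand
    rev hit) pair in productive orientation with product length between
    the summed primer lengths and ``max_len``. An empty product list is
    a valid result (no amplification)."""
    fwd_hits = [s for s in find_primer_sites(template, forward, max_mismatch) if s.strand == "+"]
    rev_hits = [s for s in find_primer_sites(template, reverse, max_mismatch) if s.strand == "-"]
    min_len = len(forward) + len(reverse)
    products = sorted(
        {
            r.position - f.position + 1
            for f in fwd_hits
            for r in rev_hits
            if f.position < r.position and min_len <= r.position - f.position + 1 <= max_len
        }
    )
    return AmpliconPrediction(forward, reverse, template_label, tuple(products))


def genotype_gel_pattern(
    genotype: tuple[str, str],
    primer_pairs: dict[str, tuple[Primer, Primer]],
    alleles: dict[str, StructuralAllele],
    locus: LocusModel,
    max_len: int = DEFAULT_MAX_LEN,
    max_mismatch: int = 0,
) -> dict[str, tuple[int, ...]]:
    """Expected band sizes per primer pair for a diploid genotype.

    The pattern is the union of the per-haplotype predictions, so a
    heterozygote shows both the wild-type and the variant band.
    Returns ``{pair_name: sorted band lengths}``.
    """
    haplotypes = []
    for label in genotype:
        if label not in alleles:
            raise ValueError(f"unknown allele label {label!r}")
        hap, _ = apply_allele(locus, alleles[label])
        haplotypes.append((label, hap))
    pattern: dict[str, tuple[int, ...]] = {}
    for pair_name, (fwd, rev) in primer_pairs.items():
        bands: set[int] = set()
        for label, hap in haplotypes:
            pred = predict_amplicons(hap, fwd, rev, max_len=max_len,
                                     max_mismatch=max_mismatch, template_label=label)
            bands.update(pred.products)
        pattern[pair_name] = tuple(sorted(bands))
    return pattern
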