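"""Synthetic-data generator emulating the double-flower miR172d locus study.

Everything the pipeline consumes can be produced here from an explicit
seed: a ~50 kb reference locus carrying a single-exon ~1.9 kb transcript
with an embedded 119 nt miRNA precursor; the three structural alleles
with the published geometry (a 4,992 bp terminal-repeat-flanked
insertion at transcript offset +221, a 1,198 bp insertion at +297, and
a 9,517 bp deletion spanning the whole gene plus flanks); diploid
short-read samples; long-read alignments whose clipped/split records
mark the variant breakpoints; a block-structured SNP dosage matrix with
high linkage disequilibrium around a causal site; and RT-qPCR Ct tables
in which homozygous-variant samples show no target amplification.

Determinism contract: every generator derives its randomness from the
config seed through a single stage-splitting scheme (`stage_rng`), so a
fixed seed yields bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pysam

from ._seq import BASES, array_to_seq, random_dna, revcomp, seq_to_array
from .alleles import LocusModel, StructuralAllele, apply_allele
from .ld import SNPMatrix
from .pcr import Primer

__all__ = [
    "AlleleSpec",
    "SimulationConfig",
    "SamplePanel",
    "PanelEntry",
    "FastqRead",
    "stage_rng",
    "make_locus",
    "make_alleles",
    "simulate_short_reads",
    "simulate_long_read_alignments",
    "simulate_snp_matrix",
    "simulate_ct_table",
    "simulate_coverage_track",
    "make_diagnostic_primer_panel",
    "make_rtqpcr_primers",
    "accession_panel",
    "all_genotype_pairs",
]

#: Sentinel written to Ct tables when target amplification is undetectable.
UNDETECTED = "UD"


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage.

    All randomness flows from one integer seed; stages are decorrelated
    by folding a CRC of the stage name into the seed sequence.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


@dataclass(frozen=True)
class AlleleSpec:
    """Geometry of one structural allele, relative to the TSS.

    Insertions: ``offset`` means the insert is placed immediately before
    the ``offset``-th+1 transcribed base, i.e. at reference coordinate
    ``tss + offset``. Deletions: ``start_offset``/``end_offset`` are
    added to the TSS to obtain the 1-based inclusive deleted interval
    (offset 0 = the TSS itself, negative = upstream).
    """

    label: str
    kind: str  # "insertion" | "deletion"
    length: int
    offset: int | None = None  # insertions
    start_offset: int | None = None  # deletions
    end_offset: int | None = None
    source: str = "random"  # "random" | "ltr-flanked"
    repeat_length: int = 300

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError(f"allele_specs[{self.label}].length must be > 0")
        if self.kind == "insertion":
            if self.offset is None:
                raise ValueError(f"allele_specs[{self.label}].offset required for insertions")
            if self.source not in ("random", "ltr-flanked"):
                raise ValueError(f"allele_specs[{self.label}].source unknown: {self.source!r}")
            if self.source == "ltr-flanked" and not 0 < 2 * self.repeat_length < self.length:
                raise ValueError(f"allele_specs[{self.label}].repeat_length incompatible with length")
        elif self.kind == "deletion":
            if self.start_offset is None or self.end_offset is None:
                raise ValueError(f"allele_specs[{self.label}] deletion requires start_offset/end_offset")
            if self.end_offset - self.start_offset + 1 != self.length:
                raise ValueError(f"allele_specs[{self.label}].length inconsistent with offsets")
        else:
            raise ValueError(f"allele_specs[{self.label}].kind unknown: {self.kind!r}")


def default_allele_specs() -> tuple[AlleleSpec, ...]:
    """The three published alleles.

    di1: 4,992 bp LTR-style insertion at +221; di2: 1,198 bp insertion
    at +297; diDelta: 9,517 bp deletion spanning the transcript plus
    4,676 bp upstream and 2,970 bp downstream flanks (the published
    deleted interval relative to the published TSS).
    """
    return (
        AlleleSpec("di1", "insertion", 4992, offset=221, source="ltr-flanked", repeat_length=300),
        AlleleSpec("di2", "insertion", 1198, offset=297, source="random"),
        AlleleSpec("diDelta", "deletion", 9517, start_offset=-4676, end_offset=4840),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic locus, with study-condition defaults."""

    seed: int = 0
    locus_length: int = 50_000
    gc_fraction: float = 0.38
    tss_offset: int = 20_000
    transcript_length: int = 1_871
    premirna_offset: int = 478  # bp from the TSS to the precursor start
    premirna_length: int = 119
    allele_specs: tuple[AlleleSpec, ...] = field(default_factory=default_allele_specs)
    short_read_length: int = 150
    error_rate: float = 0.01
    coverage: float = 20.0  # per-haplotype short-read fold coverage
    long_read_n50: int = 20_000
    long_read_coverage: float = 20.0
    long_read_min_length: int = 1_000
    mapq_below_threshold_fraction: float = 0.1
    n_snp_samples: int = 200
    n_snps: int = 80
    ld_block_length: int = 2_000
    snp_flip_rate: float = 0.02
    ct_target_mean: float = 24.0
    ct_reference_mean: float = 20.0
    ct_sd: float = 0.3
    ct_replicates: int = 3

    def validate(self) -> None:
        for name in ("locus_length", "transcript_length", "premirna_length", "short_read_length", "long_read_n50"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 1 <= self.tss_offset <= self.locus_length:
            raise ValueError("tss_offset outside the locus")
        if self.tss_offset + self.transcript_length - 1 > self.locus_length:
            raise ValueError("transcript_length extends past the locus end")
        if self.premirna_offset + self.premirna_length > self.transcript_length:
            raise ValueError("premirna_length: precursor must lie inside the transcript")
        if not 3 <= self.ct_replicates <= 4:
            raise ValueError("ct_replicates must be 3 or 4")
        tss = self.tss_offset
        for spec in self.allele_specs:
            spec.validate()
            if spec.kind == "insertion":
                pos = tss + spec.offset  # type: ignore[operator]
                if not 2 <= pos <= self.locus_length:
                    raise ValueError(f"allele_specs[{spec.label}]: insertion point outside the locus")
            else:
                s = tss + spec.start_offset  # type: ignore[operator]
                e = tss + spec.end_offset  # type: ignore[operator]
                if s <= 1 or e >= self.locus_length:
                    raise ValueError(f"allele_specs[{spec.label}]: deletion overlaps the locus edge")


class FastqRead(NamedTuple):
    """A simulated short read (fixed Phred quality is applied on write)."""

    id: str
    sequence: str


@dataclass(frozen=True)
class PanelEntry:
    genotype: tuple[str, str]  # unordered pair of allele labels ("wt" allowed)
    phenotype: str  # "single" | "double"
    dominant_override: bool = False  # double flower explained by a dominant locus elsewhere


@dataclass
class SamplePanel:
    """Truth panel: sample -> (diploid genotype, flower phenotype).

    Recessive model: phenotype is "double" iff both alleles are non-wt,
    unless ``dominant_override`` marks the sample as carrying a dominant
    double-flower allele at another locus.
    """

    entries: dict[str, PanelEntry]

    def __post_init__(self) -> None:
        for sid, entry in self.entries.items():
            if entry.phenotype not in ("single", "double"):
                raise ValueError(f"{sid}: phenotype must be 'single' or 'double'")
            both_variant = "wt" not in entry.genotype
            expected = "double" if both_variant else "single"
            if entry.phenotype != expected and not entry.dominant_override:
                raise ValueError(
                    f"{sid}: phenotype {entry.phenotype!r} inconsistent with genotype "
                    f"{entry.genotype} under the recessive model (no dominant_override)"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()


def make_locus(config: SimulationConfig) -> LocusModel:
    """Generate the reference locus with its transcript-unit annotation."""
    config.validate()
    rng = stage_rng(config.seed, "locus")
    seq = random_dna(rng, config.locus_length, config.gc_fraction)
    tss = config.tss_offset
    transcript = (tss, tss + config.transcript_length - 1)
    pre_start = tss + config.premirna_offset
    premirna = (pre_start, pre_start + config.premirna_length - 1)
    return LocusModel(sequence=seq, tss=tss, transcript_interval=transcript, premirna_interval=premirna)


def make_alleles(locus: LocusModel, config: SimulationConfig) -> list[StructuralAllele]:
    """Resolve the allele specs against the locus.

    Insertion sequences are random DNA; "ltr-flanked" inserts carry
    identical terminal repeats (``repeat_length`` each) emulating an LTR
    retroelement, as for the ~5 kb di1-like allele.
    """
    config.validate()
    out: list[StructuralAllele] = []
    for spec in config.allele_specs:
        if spec.kind == "insertion":
            pos = locus.tss + spec.offset  # type: ignore[operator]
            rng = stage_rng(config.seed, f"allele:{spec.label}")
            if spec.source == "ltr-flanked":
                repeat = random_dna(rng, spec.repeat_length, config.gc_fraction)
                core = random_dna(rng, spec.length - 2 * spec.repeat_length, config.gc_fraction)
                ins = repeat + core + repeat
            else:
                ins = random_dna(rng, spec.length, config.gc_fraction)
            out.append(StructuralAllele.insertion(spec.label, pos, ins))
        else:
            s = locus.tss + spec.start_offset  # type: ignore[operator]
            e = locus.tss + spec.end_offset  # type: ignore[operator]
            if s <= 1 or e >= len(locus.sequence):
                raise ValueError(f"deletion {spec.label} overlaps the locus edge")
            out.append(StructuralAllele.deletion(spec.label, s, e))
    return out


# ---------------------------------------------------------------------------
# short reads


def _sample_reads_from(hap: str, n: int, read_len: int, error_rate: float,
                       rng: np.random.Generator, prefix: str) -> list[FastqRead]:
    """Vectorised uniform read sampler with i.i.d. substitution errors."""
    arr = seq_to_array(hap)
    L = len(arr)
    starts = rng.integers(0, L - read_len + 1, size=n)
    mat = arr[starts[:, None] + np.arange(read_len)]
    # encode to 0..3, mutate, decode
    code = np.searchsorted(BASES, mat)  # BASES sorted ascii: A<C<G<T
    if error_rate > 0:
        errs = rng.random(mat.shape) < error_rate
        shift = rng.integers(1, 4, size=mat.shape)
        code = np.where(errs, (code + shift) % 4, code)
    mat = BASES[code]
    # reverse-complement a random half
    flip = rng.random(n) < 0.5
    comp = BASES[[3, 2, 1, 0]]  # complement by index
    reads: list[FastqRead] = []
    rc_idx = np.flatnonzero(flip)
    if rc_idx.size:
        sub = np.searchsorted(BASES, mat[rc_idx])
        mat[rc_idx] = comp[sub][:, ::-1]
    for i in range(n):
        reads.append(FastqRead(f"{prefix}:{i}:{starts[i] + 1}", mat[i].tobytes().decode("ascii")))
    return reads


def simulate_short_reads(haplotype_pair: tuple[str, str], config: SimulationConfig,
                         sample_id: str = "sample") -> list[FastqRead]:
    """Simulate diploid short reads at the configured fold coverage.

    Reads are drawn uniformly and independently from both haplotypes;
    the expected read count per haplotype is
    ``coverage * len(haplotype) / read_length`` (Poisson distributed).
    Errors are i.i.d. substitutions at ``error_rate`` per base; half the
    reads are emitted reverse-complemented.
    """
    config.validate()
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    rl = config.short_read_length
    reads: list[FastqRead] = []
    rng = stage_rng(config.seed, f"short-reads:{sample_id}")
    for h, hap in enumerate(haplotype_pair):
        if rl > len(hap):
            raise ValueError(f"read length {rl} exceeds haplotype length {len(hap)}")
        n = int(rng.poisson(config.coverage * len(hap) / rl))
        reads.extend(_sample_reads_from(hap, n, rl, config.error_rate, rng, f"{sample_id}:h{h}"))
    return reads


# ---------------------------------------------------------------------------
# long reads


def _long_read_lengths(rng: np.random.Generator, n: int, n50: int, min_len: int) -> np.ndarray:
    # exponential lengths; N50 of an exponential is ~1.678 x mean
    lengths = rng.exponential(scale=n50 / 1.678, size=n).astype(int)
    return np.clip(lengths, min_len, None)


def sam_header(locus: LocusModel, name: str = "locus") -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": name, "LN": len(locus.sequence)}]}
    )


def _mk_segment(header: pysam.AlignmentHeader, name: str, ref_start0: int, cigar: str,
                seq: str, mapq: int, supplementary: bool = False, sa: str | None = None) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.reference_id = 0
    seg.reference_start = ref_start0
    seg.cigarstring = cigar
    seg.query_sequence = seq
    seg.mapping_quality = mapq
    seg.flag = 2048 if supplementary else 0
    if sa is not None:
        seg.set_tag("SA", sa)
    return seg


def simulate_long_read_alignments(
    allele: StructuralAllele,
    locus: LocusModel,
    config: SimulationConfig,
    deletion_as_split: bool = True,
    sample_id: str = "ont",
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Emit long-read SAM records as an aligner would produce them.

    No alignment is performed: the clip/split geometry is computed
    analytically from the allele map. Reads from wild-type segments are
    full-length matches; reads crossing an insertion are soft-clipped at
    the insertion point (clip length = the read's overhang into the
    insert), with insert-spanning reads emitted as a primary plus a
    linked supplementary record; reads crossing a deletion carry either
    a deletion CIGAR or a split supplementary pair (``deletion_as_split``).
    Mapping qualities are 60 except for a configured fraction drawn
    below 40, mirroring the quality filter applied downstream.
    """
    config.validate()
    hap, _ = apply_allele(locus, allele)
    header = sam_header(locus)
    rng = stage_rng(config.seed, f"long-reads:{sample_id}:{allele.label}")
    L = len(hap)
    mean_len = max(config.long_read_min_length, config.long_read_n50 / 1.678)
    n = int(rng.poisson(config.long_read_coverage * L / mean_len))
    lengths = _long_read_lengths(rng, n, config.long_read_n50, config.long_read_min_length)
    lengths = np.minimum(lengths, L)
    starts = rng.integers(0, L - lengths + 1)
    below = rng.random(n) < config.mapq_below_threshold_fraction
    mapqs = np.where(below, rng.integers(0, 40, size=n), 60)

    records: list[pysam.AlignedSegment] = []
    for i in range(n):
        a0, ln, q = int(starts[i]), int(lengths[i]), int(mapqs[i])
        b0 = a0 + ln
        name = f"{sample_id}:{allele.label}:{i}"
        seq = hap[a0:b0]
        records.extend(_place_long_read(header, name, seq, a0, b0, allele, q, deletion_as_split))
    return header, records


def _place_long_read(header, name, seq, a0, b0, allele: StructuralAllele, mapq: int,
                     deletion_as_split: bool) -> list[pysam.AlignedSegment]:
    ln = b0 - a0
    if allele.kind == "reference":
        return [_mk_segment(header, name, a0, f"{ln}M", seq, mapq)]
    if allele.kind == "insertion":
        p0 = allele.position - 1  # 0-based ref coordinate of first displaced base
        ins = len(allele.inserted_sequence)
        left_end, right_start = p0, p0 + ins  # haplotype coords of the insert
        if b0 <= left_end:
            return [_mk_segment(header, name, a0, f"{ln}M", seq, mapq)]
        if a0 >= right_start:
            return [_mk_segment(header, name, a0 - ins, f"{ln}M", seq, mapq)]
        if a0 >= left_end and b0 <= right_start:
            return []  # fully inside the insert: no reference alignment
        if a0 < left_end and b0 <= right_start:  # enters the insert from the left
            m = left_end - a0
            return [_mk_segment(header, name, a0, f"{m}M{ln - m}S", seq, mapq)]
        if a0 >= left_end and b0 > right_start:  # exits the insert to the right
            m = b0 - right_start
            return [_mk_segment(header, name, p0, f"{ln - m}S{m}M", seq, mapq)]
        # spans the whole insert: primary on the left flank + supplementary on the right
        m1 = left_end - a0
        m2 = b0 - right_start
        cig1, cig2 = f"{m1}M{ln - m1}S", f"{ln - m2}S{m2}M"
        sa1 = f"locus,{p0 + 1},+,{cig2},{mapq},0;"
        sa2 = f"locus,{a0 + 1},+,{cig1},{mapq},0;"
        return [
            _mk_segment(header, name, a0, cig1, seq, mapq, sa=sa1),
            _mk_segment(header, name, p0, cig2, seq, mapq, supplementary=True, sa=sa2),
        ]
    # deletion
    s, e = allele.interval  # type: ignore[misc]
    d = e - s + 1
    pivot = s - 1  # haplotype 0-based coord where the fusion sits
    if b0 <= pivot:
        return [_mk_segment(header, name, a0, f"{ln}M", seq, mapq)]
    if a0 >= pivot:
        return [_mk_segment(header, name, a0 + d, f"{ln}M", seq, mapq)]
    m1 = pivot - a0
    m2 = b0 - pivot
    if not deletion_as_split:
        return [_mk_segment(header, name, a0, f"{m1}M{d}D{m2}M", seq, mapq)]
    cig1, cig2 = f"{m1}M{m2}S", f"{m1}S{m2}M"
    sa1 = f"locus,{e + 1},+,{cig2},{mapq},0;"
    sa2 = f"locus,{a0 + 1},+,{cig1},{mapq},0;"
    return [
        _mk_segment(header, name, a0, cig1, seq, mapq, sa=sa1),
        _mk_segment(header, name, e, cig2, seq, mapq, supplementary=True, sa=sa2),
    ]


# ---------------------------------------------------------------------------
# SNP matrix


def simulate_snp_matrix(config: SimulationConfig, causal_position: int) -> SNPMatrix:
    """Block-structured diploid dosage matrix around a causal site.

    SNP positions are scattered over the locus; SNPs falling in the same
    ``ld_block_length`` window copy a shared latent diploid genotype
    with per-allele flip noise ``snp_flip_rate``, so within-block r² is
    ~(1-2e)^4 while between-block r² is at the 1/n sampling floor. The
    block containing ``causal_position`` is the causal block.
    """
    config.validate()
    if config.n_snps < 10:
        raise ValueError("n_snps must be >= 10")
    if config.n_snp_samples < 10:
        raise ValueError("n_snp_samples must be >= 10")
    rng = stage_rng(config.seed, "snp-matrix")
    positions = np.sort(rng.choice(np.arange(1, config.locus_length + 1), size=config.n_snps, replace=False))
    blocks = (positions - 1) // config.ld_block_length
    n = config.n_snp_samples
    dosages = np.empty((n, config.n_snps), dtype=np.int8)
    for b in np.unique(blocks):
        latent = rng.random((n, 2)) < 0.5  # two latent alleles per sample
        for j in np.flatnonzero(blocks == b):
            flips = rng.random((n, 2)) < config.snp_flip_rate
            dosages[:, j] = (latent ^ flips).sum(axis=1)
    sample_ids = [f"S{i:03d}" for i in range(n)]
    snp_ids = [f"snp{p}" for p in positions]
    return SNPMatrix(sample_ids=sample_ids, snp_ids=snp_ids,
                     positions=positions.astype(int), dosages=dosages.astype(float))


# ---------------------------------------------------------------------------
# Ct tables / coverage


def simulate_ct_table(panel: SamplePanel, config: SimulationConfig):
    """RT-qPCR Ct table for a truth panel.

    Samples with at least one wild-type allele draw numeric target Ct
    values ~ Normal(ct_target_mean, ct_sd); homozygous-variant samples
    get the literal sentinel "UD" in every target replicate (the target
    transcript is absent). The reference gene is unaffected and always
    numeric. Returns a tidy pandas DataFrame (sample, gene, replicate, ct).
    """
    import pandas as pd

    if len(panel) == 0:
        raise ValueError("panel is empty")
    config.validate()
    rng = stage_rng(config.seed, "ct-table")
    rows = []
    for sid, entry in panel.items():
        detectable = "wt" in entry.genotype
        for rep in range(1, config.ct_replicates + 1):
            if detectable:
                ct_t = float(rng.normal(config.ct_target_mean, config.ct_sd))
            else:
                ct_t = UNDETECTED
            ct_r = float(rng.normal(config.ct_reference_mean, config.ct_sd))
            rows.append((sid, "target", rep, ct_t))
            rows.append((sid, "reference", rep, ct_r))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])


def simulate_coverage_track(locus: LocusModel, config: SimulationConfig, depth: float = 20.0) -> np.ndarray:
    """Poisson RNA-seq-style per-base coverage: ``depth`` over the
    transcript, zero elsewhere."""
    rng = stage_rng(config.seed, "coverage")
    cov = np.zeros(len(locus.sequence), dtype=int)
    ts, te = locus.transcript_interval
    cov[ts - 1 : te] = rng.poisson(depth, size=te - ts + 1)
    return cov


# ---------------------------------------------------------------------------
# diagnostic primers (synthetic stand-ins for the published assays)


def make_diagnostic_primer_panel(locus: LocusModel, alleles: list[StructuralAllele],
                                 wt_product: int = 563) -> dict[str, tuple[Primer, Primer]]:
    """Extract a synthetic diagnostic primer panel from the locus.

    Emulates the published assay layout on the synthetic sequence: the
    flagship pair ("F1_R2") brackets both insertion points and yields a
    ``wt_product`` bp amplicon on the wild-type allele (563 bp by
    default, growing by the insert size on insertion alleles and absent
    on the whole-gene deletion); allele-specific pairs anchor one primer
    inside each insert; a deletion-spanning pair amplifies only across
    the deletion fusion; a within-deletion pair serves as the wild-type
    presence control.
    """
    seq = locus.sequence
    tss = locus.tss
    by_label = {a.label: a for a in alleles}
    ins_alleles = [a for a in alleles if a.kind == "insertion"]
    dels = [a for a in alleles if a.kind == "deletion"]

    def fwd(name: str, start1: int, length: int) -> Primer:
        return Primer(name, seq[start1 - 1 : start1 - 1 + length])

    def rev(name: str, end1: int, length: int) -> Primer:
        return Primer(name, revcomp(seq[end1 - length : end1]))

    min_ins = min(a.position for a in ins_alleles) if ins_alleles else tss + 1
    f1_start = min(tss, min_ins - 30)  # 3' end clear of the first insertion point
    f1 = fwd("F1", f1_start, 22)
    r2 = rev("R2", f1_start + wt_product - 1, 25)
    panel: dict[str, tuple[Primer, Primer]] = {"F1_R2": (f1, r2)}

    for a in ins_alleles:
        # reverse primer inside the insert: amplifies only when the insert is present
        inner = revcomp(a.inserted_sequence[180:202])
        panel[f"F1_{a.label}R"] = (f1, Primer(f"{a.label}_Rev", inner))
    for a in dels:
        s, e = a.interval  # type: ignore[misc]
        # spans the deletion: product only on the fused (deleted) haplotype
        panel[f"{a.label}_span"] = (fwd(f"{a.label}_A_For", s - 300, 23), rev(f"{a.label}_D_Rev", e + 300, 23))
        # inside the deletion: wild-type presence control
        panel[f"{a.label}_wt"] = (fwd(f"{a.label}_C_For", s + 200, 23), rev(f"{a.label}_D2_Rev", s + 800, 23))
    return panel


def make_rtqpcr_primers(locus: LocusModel, product: int = 90) -> tuple[Primer, Primer]:
    """Synthetic precursor-specific RT-qPCR pair with a ``product`` bp
    amplicon inside the 119 nt precursor (the published assay amplifies
    a 90 bp region including the mature miRNA)."""
    ps, pe = locus.premirna_interval
    if product > pe - ps + 1:
        raise ValueError("product longer than the precursor")
    start = ps + (pe - ps + 1 - product) // 2
    f = Primer("pre_For", locus.sequence[start - 1 : start - 1 + 24])
    r = Primer("pre_Rev", revcomp(locus.sequence[start + product - 1 - 22 : start + product - 1]))
    return f, r


# ---------------------------------------------------------------------------
# truth panels


def accession_panel() -> SamplePanel:
    """Truth panel mirroring the published accession table: 18 ornamental
    accessions covering wt/wt, hom di1, hom di2, hom diDelta and the
    het wt/di1 case, plus the two double-flower wt/wt accessions
    explained by a dominant allele at another locus."""
    wt = "wt"
    e = PanelEntry
    return SamplePanel({
        "Crimson_Rocket": e((wt, wt), "single"),
        "Hokimomo_op": e(("di1", "di1"), "double"),
        "S7258_IRAN_6_59": e(("di2", "di2"), "double"),
        "G_Biffi_Fiore_Doppio": e(("di2", "di2"), "double"),
        "Taoflora_pink": e(("diDelta", "diDelta"), "double"),
        "Taoflora_white": e(("diDelta", "diDelta"), "double"),
        "KV872615": e(("di1", "di1"), "double"),
        "Compact_Pillar": e(("di1", "di1"), "double"),
        "Helen_Borchers": e(("di2", "di2"), "double"),
        "Peppermint_Stick": e(("di1", "di1"), "double"),
        "Kikoumomo_D": e(("di2", "di2"), "double"),
        "S10321_Hua_5_15": e(("di1", "di1"), "double"),
        "Redleaf_Pillar": e((wt, "di1"), "single"),
        "S10322_Hua_5_25": e(("di1", "di1"), "double"),
        "Okinawa": e(("di1", "di1"), "double"),
        "Klara_Meyer": e(("diDelta", "diDelta"), "double"),
        "KV045590": e((wt, wt), "double", dominant_override=True),
        "KV021779": e((wt, wt), "double", dominant_override=True),
    })


def all_genotype_pairs(labels: Iterable[str] = ("wt", "di1", "di2", "diDelta")) -> list[tuple[str, str]]:
    """All unordered diploid genotype pairs over the allele set."""
    labels = list(labels)
    return [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i, len(labels))]
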