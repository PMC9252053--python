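# Methods

This note documents the models, parameter choices and numerical
conventions behind `petalotype`, and what the synthetic-data validation
does and does not establish about real data.

## Coordinate and reporting conventions

All I/O coordinates are 1-based inclusive; BED output is converted to
0-based half-open at the file boundary only (`petalotype.coords`). Two
length conventions coexist deliberately, matching how such quantities
are conventionally printed: deleted intervals are reported inclusively
(start 25,855,441, end 25,864,957 → 9,517 bp), while an LD candidate
interval is the *distance* between its boundary SNPs
(24,277,038 → 26,628,544 = 2,351,506 bp). Gel-estimate band sizes are
formatted in kb with truncation to one decimal (1,761 → "1.7"), since a
gel reader under-calls rather than rounds; Mb-scale interval lengths
use ordinary rounding (2,351,506 → "2.4").

An insertion's `position` is the first reference base displaced
rightward by the insert — the insert sits immediately before it. For
an insertion at transcript offset +k this is `tss + k`, which is the
same arithmetic used for the published "+297" placement. The two
published absolute coordinates for the +221 insertion differ by 6 bp
between sources; the transcript offset is treated as ground truth.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions. A 50 kb i.i.d. random background (GC 0.38, typical for a
peach intergenic region) carries a single-exon 1,871 bp transcript at
position 20,000 with the 119 nt precursor starting 478 bp downstream of
the TSS. Alleles default to the published geometry: a 4,992 bp insert
with identical 300 bp terminal repeats (emulating the LTR structure of
the di1 element) at +221, a 1,198 bp unstructured insert at +297, and a
9,517 bp deletion spanning 4,676 bp upstream to 2,970 bp downstream of
the transcript.

Short reads are drawn uniformly from both haplotypes with an expected
count of `coverage × haplotype_length / read_length` per haplotype
(Poisson), i.i.d. substitution errors (default 1%) and random strand.
This deliberately omits indel/homopolymer error structure, quality
variation, GC bias and duplicated reads; conclusions about robustness
to those artefacts cannot be drawn from these tests. Long-read
*alignments* are emitted directly (no aligner is run): clip and split
geometry is computed analytically from the allele map — reads ending
inside an insert are soft-clipped at the insertion point with clip
length equal to the overhang, insert-spanning reads become a
primary/supplementary pair linked by SA tags, and deletion-crossing
reads carry either a deletion CIGAR or a split pair (selectable). Read
lengths are exponential with N50 ≈ 1.678 × mean; a configurable
fraction of mapQ values (default 10%) falls below the downstream
filter threshold of 40.

The SNP generator produces dosages 0/1/2: SNPs within the same
`ld_block_length` (default 2 kb) window copy a shared latent diploid
genotype with per-allele flip noise ε, giving expected within-block
r² = (1−2ε)⁴ and between-block r² at the 1/n sampling floor. The
default ε = 0.02 yields within-block r² ≈ 0.85, satisfying the ≥ 0.8
design contract for "high-LD blocks" (at ε = 0.05 the same arithmetic
gives ≈ 0.66, which the tests assert directly). Ct tables give
numeric target values ~ Normal(24, 0.3) to samples with at least one
intact allele and the literal sentinel `UD` to homozygous/compound
variants; the reference gene (Normal(20, 0.3)) is always numeric.
`UD` is never imputed as a cycle number (e.g. Ct 40): undetectable is a
categorical outcome, and imputing it would fabricate expression ratios.

All generators derive randomness from one seed through named-stage
seed sequences, so a fixed seed reproduces bit-identical files.

## Junction genotyping

For each allele, windows of `2 × flank` bp (default flank 50, half a
window on each side of the breakpoint) are built for: the wild-type
breakpoint(s) (one for insertions, both ends for deletions), the two
insertion junctions (reference flank + insert edge) and the deletion
fusion. A read supports a window when some ungapped offset aligns it
with ≥ `min_overlap` (20) *matched* bases on each side of the
breakpoint and an overall mismatch rate ≤ 5% per aligned base; it is
truncated when one flank matches cleanly but the continuation past the
breakpoint (≥ 5 aligned bases) matches below 50%. Classification
priority is variant > wild type > truncated; both read orientations are
tested. Under the substitution-only read model an ungapped scan is
exact, so the engine evaluates every offset via two vectorised
half-window passes; exact 15-mer seeding is used only as a
confirm-only fast path and a panel-level pre-screen (a read sharing no
15-mer with any window is counted uninformative without a full scan —
at 1% error the probability that a true junction read has no clean
shared 15-mer is negligible). The production classifier is tested for
exact agreement with an independent offset-by-offset exhaustive
classifier on 10,000 mixed reads.

Diploid calling: an allele is present when its variant-junction support
reaches `min_support` (3); truncated reads top the count up only when
at least one junction-spanning read corroborates the allele (truncation
alone is ambiguous — it also arises from unrelated inserts — and only
raises the conflicting-evidence flag). Wild type fills remaining slots
when every relevant breakpoint has ≥ `min_support` contiguous coverage
(both breakpoints for a deletion); a homozygous call additionally
requires the alternative's support ≤ `max_contra` (1). Samples below
10× mean locus coverage are no-calls with a low-coverage flag; all
thresholds are exposed in `Thresholds`, since no numeric support rule
is prescribed by the underlying method. Cosegregation checking flags
double-flower samples carrying wild type (unless marked as dominant-
locus carriers) and single-flower samples without wild type.

## Long-read SV calling

Records below mapQ 40 are dropped (inclusive threshold). Soft/hard
clips ≥ `min_clip` (200 bp) mark breakpoints at the alignment's first
or last reference base; same-side endpoints within `cluster_window`
(100 bp) merge at their median. A right-clip cluster at P adjacent to
a left-clip cluster at P+1 is an insertion; its size is the median
unaligned middle of split reads spanning the insert (read length minus
both aligned segments). With no spanning read the longest one-sided
clip only bounds the size from below and the call is flagged
accordingly. Deletions come from deletion CIGAR operations ≥ 50 bp or
split pairs with contiguous read coordinates (gap ≤ 30 bases) and a
reference gap; the call interval is the median gap and size is
end − start + 1. Calls need ≥ 3 supporting reads.

## LD scan

Composite LD — squared Pearson correlation of unphased dosage
vectors — is used because inputs are unphased WGS genotypes and no
phasing step is modelled. Pairs are computed over pairwise-complete
samples (never imputed); entries are NaN for monomorphic SNPs or < 10
shared samples. Candidate-interval delimitation is an explicit stand-in
for a visual judgement: SNPs with r² ≥ `r2_threshold` (0.6) against the
focal SNP are split into runs separated by > `max_gap` (500 kb);
single-SNP runs away from the rest are discarded but distant multi-SNP
blocks are kept, since the empirical pattern is spaced blocks of
long-range LD; the interval spans the outermost retained SNPs. Both
knobs are exposed because no numeric rule defines "high LD".

## Expression and annotation

ΔCt (no calibrator): per replicate, expression = 2^−(Ct_target −
Ct_reference), summarised as mean ± sd. A sample is undetected
(expression 0 + flag) when ≥ half its target replicates are `UD`; a
minority `UD` replicate is dropped. Any `UD` in the reference gene
excludes the sample with a `reference-failure` error — that is assay
failure, not biology. Transcript units are maximal runs of coverage ≥
`min_cov` (5) merging sub-threshold gaps ≤ `max_zero_run` (20 bp); the
locus transcript is intronless, so short gaps are noise, not splicing.

## Alignment-based geometry recovery

`infer_structural_change` anchors the haplotype and reference on their
longest common prefix and suffix and reports the single indel between
them, left-aligned (the standard variant-normalisation convention).
For a clean single indel this is exact in length and exact in position
up to edge ambiguity when the insert boundary repeats the flank; the
tests verify length against the independent unit-cost edit distance and
position by reconstructing the haplotype. A general multi-variant
aligner is out of scope; inputs differing by more than one indel are
rejected explicitly rather than mis-diffed (unit-cost dynamic
programming scatters large indels across degenerate optimal paths, so
a naive CIGAR walk would be unreliable here).

## Problem sizes in tests and the acceptance script

The 50-panel genotyping concordance sweep runs on a 20 kb locus variant
with the full-size alleles (4,992/1,198/9,517 bp) — the junction
neighbourhoods, where all evidence lives, are identical to the 50 kb
default, and 500 diploid calls complete in ~2 minutes. Long-read SV
validation uses the full 50 kb default locus (20 seeds × 10×/20× in the
test suite; 10 seeds in the acceptance script). The classifier-oracle
comparison uses 10,000 reads of 60 bp against flank-30 windows. These
sizes are the package's own choice of a fast, fully-covering test
design.

## Known limitations

* Genotyping is restricted to pre-defined alleles; there is no de novo
  SV discovery from short reads and no insert-sequence assembly.
* The in-silico PCR has no thermodynamic annealing model; defaults are
  exact-match primers and a 10 kb long-range product cap.
* The long-read module consumes alignments; basecalling, alignment and
  repeat annotation of inserts are out of scope.
* Synthetic backgrounds are i.i.d. random sequence: genome-scale
  repeat families, which could create spurious junction matches or
  ambiguous clip clusters, are not represented beyond the insert's own
  terminal repeats.
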