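# petalotype

Structural-allele modelling, junction-read genotyping and molecular
diagnostics for the peach double-flower (*di*) locus — the
miR172d-encoding gene on chromosome 2 whose disruption, in homozygosis,
converts stamens into supernumerary petals.

## The problem

Three independent structural mutations disrupt the single-exon
pri-miR172d transcription unit (1,871 bp, carrying a 119 nt miRNA
precursor):

| allele  | event     | size     | placement                          |
|---------|-----------|----------|------------------------------------|
| di1     | insertion | 4,992 bp | transcript offset +221 (LTR-style, identical terminal repeats) |
| di2     | insertion | 1,198 bp | transcript offset +297             |
| diΔ     | deletion  | 9,517 bp | removes the whole gene plus flanks |

The trait is recessive: any genotype with at least one intact copy is
single-flowered, and pre-miR172d expression is abolished only in
homozygous/compound-variant genotypes. `petalotype` implements, as a
reusable library with a thin CLI, the full computational workflow used
to find and genotype such alleles:

* **synthetic data** — a seeded generator that emulates the locus, its
  alleles, diploid short reads, long-read alignments, block-structured
  SNP LD and RT-qPCR Ct tables, so every method is testable without
  external data;
* **allele model** — haplotype construction with invertible coordinate
  maps, breakpoint junction windows, miR172 target-site scanning, and
  alignment-based recovery of allele geometry;
* **in-silico PCR** — primer-site search and amplicon prediction; the
  diagnostic pair yields 563 bp on wild type, 563 + insert on insertion
  alleles, and nothing on the deletion;
* **junction genotyper** — classifies short reads as wild-type-spanning,
  variant-junction-spanning or truncated at a breakpoint, and calls
  diploid genotypes with explicit read-support thresholds
  (min 10× coverage, ≥3 supporting reads, ≤1 contradicting read);
* **long-read SV caller** — mapQ ≥ 40 filtering, clip-endpoint
  clustering and split-read pairing recover insertion positions and
  sizes and deletion intervals from SAM alignments;
* **LD scan** — composite r² (squared dosage correlation) over unphased
  genotypes, LD decay and thresholded-run candidate-interval
  delimitation;
* **expression / annotation** — ΔCt relative expression
  (2^−(Ct_target − Ct_reference)) with an explicit "UD" sentinel for
  undetectable targets, and coverage-based transcript-unit calling.

## Worked example

```bash
python examples/02_insilico_pcr.py
```

prints the expected gel pattern of the diagnostic primer pair per
genotype:

```
wt/wt              F1/R2 bands: 563
wt/di1             F1/R2 bands: 563, 5555
di1/di1            F1/R2 bands: 5555
di2/di2            F1/R2 bands: 1761
di1/di2            F1/R2 bands: 1761, 5555
diDelta/diDelta    F1/R2 bands: no product
```

The 563 bp band is the intact allele; 1,761 bp (~1.7 kb) and 5,555 bp
(5.5 kb) are the wild-type amplicon lengthened by exactly the 1,198 and
4,992 bp inserts; heterozygotes show both bands; deletion homozygotes
lose both primer sites and amplify nothing. The other examples cover
simulation (`01`), junction genotyping (`03`), long-read SV discovery
(`04`), LD delimitation (`05`), expression/annotation (`06`) and the
end-to-end pipeline with a checksummed manifest (`07`).

The same operations are available as a CLI:

```bash
petalotype simulate --outdir out --seed 1
petalotype longread-sv --sam out/longreads_di1.sam --min-mapq 40
petalotype genotype --reads out/reads/Okinawa.fastq --alleles out/alleles.tsv \
    --inserts out/inserts.fasta --ref out/locus.fasta
```

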