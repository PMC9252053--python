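"""Build the synthetic miR172d locus and its three structural alleles.

The generator reproduces the published geometry: a 50 kb locus with a
single-exon 1,871 bp transcript carrying a 119 nt miRNA precursor, a
4,992 bp LTR-style insertion at transcript offset +221 (di1-like), a
1,198 bp insertion at +297 (di2-like) and a 9,517 bp deletion removing
the whole gene plus flanks (diDelta-like).
"""

from petalotype import SimulationConfig, apply_allele, make_alleles, make_locus

config = SimulationConfig(seed=1)
locus = make_locus(config)
alleles = make_alleles(locus, config)

print(f"locus: {len(locus.sequence):,} bp, GC-rich-neutral random background")
print(f"transcript: {locus.transcript_interval} ({locus.transcript_length:,} bp, intronless)")
print(f"precursor:  {locus.premirna_interval} ({locus.premirna_length} nt)")
for a in alleles:
    hap, _ = apply_allele(locus, a)
    where = a.position if a.kind == "insertion" else a.interval
    print(f"{a.label:8s} {a.kind:9s} at {where}: {a.size:,} bp "
          f"-> haplotype {len(hap):,} bp")

# The haplotype lengths differ from the reference by exactly the
# inserted/deleted sizes; every downstream stage consumes these objects.
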