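"""Predict the diagnostic gel patterns of the published assay layout.

The flagship primer pair brackets both insertion points: the wild-type
allele gives a 563 bp product, each insertion lengthens it by exactly
the insert size (1,761 bp ~ 1.7 kb; 5,555 bp ~ 5.5 kb), and the
whole-gene deletion removes both primer sites, so homozygotes for it
show no amplification at all.
"""

from petalotype import SimulationConfig, StructuralAllele, make_alleles, make_locus
from petalotype.pcr import genotype_gel_pattern
from petalotype.simulate import make_diagnostic_primer_panel

config = SimulationConfig(seed=1)
locus = make_locus(config)
alleles = make_alleles(locus, config)
panel = make_diagnostic_primer_panel(locus, alleles)
allele_map = {a.label: a for a in alleles}
allele_map["wt"] = StructuralAllele.reference()

for genotype in [("wt", "wt"), ("wt", "di1"), ("di1", "di1"),
                 ("di2", "di2"), ("di1", "di2"), ("diDelta", "diDelta")]:
    pattern = genotype_gel_pattern(genotype, panel, allele_map, locus)
    bands = ", ".join(str(b) for b in pattern["F1_R2"]) or "no product"
    print(f"{'/'.join(genotype):18s} F1/R2 bands: {bands}")

# A heterozygote shows both bands (563 + variant); the deletion
# homozygote shows none — the presence/absence patterns that assign
# genotypes on a gel.
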