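"""Junction-read classification and diploid genotype calling."""

import numpy as np
import pytest

from petalotype._seq import random_dna, revcomp, seq_to_array
from petalotype.alleles import junctions
from petalotype.genotyper import (
    Thresholds,
    check_recessive_cosegregation,
    classify_read,
    genotype_panel,
    genotype_sample,
)
from petalotype.simulate import (
    SimulationConfig,
    all_genotype_pairs,
    simulate_short_reads,
)

from _oracles import bruteforce_classify, exhaustive_classify


def _mutate(seq: str, positions, rng) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestClassifyRead:
    def test_exact_wt_window(self, small_junction_sets):
        js = small_junction_sets[0]
        assert classify_read(js.wt_junctions[0], js).category == "wt"

    def test_exact_variant_windows(self, small_junction_sets):
        for js in small_junction_sets:
            for w in js.variant_junctions:
                assert classify_read(w, js).category == "variant"
                assert classify_read(revcomp(w), js).category == "variant"

    def test_flank_plus_insert_read(self, small_locus, small_alleles):
        """A read carrying the reference left flank and the first bases of
        the insert supports the insertion."""
        ins = next(a for a in small_alleles if a.kind == "insertion")
        js = junctions(small_locus, ins, flank=50)
        p = ins.position
        read = small_locus.sequence[p - 41 : p - 1] + ins.inserted_sequence[:40]
        assert classify_read(read, js).category == "variant"

    def test_threshold_boundary_one_side_short(self, small_locus, small_alleles):
        """min_overlap - 1 matched bases on one side of the breakpoint is
        not enough: the read is uninformative, not wild-type support."""
        ins = next(a for a in small_alleles if a.kind == "insertion")
        js = junctions(small_locus, ins, flank=50)
        p = ins.position
        # 60 bases left of the breakpoint, 19 right of it
        read = small_locus.sequence[p - 61 : p + 18]
        cls = classify_read(read, js, min_overlap=20)
        assert cls.category != "wt"

    def test_truncated_read(self, small_locus, small_alleles):
        """Matches the wt flank then runs into the insert: truncated."""
        ins = next(a for a in small_alleles if a.kind == "insertion")
        js = junctions(small_locus, ins, flank=50)
        p = ins.position
        read = small_locus.sequence[p - 41 : p - 1] + ins.inserted_sequence[:15]
        cls = classify_read(read, js)
        assert cls.category in ("truncated", "variant")
        # with a continuation too short to seed the variant junction the
        # read can only be truncated evidence
        short = small_locus.sequence[p - 61 : p - 1] + ins.inserted_sequence[:10]
        assert classify_read(short, js).category == "truncated"

    def test_short_read_uninformative(self, small_junction_sets):
        assert classify_read("ACGTACGTACGTACG", small_junction_sets[0]).category == "uninformative"

    def test_deletion_breakpoint_indices(self, small_locus, small_alleles):
        deletion = next(a for a in small_alleles if a.kind == "deletion")
        js = junctions(small_locus, deletion, flank=50)
        left = classify_read(js.wt_junctions[0], js)
        right = classify_read(js.wt_junctions[1], js)
        assert left.wt_breakpoints == (0,)
        assert right.wt_breakpoints == (1,)

    def test_matches_bruteforce_oracle_sample(self, small_locus, small_alleles, small_junction_sets):
        """Spot check against the pure-python exhaustive classifier (the
        full 10,000-read comparison runs in the acceptance suite)."""
        rng = np.random.default_rng(31)
        reads = _random_read_mix(rng, small_locus, small_alleles, n=300, read_len=80)
        for js in small_junction_sets:
            for read in reads:
                got = classify_read(read, js)
                want = bruteforce_classify(read, js)
                assert got.category == want, (read, js.label)
                # the fast offset-loop oracle agrees with the base-by-base one
                assert exhaustive_classify(read, js) == want


def _random_read_mix(rng, locus, alleles, n, read_len):
    """Reads concentrated around breakpoints (wt and variant haplotypes)
    plus fully random ones, with sprinkled substitution errors."""
    from petalotype.alleles import apply_allele

    haps = [locus.sequence] + [apply_allele(locus, a)[0] for a in alleles]
    hotspots = []
    for a in alleles:
        p = a.position if a.kind == "insertion" else a.interval[0]
        hotspots.append(p)
        if a.kind == "deletion":
            hotspots.append(a.interval[1])
    reads = []
    for _ in range(n):
        kind = rng.random()
        if kind < 0.15:
            reads.append(random_dna(rng, read_len, 0.4))
            continue
        hap = haps[int(rng.integers(len(haps)))]
        if kind < 0.8:
            centre = int(hotspots[int(rng.integers(len(hotspots)))])
            start = int(np.clip(centre - int(rng.integers(read_len)), 0, len(hap) - read_len))
        else:
            start = int(rng.integers(0, len(hap) - read_len))
        read = hap[start : start + read_len]
        n_err = int(rng.poisson(0.01 * read_len))
        if n_err:
            read = _mutate(read, rng.integers(0, read_len, size=n_err), rng)
        if rng.random() < 0.5:
            read = revcomp(read)
        reads.append(read)
    return reads


@pytest.fixture(scope="module")
def reads_for(small_config, small_haplotypes):
    def _make(genotype, seed=0, coverage=None):
        cfg = SimulationConfig(**{**small_config.__dict__, "seed": seed,
                                  **({"coverage": coverage} if coverage else {})})
        pair = (small_haplotypes[genotype[0]], small_haplotypes[genotype[1]])
        return simulate_short_reads(pair, cfg, sample_id="-".join(genotype))

    return _make


class TestGenotypeSample:

    def test_hom_insertion(self, reads_for, small_junction_sets, small_locus):
        call = genotype_sample("s", reads_for(("ins1", "ins1")), small_junction_sets,
                               locus_length=len(small_locus.sequence))
        assert call.genotype == ("ins1", "ins1")
        assert call.evidence["ins1"].supports_variant >= 3
        assert call.evidence["ins1"].supports_wt <= 1

    def test_het_wt_deletion(self, reads_for, small_junction_sets, small_locus):
        call = genotype_sample("s", reads_for(("wt", "del1")), small_junction_sets,
                               locus_length=len(small_locus.sequence))
        assert call.genotype == ("wt", "del1")
        ev = call.evidence["del1"]
        assert ev.supports_variant >= 3
        assert ev.supports_wt >= 3  # both deletion breakpoints covered by the wt haplotype

    def test_compound_het_insertions(self, reads_for, small_junction_sets, small_locus):
        """Two insertion alleles and no wild type: the compound het call."""
        call = genotype_sample("s", reads_for(("ins1", "ins2")), small_junction_sets,
                               locus_length=len(small_locus.sequence))
        assert call.genotype is not None
        assert sorted(call.genotype) == ["ins1", "ins2"]

    def test_low_coverage_no_call(self, reads_for, small_junction_sets, small_locus):
        reads = reads_for(("wt", "wt"), coverage=2.5)
        call = genotype_sample("s", reads, small_junction_sets,
                               locus_length=len(small_locus.sequence))
        assert call.genotype is None
        assert "low-coverage" in call.flags

    def test_all_wt_panel(self, reads_for, small_junction_sets, small_locus):
        samples = [(f"s{i}", reads_for(("wt", "wt"), seed=i)) for i in range(3)]
        calls = genotype_panel(samples, small_junction_sets,
                               locus_length=len(small_locus.sequence))
        for c in calls:
            assert c.genotype == ("wt", "wt")
            assert all(ev.supports_variant == 0 for ev in c.evidence.values())

    def test_duplicate_sample_ids_rejected(self, reads_for, small_junction_sets):
        reads = reads_for(("wt", "wt"))
        with pytest.raises(ValueError, match="duplicate"):
            genotype_panel([("dup", reads), ("dup", reads)], small_junction_sets)

    def test_coverage_monotonicity(self, small_config, small_haplotypes,
                                   small_junction_sets, small_locus):
        """Raising coverage never lowers concordance (10/20/40x)."""
        rates = []
        for cov in (10.0, 20.0, 40.0):
            correct = 0
            pairs = all_genotype_pairs(("wt", "ins1", "ins2", "del1"))
            for seed, g in enumerate(pairs):
                cfg = SimulationConfig(**{**small_config.__dict__, "seed": 100 + seed,
                                          "coverage": cov})
                reads = simulate_short_reads(
                    (small_haplotypes[g[0]], small_haplotypes[g[1]]), cfg,
                    sample_id="-".join(g))
                call = genotype_sample("s", reads, small_junction_sets,
                                       locus_length=len(small_locus.sequence))
                correct += call.genotype is not None and sorted(call.genotype) == sorted(g)
            rates.append(correct / len(pairs))
        assert rates[0] <= rates[1] + 1e-9 <= rates[2] + 1e-9
        assert rates[-1] == 1.0


class TestCosegregation:
    def _call(self, sid, genotype):
        from petalotype.genotyper import GenotypeCall

        return GenotypeCall(sid, genotype, {}, 20.0)

    def test_consistent_panel_with_dominant_override(self):
        calls = [
            self._call("single_wt", ("wt", "wt")),
            self._call("double_hom", ("di1", "di1")),
            self._call("double_dominant", ("wt", "wt")),
        ]
        pheno = {"single_wt": "single", "double_hom": "double", "double_dominant": "double"}
        report = check_recessive_cosegregation(calls, pheno, dominant_carriers={"double_dominant"})
        assert report.n_inconsistent == 0
        assert report.n_consistent == 3

    def test_unexplained_double_flagged(self):
        calls = [self._call("odd", ("wt", "di1"))]
        report = check_recessive_cosegregation(calls, {"odd": "double"})
        assert report.double_with_wt == ("odd",)
        assert report.n_inconsistent == 1

    def test_single_with_hom_variant_flagged(self):
        calls = [self._call("odd", ("di1", "di2"))]
        report = check_recessive_cosegregation(calls, {"odd": "single"})
        assert report.single_with_variant == ("odd",)

    def test_empty_and_nocall(self):
        assert check_recessive_cosegregation([], {}).n_inconsistent == 0
        calls = [self._call("nc", None)]
        report = check_recessive_cosegregation(calls, {"nc": "double"})
        assert report.n_no_call == 1
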