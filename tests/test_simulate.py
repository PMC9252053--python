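"""Synthetic-data generators: determinism, geometry, error models and
the statistical structure the downstream analyses rely on."""

import numpy as np
import pytest

from petalotype._seq import gc_content, revcomp
from petalotype.alleles import apply_allele
from petalotype.expression import UNDETECTED
from petalotype.ld import pairwise_r2
from petalotype.simulate import (
    AlleleSpec,
    PanelEntry,
    SamplePanel,
    SimulationConfig,
    make_alleles,
    make_locus,
    simulate_ct_table,
    simulate_long_read_alignments,
    simulate_short_reads,
    simulate_snp_matrix,
    accession_panel,
)


class TestMakeLocus:
    def test_defaults_match_study_geometry(self):
        locus = make_locus(SimulationConfig(seed=1))
        assert len(locus.sequence) == 50_000
        assert locus.transcript_length == 1_871
        assert locus.premirna_length == 119
        # precursor starts 478 bp downstream of the TSS
        assert locus.premirna_interval[0] - locus.tss == 478

    def test_deterministic(self):
        a = make_locus(SimulationConfig(seed=42))
        b = make_locus(SimulationConfig(seed=42))
        assert a.sequence == b.sequence
        assert a.sequence != make_locus(SimulationConfig(seed=43)).sequence

    def test_gc_within_binomial_bound(self):
        locus = make_locus(SimulationConfig(seed=2, gc_fraction=0.5))
        assert abs(gc_content(locus.sequence) - 0.5) < 0.02

    def test_validation_names_field(self):
        with pytest.raises(ValueError, match="error_rate"):
            make_locus(SimulationConfig(seed=1, error_rate=0.5))
        with pytest.raises(ValueError, match="premirna_length"):
            make_locus(SimulationConfig(seed=1, premirna_length=5_000))


class TestMakeAlleles:
    def test_default_published_sizes(self, full_locus, full_config):
        alleles = make_alleles(full_locus, full_config)
        sizes = {a.label: a.size for a in alleles}
        assert sizes == {"di1": 4_992, "di2": 1_198, "diDelta": 9_517}

    def test_insertion_positions_from_tss_offsets(self, full_locus, full_alleles):
        by_label = {a.label: a for a in full_alleles}
        assert by_label["di1"].position == full_locus.tss + 221
        assert by_label["di2"].position == full_locus.tss + 297

    def test_deletion_contains_transcript(self, full_locus, full_alleles):
        deletion = next(a for a in full_alleles if a.kind == "deletion")
        s, e = deletion.interval
        ts, te = full_locus.transcript_interval
        assert s < ts and te < e

    def test_ltr_terminal_repeats(self, full_alleles):
        di1 = next(a for a in full_alleles if a.label == "di1")
        assert di1.inserted_sequence[:300] == di1.inserted_sequence[-300:]

    def test_zero_length_insertion_rejected(self):
        spec = AlleleSpec("bad", "insertion", 0, offset=100)
        with pytest.raises(ValueError, match="length"):
            SimulationConfig(seed=1, allele_specs=(spec,)).validate()

    def test_edge_deletion_rejected(self):
        spec = AlleleSpec("edge", "deletion", 30_001, start_offset=-25_000, end_offset=5_000)
        with pytest.raises(ValueError, match="edge"):
            SimulationConfig(seed=1, allele_specs=(spec,)).validate()


class TestShortReads:
    def test_read_count_poisson(self):
        """coverage 20, error 0, 10 kb haplotype pair, 100 bp reads ->
        4,000 reads expected, observed within 3 sigma."""
        cfg = SimulationConfig(seed=9, locus_length=10_000, tss_offset=4_000,
                               allele_specs=(), short_read_length=100,
                               coverage=20.0, error_rate=0.0)
        locus = make_locus(cfg)
        reads = simulate_short_reads((locus.sequence, locus.sequence), cfg)
        expected = 2 * 20.0 * 10_000 / 100
        assert abs(len(reads) - expected) < 3 * np.sqrt(expected)

    def test_error_free_reads_are_substrings(self):
        cfg = SimulationConfig(seed=9, locus_length=10_000, tss_offset=4_000,
                               allele_specs=(), coverage=2.0, error_rate=0.0)
        locus = make_locus(cfg)
        reads = simulate_short_reads((locus.sequence, locus.sequence), cfg)
        assert reads
        for r in reads[:200]:
            assert r.sequence in locus.sequence or revcomp(r.sequence) in locus.sequence

    def test_error_rate_calibration(self):
        """1% substitution rate: observed mismatch fraction 0.01 +- 0.003
        over >= 1e5 sampled bases (binomial bound)."""
        cfg = SimulationConfig(seed=10, locus_length=10_000, tss_offset=4_000,
                               allele_specs=(), coverage=10.0, error_rate=0.01,
                               short_read_length=100)
        locus = make_locus(cfg)
        reads = simulate_short_reads((locus.sequence, locus.sequence), cfg)
        mismatches = bases = 0
        for r in reads:
            fwd = r.sequence
            rc = revcomp(fwd)
            # locate the true origin via the read id ({sample}:h{hap}:{i}:{start})
            start = int(r.id.rsplit(":", 1)[1])
            window = locus.sequence[start - 1 : start - 1 + len(fwd)]
            mm = min(sum(a != b for a, b in zip(fwd, window)),
                     sum(a != b for a, b in zip(rc, window)))
            mismatches += mm
            bases += len(fwd)
        assert bases > 1e5
        assert abs(mismatches / bases - 0.01) < 0.003

    def test_deterministic_and_length_guard(self):
        cfg = SimulationConfig(seed=3, locus_length=10_000, tss_offset=4_000,
                               allele_specs=(), coverage=2.0)
        locus = make_locus(cfg)
        r1 = simulate_short_reads((locus.sequence, locus.sequence), cfg, sample_id="s")
        r2 = simulate_short_reads((locus.sequence, locus.sequence), cfg, sample_id="s")
        assert r1 == r2
        with pytest.raises(ValueError, match="read length"):
            simulate_short_reads(("ACGT" * 10, "ACGT" * 10), cfg)


class TestLongReads:
    def test_wt_has_no_clipped_records(self, small_locus, small_config):
        from petalotype.alleles import StructuralAllele

        _, records = simulate_long_read_alignments(
            StructuralAllele.reference(), small_locus, small_config
        )
        assert records
        for rec in records:
            assert all(op not in (4, 5) for op, _ in rec.cigartuples)

    def test_insertion_clip_coordinates(self, small_locus, small_alleles, small_config):
        """Soft clips sit exactly at the insertion point: right clips end
        at position - 1, left clips start at the insertion position."""
        ins = next(a for a in small_alleles if a.kind == "insertion")
        _, records = simulate_long_read_alignments(ins, small_locus, small_config)
        right_clipped = [r for r in records if r.cigartuples[-1][0] == 4]
        left_clipped = [r for r in records if r.cigartuples[0][0] == 4]
        assert right_clipped and left_clipped
        for rec in right_clipped:
            assert rec.reference_end == ins.position - 1
        for rec in left_clipped:
            assert rec.reference_start + 1 == ins.position

    def test_deletion_split_gap_equals_deletion(self, small_locus, small_alleles, small_config):
        deletion = next(a for a in small_alleles if a.kind == "deletion")
        s, e = deletion.interval
        _, records = simulate_long_read_alignments(
            deletion, small_locus, small_config, deletion_as_split=True
        )
        pairs = {}
        for rec in records:
            pairs.setdefault(rec.query_name, []).append(rec)
        split = [sorted(v, key=lambda r: r.reference_start) for v in pairs.values() if len(v) == 2]
        assert split
        for a_seg, b_seg in split:
            gap = b_seg.reference_start - a_seg.reference_end
            assert gap == e - s + 1

    def test_deletion_cigar_mode(self, small_locus, small_alleles, small_config):
        deletion = next(a for a in small_alleles if a.kind == "deletion")
        _, records = simulate_long_read_alignments(
            deletion, small_locus, small_config, deletion_as_split=False
        )
        d_ops = [ln for rec in records for op, ln in rec.cigartuples if op == 2]
        assert d_ops and all(ln == deletion.size for ln in d_ops)

    def test_mapq_fraction_below_threshold(self, small_locus, small_config):
        from petalotype.alleles import StructuralAllele

        cfg = SimulationConfig(**{**small_config.__dict__,
                                  "mapq_below_threshold_fraction": 0.3,
                                  "long_read_coverage": 60.0})
        _, records = simulate_long_read_alignments(StructuralAllele.reference(), small_locus, cfg)
        frac = np.mean([r.mapping_quality < 40 for r in records])
        assert 0.2 < frac < 0.4


class TestSNPMatrix:
    def test_block_structure_r2(self):
        """Within-block r2 reflects the flip noise ((1-2e)^4); between-block
        r2 sits at the 1/n sampling floor."""
        cfg = SimulationConfig(seed=21, n_snp_samples=300, n_snps=60)
        snp = simulate_snp_matrix(cfg, causal_position=20_000)
        r2 = pairwise_r2(snp)
        blocks = (snp.positions - 1) // cfg.ld_block_length
        iu = np.triu_indices(snp.n_snps, k=1)
        same = blocks[iu[0]] == blocks[iu[1]]
        within = np.nanmean(r2[iu][same])
        between = np.nanmean(r2[iu][~same])
        assert within > 0.8
        assert between < 0.05

    def test_five_percent_flip_noise_r2(self):
        """Direct check of the expected within-block r2 at 5% per-allele
        flip noise: (1 - 2*0.05)^4 ~ 0.66 (well above between-block LD
        but below the 0.8 reached at the default noise level)."""
        cfg = SimulationConfig(seed=22, n_snp_samples=400, n_snps=40, snp_flip_rate=0.05)
        snp = simulate_snp_matrix(cfg, causal_position=20_000)
        r2 = pairwise_r2(snp)
        blocks = (snp.positions - 1) // cfg.ld_block_length
        iu = np.triu_indices(snp.n_snps, k=1)
        same = blocks[iu[0]] == blocks[iu[1]]
        assert abs(np.nanmean(r2[iu][same]) - 0.9**4) < 0.08

    def test_independent_snps_background(self):
        """One SNP per block -> all pairs are between-block; mean off-diagonal
        r2 stays at the 1/(n-1) scale."""
        cfg = SimulationConfig(seed=23, n_snp_samples=200, n_snps=30,
                               ld_block_length=1)  # every SNP its own block
        snp = simulate_snp_matrix(cfg, causal_position=20_000)
        r2 = pairwise_r2(snp)
        iu = np.triu_indices(snp.n_snps, k=1)
        assert np.nanmean(r2[iu]) < 0.05

    def test_refuses_tiny_panels(self):
        with pytest.raises(ValueError, match="n_snp_samples"):
            simulate_snp_matrix(SimulationConfig(seed=1, n_snp_samples=5), 100)
        with pytest.raises(ValueError, match="n_snps"):
            simulate_snp_matrix(SimulationConfig(seed=1, n_snps=4), 100)


class TestCtTable:
    def test_homozygous_variant_is_undetected(self):
        panel = SamplePanel({
            "wtwt": PanelEntry(("wt", "wt"), "single"),
            "varvar": PanelEntry(("di1", "di1"), "double"),
        })
        table = simulate_ct_table(panel, SimulationConfig(seed=5))
        target = table[table.gene == "target"]
        assert all(v != UNDETECTED for v in target[target["sample"] == "wtwt"].ct)
        assert all(v == UNDETECTED for v in target[target["sample"] == "varvar"].ct)
        # the reference gene is unaffected, even in variant homozygotes
        ref = table[table.gene == "reference"]
        assert all(isinstance(v, float) for v in ref.ct)

    def test_zero_sd_gives_identical_replicates(self):
        panel = SamplePanel({"s": PanelEntry(("wt", "wt"), "single")})
        table = simulate_ct_table(panel, SimulationConfig(seed=5, ct_sd=0.0))
        assert table[table.gene == "target"].ct.nunique() == 1

    def test_replicate_count(self):
        panel = accession_panel()
        table = simulate_ct_table(panel, SimulationConfig(seed=5, ct_replicates=4))
        counts = table.groupby(["sample", "gene"]).size()
        assert (counts == 4).all()


class TestSamplePanel:
    def test_recessive_model_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SamplePanel({"bad": PanelEntry(("wt", "di1"), "double")})
        # the dominant override legitimises a double-flower wt/wt sample
        SamplePanel({"ok": PanelEntry(("wt", "wt"), "double", dominant_override=True)})

    def test_accession_panel_composition(self):
        panel = accession_panel()
        assert len(panel) == 18
        genotypes = [tuple(sorted(e.genotype)) for _, e in panel.items()]
        assert genotypes.count(("di1", "di1")) == 7
        assert genotypes.count(("di2", "di2")) == 4
        assert genotypes.count(("diDelta", "diDelta")) == 3
        assert genotypes.count(("di1", "wt")) == 1
        overrides = [sid for sid, e in panel.items() if e.dominant_override]
        assert len(overrides) == 2


def test_haplotype_length_bookkeeping(small_locus, small_alleles):
    """|insertion hap| = |locus| + insert; |deletion hap| = |locus| - deleted."""
    for a in small_alleles:
        hap, _ = apply_allele(small_locus, a)
        delta = len(hap) - len(small_locus.sequence)
        assert delta == (a.size if a.kind == "insertion" else -a.size)
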