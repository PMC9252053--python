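"""End-to-end pipeline: simulate the locus, then run every analysis
stage on the simulated data, with a machine-readable run manifest.

Stages run in dependency order (simulate first, then LD scan, junction
genotyping, long-read SV calling, in-silico PCR and expression /
annotation, which are independent of one another). Each output file is
checksummed into the manifest; a rerun with the same config and seed
reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, io
from .alleles import StructuralAllele, junctions
from .expression import call_transcribed_region, delta_ct, expression_frame
from .genotyper import Thresholds, calls_to_frame, check_recessive_cosegregation, genotype_panel
from .ld import candidate_interval, pairwise_r2
from .longread import call_sv, detect_breakpoints, filter_alignments
from .pcr import genotype_gel_pattern
from .simulate import (
    SamplePanel,
    SimulationConfig,
    apply_allele,
    make_alleles,
    make_diagnostic_primer_panel,
    make_locus,
    simulate_coverage_track,
    simulate_ct_table,
    simulate_long_read_alignments,
    simulate_short_reads,
    simulate_snp_matrix,
    accession_panel,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

ALL_STAGES = ("simulate", "ld", "genotype", "longread_sv", "pcr", "expression", "annotate")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Single config object driving a full run.

    ``simulation`` fields mirror :class:`SimulationConfig`; stage
    toggles switch whole stages off (dependents of a disabled stage
    error out by name). Unknown keys are rejected on load.
    """

    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    simulation: dict = field(default_factory=dict)
    junction_flank: int = 50
    thresholds: dict = field(default_factory=dict)
    ld_r2_threshold: float = 0.6
    ld_max_gap: int = 500_000
    pcr_max_len: int = 10_000
    min_cov: int = 5
    max_zero_run: int = 20
    panel: str = "accessions"  # only built-in truth panel for now

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        unknown_stages = set(cfg.stages) - set(ALL_STAGES)
        if unknown_stages:
            raise ValueError(f"unknown stages: {sorted(unknown_stages)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown_sim = set(cfg.simulation) - sim_known
        if unknown_sim:
            raise ValueError(f"unknown simulation keys: {sorted(unknown_sim)}")
        thr_known = {f.name for f in dataclasses.fields(Thresholds)}
        unknown_thr = set(cfg.thresholds) - thr_known
        if unknown_thr:
            raise ValueError(f"unknown threshold keys: {sorted(unknown_thr)}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(io.load_yaml_config(path))

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)

    def thresholds_config(self) -> Thresholds:
        return Thresholds(**self.thresholds)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the enabled stages and return (and write) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    on = {s: bool(config.stages.get(s, False)) for s in ALL_STAGES}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    files: dict[str, dict[str, str]] = {}

    def record(stage: str, *paths: Path) -> None:
        files.setdefault(stage, {})
        for p in paths:
            files[stage][p.name] = _sha256(p)

    sim_cfg = config.simulation_config()
    ctx: dict = {}

    if on["simulate"]:
        locus = make_locus(sim_cfg)
        alleles = make_alleles(locus, sim_cfg)
        panel = accession_panel() if config.panel == "accessions" else None
        if panel is None:
            raise PipelineError(f"unknown panel {config.panel!r}")
        ctx.update(locus=locus, alleles=alleles, panel=panel)

        io.write_fasta({"locus": locus.sequence}, outdir / "locus.fasta")
        io.write_alleles_tsv(alleles, outdir / "alleles.tsv", outdir / "inserts.fasta")
        primer_panel = make_diagnostic_primer_panel(locus, alleles)
        io.write_primers_tsv(primer_panel, outdir / "primers.tsv")
        ctx["primer_panel"] = primer_panel

        haps = {"wt": locus.sequence}
        for a in alleles:
            haps[a.label], _ = apply_allele(locus, a)
        ctx["haplotypes"] = haps

        reads_dir = outdir / "reads"
        reads_dir.mkdir(exist_ok=True)
        sample_reads = []
        for sid, entry in panel.items():
            pair = (haps[entry.genotype[0]], haps[entry.genotype[1]])
            reads = simulate_short_reads(pair, sim_cfg, sample_id=sid)
            io.write_fastq(reads, reads_dir / f"{sid}.fastq")
            sample_reads.append((sid, reads))
        ctx["sample_reads"] = sample_reads

        sam_paths = []
        for a in alleles:
            header, records = simulate_long_read_alignments(a, locus, sim_cfg, sample_id=f"ont_{a.label}")
            p = outdir / f"longreads_{a.label}.sam"
            io.write_sam(header, records, p)
            sam_paths.append(p)
            ctx.setdefault("long_reads", {})[a.label] = records
        snp = simulate_snp_matrix(sim_cfg, causal_position=locus.tss)
        io.write_snp_matrix_tsv(snp, outdir / "snp_matrix.tsv")
        ctx["snp"] = snp
        ct = simulate_ct_table(panel, sim_cfg)
        io.write_ct_table(ct, outdir / "ct_table.tsv")
        ctx["ct"] = ct
        cov = simulate_coverage_track(locus, sim_cfg)
        io.write_bedgraph(cov, outdir / "coverage.bedgraph")
        ctx["coverage"] = cov
        record("simulate", outdir / "locus.fasta", outdir / "alleles.tsv", outdir / "inserts.fasta",
               outdir / "primers.tsv", outdir / "snp_matrix.tsv", outdir / "ct_table.tsv",
               outdir / "coverage.bedgraph", *sam_paths,
               *sorted(reads_dir.glob("*.fastq")))

    def need(stage: str, key: str):
        if key not in ctx:
            raise PipelineError(f"stage {stage!r} requires outputs of stage 'simulate' (disabled or failed)")
        return ctx[key]

    if on["ld"]:
        snp = need("ld", "snp")
        locus = need("ld", "locus")
        r2 = pairwise_r2(snp)
        focal = int(min(range(snp.n_snps), key=lambda j: abs(int(snp.positions[j]) - locus.tss)))
        interval = candidate_interval(r2, snp.positions, snp.snp_ids, focal,
                                      config.ld_r2_threshold, config.ld_max_gap)
        io.write_bed_interval(interval, outdir / "ld_interval.bed", chrom="locus")
        record("ld", outdir / "ld_interval.bed")
        manifest["stages"]["ld"] = {"interval": [interval.start, interval.end],
                                    "n_snps": interval.n_snps}

    if on["genotype"]:
        locus = need("genotype", "locus")
        alleles = need("genotype", "alleles")
        panel = need("genotype", "panel")
        jsets = [junctions(locus, a, config.junction_flank) for a in alleles]
        calls = genotype_panel(need("genotype", "sample_reads"), jsets,
                               config.thresholds_config(), len(locus.sequence))
        frame = calls_to_frame(calls)
        frame.to_csv(outdir / "genotype_calls.tsv", sep="\t", index=False)
        io.write_sv_vcf(alleles, locus, outdir / "genotype_calls.vcf", calls=calls)
        pheno = {sid: e.phenotype for sid, e in panel.items()}
        overrides = {sid for sid, e in panel.items() if e.dominant_override}
        report = check_recessive_cosegregation(calls, pheno, overrides)
        record("genotype", outdir / "genotype_calls.tsv", outdir / "genotype_calls.vcf")
        manifest["stages"]["genotype"] = {
            "n_samples": len(calls),
            "n_no_call": report.n_no_call,
            "n_inconsistent": report.n_inconsistent,
        }

    if on["longread_sv"]:
        locus = need("longread_sv", "locus")
        alleles = need("longread_sv", "alleles")
        sv_rows = []
        for a in alleles:
            records = ctx["long_reads"][a.label]
            kept, _ = filter_alignments(records)
            clusters = detect_breakpoints(kept)
            sv_rows.extend(call_sv(clusters, kept))
        io.write_sv_calls_tsv(sv_rows, outdir / "sv_calls.tsv")
        record("longread_sv", outdir / "sv_calls.tsv")
        manifest["stages"]["longread_sv"] = {"n_calls": len(sv_rows)}

    if on["pcr"]:
        locus = need("pcr", "locus")
        alleles = need("pcr", "alleles")
        panel = need("pcr", "panel")
        primer_panel = need("pcr", "primer_panel")
        allele_map = {a.label: a for a in alleles}
        allele_map["wt"] = StructuralAllele.reference()
        rows = []
        for sid, entry in panel.items():
            pattern = genotype_gel_pattern(entry.genotype, primer_panel, allele_map, locus,
                                           max_len=config.pcr_max_len)
            for pair, bands in pattern.items():
                for band in bands:
                    rows.append((sid, pair, band))
        import pandas as pd

        pd.DataFrame(rows, columns=["sample", "pair", "band_bp"]).to_csv(
            outdir / "pcr_bands.tsv", sep="\t", index=False
        )
        record("pcr", outdir / "pcr_bands.tsv")
        manifest["stages"]["pcr"] = {"n_bands": len(rows)}

    if on["expression"]:
        ct = need("expression", "ct")
        results = delta_ct(ct)
        expression_frame(results).to_csv(outdir / "expression.tsv", sep="\t", index=False)
        record("expression", outdir / "expression.tsv")
        manifest["stages"]["expression"] = {
            "n_undetected": sum(1 for r in results if not r.detected and r.error is None)
        }

    if on["annotate"]:
        locus = need("annotate", "locus")
        cov = need("annotate", "coverage")
        intervals = call_transcribed_region(cov, config.min_cov, config.max_zero_run)
        io.write_gff3(intervals, outdir / "transcripts.gff3", premirna=locus.premirna_interval)
        record("annotate", outdir / "transcripts.gff3")
        manifest["stages"]["annotate"] = {"intervals": intervals}

    manifest["files"] = files
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
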