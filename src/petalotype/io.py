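"""Standard-format I/O shared by all pipeline stages.

FASTA/FASTQ go through Biopython, SAM and VCF through pysam, tabular
formats through pandas. Internal coordinates are 1-based inclusive
everywhere; the BED conversion is centralised in
:mod:`petalotype.coords` and applied only at the file boundary.
Structural alleles are exported both as a TSV + insert-FASTA pair and
as symbolic-ALT VCF records (SVTYPE=INS/DEL with END/SVLEN).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alleles import LocusModel, StructuralAllele
from .coords import one_based_to_bed
from .genotyper import GenotypeCall
from .ld import LDInterval, SNPMatrix
from .longread import SVCall
from .pcr import Primer

__all__ = [
    "write_fasta", "read_fasta",
    "write_fastq", "read_fastq",
    "write_sam", "read_sam",
    "write_alleles_tsv", "read_alleles_tsv",
    "write_sv_vcf", "read_sv_vcf",
    "write_bed_interval", "write_bedgraph", "read_bedgraph",
    "write_gff3",
    "write_snp_matrix_tsv", "read_snp_matrix_tsv",
    "write_ct_table", "read_ct_table",
    "write_primers_tsv", "read_primers_tsv",
    "load_yaml_config", "dump_yaml_config",
]


# --- FASTA / FASTQ ---------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable, path: str | Path, quality: int = 30) -> None:
    """Write (id, sequence) read tuples as FASTQ with a fixed quality."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    qchar = chr(quality + 33)
    with opener(path, "wt") as fh:
        for read in reads:
            rid, seq = read[0], read[1]
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTQ (optionally gzipped) into (id, sequence) tuples.

    A truncated gzip stream raises EOFError rather than yielding a
    silent partial parse.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            data = fh.read()  # force full decompression: truncation -> EOFError
        from io import StringIO

        handle = StringIO(data)
    else:
        handle = open(path)
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            out.append((rec.id, str(rec.seq).upper()))
    finally:
        handle.close()
    return out


# --- SAM -------------------------------------------------------------------


def write_sam(header: pysam.AlignmentHeader, records: Sequence[pysam.AlignedSegment],
              path: str | Path) -> None:
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for rec in records:
            fh.write(rec)


def read_sam(path: str | Path) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        header = fh.header
        records = [rec for rec in fh]
    return header, records


# --- structural alleles ----------------------------------------------------


def write_alleles_tsv(alleles: Sequence[StructuralAllele], tsv_path: str | Path,
                      inserts_fasta: str | Path, chrom: str = "locus") -> None:
    """Allele table (label, kind, chrom, pos/start, end, insert name);
    insertion sequences go to a companion FASTA referenced by name."""
    rows = []
    inserts: dict[str, str] = {}
    for a in alleles:
        if a.kind == "insertion":
            name = f"{a.label}_insert"
            inserts[name] = a.inserted_sequence
            rows.append((a.label, a.kind, chrom, a.position, "", name))
        elif a.kind == "deletion":
            s, e = a.interval  # type: ignore[misc]
            rows.append((a.label, a.kind, chrom, s, e, ""))
        else:
            rows.append((a.label, a.kind, chrom, "", "", ""))
    pd.DataFrame(rows, columns=["label", "kind", "chrom", "pos", "end", "insert"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    write_fasta(inserts, inserts_fasta)


def read_alleles_tsv(tsv_path: str | Path, inserts_fasta: str | Path) -> list[StructuralAllele]:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    inserts = read_fasta(inserts_fasta) if Path(inserts_fasta).exists() else {}
    out: list[StructuralAllele] = []
    for _, row in df.iterrows():
        kind = row["kind"]
        if kind == "insertion":
            out.append(StructuralAllele.insertion(row["label"], int(row["pos"]), inserts[row["insert"]]))
        elif kind == "deletion":
            out.append(StructuralAllele.deletion(row["label"], int(row["pos"]), int(row["end"])))
        else:
            out.append(StructuralAllele.reference(row["label"]))
    return out


# --- VCF -------------------------------------------------------------------


def _sv_vcf_header(locus_length: int, sample_ids: Sequence[str], chrom: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={locus_length}>")
    header.add_line('##ALT=<ID=INS,Description="Insertion">')
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End of the variant">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=RE,Number=1,Type=Integer,Description="Supporting reads">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=VS,Number=1,Type=Integer,Description="Variant junction reads">')
    header.add_line('##FORMAT=<ID=WS,Number=1,Type=Integer,Description="Wild-type junction reads">')
    header.add_line('##FORMAT=<ID=TR,Number=1,Type=Integer,Description="Truncated reads">')
    for sid in sample_ids:
        header.add_sample(sid)
    return header


def _allele_vcf_coords(allele: StructuralAllele) -> tuple[int, int, int, str]:
    """(POS, END, SVLEN, symbolic ALT) for a structural allele; POS is the
    anchor base before the event, per VCF convention."""
    if allele.kind == "insertion":
        pos = allele.position - 1
        return pos, pos, len(allele.inserted_sequence), "<INS>"
    s, e = allele.interval  # type: ignore[misc]
    return s - 1, e, -(e - s + 1), "<DEL>"


def write_sv_vcf(
    alleles: Sequence[StructuralAllele],
    locus: LocusModel,
    path: str | Path,
    calls: Sequence[GenotypeCall] = (),
    support: dict[str, int] | None = None,
    chrom: str = "locus",
) -> None:
    """Symbolic-ALT VCF of the structural alleles, with one sample column
    per genotype call (GT plus evidence counts in FORMAT)."""
    variant_alleles = [a for a in alleles if a.kind != "reference"]
    header = _sv_vcf_header(len(locus.sequence), [c.sample_id for c in calls], chrom)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for a in variant_alleles:
            pos, end, svlen, alt = _allele_vcf_coords(a)
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, stop=end, alleles=(locus.sequence[pos - 1], alt), id=a.label
            )
            rec.info["SVTYPE"] = "INS" if a.kind == "insertion" else "DEL"
            rec.info["SVLEN"] = svlen
            if support and a.label in support:
                rec.info["RE"] = support[a.label]
            for call in calls:
                smp = rec.samples[call.sample_id]
                if call.genotype is None:
                    smp["GT"] = (None, None)
                else:
                    smp["GT"] = tuple(1 if g == a.label else 0 for g in call.genotype)
                ev = call.evidence.get(a.label)
                if ev is not None:
                    smp["VS"] = ev.supports_variant
                    smp["WS"] = ev.supports_wt
                    smp["TR"] = ev.truncated_wt
            vcf.write(rec)


def read_sv_vcf(path: str | Path) -> list[dict]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append(
                {
                    "id": rec.id,
                    "pos": rec.pos,
                    "end": rec.stop,
                    "svtype": rec.info["SVTYPE"],
                    "svlen": rec.info["SVLEN"],
                    "alt": rec.alts[0],
                    "samples": {
                        s: dict(GT=rec.samples[s]["GT"]) for s in rec.samples
                    },
                }
            )
    return out


def write_sv_calls_tsv(calls: Sequence[SVCall], path: str | Path) -> None:
    rows = [
        (c.type, c.position, c.end if c.end is not None else "", c.size,
         c.n_support, c.size_is_lower_bound)
        for c in calls
    ]
    pd.DataFrame(rows, columns=["type", "position", "end", "size", "n_support", "size_lower_bound"]).to_csv(
        path, sep="\t", index=False
    )


# --- BED / bedGraph / GFF3 -------------------------------------------------


def write_bed_interval(interval: LDInterval, path: str | Path, chrom: str = "chr") -> None:
    """Single-row BED (0-based half-open) of a candidate interval."""
    start0, end0 = one_based_to_bed(interval.start, interval.end)
    with open(path, "w") as fh:
        fh.write(f"{chrom}\t{start0}\t{end0}\t{interval.start_snp}-{interval.end_snp}\n")


def write_bedgraph(coverage: np.ndarray, path: str | Path, chrom: str = "locus") -> None:
    cov = np.asarray(coverage)
    with open(path, "w") as fh:
        if len(cov) == 0:
            return
        run_start = 0
        for i in range(1, len(cov) + 1):
            if i == len(cov) or cov[i] != cov[run_start]:
                if cov[run_start] != 0:
                    fh.write(f"{chrom}\t{run_start}\t{i}\t{int(cov[run_start])}\n")
                run_start = i


def read_bedgraph(path: str | Path, length: int, chrom: str | None = None) -> np.ndarray:
    cov = np.zeros(length, dtype=int)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{ln}: malformed bedGraph record")
            cov[int(fields[1]) : int(fields[2])] = int(float(fields[3]))
    return cov


def write_gff3(intervals: Sequence[tuple[int, int]], path: str | Path, chrom: str = "locus",
               premirna: tuple[int, int] | None = None) -> None:
    """Transcript intervals as GFF3 primary_transcript features, with a
    nested precursor feature when its coordinates are known."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (s, e) in enumerate(intervals, 1):
            tid = f"primary_transcript_{i}"
            fh.write(f"{chrom}\t.\tprimary_transcript\t{s}\t{e}\t.\t+\t.\tID={tid}\n")
            if premirna and s <= premirna[0] <= premirna[1] <= e:
                fh.write(
                    f"{chrom}\t.\tmiRNA_primary_transcript\t{premirna[0]}\t{premirna[1]}"
                    f"\t.\t+\t.\tID={tid}.premirna;Parent={tid}\n"
                )


# --- tabular ---------------------------------------------------------------


def write_snp_matrix_tsv(matrix: SNPMatrix, path: str | Path) -> None:
    """Samples x SNPs dosage TSV with a positions header row."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(matrix.snp_ids) + "\n")
        fh.write("#position\t" + "\t".join(str(p) for p in matrix.positions) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            vals = ["NA" if np.isnan(v) else str(int(v)) for v in matrix.dosages[i]]
            fh.write(sid + "\t" + "\t".join(vals) + "\n")


def read_snp_matrix_tsv(path: str | Path) -> SNPMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        pos_line = fh.readline().rstrip("\n").split("\t")
        if header[0] != "sample" or pos_line[0] != "#position":
            raise ValueError(f"{path}: not a SNP matrix TSV (missing header/positions rows)")
        snp_ids = header[1:]
        positions = np.array([int(p) for p in pos_line[1:]])
        sample_ids, rows = [], []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            sample_ids.append(fields[0])
            rows.append([np.nan if v == "NA" else float(v) for v in fields[1:]])
    return SNPMatrix(sample_ids, snp_ids, positions, np.array(rows))


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str, "replicate": int, "ct": str})
    df["ct"] = [v if v == "UD" else float(v) for v in df["ct"]]
    return df


def write_primers_tsv(panel: dict[str, tuple[Primer, Primer]], path: str | Path) -> None:
    rows = []
    for pair_id, (fwd, rev) in panel.items():
        rows.append((fwd.name, fwd.sequence, pair_id, "forward"))
        rows.append((rev.name, rev.sequence, pair_id, "reverse"))
    pd.DataFrame(rows, columns=["name", "sequence", "pair_id", "role"]).to_csv(path, sep="\t", index=False)


def read_primers_tsv(path: str | Path) -> dict[str, tuple[Primer, Primer]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    panel: dict[str, dict[str, Primer]] = {}
    for _, row in df.iterrows():
        panel.setdefault(row["pair_id"], {})[row["role"]] = Primer(row["name"], row["sequence"])
    out = {}
    for pair_id, roles in panel.items():
        if set(roles) != {"forward", "reverse"}:
            raise ValueError(f"primer pair {pair_id!r} incomplete")
        out[pair_id] = (roles["forward"], roles["reverse"])
    return out


# --- config ----------------------------------------------------------------


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return data


def dump_yaml_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
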