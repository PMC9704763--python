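"""Readers and writers for the pipeline's on-disk formats.

Standard formats go through the usual libraries: FASTA via pyfaidx, SAM
via pysam, VCF via pysam's VariantFile.  GFF3 is restricted to CDS
features and read directly (coordinates converted from 1-based inclusive
to 0-based half-open).  The simulator's alignment dialect is a TSV with
columns read_id, sample, chrom, start, end, mq, proper_pair, mate, bases
(bases as "pos:base" pairs joined by commas).

All tables are written tab-delimited with a fixed column order and
floats at six significant digits, so identical runs are byte-identical.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .alleles import ReadAlignment
from .gene_selection import CoverageProfile, GeneModel, StrainVariantSet, Variant

FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_counts(path) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample ids and gene ids in
    the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.insert(0, "gene_id", out.index)
    write_table(out, path)


def read_gff3_genes(path) -> list[GeneModel]:
    """CDS features grouped by parent (or gene_id/ID) into gene models."""
    exons: dict[tuple[str, str, str], list[tuple[int, int]]] = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gid = None
            for field in attrs.split(";"):
                if "=" not in field:
                    continue
                k, v = field.split("=", 1)
                if k in ("Parent", "gene_id", "ID"):
                    gid = v.split(".")[0] if k == "Parent" else v
                    if k == "Parent":
                        break
            if gid is None:
                raise ValueError(f"CDS feature without Parent/ID in {path}")
            exons[(gid, chrom, strand)].append((start - 1, end))
    return [
        GeneModel(gid, chrom, strand, tuple(sorted(ex)))
        for (gid, chrom, strand), ex in sorted(exons.items())
    ]


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span
            fh.write(
                f"{g.chromosome}\t.\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chromosome}\t.\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}.mrna\n"
                )


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    return {name: str(rec[:]) for name, rec in Fasta(str(path)).items()}


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_vcf_strain(path, strain_id: str) -> StrainVariantSet:
    """All records of a (possibly bgzipped) VCF as one strain's variants;
    MQ taken from the INFO field when present."""
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            mq = float(rec.info.get("MQ", 60.0)) if "MQ" in rec.info else 60.0
            for alt in rec.alts or ():
                variants.append(Variant(rec.chrom, rec.pos - 1, rec.ref, alt, mq=mq))
    return StrainVariantSet(strain_id, variants)


def write_vcf(variants: StrainVariantSet, path, contigs: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants.variants, key=lambda v: (v.chromosome, v.position)):
            fh.write(
                f"{v.chromosome}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tMQ={v.mq:g}\n"
            )


def read_depth_tsv(path, strain_id: str) -> CoverageProfile:
    """Precomputed per-exon depth TSV: columns strain, gene_id, exon_index,
    mean_depth, plus one 'genome_median' row per strain (gene_id '.')"""
    df = pd.read_csv(path, sep="\t")
    sub = df[df["strain"] == strain_id]
    if sub.empty:
        raise ValueError(f"strain {strain_id!r} not in {path}")
    med_rows = sub[sub["gene_id"] == "."]
    if med_rows.empty:
        raise ValueError("depth TSV lacks a genome_median row (gene_id '.')")
    median = float(med_rows["mean_depth"].iloc[0])
    means = {
        (str(r.gene_id), int(r.exon_index)): float(r.mean_depth)
        for r in sub[sub["gene_id"] != "."].itertuples()
    }
    return CoverageProfile(strain_id, exon_means=means, genome_median=median)


def read_pileup_tsv(path, strain_id: str):
    """Base-call pileup TSV: columns strain, chrom, pos (0-based), A, C, G, T."""
    df = pd.read_csv(path, sep="\t")
    sub = df[df["strain"] == strain_id]
    out = {}
    for r in sub.itertuples():
        out[(str(r.chrom), int(r.pos))] = {
            b: int(getattr(r, b)) for b in "ACGT" if getattr(r, b) > 0
        }
    return out


# ---------------------------------------------------------------------------
# alignment records: simulator TSV dialect and SAM


def write_alignment_tsv(reads: Iterable[ReadAlignment], path) -> None:
    rows = []
    for r in reads:
        bases = ",".join(f"{p}:{b}" for p, b in sorted(r.bases.items()))
        rows.append(
            {
                "read_id": r.read_id,
                "sample": r.sample,
                "chrom": r.chromosome,
                "start": r.start,
                "end": r.end,
                "mq": r.mq,
                "proper_pair": int(r.proper_pair),
                "mate": r.mate,
                "bases": bases,
            }
        )
    write_table(pd.DataFrame(rows), path)


def read_alignment_tsv(path) -> list[ReadAlignment]:
    df = pd.read_csv(path, sep="\t", dtype={"bases": str}, keep_default_na=False)
    out = []
    for r in df.itertuples():
        bases = {}
        if r.bases:
            for item in str(r.bases).split(","):
                p, b = item.split(":")
                bases[int(p)] = b
        out.append(
            ReadAlignment(
                read_id=str(r.read_id),
                sample=str(r.sample),
                chromosome=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                mq=int(r.mq),
                proper_pair=bool(int(r.proper_pair)),
                mate=int(r.mate),
                bases=bases,
            )
        )
    return out


def read_sam_fragments(path, sample: str, positions: Iterable[tuple[str, int]]) -> list[ReadAlignment]:
    """Extract alignment records from a SAM/BAM file, with base calls at
    the given (chrom, 0-based pos) sites taken from the aligned query
    sequence."""
    import pysam

    wanted = defaultdict(set)
    for chrom, pos in positions:
        wanted[chrom].add(pos)
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            bases = {}
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                if rpos in wanted.get(aln.reference_name, ()):  # 0-based
                    bases[rpos] = aln.query_sequence[qpos]
            out.append(
                ReadAlignment(
                    read_id=aln.query_name,
                    sample=sample,
                    chromosome=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end or aln.reference_start,
                    mq=aln.mapping_quality,
                    proper_pair=aln.is_proper_pair or not aln.is_paired,
                    mate=2 if aln.is_read2 else 1,
                    bases=bases,
                )
            )
    return out


def pileup_from_sam(path, min_bq: int = 30, min_mq: int = 40):
    """Pooled base-call counts per reference position from a SAM/BAM,
    restricted to proper-pair reads at the MQ threshold and base calls at
    quality >= min_bq."""
    import pysam

    counts: dict[tuple[str, int], dict[str, int]] = defaultdict(lambda: defaultdict(int))
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            if aln.mapping_quality < min_mq:
                continue
            if aln.is_paired and not aln.is_proper_pair:
                continue
            quals = aln.query_qualities
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] < min_bq:
                    continue
                counts[(aln.reference_name, rpos)][aln.query_sequence[qpos]] += 1
    return {k: dict(v) for k, v in counts.items()}
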