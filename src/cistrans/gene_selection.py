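"""Selection of putatively intact, single-copy gene sets.

For a pairwise strain comparison, a gene enters the allele-specific
expression analysis only if, in both strains, it (1) shows no copy-number
signal in DNA coverage, (2) has an intact longest ORF after substituting
the strain's variants into the reference, (3) its predicted proteins are
at least 90% identical between the strains, and (4) shows no residual
heterozygosity in pooled RNA-seq base calls (minor allele frequency at
most 0.1 at base quality >= 30).  The filters are conjunctive and
order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "Variant",
    "StrainVariantSet",
    "CoverageProfile",
    "FilterReport",
    "flag_copy_variable",
    "build_strain_cds",
    "orf_intact",
    "rna_het_filter",
    "select_intact_single_copy",
]

FLANK = 12  # bases added beyond the first/last CDS exon before ORF search
COVERAGE_LOW = 0.05  # fraction of genome-wide median
COVERAGE_HIGH = 1.50
IDENTITY_MIN = 0.90
MAF_MAX = 0.1
STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class GeneModel:
    """CDS-exon structure of one gene; exons are 0-based half-open
    genomic intervals sorted by start (convert 1-based inclusive GFF3
    coordinates on input)."""

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        ex = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", ex)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS exons")
        if sum(e - s for s, e in ex) <= 0:
            raise ValueError(f"{self.gene_id}: empty CDS")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class Variant:
    """One substitution or small indel vs the reference (0-based pos)."""

    chromosome: str
    position: int
    ref: str
    alt: str
    mq: float = 60.0

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        return self.position + len(self.ref)


@dataclass
class StrainVariantSet:
    strain_id: str
    variants: list[Variant] = field(default_factory=list)

    def in_interval(self, chrom: str, start: int, end: int) -> list[Variant]:
        return [
            v
            for v in self.variants
            if v.chromosome == chrom and v.position >= start and v.end <= end
        ]


class CoverageProfile:
    """Per-base DNA read depth for one strain plus the genome-wide median
    of non-zero per-base depths.

    Backed either by dense per-chromosome arrays or by precomputed
    per-exon mean depths (``exon_means`` keyed by (gene_id, exon_index)).
    """

    def __init__(
        self,
        strain_id: str,
        depths: Mapping[str, np.ndarray] | None = None,
        exon_means: Mapping[tuple[str, int], float] | None = None,
        genome_median: float | None = None,
    ):
        self.strain_id = strain_id
        self.depths = {c: np.asarray(d, dtype=float) for c, d in (depths or {}).items()}
        self.exon_means = dict(exon_means or {})
        if genome_median is None:
            allv = np.concatenate([d for d in self.depths.values()]) if self.depths else np.array([])
            nz = allv[allv > 0]
            if nz.size == 0:
                raise ValueError("cannot derive genome median: no non-zero depth")
            genome_median = float(np.median(nz))
        if genome_median <= 0:
            raise ValueError("genome_median must be > 0")
        self.genome_median = float(genome_median)

    def exon_mean(self, gene: GeneModel, exon_index: int) -> float:
        key = (gene.gene_id, exon_index)
        if key in self.exon_means:
            return float(self.exon_means[key])
        if gene.chromosome not in self.depths:
            raise KeyError(
                f"chromosome {gene.chromosome!r} absent from coverage profile "
                f"of strain {self.strain_id!r}"
            )
        s, e = gene.exons[exon_index]
        return float(self.depths[gene.chromosome][s:e].mean())


def flag_copy_variable(gene: GeneModel, cov: CoverageProfile) -> bool:
    """True iff any CDS exon's mean depth falls below 5% or above 150% of
    the genome-wide median — a copy-number signal in either direction."""
    lo = COVERAGE_LOW * cov.genome_median
    hi = COVERAGE_HIGH * cov.genome_median
    for i in range(len(gene.exons)):
        d = cov.exon_mean(gene, i)
        if d < lo or d > hi:
            return True
    return False


def _apply_variants(piece: str, start: int, variants: Sequence[Variant]) -> str:
    """Substitute variants into one genomic piece [start, start+len).

    Applied right-to-left so earlier coordinates stay valid; a SNP that
    falls inside an indel's reference span is dropped with a warning."""
    inside = [
        v for v in variants if v.position >= start and v.end <= start + len(piece)
    ]
    indel_spans = [(v.position, v.end) for v in inside if not v.is_snp]
    kept = []
    for v in inside:
        if v.is_snp and any(s <= v.position < e for s, e in indel_spans):
            warnings.warn(
                f"SNP at {v.chromosome}:{v.position} inside an indel span; dropped"
            )
            continue
        kept.append(v)
    seq = piece
    for v in sorted(kept, key=lambda v: v.position, reverse=True):
        off = v.position - start
        if seq[off : off + len(v.ref)].upper() != v.ref.upper():
            raise ValueError(
                f"variant ref mismatch at {v.chromosome}:{v.position}: "
                f"expected {v.ref!r}, reference has {seq[off:off + len(v.ref)]!r}"
            )
        seq = seq[:off] + v.alt + seq[off + len(v.ref):]
    return seq


def build_strain_cds(
    gene: GeneModel, reference: Mapping[str, str], variants: StrainVariantSet
) -> str:
    """Strain-specific CDS with 12 bp flanks, in transcription orientation.

    The reference CDS exons (plus 12 bp beyond the first and last exon)
    are extracted in genomic order, each piece has the strain's variants
    substituted right-to-left, pieces are concatenated, and minus-strand
    genes are reverse-complemented before the ORF search.  Variants that
    straddle a piece boundary are rejected.
    """
    chrom_seq = reference[gene.chromosome]
    chrom_seq = str(chrom_seq)
    lo, hi = gene.span
    pieces: list[tuple[int, int]] = [(max(lo - FLANK, 0), lo)]
    pieces += [(s, e) for s, e in gene.exons]
    pieces.append((hi, min(hi + FLANK, len(chrom_seq))))
    relevant = variants.in_interval(gene.chromosome, pieces[0][0], pieces[-1][1])
    for v in variants.variants:
        if v.chromosome != gene.chromosome:
            continue
        if any(s < v.end and v.position < e for s, e in pieces) and v not in relevant:
            raise ValueError(
                f"variant at {v.chromosome}:{v.position} straddles an exon "
                "or flank boundary"
            )
    parts = []
    for s, e in pieces:
        parts.append(_apply_variants(chrom_seq[s:e], s, relevant))
    seq = "".join(parts).upper()
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _longest_orf(seq: str) -> str | None:
    """Longest ATG..stop open reading frame across the three forward
    frames of an already-oriented sequence; None if no complete ORF."""
    best: str | None = None
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOPS:
                orf = seq[start : i + 3]
                if best is None or len(orf) > len(best):
                    best = orf
                start = None
            i += 3
    return best


def _identity(prot1: str, prot2: str) -> float:
    """Global-alignment identity: identical residues score 1 (mismatch and
    gap 0), divided by the longer sequence's length."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    score = aligner.score(prot1, prot2)
    return float(score) / max(len(prot1), len(prot2))


def orf_intact(seq_p1: str, seq_p2: str) -> tuple[bool, float]:
    """Check ORF integrity of a gene across the two strains.

    Each strain sequence must contain a longest ORF with a start (Met) and
    a stop codon; the two predicted proteins must be >= 90% identical.
    Returns (pass, identity percent); identity 0 when either ORF is absent.
    """
    if not seq_p1 or not seq_p2:
        raise ValueError("empty sequence")
    orfs = [_longest_orf(s) for s in (seq_p1, seq_p2)]
    if any(o is None for o in orfs):
        return False, 0.0
    prots = [str(Seq(o).translate())[:-1] for o in orfs]  # drop trailing '*'
    if any(len(p) == 0 for p in prots):
        return False, 0.0
    ident = _identity(*prots)
    return ident >= IDENTITY_MIN, 100.0 * ident


PileupCounts = Mapping[tuple[str, int], Mapping[str, int]]


def rna_het_filter(gene: GeneModel, pileup: PileupCounts) -> bool:
    """Residual-heterozygosity filter on pooled parental RNA alignments.

    At every covered CDS position the minor allele frequency among base
    calls (already filtered to base quality >= 30 upstream) must be at
    most 0.1; zero-coverage positions are skipped.  The boundary is
    inclusive: MAF exactly 0.1 passes.
    """
    for s, e in gene.exons:
        for pos in range(s, e):
            calls = pileup.get((gene.chromosome, pos))
            if not calls:
                continue
            counts = np.array([c for c in calls.values() if c > 0], dtype=float)
            if counts.size < 2:
                continue
            total = counts.sum()
            maf = (total - counts.max()) / total
            if maf > MAF_MAX + 1e-12:
                return False
    return True


@dataclass
class FilterReport:
    gene_id: str
    copy_variable: dict[str, bool]
    orf_intact: bool
    identity_pct: float
    rna_het_pass: dict[str, bool]

    @property
    def verdict(self) -> bool:
        return (
            not any(self.copy_variable.values())
            and self.orf_intact
            and all(self.rna_het_pass.values())
        )


def select_intact_single_copy(
    genes: Iterable[GeneModel],
    reference: Mapping[str, str],
    variant_sets: Mapping[str, StrainVariantSet],
    coverage: Mapping[str, CoverageProfile],
    rna_pileups: Mapping[str, PileupCounts],
    pair: tuple[str, str],
) -> dict[str, FilterReport]:
    """Run all four filters for a strain pair and report per-gene verdicts.

    A gene passes iff it is single copy in both strains, its longest ORF
    is intact with >= 90% protein identity between strains, and it shows no
    RNA-level heterozygosity in either strain.
    """
    missing = []
    for label, m in (
        ("variant_sets", variant_sets),
        ("coverage", coverage),
        ("rna_pileups", rna_pileups),
    ):
        for s in pair:
            if s not in m:
                missing.append(f"{label}[{s}]")
    if missing:
        raise ValueError(f"missing inputs: {', '.join(missing)}")
    reports: dict[str, FilterReport] = {}
    for gene in genes:
        cv = {s: flag_copy_variable(gene, coverage[s]) for s in pair}
        seqs = {s: build_strain_cds(gene, reference, variant_sets[s]) for s in pair}
        ok, ident = orf_intact(seqs[pair[0]], seqs[pair[1]])
        het = {s: rna_het_filter(gene, rna_pileups[s]) for s in pair}
        reports[gene.gene_id] = FilterReport(
            gene_id=gene.gene_id,
            copy_variable=cv,
            orf_intact=ok,
            identity_pct=ident,
            rna_het_pass=het,
        )
    return reports
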