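"""Parent-of-origin assignment of F1 reads at diagnostic SNPs.

In an F1 heterozygote, a read can be traced to its parental allele only
where the two parental strains carry different fixed bases.  This module
builds the diagnostic SNP set for a strain pair, assigns F1 fragments to
the P1- or P2-derived allele, and quantifies the parental replicates at
the same sites with the same workflow so that parental and F1 allele
counts are commensurate.

Quality contract (matching the alignment filters used throughout the
pipeline): only reads mapped in a proper pair with mapping quality 40
are used, and diagnostic SNPs themselves require variant MQ >= 40.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gene_selection import GeneModel, StrainVariantSet

__all__ = [
    "ReadAlignment",
    "DiagnosticSnp",
    "DiagnosticSnpSet",
    "AlleleCounts",
    "diagnostic_snps",
    "assign_parent_of_origin",
    "matched_parental_counts",
]

MIN_MQ = 40

P1_ALLELE = "P1_allele"
P2_ALLELE = "P2_allele"


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned mate in the pipeline's CIGAR-free dialect: an aligned
    genomic span plus the base calls observed at diagnostic positions."""

    read_id: str
    sample: str
    chromosome: str
    start: int
    end: int
    mq: int
    proper_pair: bool
    mate: int = 1
    bases: Mapping[int, str] = field(default_factory=dict)


@dataclass(frozen=True)
class DiagnosticSnp:
    chromosome: str
    position: int
    p1_base: str
    p2_base: str
    gene_id: str

    def __post_init__(self):
        if self.p1_base == self.p2_base:
            raise ValueError(f"non-diagnostic site at {self.chromosome}:{self.position}")


class DiagnosticSnpSet:
    """Diagnostic SNPs indexed by gene and by genomic position."""

    def __init__(self, snps: Iterable[DiagnosticSnp]):
        self.by_gene: dict[str, list[DiagnosticSnp]] = defaultdict(list)
        self.by_pos: dict[tuple[str, int], DiagnosticSnp] = {}
        for s in snps:
            self.by_gene[s.gene_id].append(s)
            self.by_pos[(s.chromosome, s.position)] = s

    def __len__(self) -> int:
        return len(self.by_pos)

    def genes(self) -> list[str]:
        return sorted(self.by_gene)


def diagnostic_snps(
    genes: Sequence[GeneModel],
    p1_variants: StrainVariantSet,
    p2_variants: StrainVariantSet,
    reference: Mapping[str, str] | None = None,
    min_mq: int = MIN_MQ,
) -> DiagnosticSnpSet:
    """Sites within CDS exons where the two parents carry different bases.

    Each strain's base at a position is its SNP alt allele if one is
    called there (with MQ >= ``min_mq``), otherwise the reference base.
    Indels are ignored.  Sites where either involved call falls below the
    MQ threshold are dropped; sites outside every gene are ignored with a
    warning.
    """
    calls: dict[tuple[str, int], dict[str, tuple[str, float]]] = defaultdict(dict)
    for label, vs in (("P1", p1_variants), ("P2", p2_variants)):
        for v in vs.variants:
            if not v.is_snp:
                continue
            calls[(v.chromosome, v.position)][label] = (v.alt.upper(), v.mq)

    def base_of(chrom: str, pos: int, label: str) -> tuple[str | None, float]:
        if label in calls[(chrom, pos)]:
            return calls[(chrom, pos)][label]
        if reference is not None:
            return str(reference[chrom])[pos].upper(), float("inf")
        return None, float("inf")

    out: list[DiagnosticSnp] = []
    gene_index: list[tuple[str, int, int, str]] = [
        (g.chromosome, s, e, g.gene_id) for g in genes for s, e in g.exons
    ]
    for (chrom, pos) in sorted(calls):
        b1, mq1 = base_of(chrom, pos, "P1")
        b2, mq2 = base_of(chrom, pos, "P2")
        if b1 is None or b2 is None or b1 == b2:
            continue
        if min(mq1, mq2) < min_mq:
            continue
        hits = [gid for (c, s, e, gid) in gene_index if c == chrom and s <= pos < e]
        if not hits:
            warnings.warn(f"diagnostic SNP at {chrom}:{pos} outside any CDS; ignored")
            continue
        for gid in hits:
            out.append(DiagnosticSnp(chrom, pos, b1, b2, gid))
    return DiagnosticSnpSet(out)


@dataclass
class AlleleCounts:
    """Fragment counts per (gene, sample, allele) plus a discarded tally
    per (gene-or-None, sample, reason)."""

    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    discarded: dict[tuple[str | None, str, str], int] = field(default_factory=dict)

    def add(self, gene: str, sample: str, allele: str, n: int = 1) -> None:
        key = (gene, sample, allele)
        self.counts[key] = self.counts.get(key, 0) + n

    def drop(self, gene: str | None, sample: str, reason: str, n: int = 1) -> None:
        key = (gene, sample, reason)
        self.discarded[key] = self.discarded.get(key, 0) + n

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "sample": s, "allele": a, "count": n}
            for (g, s, a), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "sample", "allele", "count"])

    def matrix(self, allele: str) -> pd.DataFrame:
        """Genes x samples matrix for one allele label (missing cells 0)."""
        df = self.to_frame()
        df = df[df["allele"] == allele]
        if df.empty:
            return pd.DataFrame()
        return (
            df.pivot_table(index="gene_id", columns="sample", values="count", fill_value=0)
            .astype(int)
            .rename_axis(index=None, columns=None)
        )


def _mate_votes(
    read: ReadAlignment, snps: DiagnosticSnpSet
) -> dict[str, set[str]]:
    """Per gene, the set of parents supported by this mate's base calls at
    diagnostic sites (a call matching neither parent votes 'neither')."""
    votes: dict[str, set[str]] = defaultdict(set)
    for pos, base in read.bases.items():
        snp = snps.by_pos.get((read.chromosome, pos))
        if snp is None:
            continue
        b = base.upper()
        if b == snp.p1_base:
            votes[snp.gene_id].add("P1")
        elif b == snp.p2_base:
            votes[snp.gene_id].add("P2")
        else:
            votes[snp.gene_id].add("neither")
    return votes


def _overlapping_gene(
    read: ReadAlignment, genes_by_chrom: Mapping[str, list[GeneModel]] | None
) -> str | None:
    if not genes_by_chrom:
        return None
    for g in genes_by_chrom.get(read.chromosome, []):
        lo, hi = g.span
        if read.start < hi and lo < read.end:
            return g.gene_id
    return None


def _group_fragments(
    alignments: Iterable[ReadAlignment],
) -> dict[tuple[str, str], list[ReadAlignment]]:
    frags: dict[tuple[str, str], list[ReadAlignment]] = defaultdict(list)
    for r in alignments:
        frags[(r.sample, r.read_id)].append(r)
    return frags


def _assign(
    alignments: Iterable[ReadAlignment],
    snps: DiagnosticSnpSet,
    allele_of: Mapping[str, str],
    genes: Sequence[GeneModel] | None = None,
    min_mq: int = MIN_MQ,
    require_proper_pair: bool = True,
) -> AlleleCounts:
    genes_by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes or []:
        genes_by_chrom[g.chromosome].append(g)
    out = AlleleCounts()
    for (sample, _rid), mates in sorted(_group_fragments(alignments).items()):
        kept = [
            m
            for m in mates
            if m.mq >= min_mq and (m.proper_pair or not require_proper_pair)
        ]
        fallback_gene = _overlapping_gene(mates[0], genes_by_chrom)
        if not kept:
            out.drop(fallback_gene, sample, "quality")
            continue
        votes: dict[str, set[str]] = defaultdict(set)
        for m in kept:
            for gid, v in _mate_votes(m, snps).items():
                votes[gid] |= v
        if not votes:
            out.drop(fallback_gene, sample, "uninformative")
            continue
        if len(votes) > 1:
            out.drop(None, sample, "multi_gene")
            continue
        gid, support = next(iter(votes.items()))
        if support == {"P1"}:
            parent = "P1"
        elif support == {"P2"}:
            parent = "P2"
        else:
            out.drop(gid, sample, "conflict")
            continue
        allele = allele_of.get(parent)
        if allele is None:
            out.drop(gid, sample, "other_parent")
            continue
        out.add(gid, sample, allele)
    return out


def assign_parent_of_origin(
    f1_alignments: Iterable[ReadAlignment],
    snps: DiagnosticSnpSet,
    genes: Sequence[GeneModel] | None = None,
    min_mq: int = MIN_MQ,
    require_proper_pair: bool = True,
) -> AlleleCounts:
    """Assign each F1 fragment to its parental allele of origin.

    A fragment is assigned to P1 (resp. P2) iff every diagnostic site it
    covers shows the P1 (resp. P2) base; fragments covering no diagnostic
    site, showing conflicting support, failing the proper-pair/MQ filter,
    or informative for more than one gene are discarded, with the reason
    tallied.  The two mates of a pair are evaluated independently and a
    concordant pair counts once.
    """
    allele_of = {"P1": P1_ALLELE, "P2": P2_ALLELE}
    return _assign(f1_alignments, snps, allele_of, genes, min_mq, require_proper_pair)


def matched_parental_counts(
    parental_alignments: Iterable[ReadAlignment],
    snps: DiagnosticSnpSet,
    parent: str,
    genes: Sequence[GeneModel] | None = None,
    min_mq: int = MIN_MQ,
    require_proper_pair: bool = True,
) -> AlleleCounts:
    """Quantify one parent's replicates at the same diagnostic sites with
    the same workflow as the F1 assignment.

    Only fragments overlapping at least one diagnostic site and matching
    that parent's base at every covered site are counted; fragments
    showing the other parent's base (residual heterozygosity or error) are
    discarded.  ``parent`` is "P1" or "P2".
    """
    if parent not in ("P1", "P2"):
        raise ValueError("parent must be 'P1' or 'P2'")
    allele = P1_ALLELE if parent == "P1" else P2_ALLELE
    allele_of = {parent: allele}
    return _assign(parental_alignments, snps, allele_of, genes, min_mq, require_proper_pair)
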