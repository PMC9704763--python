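"""A deterministic 12-gene fixture for the intact/single-copy filters.

Each gene is engineered to pass all filters or to violate exactly one:

=====  ======  ==========================================================
gene   passes  engineered property
=====  ======  ==========================================================
g01    yes     clean single-exon gene
g02    yes     clean two-exon gene (split CDS reassembles)
g03    no      DNA coverage 3% of the genome median in P1 (copy loss)
g04    no      DNA coverage 160% of the genome median in P2 (copy gain)
g05    no      1-bp deletion in P1 shifts the frame; no complete ORF
g06    no      11 of 106 residues substituted in P2 -> 89.6% identity
g07    no      RNA minor allele frequency 0.2 at a CDS site in P1
g08    yes     clean; carries a benign MAF 0.05 RNA site
g09    yes     synonymous SNP in P2; MAF exactly 0.1 site (boundary)
g10    yes     SNP in the 12-bp flank only
g11    no      nonsense SNP in P2 truncates the protein (identity 55%)
g12    yes     clean gene on the minus strand
=====  ======  ==========================================================
"""

from __future__ import annotations

from cistrans.gene_selection import GeneModel, StrainVariantSet, Variant

EXPECTED_SURVIVORS = ["g01", "g02", "g08", "g09", "g10", "g12"]

FLANK = "C" * 12
GAP = "C" * 30
STD_CDS = "ATG" + "AAA" * 10 + "TAA"  # M + 10K + stop
BIG_CDS = "ATG" + "AAA" * 105 + "TAA"  # M + 105K + stop


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def build():
    """Assemble the reference, gene models, per-strain variants, per-exon
    depths and RNA pileups.  Returns a dict of inputs plus the expected
    survivor list."""
    chrom = "chrT"
    seq_parts = [GAP]
    genes: list[GeneModel] = []
    pos = len(GAP)
    p1_vars: list[Variant] = []
    p2_vars: list[Variant] = []
    depth: dict[str, dict[tuple[str, int], float]] = {"P1": {}, "P2": {}}
    pileup: dict[str, dict[tuple[str, int], dict[str, int]]] = {"P1": {}, "P2": {}}

    def add_gene(gid: str, cds: str, strand: str = "+", split: bool = False):
        nonlocal pos, seq_parts
        start = pos + len(FLANK)
        body = cds if strand == "+" else _revcomp(cds)
        if split:
            half = (len(body) // 6) * 3
            intron = "C" * 21
            exons = ((start, start + half), (start + half + len(intron), start + len(body) + len(intron)))
            seq_parts += [FLANK, body[:half], intron, body[half:], FLANK, GAP]
            pos = exons[1][1] + len(FLANK) + len(GAP)
        else:
            exons = ((start, start + len(body)),)
            seq_parts += [FLANK, body, FLANK, GAP]
            pos = start + len(body) + len(FLANK) + len(GAP)
        g = GeneModel(gid, chrom, strand, exons)
        genes.append(g)
        for strain in ("P1", "P2"):
            for i in range(len(exons)):
                depth[strain][(gid, i)] = 100.0
        return g

    g01 = add_gene("g01", STD_CDS)
    g02 = add_gene("g02", STD_CDS, split=True)
    g03 = add_gene("g03", STD_CDS)
    depth["P1"][("g03", 0)] = 3.0  # 3% of median 100
    g04 = add_gene("g04", STD_CDS)
    depth["P2"][("g04", 0)] = 160.0  # 160% of median
    g05 = add_gene("g05", STD_CDS)
    # delete one base of codon 5: ref "AA" -> alt "A" (frameshift in P1)
    del_pos = g05.exons[0][0] + 3 + 4 * 3
    p1_vars.append(Variant(chrom, del_pos, "AA", "A"))
    g06 = add_gene("g06", BIG_CDS)
    # 11 nonsynonymous K->E substitutions in P2: identity 95/106 = 89.6%
    for k in range(11):
        snp = g06.exons[0][0] + 3 + (2 * k) * 3  # first base of codon
        p2_vars.append(Variant(chrom, snp, "A", "G"))
    g07 = add_gene("g07", STD_CDS)
    pileup["P1"][(chrom, g07.exons[0][0] + 6)] = {"A": 80, "G": 20}  # MAF 0.2
    g08 = add_gene("g08", STD_CDS)
    pileup["P1"][(chrom, g08.exons[0][0] + 6)] = {"A": 95, "G": 5}  # MAF 0.05
    g09 = add_gene("g09", STD_CDS)
    # synonymous AAA -> AAG at codon 3, plus a boundary MAF 0.1 site
    p2_vars.append(Variant(chrom, g09.exons[0][0] + 3 + 2 * 3 + 2, "A", "G"))
    pileup["P2"][(chrom, g09.exons[0][0] + 9)] = {"A": 9, "G": 1}
    g10 = add_gene("g10", STD_CDS)
    p2_vars.append(Variant(chrom, g10.exons[0][0] - 5, "C", "T"))  # flank only
    g11 = add_gene("g11", STD_CDS)
    # nonsense AAA -> TAA at codon 6 in P2
    p2_vars.append(Variant(chrom, g11.exons[0][0] + 3 + 5 * 3, "A", "T"))
    add_gene("g12", STD_CDS, strand="-")

    reference = {chrom: "".join(seq_parts)}
    for v in p1_vars + p2_vars:
        ref_here = reference[chrom][v.position : v.position + len(v.ref)]
        assert ref_here == v.ref, f"fixture bug at {v.position}: {ref_here} != {v.ref}"
    return {
        "reference": reference,
        "genes": genes,
        "variants": {
            "P1": StrainVariantSet("P1", p1_vars),
            "P2": StrainVariantSet("P2", p2_vars),
        },
        "depth": depth,
        "pileup": pileup,
        "genome_median": 100.0,
        "expected_survivors": EXPECTED_SURVIVORS,
    }
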