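"""Synthetic parental/F1 expression experiments with known cis/trans truth.

The generator emulates the statistical structure of a two-parent + F1
cross design with 4-5 biological replicates per genotype: per-gene
baseline means on a log scale, allele-linked cis fold changes c_g,
background-linked trans fold changes t_g, negative-binomial count noise
(variance mu + alpha mu^2), per-sample multiplicative depth factors, and
diagnostic-SNP-limited read informativeness.

Expected means before noise, for baseline mu_g and trans dominance
exponent d in [0, 1]:

    P2 total:      mu_g
    P1 total:      mu_g * c_g * t_g
    F1 P1-allele: (mu_g / 2) * c_g * t_g**d
    F1 P2-allele: (mu_g / 2) * t_g**d
    F1 total:      sum of the two alleles

so a pure-cis gene shows the same ratio between parents and between F1
alleles, while a pure-trans gene shows a parental ratio but balanced F1
alleles.  d interpolates the F1 trans environment between the parental
midpoint on the log scale (d = 0.5, additive) and the P1 background
(d = 1, dominant).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_selection import GeneModel, StrainVariantSet, Variant
from .alleles import ReadAlignment, P1_ALLELE, P2_ALLELE

__all__ = ["SimConfig", "simulate_counts", "simulate_read_level", "rng_for", "ReadLevelData"]

TRUE_MODES = ("cis", "trans", "synergism", "antagonism", "compensatory", "conserved")


def rng_for(seed: int, name: str) -> np.random.Generator:
    """One PRNG stream per module/purpose, derived from the master seed by
    a stable name so module outputs do not depend on execution order."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class SimConfig:
    """Parameters of the generative model; defaults encode a five-replicate
    cross with moderate effects and realistic RNA-seq depth variation."""

    n_genes: int = 1000
    n_reps: int = 5
    # log-normal baseline: log mu_g ~ N(meanlog, sdlog), clipped below
    mean_log_expression: tuple[float, float] = (math.log(300.0), 1.0)
    min_mean: float = 10.0
    # NB dispersion trend alpha(mu) = a0 + a1/mu
    dispersion_model: tuple[float, float] = (0.05, 0.0)
    frac_cis: float = 0.25
    frac_trans: float = 0.25
    frac_both: float = 0.20
    frac_null: float = 0.30
    # fraction of "both" genes forced compensatory (t = 1/c)
    both_compensatory_frac: float = 0.0
    # |log2 effect| ~ Uniform(low, high), sign +/- with equal probability
    effect_size_dist: tuple[float, float] = (1.0, 2.0)
    trans_dominance: float = 0.5
    size_factor_range: tuple[float, float] = (0.75, 1.33)
    informative_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "mean_log_expression",
            "dispersion_model",
            "effect_size_dist",
            "size_factor_range",
        ):
            vals = getattr(self, name)
            if not all(math.isfinite(v) for v in vals):
                raise ValueError(f"non-finite value in {name}")
        for name in (
            "frac_cis",
            "frac_trans",
            "frac_both",
            "frac_null",
            "both_compensatory_frac",
            "trans_dominance",
            "informative_fraction",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite value in {name}")
        total = self.frac_cis + self.frac_trans + self.frac_both + self.frac_null
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {total}, not 1")
        if not 0.0 <= self.trans_dominance <= 1.0:
            raise ValueError("trans_dominance must lie in [0, 1]")
        if self.size_factor_range[0] <= 0:
            raise ValueError("size factors must be positive")
        if self.dispersion_model[0] < 0 or self.dispersion_model[1] < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must lie in [0, 1]")


def _true_mode(c: float, t: float) -> str:
    """Deterministic mode implied by the planted effects, mirroring the
    seven-way decision table on expectation values."""
    lc, lt = math.log2(c), math.log2(t)
    has_c, has_t = abs(lc) > 1e-12, abs(lt) > 1e-12
    if not has_c and not has_t:
        return "conserved"
    if has_c and not has_t:
        return "cis"
    if has_t and not has_c:
        return "trans"
    if lc * lt > 0:
        return "synergism"
    if abs(abs(lc) - abs(lt)) <= 1e-9:
        return "compensatory"
    return "antagonism"


def _true_inheritance(c: float, t: float, d: float) -> str:
    """Inheritance implied by expected means: compare F1 = mu t^d (c+1)/2
    against P1 = mu c t, P2 = mu and their midpoint (5% relative slack)."""
    p1, p2 = c * t, 1.0
    f1 = t**d * (c + 1.0) / 2.0
    mid = (p1 + p2) / 2.0

    def eq(a: float, b: float) -> bool:
        return abs(math.log(a / b)) < math.log(1.05)

    if eq(p1, p2):
        if f1 > max(p1, p2) and not eq(f1, max(p1, p2)):
            return "transgressive_up"
        if f1 < min(p1, p2) and not eq(f1, min(p1, p2)):
            return "transgressive_down"
        return "none"
    if f1 > max(p1, p2) and not eq(f1, max(p1, p2)):
        return "transgressive_up"
    if f1 < min(p1, p2) and not eq(f1, min(p1, p2)):
        return "transgressive_down"
    if eq(f1, p1) and not eq(f1, p2) and not eq(f1, mid):
        return "dominant_toward_P1"
    if eq(f1, p2) and not eq(f1, p1) and not eq(f1, mid):
        return "dominant_toward_P2"
    if eq(f1, mid) and not eq(f1, p1) and not eq(f1, p2):
        return "additive"
    return "none"


def _gamma_noise(rng: np.random.Generator, alpha: np.ndarray, shape: tuple) -> np.ndarray:
    """Unit-mean gamma multipliers G with Var(G) = alpha, so that
    Poisson(mean * G) is marginally NB with variance mean + alpha*mean^2.

    One multiplier per gene x sample captures sample-level biological
    variability; it is shared by both alleles of a gene in an F1 sample,
    which is what makes the within-sample allele ratio conditionally
    binomial, as in real replicates."""
    a = np.broadcast_to(np.asarray(alpha, dtype=float)[:, None], shape)
    g = np.ones(shape)
    pos = a > 1e-12
    g[pos] = rng.gamma(shape=1.0 / a[pos], scale=a[pos])
    return g


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray, noise: np.ndarray | None = None
) -> np.ndarray:
    """NB(mean, alpha) with variance mean + alpha*mean^2, via gamma-Poisson
    so alpha -> 0 degrades gracefully to Poisson.  A precomputed gamma
    field ``noise`` shares the biological component between draws."""
    mean = np.asarray(mean, dtype=float)
    if noise is None:
        noise = _gamma_noise(rng, alpha, mean.shape)
    return rng.poisson(mean * noise)


@dataclass
class SimCounts:
    parental: pd.DataFrame  # totals, P1_rep*/P2_rep* columns
    f1_alleles: pd.DataFrame  # F1_rep*_P1_allele / ..._P2_allele columns
    f1_totals: pd.DataFrame  # F1_rep* columns
    truth: pd.DataFrame
    size_factors: pd.Series
    sample_table: pd.DataFrame


def simulate_counts(config: SimConfig) -> SimCounts:
    """Draw a full parental/F1 counts experiment plus its truth table.

    Returns parental totals, F1 allele-resolved counts (binomially thinned
    by the informative fraction, identically for both alleles of a gene),
    F1 totals (the sum of the un-thinned allele draws), the per-gene truth
    (c_g, t_g, true mode, true inheritance), the planted size factors, and
    a sample table.  Deterministic for a fixed config.
    """
    rng = rng_for(config.seed, "simulate_counts")
    n = config.n_genes
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]

    meanlog, sdlog = config.mean_log_expression
    mu = np.exp(rng.normal(meanlog, sdlog, size=n))
    mu = np.maximum(mu, config.min_mean)
    a0, a1 = config.dispersion_model
    alpha = np.maximum(a0 + a1 / mu, 1e-8)

    # effect classes with exact proportions (largest-remainder rounding)
    fracs = [config.frac_cis, config.frac_trans, config.frac_both, config.frac_null]
    counts = [int(math.floor(f * n)) for f in fracs]
    rema = sorted(range(4), key=lambda i: fracs[i] * n - counts[i], reverse=True)
    for i in rema[: n - sum(counts)]:
        counts[i] += 1
    classes = np.repeat(np.arange(4), counts)
    rng.shuffle(classes)

    lo, hi = config.effect_size_dist
    mag = rng.uniform(lo, hi, size=(n, 2))
    sign = rng.choice([-1.0, 1.0], size=(n, 2))
    lc = mag[:, 0] * sign[:, 0]
    lt = mag[:, 1] * sign[:, 1]
    c = np.ones(n)
    t = np.ones(n)
    c[classes == 0] = 2.0 ** lc[classes == 0]
    t[classes == 1] = 2.0 ** lt[classes == 1]
    both = classes == 2
    c[both] = 2.0 ** lc[both]
    t[both] = 2.0 ** lt[both]
    if config.both_compensatory_frac > 0:
        idx = np.flatnonzero(both)
        k = int(round(config.both_compensatory_frac * idx.size))
        comp = idx[:k]
        t[comp] = 1.0 / c[comp]

    d = config.trans_dominance
    mean_p1 = mu * c * t
    mean_p2 = mu.copy()
    mean_f1_a1 = (mu / 2.0) * c * t**d
    mean_f1_a2 = (mu / 2.0) * t**d

    r = config.n_reps
    sf_lo, sf_hi = config.size_factor_range
    samples = (
        [f"P1_rep{i + 1}" for i in range(r)]
        + [f"P2_rep{i + 1}" for i in range(r)]
        + [f"F1_rep{i + 1}" for i in range(r)]
    )
    sf = pd.Series(rng.uniform(sf_lo, sf_hi, size=len(samples)), index=samples)

    def draw(
        mean_vec: np.ndarray, cols: list[str], noise: np.ndarray | None = None
    ) -> pd.DataFrame:
        m = mean_vec[:, None] * sf[cols].to_numpy()[None, :]
        return pd.DataFrame(
            _nb_draw(rng, m, alpha, noise=noise), index=gene_ids, columns=cols
        )

    p1_cols = samples[:r]
    p2_cols = samples[r : 2 * r]
    f1_cols = samples[2 * r :]
    parental = pd.concat(
        [
            draw(mean_p1, p1_cols, _gamma_noise(rng, alpha, (n, r))),
            draw(mean_p2, p2_cols, _gamma_noise(rng, alpha, (n, r))),
        ],
        axis=1,
    )

    # both alleles of a gene in an F1 replicate share that replicate's
    # biological noise; the F1 total is the sum of the allele draws
    f1_noise = _gamma_noise(rng, alpha, (n, r))
    a1_draw = draw(mean_f1_a1, f1_cols, f1_noise)
    a2_draw = draw(mean_f1_a2, f1_cols, f1_noise)
    f1_totals = a1_draw + a2_draw

    # diagnostic-SNP informativeness: identical binomial thinning of both
    # alleles of a gene, so the thinning cancels in the allele ratio
    pinf = np.full(n, config.informative_fraction)
    a1_thin = rng.binomial(a1_draw.to_numpy(), pinf[:, None])
    a2_thin = rng.binomial(a2_draw.to_numpy(), pinf[:, None])
    f1_alleles = pd.concat(
        [
            pd.DataFrame(a1_thin, index=gene_ids, columns=[f"{s}_{P1_ALLELE}" for s in f1_cols]),
            pd.DataFrame(a2_thin, index=gene_ids, columns=[f"{s}_{P2_ALLELE}" for s in f1_cols]),
        ],
        axis=1,
    )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mu": mu,
            "dispersion": alpha,
            "c_g": c,
            "t_g": t,
            "informative_fraction": pinf,
            "true_mode": [_true_mode(ci, ti) for ci, ti in zip(c, t)],
            "true_inheritance": [_true_inheritance(ci, ti, d) for ci, ti in zip(c, t)],
        }
    ).set_index("gene_id", drop=False)
    truth.index.name = None

    sample_table = pd.DataFrame(
        {
            "sample": samples,
            "genotype": ["P1"] * r + ["P2"] * r + ["F1"] * r,
            "size_factor": sf.to_numpy(),
        }
    )
    return SimCounts(parental, f1_alleles, f1_totals, truth, sf, sample_table)


@dataclass
class ReadLevelData:
    genes: list[GeneModel]
    reference: dict[str, str]
    p1_variants: StrainVariantSet
    p2_variants: StrainVariantSet
    f1_reads: list[ReadAlignment]
    parent_reads: dict[str, list[ReadAlignment]]  # "P1"/"P2" -> reads
    planted: pd.DataFrame  # gene x sample x allele planted informative counts


GENE_LEN = 240
GENE_GAP = 60
BASES = "ACGT"


def simulate_read_level(
    config: SimConfig,
    sim: SimCounts,
    n_snps_per_gene: int = 2,
    frac_fail_mq: float = 0.05,
    frac_fail_pair: float = 0.05,
    frac_uninformative: float = 0.05,
) -> ReadLevelData:
    """Materialize a counts simulation as gene models, parental variant
    sets, and alignment records.

    Every allele-resolved F1 count (and matched parental count) becomes
    that many informative single-fragment alignments whose base calls at
    the planted diagnostic SNPs identify the allele, so downstream
    assignment recovers the counts exactly.  Extra fragments exercising
    the quality filters are appended: low-MQ, non-proper-pair, and
    SNP-free (uninformative) reads, in the given proportions of each
    gene-sample informative total.
    """
    if n_snps_per_gene < 1:
        raise ValueError("each testable gene needs at least one planted SNP")
    rng = rng_for(config.seed, "simulate_read_level")
    n = config.n_genes
    gene_ids = list(sim.truth["gene_id"])

    chrom = "chr1"
    ref_len = n * (GENE_LEN + GENE_GAP) + GENE_GAP
    ref = rng.choice(list(BASES), size=ref_len)
    genes: list[GeneModel] = []
    p1_vars: list[Variant] = []
    p2_vars: list[Variant] = []
    snp_pos: dict[str, list[int]] = {}
    for i, gid in enumerate(gene_ids):
        start = GENE_GAP + i * (GENE_LEN + GENE_GAP)
        half = GENE_LEN // 2
        exons = ((start, start + half), (start + half + 10, start + GENE_LEN + 10))
        genes.append(GeneModel(gid, chrom, "+", exons))
        pos_choices = rng.choice(np.arange(start + 5, start + half - 5), size=n_snps_per_gene, replace=False)
        positions = sorted(int(p) for p in pos_choices)
        snp_pos[gid] = positions
        for pos in positions:
            refb = ref[pos]
            alt1, alt2 = rng.choice([b for b in BASES if b != refb], size=2, replace=False)
            p1_vars.append(Variant(chrom, pos, refb, alt1, mq=60.0))
            # P2 carries the reference base at half the sites, an alt at the rest
            if rng.random() < 0.5:
                p2_vars.append(Variant(chrom, pos, refb, alt2, mq=60.0))

    p1_set = StrainVariantSet("P1", p1_vars)
    p2_set = StrainVariantSet("P2", p2_vars)
    p1_alt = {v.position: v.alt for v in p1_vars}
    p2_alt = {v.position: v.alt for v in p2_vars}
    gene_by_id = {g.gene_id: g for g in genes}

    def allele_base(gid: str, pos: int, parent: str) -> str:
        if parent == "P1":
            return p1_alt[pos]
        return p2_alt.get(pos, ref[pos])

    def make_reads(
        sample: str, gid: str, parent: str, count: int, tag: str
    ) -> list[ReadAlignment]:
        g = gene_by_id[gid]
        lo, hi = g.span
        positions = snp_pos[gid]
        reads = []
        for k in range(count):
            bases = {p: allele_base(gid, p, parent) for p in positions}
            reads.append(
                ReadAlignment(
                    read_id=f"{gid}_{sample}_{tag}_{k}",
                    sample=sample,
                    chromosome=chrom,
                    start=lo,
                    end=positions[-1] + 30,
                    mq=40,
                    proper_pair=True,
                    bases=bases,
                )
            )
        return reads

    f1_reads: list[ReadAlignment] = []
    parent_reads: dict[str, list[ReadAlignment]] = {"P1": [], "P2": []}
    planted_rows = []

    f1_samples = [s for s in sim.sample_table["sample"] if s.startswith("F1")]
    for gid in gene_ids:
        for s in f1_samples:
            for parent, allele in (("P1", P1_ALLELE), ("P2", P2_ALLELE)):
                cnt = int(sim.f1_alleles.loc[gid, f"{s}_{allele}"])
                f1_reads += make_reads(s, gid, parent, cnt, allele)
                planted_rows.append(
                    {"gene_id": gid, "sample": s, "allele": allele, "count": cnt}
                )
            n_inf = int(sim.f1_alleles.loc[gid, [f"{s}_{P1_ALLELE}", f"{s}_{P2_ALLELE}"]].sum())
            for frac, tag in (
                (frac_fail_mq, "lowmq"),
                (frac_fail_pair, "nopair"),
                (frac_uninformative, "nosnp"),
            ):
                extra = int(round(frac * n_inf))
                for k in range(extra):
                    g = gene_by_id[gid]
                    lo, hi = g.span
                    if tag == "nosnp":
                        r = ReadAlignment(
                            f"{gid}_{s}_{tag}_{k}", s, chrom, hi - 20, hi, 40, True, bases={}
                        )
                    else:
                        parent = "P1" if rng.random() < 0.5 else "P2"
                        bases = {p: allele_base(gid, p, parent) for p in snp_pos[gid]}
                        r = ReadAlignment(
                            f"{gid}_{s}_{tag}_{k}",
                            s,
                            chrom,
                            lo,
                            snp_pos[gid][-1] + 30,
                            20 if tag == "lowmq" else 40,
                            tag != "nopair",
                            bases=bases,
                        )
                    f1_reads.append(r)

    # matched parental reads: thin parental totals by the informative
    # fraction, as only SNP-overlapping fragments are commensurate
    pinf = sim.truth["informative_fraction"]
    for parent in ("P1", "P2"):
        cols = [s for s in sim.sample_table["sample"] if s.startswith(parent)]
        for gid in gene_ids:
            for s in cols:
                tot = int(sim.parental.loc[gid, s])
                cnt = int(rng.binomial(tot, float(pinf.loc[gid])))
                parent_reads[parent] += make_reads(s, gid, parent, cnt, "par")
                planted_rows.append(
                    {"gene_id": gid, "sample": s, "allele": f"{parent}_allele", "count": cnt}
                )

    planted = pd.DataFrame(planted_rows, columns=["gene_id", "sample", "allele", "count"])
    reference = {chrom: "".join(ref)}
    return ReadLevelData(genes, reference, p1_set, p2_set, f1_reads, parent_reads, planted)
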