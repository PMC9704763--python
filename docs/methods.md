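# Methods

## The generative model behind the simulator

Each synthetic experiment draws, per gene g, a baseline mean
μ_g ~ LogNormal(meanlog, sdlog) (clipped below at `min_mean`), a cis
fold change c_g linked to the P1-derived allele, and a trans fold
change t_g linked to the P1 genetic background.  Expected means before
noise are

| quantity | mean |
|---|---|
| P2 total | μ_g |
| P1 total | μ_g · c_g · t_g |
| F1 P1-allele | (μ_g/2) · c_g · t_g^d |
| F1 P2-allele | (μ_g/2) · t_g^d |
| F1 total | sum of the two alleles |

so a pure-cis gene shows the same ratio between parents and between F1
alleles, while a pure-trans gene shows a parental ratio with balanced
F1 alleles — the identities the three-test design exploits.  The
exponent d ∈ [0, 1] models the F1 trans environment, for which the
parental measurements carry no information: d = 0.5 makes the F1 the
log-scale midpoint of the parental trans environments, d = 1 lets the
P1 environment dominate completely.  The default is d = 0.5; the
trans-dominance analysis varies it explicitly.

Counts are gamma-Poisson: one unit-mean gamma multiplier G_{g,s} with
Var(G) = α_g per gene and sample, then Poisson(mean · size_factor · G).
Marginally every count is exactly NB with Var = μ + α μ².  The
multiplier is *shared by the two alleles of a gene in an F1 sample*,
because biological replicate variability is sample-level and affects
both alleles jointly; this makes the within-sample allele ratio
conditionally binomial, as it is in real ASE data, and it makes the F1
total (the sum of the allele draws) exactly NB as well.  Diagnostic-SNP
informativeness is a per-gene binomial thinning applied identically to
both alleles, so it cancels from the allele ratio and leaves the ASE
estimand unbiased.

Effect classes are drawn with exact mixture proportions
(largest-remainder rounding): cis-only (t = 1), trans-only (c = 1),
both, or null (c = t = 1); |log2 effects| are uniform on a configurable
interval (default [1, 2]) with random signs.  "Both" genes split
roughly evenly into same-sign (synergistic) and opposite-sign
(antagonistic) combinations; exactly compensatory genes (t = 1/c) have
measure zero under the continuous draw and are planted only via
`both_compensatory_frac`.  The implied true mode is a deterministic
function of (c, t) mirroring the seven-way decision table; the implied
true inheritance compares the expected F1 mean against the parents and
their arithmetic midpoint with 5% relative slack.

What the simulator does **not** model: sequencing error, splice
isoforms, mapping bias, indel-bearing reads, GC effects, or
gene–gene correlation beyond the shared per-sample noise.  Passing
tests therefore demonstrate that the statistical pipeline recovers the
planted structure under its own distributional assumptions — not that
those assumptions hold for any particular organism's data.

The read-level generator materializes a counts simulation as gene
models (two CDS exons per gene on one synthetic chromosome), planted
exonic SNPs distinguishing the parents (P1 always carries a non-
reference base; P2 carries the reference or a second alternative), and
one alignment record per informative fragment, plus configurable
fractions of fragments that fail the MQ-40 or proper-pair filters or
cover no diagnostic SNP.  Round-trip recovery is exact by construction
and is asserted exactly in the tests.

## The DE engine

Size factors are DESeq-style medians of ratios to a per-gene
geometric-mean reference over genes positive in every sample, centred
to geometric mean 1 (a "poscounts"-style fallback exists for matrices
with no all-positive gene).  Dispersions are method-of-moments
estimates on normalized counts, α̂ = max(0, (s² − μ̄)/μ̄²) with the
variance pooled within groups, shrunk halfway (weight 0.5, floor 1e-8)
toward a least-squares trend α(μ) = a₁/μ + a₀.  The weight balances
per-gene signal against the trend's stability at n = 5; the all-null
calibration test pins the resulting type-I behavior.

The two-group fit solves the NB score equation for a common mean per
group with per-sample size factors as offsets by vectorized Newton
iteration; with equal size factors it reduces to the normalized mean.
Wald statistics use the observed Fisher information and a standard
normal reference — the NB-GLM convention — which the calibration
experiment (2000 all-null genes, five replicates per group, α = 0.05)
places at a raw p < 0.05 fraction of 0.05–0.065 across seeds.  A group
with all-zero counts is reported with a 0.5 pseudo-total so the fold
change stays finite, and its standard error comes from the information
at that floor.

Log2 fold changes are shrunk with a normal prior N(0, τ²), τ²
estimated by marginal likelihood across the tested genes, posterior
mean lfc · τ²/(τ² + se²).  Shrinkage preserves sign, never increases
magnitude, and vanishes as se → 0.  BH adjustment is the standard
step-up with running-minimum enforcement; NaN inputs propagate and do
not count toward the family size.

## The Fisher ratio test and its variance-inflation correction

The trans test compares the F1 allele ratio with the SNP-matched
parental ratio on a 2×2 table of normalized counts summed across
replicates, each cell weighted by (max replicates)/(its replicates)
when replicate numbers differ, rounded half-even.

On raw summed cells the exact test sees only counting noise.  With
five replicates and dispersion α, replicate-level biological
variability contributes ~sqrt(2α/5) ≈ 0.14 (α = 0.05) to the parental
log-ratio — an order of magnitude above the hypergeometric standard
error for well-expressed genes — and the test rejects 35–50% of truly
conserved genes.  Each row of the table is therefore deflated by its
common design-effect factor 1 + α·m, where m is the row's mean
per-replicate count and α the per-gene dispersion from the DE fits
(the two contrasts' estimates averaged): under NB noise a cell of
weighted sum S has relative variance (1 + α·m)/S rather than 1/S, so
the deflated cell is the count whose Poisson noise matches the data's
actual noise.  The factor is shared within a row, leaving the tested
ratios untouched, and with α = 0 the table reduces exactly to the
plain summed table.  With the correction, null genes are called
conserved at 92–97% while cis/trans recall stays at 99–100% in the
recovery experiment.

## Mode classification

Genes below a base-mean floor of 20 in either DE contrast, or missing
any of the three tests, are `not_assessed`.  The significance triple
at adjusted p < 0.1 maps through the seven-way table; for the
all-significant row the sign comparison of cis_lfc and trans_lfc
(shrunken estimates; trans = parental − cis exactly) separates
synergism from antagonism, and an exactly-zero component falls to
`ambiguous` because its direction is undefined.

## Inheritance classification

The four contrasts run under one joint normalization and one pooled
dispersion fit.  The midpoint contrast builds pseudo-replicates by
pairing parental replicates (cycling the shorter genotype), averaging
their normalized counts gene-wise, and testing F1 (normalized, unit
size factors) against them.  Averaging two replicates halves the NB
variance at a given mean, so the pseudo-group's dispersion is
moment-matched as α_mid = α/2 − 1/(2μ), floored at 1e-8; without this
the midpoint contrast is far too conservative and complete dominance
is nearly undetectable.  The arithmetic midpoint (P1+P2)/2 is used,
matching Stone's H; a log-scale midpoint is a one-line switch in
`inheritance_contrasts` if ever wanted.

Transgressive calls (F1 significantly beyond both parents in the same
direction) take precedence and do not require parental divergence; the
other strict categories require the parental contrast to pass all
three criteria (adjusted p < 0.01, |log2FC| > 0.5, base mean > 15).
H is computed from DE-normalized genotype means, guarded by
ε = 1e-8 × the mean expression scale; |H| ≥ 1 with no strict category
yields no partial category, as it falls outside both open intervals.

## Downstream summaries

Mode × inheritance association uses Pearson chi-square without
continuity correction on 2×2 in/out tables per combination (12
combinations; BH across them; a `--yates` flag exists because the
historical default of the usual R test function applies the correction
to 2×2 tables).  Expected cells below 1 are flagged low-count.
Extreme tails take the lower/upper floor(n · 0.05) order statistics of
the significant cis and trans log2FC distributions per comparison —
genes with combined control contribute to both distributions
independently — and union gene sets across comparisons; distributions
smaller than 1/tail_frac are used whole with a warning.  Term
enrichment is the one-sided hypergeometric upper tail with BH across
terms; reported terms need adjusted p < 0.05 and an overlap of at
least two genes.

## Problem sizes and determinism

The bundled analyses use 2000 genes × 15 samples for the recovery and
calibration experiments, 1000 genes for each trans-dominance arm, 20
genes for the read-level round trip and 300 genes for the determinism
check; these sizes put Monte-Carlo error well inside the asserted
margins while keeping every script and the full test suite quick on a
single core.  One PRNG stream per module is derived from the master
seed by a stable name (CRC32), so module outputs do not depend on
execution order, and tables are written tab-delimited with fixed
column order and six-significant-digit floats, making identical
config + seed runs byte-identical.

## Known limitations

* Antagonistic genes with near-cancelling effects have small parental
  fold changes and are intrinsically hard to separate from
  compensatory control; the recovery experiment shows ~47% antagonism
  recall with most misses called compensatory — a power limit of the
  design, not a defect of the decision table.
* The Wald test with plug-in trend-shrunken dispersions is mildly
  liberal (~0.06 at nominal 0.05) at five replicates; the BH layer and
  the decision table absorb this in practice.
* The gene filters assume SNPs and small indels only; structural
  variants and annotation errors are out of scope.
* Parent-of-origin assignment discards fragments informative for two
  overlapping genes; in dense genomes this loses a small amount of
  signal in exchange for the uniqueness guarantee.
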