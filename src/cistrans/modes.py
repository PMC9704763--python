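"""Seven-way cis/trans regulatory-mode classification.

Three tests feed the decision table, all at BH-adjusted p < 0.1:

* parents  — differential expression between the parental strains on
  total counts (combined cis + trans signal);
* ase      — differential expression between the F1's parent-of-origin
  read sets (pure cis signal);
* ratio    — Fisher's exact test comparing the F1 allele ratio with the
  SNP-matched parental ratio (a difference indicates trans).

The trans contribution to a gene's fold change is approximated as
parental log2FC minus the ASE (cis) log2FC.  Positive log2FC means
upregulation in parent one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "fisher_two_sided",
    "ratio_test",
    "decompose_effects",
    "classify_mode",
    "classify_modes",
    "MODES",
]

MODES = (
    "cis",
    "trans",
    "synergism",
    "antagonism",
    "compensatory",
    "conserved",
    "ambiguous",
    "not_assessed",
)

PADJ_CUTOFF = 0.1
BASE_MEAN_FLOOR = 20.0


def fisher_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative ints."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative cell in contingency table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def ratio_test(
    f1_p1: pd.DataFrame,
    f1_p2: pd.DataFrame,
    par_p1: pd.DataFrame,
    par_p2: pd.DataFrame,
    size_factors: pd.Series,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Fisher ratio test of F1 allele balance against the matched parental
    balance.

    Inputs are genes x replicates matrices of SNP-matched counts for the
    four cells (F1 P1-allele, F1 P2-allele, parental P1, parental P2) and
    size factors for every column involved.  Normalized counts are summed
    across replicates per cell; when replicate numbers differ, each cell's
    sum is scaled by (max replicates)/(its replicates) so cells are
    commensurate; cells are rounded half-even before the exact test.

    When per-gene NB ``dispersion`` estimates are supplied, each row of
    the table (F1 alleles; parental strains) is deflated by its common
    variance-inflation factor 1 + alpha*m, with m the row's mean
    per-replicate count: under NB noise the relative variance of a cell
    is (1 + alpha*m)/S rather than the 1/S the exact test assumes, and
    without the correction replicate-level biological variability
    masquerades as allele-ratio signal for well-expressed genes.  The
    factor is shared within a row, so row ratios — the quantity under
    test — are untouched.  With alpha = 0 the table is the literal
    summed table.

    Returns a per-gene frame with the table cells, p_raw and p_adj.
    """
    mats = {"f1_p1": f1_p1, "f1_p2": f1_p2, "par_p1": par_p1, "par_p2": par_p2}
    genes = f1_p1.index
    reps = {k: m.shape[1] for k, m in mats.items()}
    max_rep = max(reps.values())
    if dispersion is None:
        alpha = np.zeros(len(genes))
    else:
        alpha = dispersion.reindex(genes).fillna(0.0).to_numpy(dtype=float)
    totals, means = {}, {}
    for k, m in mats.items():
        if not m.index.equals(genes):
            m = m.reindex(genes, fill_value=0)
        sf = size_factors.loc[m.columns].to_numpy()
        norm = m.to_numpy(dtype=float) / sf[None, :]
        totals[k] = norm.sum(axis=1) * (max_rep / reps[k])
        means[k] = norm.mean(axis=1)
    sums = {}
    for row in (("f1_p1", "f1_p2"), ("par_p1", "par_p2")):
        phi = 1.0 + alpha * 0.5 * (means[row[0]] + means[row[1]])
        for k in row:
            cell = np.round(totals[k] / phi)  # numpy rounds half-even
            if (cell < 0).any():
                raise ValueError("negative cell after normalization")
            sums[k] = cell.astype(int)

    p = np.ones(len(genes))
    for i in range(len(genes)):
        table = [
            [sums["f1_p1"][i], sums["f1_p2"][i]],
            [sums["par_p1"][i], sums["par_p2"][i]],
        ]
        p[i] = fisher_two_sided(np.array(table))
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "f1_p1": sums["f1_p1"],
            "f1_p2": sums["f1_p2"],
            "par_p1": sums["par_p1"],
            "par_p2": sums["par_p2"],
            "p_raw": p,
            "p_adj": bh_adjust(p),
        }
    ).set_index("gene_id", drop=False)
    out.index.name = None
    return out


def decompose_effects(parental_lfc: float, cis_lfc: float) -> float:
    """trans log2FC = parental log2FC - cis (ASE) log2FC."""
    return parental_lfc - cis_lfc


def classify_mode(
    sig_parents: bool,
    sig_ase: bool,
    sig_ratio: bool,
    cis_lfc: float,
    trans_lfc: float,
) -> str:
    """Map a significance triple (parents, ASE, ratio) to a regulatory mode.

    (T,T,F) cis; (T,F,T) trans; (T,T,T) synergism or antagonism by whether
    cis and trans point the same way (an exactly-zero component makes the
    direction undefined -> ambiguous); (F,T,T) compensatory; (F,F,F)
    conserved; the three remaining single-significance patterns are
    ambiguous.
    """
    key = (bool(sig_parents), bool(sig_ase), bool(sig_ratio))
    if key == (True, True, False):
        return "cis"
    if key == (True, False, True):
        return "trans"
    if key == (True, True, True):
        s1, s2 = np.sign(cis_lfc), np.sign(trans_lfc)
        if s1 == 0 or s2 == 0:
            return "ambiguous"
        return "synergism" if s1 == s2 else "antagonism"
    if key == (False, True, True):
        return "compensatory"
    if key == (False, False, False):
        return "conserved"
    return "ambiguous"


def classify_modes(
    parents_de: pd.DataFrame,
    ase_de: pd.DataFrame,
    ratio: pd.DataFrame,
    padj_cutoff: float = PADJ_CUTOFF,
    base_mean_floor: float = BASE_MEAN_FLOOR,
) -> pd.DataFrame:
    """Per-gene mode assignment from the three test result frames.

    A gene is ``not_assessed`` when any of the three tests is missing for
    it or when either DE contrast's base mean falls below the expression
    floor (default 20).  ``trans_lfc`` is the parental minus the cis
    (ASE) shrunken log2FC, so cis + trans = parental exactly.
    """
    genes = parents_de.index.union(ase_de.index).union(ratio.index)
    rows = []
    for g in genes:
        have = g in parents_de.index and g in ase_de.index and g in ratio.index
        if have:
            pr = parents_de.loc[g]
            ar = ase_de.loc[g]
            rr = ratio.loc[g]
            tested = (
                bool(pr["tested"])
                and bool(ar["tested"])
                and pr["base_mean"] >= base_mean_floor
                and ar["base_mean"] >= base_mean_floor
            )
        else:
            tested = False
        if not tested:
            rows.append(
                {
                    "gene_id": g,
                    "mode": "not_assessed",
                    "parental_lfc": np.nan,
                    "cis_lfc": np.nan,
                    "trans_lfc": np.nan,
                    "sig_parents": False,
                    "sig_ase": False,
                    "sig_ratio": False,
                    "p_adj_parents": np.nan,
                    "p_adj_ase": np.nan,
                    "p_adj_ratio": np.nan,
                }
            )
            continue
        parental_lfc = float(pr["log2fc_shrunk"])
        cis_lfc = float(ar["log2fc_shrunk"])
        trans_lfc = decompose_effects(parental_lfc, cis_lfc)
        sig_p = bool(pr["p_adj"] < padj_cutoff)
        sig_a = bool(ar["p_adj"] < padj_cutoff)
        sig_r = bool(rr["p_adj"] < padj_cutoff)
        rows.append(
            {
                "gene_id": g,
                "mode": classify_mode(sig_p, sig_a, sig_r, cis_lfc, trans_lfc),
                "parental_lfc": parental_lfc,
                "cis_lfc": cis_lfc,
                "trans_lfc": trans_lfc,
                "sig_parents": sig_p,
                "sig_ase": sig_a,
                "sig_ratio": sig_r,
                "p_adj_parents": float(pr["p_adj"]),
                "p_adj_ase": float(ar["p_adj"]),
                "p_adj_ratio": float(rr["p_adj"]),
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id", drop=False)
    out.index.name = None
    return out
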