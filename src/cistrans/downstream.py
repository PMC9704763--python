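"""Downstream association and enrichment summaries.

* mode x inheritance association: per (regulatory mode, inheritance
  category) combination, a 2x2 Pearson chi-square test of independence
  over genes pooled across comparisons, BH-corrected;
* extreme tails: upper/lower 5% of the significant cis and trans log2FC
  distributions, unioned across comparisons;
* term enrichment: one-sided hypergeometric test of a selected gene set
  against a background, BH-corrected, reporting terms supported by at
  least two genes.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "mode_inheritance_association",
    "extreme_tails",
    "term_enrichment",
    "load_term_map",
]

ASSOC_MODES = ("cis", "trans", "synergism", "antagonism")
ASSOC_INHERITANCE = ("additive", "dominant", "transgressive")


def _collapse_inheritance(cat: str) -> str | None:
    if cat == "additive":
        return "additive"
    if cat.startswith("dominant"):
        return "dominant"
    if cat.startswith("transgressive"):
        return "transgressive"
    return None


def mode_inheritance_association(
    assignments: pd.DataFrame, yates: bool = False
) -> pd.DataFrame:
    """Chi-square tests of independence between regulatory mode and
    inheritance category.

    ``assignments`` needs columns ``mode`` and ``inheritance`` (one row
    per gene x comparison, already pooled).  Only genes with a mode in
    {cis, trans, synergism, antagonism} and an inheritance in {additive,
    dominant, transgressive} (directions collapsed) enter.  For each of
    the 12 combinations a 2x2 table (in-mode vs not x in-inheritance vs
    not) is tested with Pearson's chi-square, without continuity
    correction by default; BH across the combinations; the direction is
    the sign of observed minus expected in the in/in cell.  Combinations
    with any expected cell below 1 are flagged low-count.
    """
    df = assignments.copy()
    df["inh"] = df["inheritance"].map(_collapse_inheritance)
    df = df[df["mode"].isin(ASSOC_MODES) & df["inh"].notna()]
    rows = []
    for m in ASSOC_MODES:
        for h in ASSOC_INHERITANCE:
            a = int(((df["mode"] == m) & (df["inh"] == h)).sum())
            b = int(((df["mode"] == m) & (df["inh"] != h)).sum())
            c = int(((df["mode"] != m) & (df["inh"] == h)).sum())
            d = int(((df["mode"] != m) & (df["inh"] != h)).sum())
            table = np.array([[a, b], [c, d]])
            n = table.sum()
            if n == 0 or table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                chi2, p, expected = np.nan, np.nan, np.full((2, 2), np.nan)
            else:
                chi2, p, _, expected = stats.chi2_contingency(table, correction=yates)
            rows.append(
                {
                    "mode": m,
                    "inheritance": h,
                    "n_in_in": a,
                    "chi2": chi2,
                    "p_raw": p,
                    "direction": int(np.sign(a - expected[0, 0])) if np.isfinite(p) else 0,
                    "low_count": bool(np.isfinite(p) and (expected < 1).any()),
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def extreme_tails(
    mode_tables: Mapping[str, pd.DataFrame], tail_frac: float = 0.05
) -> dict[str, set[str]]:
    """Extreme-tail gene sets of the significant cis and trans effects.

    ``mode_tables`` maps comparison name -> mode-assignment frame.  Per
    comparison, the cis distribution collects ``cis_lfc`` of genes whose
    cis component is significant (modes cis, synergism, antagonism,
    compensatory) and the trans distribution collects ``trans_lfc`` of
    genes with a significant trans component (trans, synergism,
    antagonism, compensatory) — a gene controlled by both contributes to
    both distributions independently.  The upper and lower ``tail_frac``
    of each distribution are taken per comparison and unioned across
    comparisons.  Distributions with fewer than 1/tail_frac entries are
    used whole, with a warning.

    Returns sets keyed cis_up, cis_down, trans_up, trans_down.
    """
    cis_modes = {"cis", "synergism", "antagonism", "compensatory"}
    trans_modes = {"trans", "synergism", "antagonism", "compensatory"}
    out: dict[str, set[str]] = {k: set() for k in ("cis_up", "cis_down", "trans_up", "trans_down")}
    for comp, table in mode_tables.items():
        if "gene_id" not in table.columns:
            table = table.reset_index(names="gene_id")
        for effect, member_modes, col in (
            ("cis", cis_modes, "cis_lfc"),
            ("trans", trans_modes, "trans_lfc"),
        ):
            sub = table[table["mode"].isin(member_modes)][["gene_id", col]].dropna()
            n = len(sub)
            if n == 0:
                continue
            k = int(np.floor(n * tail_frac))
            if k < 1:
                warnings.warn(
                    f"{comp}/{effect}: {n} values < 1/tail_frac; using whole distribution"
                )
                up = down = set(sub["gene_id"])
            else:
                ordered = sub.sort_values(col, kind="mergesort")
                down = set(ordered["gene_id"].iloc[:k])
                up = set(ordered["gene_id"].iloc[-k:])
            out[f"{effect}_up"] |= up
            out[f"{effect}_down"] |= down
    return out


def load_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> term -> member gene set;
    empty terms cannot arise and duplicate rows collapse."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"], comment="#")
    out: dict[str, set[str]] = {}
    for term, grp in df.groupby("term_id"):
        out[str(term)] = set(grp["gene_id"].astype(str))
    return out


def term_enrichment(
    selected: set[str],
    background: set[str],
    terms: Mapping[str, set[str]],
    padj_cutoff: float = 0.05,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``selected`` within
    ``background``.

    For a term with K members in the background and an overlap of k with
    the n selected genes, p = P[X >= k], X ~ Hypergeom(N, K, n).  BH
    across terms with at least one background member.  The ``reported``
    flag marks terms at adjusted p below the cutoff that are supported by
    at least two genes (single-gene terms are never reported).
    """
    stray = selected - background
    if stray:
        raise ValueError(f"selected genes outside background: {sorted(stray)[:10]}")
    N = len(background)
    n = len(selected)
    rows = []
    for term, members in sorted(terms.items()):
        K = len(members & background)
        if K == 0:
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "overlap": k,
                "selected_size": n,
                "term_size": K,
                "background_size": N,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "overlap", "selected_size", "term_size", "background_size", "p_raw"]
    )
    if out.empty:
        out["p_adj"] = []
        out["reported"] = []
        return out
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["reported"] = (out["p_adj"] < padj_cutoff) & (out["overlap"] >= min_overlap)
    return out
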