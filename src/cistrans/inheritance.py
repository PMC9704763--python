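"""Inheritance-mode classification from parental and F1 total counts.

Four NB contrasts on total (not allele-resolved) counts decide how F1
expression relates to the parents:

1. P1 vs P2 — parental divergence; significant at adjusted p < 0.01 AND
   |log2FC| > 0.5 AND base mean > 15;
2. F1 vs P1 at adjusted p < 0.01;
3. F1 vs P2 at adjusted p < 0.01;
4. F1 vs the arithmetic parental midpoint at adjusted p < 0.01, tested
   against pseudo-replicates built by pairing and averaging normalized
   parental replicates.

Strict categories: dominant toward a parent (F1 equals that parent only),
additive (F1 equals the midpoint only), transgressive (F1 significantly
outside the parental range).  Genes with parental divergence that fit no
strict category get Stone's partial-dominance statistic

    H = (2*F1 - P1 - P2) / (P1 - P2)

on normalized means: 0 < H < 1 is partial dominance toward P1, -1 < H < 0
toward P2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import estimate_dispersion, median_of_ratios, nb_wald_test

__all__ = [
    "inheritance_contrasts",
    "classify_inheritance",
    "stone_h",
    "classify_inheritance_table",
    "direction_summaries",
    "INHERITANCE_CATEGORIES",
]

INHERITANCE_CATEGORIES = (
    "additive",
    "dominant_toward_P1",
    "dominant_toward_P2",
    "transgressive_up",
    "transgressive_down",
    "unassigned",
)

PADJ_CUTOFF = 0.01
PARENT_LFC_MIN = 0.5
PARENT_BASE_MEAN_MIN = 15.0


def _two_group(
    counts_a, counts_b, label_a, label_b, size_factors, dispersion, group_dispersion=None
):
    counts = pd.concat([counts_a, counts_b], axis=1)
    groups = pd.Series(
        pd.Categorical(
            [label_a] * counts_a.shape[1] + [label_b] * counts_b.shape[1],
            categories=[label_a, label_b],
        ),
        index=counts.columns,
    )
    return nb_wald_test(
        counts,
        groups,
        size_factors=size_factors.loc[counts.columns],
        dispersion=dispersion,
        group_dispersion=group_dispersion,
    )


def inheritance_contrasts(
    p1: pd.DataFrame, p2: pd.DataFrame, f1: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Run the four total-count contrasts with one joint normalization.

    Size factors and the dispersion trend are estimated once on all
    samples; the midpoint contrast pairs parental replicates (cycling the
    shorter genotype when replicate numbers differ), averages their
    normalized counts gene-wise into pseudo-replicates with unit size
    factor, and tests F1 against them with the pooled dispersions.

    Returns contrasts keyed 'p1_vs_p2', 'f1_vs_p1', 'f1_vs_p2',
    'f1_vs_mid'; log2FC orientation is first-over-second.
    """
    allc = pd.concat([p1, p2, f1], axis=1)
    sf = median_of_ratios(allc)
    genotype = pd.Series(
        ["P1"] * p1.shape[1] + ["P2"] * p2.shape[1] + ["F1"] * f1.shape[1],
        index=allc.columns,
    )
    disp = estimate_dispersion(allc, sf, genotype)

    res = {
        "p1_vs_p2": _two_group(p1, p2, "P1", "P2", sf, disp),
        "f1_vs_p1": _two_group(f1, p1, "F1", "P1", sf, disp),
        "f1_vs_p2": _two_group(f1, p2, "F1", "P2", sf, disp),
    }

    # midpoint pseudo-replicates on normalized counts
    n_mid = max(p1.shape[1], p2.shape[1])
    p1n = p1.to_numpy(dtype=float) / sf.loc[p1.columns].to_numpy()[None, :]
    p2n = p2.to_numpy(dtype=float) / sf.loc[p2.columns].to_numpy()[None, :]
    mid = np.empty((p1.shape[0], n_mid))
    for k in range(n_mid):
        mid[:, k] = 0.5 * (p1n[:, k % p1.shape[1]] + p2n[:, k % p2.shape[1]])
    mid_df = pd.DataFrame(mid, index=p1.index, columns=[f"MID_rep{k + 1}" for k in range(n_mid)])
    f1n = f1.to_numpy(dtype=float) / sf.loc[f1.columns].to_numpy()[None, :]
    f1n_df = pd.DataFrame(f1n, index=f1.index, columns=f1.columns)
    unit_sf = pd.Series(1.0, index=list(f1.columns) + list(mid_df.columns))
    # a pseudo-replicate averages two parental replicates, so its variance
    # is half the NB variance at its mean; moment-match the dispersion:
    # (mu + a*mu^2)/2 = mu + a_mid*mu^2  =>  a_mid = a/2 - 1/(2*mu)
    mid_mean = np.maximum(mid.mean(axis=1), 1e-8)
    disp_arr = disp.loc[p1.index].to_numpy(dtype=float)
    mid_disp = pd.Series(
        np.maximum(disp_arr / 2.0 - 1.0 / (2.0 * mid_mean), 1e-8), index=p1.index
    )
    res["f1_vs_mid"] = _two_group(
        f1n_df, mid_df, "F1", "MID", unit_sf, disp, group_dispersion={"MID": mid_disp}
    )

    # normalized genotype means for Stone's H
    means = pd.DataFrame(
        {
            "mean_P1": p1n.mean(axis=1),
            "mean_P2": p2n.mean(axis=1),
            "mean_F1": f1n.mean(axis=1),
        },
        index=p1.index,
    )
    res["means"] = means
    return res


def stone_h(
    mean_p1: float, mean_p2: float, mean_f1: float, eps: float = None
) -> float:
    """Stone's partial-dominance statistic on normalized means.

    H = 1 when F1 equals P1 exactly, -1 at P2, 0 at the midpoint.
    Undefined (NaN) when |P1 - P2| falls below eps (default 1e-8 times
    the overall mean)."""
    if eps is None:
        eps = 1e-8 * (abs(mean_p1) + abs(mean_p2) + abs(mean_f1)) / 3.0
    denom = mean_p1 - mean_p2
    if abs(denom) <= eps:
        return float("nan")
    return (2.0 * mean_f1 - mean_p1 - mean_p2) / denom


def _partial_category(h: float) -> str:
    if np.isnan(h):
        return "none"
    if 0.0 < h < 1.0:
        return "partial_dominant_P1"
    if -1.0 < h < 0.0:
        return "partial_dominant_P2"
    return "none"


def classify_inheritance(
    sig1: bool,
    lfc1: float,
    sig2: bool,
    lfc2: float,
    sig3: bool,
    lfc3: float,
    sig4: bool,
) -> str:
    """Strict category from the four contrast outcomes.

    sig1/lfc1: P1 vs P2 (full criteria applied by the caller);
    sig2/lfc2: F1 vs P1; sig3/lfc3: F1 vs P2; sig4: F1 vs midpoint.
    Transgressive needs F1 significantly beyond both parents in the same
    direction and applies regardless of parental divergence; the other
    categories require P1 != P2.
    """
    if sig2 and sig3 and lfc2 > 0 and lfc3 > 0:
        return "transgressive_up"
    if sig2 and sig3 and lfc2 < 0 and lfc3 < 0:
        return "transgressive_down"
    if not sig1:
        return "unassigned"
    if (not sig2) and sig3 and sig4:
        return "dominant_toward_P1"
    if sig2 and (not sig3) and sig4:
        return "dominant_toward_P2"
    if sig2 and sig3 and not sig4:
        return "additive"
    return "unassigned"


def classify_inheritance_table(
    contrasts: dict[str, pd.DataFrame],
    padj_cutoff: float = PADJ_CUTOFF,
    parent_lfc_min: float = PARENT_LFC_MIN,
    parent_base_mean_min: float = PARENT_BASE_MEAN_MIN,
) -> pd.DataFrame:
    """Per-gene inheritance assignment from the four contrasts.

    Returns a frame with the strict category, parental direction, Stone's
    H and the partial-dominance category (computed only for genes with
    parental divergence left unassigned by the strict rules).
    """
    c1 = contrasts["p1_vs_p2"]
    c2 = contrasts["f1_vs_p1"]
    c3 = contrasts["f1_vs_p2"]
    c4 = contrasts["f1_vs_mid"]
    means = contrasts["means"]
    rows = []
    for g in c1.index:
        sig1 = bool(
            (c1.loc[g, "p_adj"] < padj_cutoff)
            and (abs(c1.loc[g, "log2fc_raw"]) > parent_lfc_min)
            and (c1.loc[g, "base_mean"] > parent_base_mean_min)
        )
        sig2 = bool(c2.loc[g, "p_adj"] < padj_cutoff)
        sig3 = bool(c3.loc[g, "p_adj"] < padj_cutoff)
        sig4 = bool(c4.loc[g, "p_adj"] < padj_cutoff)
        cat = classify_inheritance(
            sig1,
            float(c1.loc[g, "log2fc_raw"]),
            sig2,
            float(c2.loc[g, "log2fc_raw"]),
            sig3,
            float(c3.loc[g, "log2fc_raw"]),
            sig4,
        )
        direction = (
            "P1>P2"
            if sig1 and c1.loc[g, "log2fc_raw"] > 0
            else ("P1<P2" if sig1 else "P1=P2")
        )
        h = float("nan")
        partial = "none"
        if sig1:
            h = stone_h(
                float(means.loc[g, "mean_P1"]),
                float(means.loc[g, "mean_P2"]),
                float(means.loc[g, "mean_F1"]),
            )
            if cat == "unassigned":
                partial = _partial_category(h)
        rows.append(
            {
                "gene_id": g,
                "category": cat,
                "direction": direction,
                "H": h,
                "partial_category": partial,
                "parental_lfc": float(c1.loc[g, "log2fc_raw"]),
                "sig_parents": sig1,
                "sig_f1_vs_p1": sig2,
                "sig_f1_vs_p2": sig3,
                "sig_f1_vs_mid": sig4,
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id", drop=False)
    out.index.name = None
    return out


DEFAULT_LFC_BINS = (0.5, 1.0, 1.5, 2.0)
MODE_LFC_BINS = (1.0, 2.0)


def _bin_labels(edges: tuple[float, ...]) -> list[str]:
    labels = [f"<{edges[0]:g}"]
    for a, b in zip(edges, edges[1:]):
        labels.append(f"{a:g}-{b:g}")
    labels.append(f">{edges[-1]:g}")
    return labels


def _bin_of(value: float, edges: tuple[float, ...]) -> str:
    labels = _bin_labels(edges)
    for i, e in enumerate(edges):
        if value < e:
            return labels[i]
    return labels[-1]


def direction_summaries(
    assignments: pd.DataFrame,
    modes: pd.DataFrame | None = None,
    gene_sets: pd.Series | None = None,
    lfc_bins: tuple[float, ...] = DEFAULT_LFC_BINS,
    mode_bins: tuple[float, ...] = MODE_LFC_BINS,
) -> dict[str, pd.DataFrame]:
    """Downstream summary tables over inheritance and mode assignments.

    * ``direction_counts``: genes per (category, parental direction),
      overall and, when ``gene_sets`` (gene_id -> set label) is given,
      per annotated subset;
    * ``inheritance_by_lfc``: additive vs dominant composition in
      |parental log2FC| bins (default edges 0.5, 1, 1.5, 2);
    * ``mode_by_lfc`` (when ``modes`` given): regulatory-mode composition
      in |parental log2FC| bins <1, 1-2, >2.
    Empty bins appear as zero-count rows.
    """
    out: dict[str, pd.DataFrame] = {}

    df = assignments.copy()
    df["subset"] = "all"
    frames = [df]
    if gene_sets is not None:
        sub = assignments.loc[assignments.index.intersection(gene_sets.index)].copy()
        sub["subset"] = gene_sets.loc[sub.index]
        frames.append(sub)
    both = pd.concat(frames)
    out["direction_counts"] = (
        both.groupby(["subset", "category", "direction"], observed=True)
        .size()
        .rename("n_genes")
        .reset_index()
    )

    labels = _bin_labels(lfc_bins)
    strict = df[df["category"].isin(["additive", "dominant_toward_P1", "dominant_toward_P2"])]
    rows = []
    for lab in labels:
        in_bin = strict[strict["parental_lfc"].abs().map(lambda v: _bin_of(v, lfc_bins)) == lab]
        n_add = int((in_bin["category"] == "additive").sum())
        n_dom = int(in_bin["category"].str.startswith("dominant").sum())
        tot = n_add + n_dom
        rows.append(
            {
                "lfc_bin": lab,
                "n_additive": n_add,
                "n_dominant": n_dom,
                "prop_dominant": n_dom / tot if tot else 0.0,
            }
        )
    out["inheritance_by_lfc"] = pd.DataFrame(rows)

    if modes is not None:
        labels = _bin_labels(mode_bins)
        assessed = modes[modes["mode"] != "not_assessed"]
        rows = []
        for lab in labels:
            in_bin = assessed[
                assessed["parental_lfc"].abs().map(lambda v: _bin_of(v, mode_bins)) == lab
            ]
            row = {"lfc_bin": lab, "n_genes": len(in_bin)}
            for m in ("cis", "trans", "synergism", "antagonism", "compensatory", "conserved", "ambiguous"):
                row[f"n_{m}"] = int((in_bin["mode"] == m).sum())
            rows.append(row)
        out["mode_by_lfc"] = pd.DataFrame(rows)
    return out
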