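#!/usr/bin/env python
"""Downstream association and enrichment summaries.

Joins the mode and inheritance assignments from 04/05, tests each
(mode x inheritance) combination for association with a 2x2 chi-square,
builds the upper/lower 5% tails of the significant cis and trans effect
distributions, and runs a hypergeometric enrichment of the trans tails
against a synthetic term map in which one term is planted to be
enriched.  Writes tables under results/downstream/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cistrans import io as cio
from cistrans.downstream import extreme_tails, mode_inheritance_association, term_enrichment

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "downstream"
SEED = 515


def main() -> None:
    modes_path = ROOT / "results" / "modes" / "modes.tsv"
    inh_path = ROOT / "results" / "inheritance" / "inheritance.tsv"
    if not (modes_path.exists() and inh_path.exists()):
        raise SystemExit("run analysis/04 and 05 first")
    modes = pd.read_csv(modes_path, sep="\t", index_col=0)
    inh = pd.read_csv(inh_path, sep="\t", index_col=0)

    joined = pd.DataFrame(
        {"mode": modes["mode"], "inheritance": inh["category"].reindex(modes.index)}
    ).dropna()
    assoc = mode_inheritance_association(joined)
    OUT.mkdir(parents=True, exist_ok=True)
    cio.write_table(assoc, OUT / "mode_inheritance_association.tsv")
    sig = assoc[assoc["p_adj"] < 0.05]
    print(f"{len(sig)}/{len(assoc)} mode x inheritance combinations associated "
          "(adjusted p < 0.05):")
    for r in sig.itertuples():
        arrow = "enriched" if r.direction > 0 else "depleted"
        print(f"  {r.mode:11s} x {r.inheritance:13s} {arrow:9s} chi2={r.chi2:7.1f}")

    tails = extreme_tails({"P1_vs_P2": modes})
    rows = [{"tail": k, "gene_id": g} for k, gs in sorted(tails.items()) for g in sorted(gs)]
    cio.write_table(pd.DataFrame(rows), OUT / "extreme_tails.tsv")
    print("tail sizes:", {k: len(v) for k, v in tails.items()})

    # synthetic term map: term T01 drawn preferentially from the trans-up
    # tail, the rest uniform — T01 should come out enriched
    rng = np.random.default_rng(SEED)
    background = sorted(modes.index[modes["mode"] != "not_assessed"])
    terms: dict[str, set] = {}
    up = sorted(set(background) & tails["trans_up"])
    terms["T01"] = set(rng.choice(up, size=min(12, len(up)), replace=False)) | set(
        rng.choice(background, size=8, replace=False)
    )
    for i in range(2, 11):
        terms[f"T{i:02d}"] = set(rng.choice(background, size=20, replace=False))
    selected = (tails["trans_up"] | tails["trans_down"]) & set(background)
    enr = term_enrichment(selected, set(background), terms)
    cio.write_table(enr, OUT / "enrichment_trans_tails.tsv")
    rep = enr[enr["reported"]]
    print(f"enriched terms among trans tails: {sorted(rep['term_id'])} "
          f"(planted: ['T01'])")


if __name__ == "__main__":
    main()
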