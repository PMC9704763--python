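#!/usr/bin/env python
"""Classify inheritance modes for the reference simulation.

Runs the four total-count contrasts (parents; F1 vs each parent; F1 vs
the parental midpoint via averaged pseudo-replicates), the strict
additive/dominant/transgressive rules, and Stone's partial-dominance H
for divergent genes the strict rules leave unassigned.  Writes the
assignment table and the fold-change-stratified summaries under
results/inheritance/.
"""

from pathlib import Path

import pandas as pd

from cistrans import io as cio
from cistrans.inheritance import (
    classify_inheritance_table,
    direction_summaries,
    inheritance_contrasts,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results" / "inheritance"


def main() -> None:
    if not SIM.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    parental = cio.read_counts(SIM / "parental_counts.tsv")
    f1 = cio.read_counts(SIM / "f1_total_counts.tsv")
    p1 = parental[[c for c in parental.columns if c.startswith("P1")]]
    p2 = parental[[c for c in parental.columns if c.startswith("P2")]]

    contrasts = inheritance_contrasts(p1, p2, f1)
    inh = classify_inheritance_table(contrasts)
    OUT.mkdir(parents=True, exist_ok=True)
    cio.write_table(inh, OUT / "inheritance.tsv")

    modes_path = ROOT / "results" / "modes" / "modes.tsv"
    modes = None
    if modes_path.exists():
        modes = pd.read_csv(modes_path, sep="\t", index_col=0)
    summaries = direction_summaries(inh, modes)
    for name, df in summaries.items():
        cio.write_table(df, OUT / f"summary_{name}.tsv")

    comp = inh["category"].value_counts()
    print("inheritance composition:", comp.to_dict())
    partial = inh["partial_category"].value_counts().drop("none", errors="ignore")
    print("partial dominance among divergent unassigned genes:", partial.to_dict())
    h = inh.loc[inh["H"].notna(), "H"]
    if len(h):
        print(f"Stone's H over {len(h)} divergent genes: "
              f"median {h.median():.3f}, IQR [{h.quantile(0.25):.3f}, {h.quantile(0.75):.3f}]")


if __name__ == "__main__":
    main()
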