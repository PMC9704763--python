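#!/usr/bin/env python
"""Classify regulatory modes for the reference simulation.

Reads the counts written by 01_simulate.py, runs the three tests
(parental DE on total counts, F1 allele-specific DE, the Fisher ratio
test with the NB variance-inflation correction), applies the seven-way
decision table at adjusted p < 0.1 with the base-mean-20 floor, and
compares the calls against the simulation truth.  Writes the mode table
and the confusion matrix under results/modes/.
"""

from pathlib import Path

import pandas as pd

from cistrans import io as cio
from cistrans.alleles import P1_ALLELE, P2_ALLELE
from cistrans.de import median_of_ratios, nb_wald_test
from cistrans.modes import classify_modes, ratio_test

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results" / "modes"


def main() -> None:
    if not SIM.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    parental = cio.read_counts(SIM / "parental_counts.tsv")
    alleles = cio.read_counts(SIM / "f1_allele_counts.tsv")
    truth = pd.read_csv(SIM / "truth.tsv", sep="\t", index_col=0)

    p1_cols = [c for c in parental.columns if c.startswith("P1")]
    p2_cols = [c for c in parental.columns if c.startswith("P2")]
    a1_cols = [c for c in alleles.columns if c.endswith(P1_ALLELE)]
    a2_cols = [c for c in alleles.columns if c.endswith(P2_ALLELE)]

    groups = pd.Series(
        pd.Categorical(["P1"] * len(p1_cols) + ["P2"] * len(p2_cols), categories=["P1", "P2"]),
        index=p1_cols + p2_cols,
    )
    parents_de = nb_wald_test(parental, groups, base_mean_floor=20.0)

    ase_groups = pd.Series(
        pd.Categorical(
            [P1_ALLELE] * len(a1_cols) + [P2_ALLELE] * len(a2_cols),
            categories=[P1_ALLELE, P2_ALLELE],
        ),
        index=a1_cols + a2_cols,
    )
    ase_de = nb_wald_test(alleles[a1_cols + a2_cols], ase_groups, base_mean_floor=20.0)

    ase_sf = median_of_ratios(alleles[a1_cols + a2_cols])
    par_sf = median_of_ratios(parental)
    sf = pd.concat([ase_sf, par_sf])
    disp = 0.5 * (parents_de["dispersion"] + ase_de["dispersion"])
    ratio = ratio_test(
        alleles[a1_cols], alleles[a2_cols], parental[p1_cols], parental[p2_cols],
        sf, dispersion=disp,
    )

    modes = classify_modes(parents_de, ase_de, ratio)
    OUT.mkdir(parents=True, exist_ok=True)
    cio.write_table(modes, OUT / "modes.tsv")

    joint = pd.DataFrame({"true": truth["true_mode"], "called": modes["mode"]})
    confusion = joint.groupby(["true", "called"], observed=True).size().unstack(fill_value=0)
    cio.write_table(confusion.reset_index(), OUT / "confusion.tsv")

    print("mode composition:", modes["mode"].value_counts().to_dict())
    for m in ("cis", "trans", "synergism", "antagonism"):
        sub = joint[joint["true"] == m]
        if len(sub):
            print(f"  {m:11s} recall {100 * (sub['called'] == m).mean():5.1f}%  (n={len(sub)})")
    null = joint[joint["true"] == "conserved"]
    print(f"  null called conserved {100 * (null['called'] == 'conserved').mean():5.1f}%  (n={len(null)})")


if __name__ == "__main__":
    main()
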