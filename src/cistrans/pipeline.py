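"""End-to-end pipeline: simulate -> (select, assign) -> test -> classify
-> summarize.

A run is driven by a :class:`RunConfig` (thresholds default to the
analysis' standard values) and writes every stage's table plus a
machine-readable summary into the run directory.  Identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .alleles import (
    P1_ALLELE,
    P2_ALLELE,
    assign_parent_of_origin,
    diagnostic_snps,
    matched_parental_counts,
)
from .de import median_of_ratios, nb_wald_test
from .downstream import extreme_tails, mode_inheritance_association, term_enrichment
from .inheritance import classify_inheritance_table, direction_summaries, inheritance_contrasts
from .modes import classify_modes, ratio_test
from .simulate import SimConfig, simulate_counts, simulate_read_level

log = logging.getLogger("cistrans")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; threshold defaults are the standard
    analysis values."""

    outdir: str = "run"
    seed: int = 0
    simulation: SimConfig = field(default_factory=SimConfig)
    read_level: bool = False
    mode_padj: float = 0.1
    inheritance_padj: float = 0.01
    parent_lfc_min: float = 0.5
    mode_base_mean_floor: float = 20.0
    inheritance_base_mean_floor: float = 15.0
    tail_frac: float = 0.05
    terms_path: str | None = None
    comparison: str = "P1_vs_P2"

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimConfig(**self.simulation)
        self.simulation.seed = self.seed
        for name, lo, hi in (
            ("mode_padj", 0.0, 1.0),
            ("inheritance_padj", 0.0, 1.0),
            ("tail_frac", 0.0, 0.5),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _safe_size_factors(counts: pd.DataFrame) -> pd.Series:
    try:
        return median_of_ratios(counts)
    except ValueError:
        return median_of_ratios(counts, pseudo_reference=True)


_CURRENT_STAGE: list[str] = ["start"]


def _stage(name: str):
    _CURRENT_STAGE[0] = name
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order and return the summary.

    Stages: simulation (counts, optionally read level), gene selection and
    allele assignment (read-level runs), the three mode tests and the
    seven-way classification, the four inheritance contrasts with Stone's
    H, mode x inheritance association, extreme-tail sets, and optional
    term enrichment.  All tables land under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"comparison": config.comparison, "seed": config.seed, "stages": {}}

    try:
        _stage("simulate")
        sim = simulate_counts(config.simulation)
        cio.write_counts(sim.parental, out / "parental_counts.tsv")
        cio.write_counts(sim.f1_totals, out / "f1_total_counts.tsv")
        cio.write_counts(sim.f1_alleles, out / "f1_allele_counts.tsv")
        cio.write_table(sim.truth, out / "truth.tsv")
        cio.write_table(sim.sample_table, out / "samples.tsv")
        summary["stages"]["simulate"] = {"n_genes": int(config.simulation.n_genes)}

        r = config.simulation.n_reps
        p1_cols = [f"P1_rep{i + 1}" for i in range(r)]
        p2_cols = [f"P2_rep{i + 1}" for i in range(r)]
        f1_cols = [f"F1_rep{i + 1}" for i in range(r)]
        a1_cols = [f"{s}_{P1_ALLELE}" for s in f1_cols]
        a2_cols = [f"{s}_{P2_ALLELE}" for s in f1_cols]

        if config.read_level:
            _stage("assign-alleles")
            rl = simulate_read_level(config.simulation, sim)
            snps = diagnostic_snps(rl.genes, rl.p1_variants, rl.p2_variants, rl.reference)
            f1_ac = assign_parent_of_origin(rl.f1_reads, snps, rl.genes)
            f1_p1 = f1_ac.matrix(P1_ALLELE).reindex(index=sim.truth.index, columns=f1_cols, fill_value=0)
            f1_p2 = f1_ac.matrix(P2_ALLELE).reindex(index=sim.truth.index, columns=f1_cols, fill_value=0)
            par_m = {
                p: matched_parental_counts(rl.parent_reads[p], snps, p, rl.genes)
                for p in ("P1", "P2")
            }
            par_p1 = par_m["P1"].matrix(P1_ALLELE).reindex(index=sim.truth.index, columns=p1_cols, fill_value=0)
            par_p2 = par_m["P2"].matrix(P2_ALLELE).reindex(index=sim.truth.index, columns=p2_cols, fill_value=0)
            cio.write_table(f1_ac.to_frame(), out / "assigned_allele_counts.tsv")
            summary["stages"]["assign"] = {
                "fragments_assigned": int(sum(f1_ac.counts.values())),
                "fragments_discarded": int(sum(f1_ac.discarded.values())),
            }
        else:
            f1_p1 = sim.f1_alleles[a1_cols].set_axis(f1_cols, axis=1)
            f1_p2 = sim.f1_alleles[a2_cols].set_axis(f1_cols, axis=1)
            par_p1 = sim.parental[p1_cols]
            par_p2 = sim.parental[p2_cols]

        _stage("de-test: parents")
        parent_groups = pd.Series(
            pd.Categorical(["P1"] * r + ["P2"] * r, categories=["P1", "P2"]),
            index=p1_cols + p2_cols,
        )
        parents_de = nb_wald_test(
            sim.parental[p1_cols + p2_cols],
            parent_groups,
            base_mean_floor=config.mode_base_mean_floor,
        )
        cio.write_table(parents_de, out / "de_parents.tsv")

        _stage("de-test: ASE")
        ase_counts = pd.concat(
            [f1_p1.set_axis(a1_cols, axis=1), f1_p2.set_axis(a2_cols, axis=1)], axis=1
        )
        ase_groups = pd.Series(
            pd.Categorical(
                [P1_ALLELE] * r + [P2_ALLELE] * r, categories=[P1_ALLELE, P2_ALLELE]
            ),
            index=a1_cols + a2_cols,
        )
        ase_sf = _safe_size_factors(ase_counts)
        ase_de = nb_wald_test(
            ase_counts,
            ase_groups,
            size_factors=ase_sf,
            base_mean_floor=config.mode_base_mean_floor,
        )
        cio.write_table(ase_de, out / "de_ase.tsv")

        _stage("ratio-test")
        par_counts = pd.concat([par_p1, par_p2], axis=1)
        par_sf = _safe_size_factors(par_counts)
        sf_all = pd.concat(
            [
                pd.Series(ase_sf.to_numpy(), index=list(f1_p1.columns) + list(f1_p2.columns)),
                par_sf,
            ]
        )
        sf_all = sf_all[~sf_all.index.duplicated()]
        ratio_disp = 0.5 * (
            parents_de["dispersion"].reindex(sim.truth.index).fillna(0.0)
            + ase_de["dispersion"].reindex(sim.truth.index).fillna(0.0)
        )
        ratio = ratio_test(f1_p1, f1_p2, par_p1, par_p2, sf_all, dispersion=ratio_disp)
        cio.write_table(ratio, out / "ratio_test.tsv")

        _stage("classify-modes")
        modes = classify_modes(
            parents_de,
            ase_de,
            ratio,
            padj_cutoff=config.mode_padj,
            base_mean_floor=config.mode_base_mean_floor,
        )
        modes.insert(1, "comparison", config.comparison)
        cio.write_table(modes, out / "modes.tsv")
        summary["stages"]["modes"] = {
            m: int((modes["mode"] == m).sum()) for m in modes["mode"].unique()
        }

        _stage("classify-inheritance")
        contrasts = inheritance_contrasts(sim.parental[p1_cols], sim.parental[p2_cols], sim.f1_totals)
        inh = classify_inheritance_table(
            contrasts,
            padj_cutoff=config.inheritance_padj,
            parent_lfc_min=config.parent_lfc_min,
            parent_base_mean_min=config.inheritance_base_mean_floor,
        )
        inh.insert(1, "comparison", config.comparison)
        cio.write_table(inh, out / "inheritance.tsv")
        summary["stages"]["inheritance"] = {
            c: int((inh["category"] == c).sum()) for c in inh["category"].unique()
        }

        _stage("summaries")
        summaries = direction_summaries(inh, modes)
        for name, df in summaries.items():
            cio.write_table(df, out / f"summary_{name}.tsv")

        _stage("associate")
        joined = pd.DataFrame(
            {"mode": modes["mode"], "inheritance": inh["category"].reindex(modes.index)}
        ).dropna()
        assoc = mode_inheritance_association(joined)
        cio.write_table(assoc, out / "mode_inheritance_association.tsv")

        _stage("tails")
        tails = extreme_tails({config.comparison: modes}, tail_frac=config.tail_frac)
        tail_rows = [
            {"tail": k, "gene_id": g} for k, gs in sorted(tails.items()) for g in sorted(gs)
        ]
        cio.write_table(
            pd.DataFrame(tail_rows, columns=["tail", "gene_id"]), out / "extreme_tails.tsv"
        )
        summary["stages"]["tails"] = {k: len(v) for k, v in tails.items()}

        if config.terms_path:
            _stage("enrich")
            terms = cio.load_term_map(config.terms_path)
            background = set(modes.index[modes["mode"] != "not_assessed"])
            for tail_name in ("cis_up", "cis_down", "trans_up", "trans_down"):
                sel = tails[tail_name] & background
                enr = term_enrichment(sel, background, terms)
                cio.write_table(enr, out / f"enrichment_{tail_name}.tsv")

        _stage("recovery")
        truth = sim.truth
        joint = pd.DataFrame(
            {"true_mode": truth["true_mode"], "called": modes["mode"].reindex(truth.index)}
        )
        confusion = (
            joint.groupby(["true_mode", "called"], observed=True).size().rename("n").reset_index()
        )
        cio.write_table(confusion, out / "mode_confusion.tsv")
        recov = {}
        for m in ("cis", "trans", "synergism", "antagonism"):
            sub = joint[joint["true_mode"] == m]
            if len(sub):
                recov[f"{m}_recall"] = float((sub["called"] == m).mean())
        null_sub = joint[joint["true_mode"] == "conserved"]
        if len(null_sub):
            recov["null_conserved_rate"] = float((null_sub["called"] == "conserved").mean())
        summary["stages"]["recovery"] = recov

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        raise RuntimeError(
            f"pipeline failed at stage {_CURRENT_STAGE[0]!r}: {exc}"
        ) from exc
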