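"""Tests of inheritance classification and Stone's partial-dominance H."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cistrans.inheritance import (
    classify_inheritance,
    classify_inheritance_table,
    direction_summaries,
    inheritance_contrasts,
    stone_h,
)
from cistrans.simulate import SimConfig, simulate_counts


class TestStoneH:
    def test_midpoint_gives_zero(self):
        assert stone_h(100.0, 50.0, 75.0) == 0.0

    def test_complete_dominance_identities(self):
        assert stone_h(100.0, 50.0, 100.0) == 1.0
        assert stone_h(100.0, 50.0, 50.0) == -1.0

    def test_direct_substitution(self):
        # H = (2*90 - 100 - 50)/(100 - 50) = 30/50
        assert stone_h(100.0, 50.0, 90.0) == pytest.approx(0.6)

    def test_equal_parents_undefined(self):
        assert math.isnan(stone_h(100.0, 100.0, 80.0))

    @settings(deadline=None, max_examples=80)
    @given(
        p1=st.floats(min_value=1.0, max_value=1e4),
        p2=st.floats(min_value=1.0, max_value=1e4),
        f1=st.floats(min_value=0.0, max_value=1e4),
    )
    def test_antisymmetry_under_parent_relabel(self, p1, p2, f1):
        h = stone_h(p1, p2, f1)
        h_swapped = stone_h(p2, p1, f1)
        if math.isnan(h):
            assert math.isnan(h_swapped)
        else:
            assert h_swapped == pytest.approx(-h, rel=1e-9, abs=1e-12)


class TestStrictRules:
    def test_all_contrasts_null_is_unassigned(self):
        assert classify_inheritance(False, 0.0, False, 0.0, False, 0.0, False) == "unassigned"

    def test_dominant_toward_p1(self):
        # P1>P2; F1 = P1 (c2 ns), F1 != P2 (c3 sig), F1 != mid (c4 sig)
        assert (
            classify_inheritance(True, 2.0, False, 0.0, True, 2.0, True)
            == "dominant_toward_P1"
        )

    def test_dominant_toward_p2(self):
        assert (
            classify_inheritance(True, 2.0, True, -2.0, False, 0.0, True)
            == "dominant_toward_P2"
        )

    def test_additive(self):
        assert classify_inheritance(True, 2.0, True, -1.0, True, 1.0, False) == "additive"

    def test_transgressive_up_even_without_parental_divergence(self):
        assert classify_inheritance(False, 0.0, True, 1.0, True, 1.2, True) == "transgressive_up"

    def test_transgressive_down(self):
        assert classify_inheritance(True, 1.0, True, -1.0, True, -0.5, False) == "transgressive_down"

    def test_incongruent_pattern_unassigned(self):
        # F1 equal to both parents but different from mid: incoherent
        assert classify_inheritance(True, 2.0, False, 0.0, False, 0.0, True) == "unassigned"

    def test_categories_mutually_exclusive(self):
        import itertools

        cats = set()
        for s1, s2, s3, s4 in itertools.product([False, True], repeat=4):
            for l2, l3 in [(1.0, 1.0), (-1.0, -1.0), (1.0, -1.0), (-1.0, 1.0)]:
                cats.add(classify_inheritance(s1, 1.0, s2, l2, s3, l3, s4))
        assert cats <= {
            "additive", "dominant_toward_P1", "dominant_toward_P2",
            "transgressive_up", "transgressive_down", "unassigned",
        }


class TestContrasts:
    def _sim(self, **kw):
        base = dict(
            n_genes=400, seed=55, mean_log_expression=(math.log(800), 0.7), min_mean=300.0
        )
        base.update(kw)
        cfg = SimConfig(**base)
        sim = simulate_counts(cfg)
        r = cfg.n_reps
        p1 = sim.parental[[f"P1_rep{i + 1}" for i in range(r)]]
        p2 = sim.parental[[f"P2_rep{i + 1}" for i in range(r)]]
        return sim, p1, p2

    def test_identical_genotypes_unassigned(self):
        sim, p1, p2 = self._sim(frac_cis=0, frac_trans=0, frac_both=0, frac_null=1.0)
        con = inheritance_contrasts(p1, p2, sim.f1_totals)
        inh = classify_inheritance_table(con)
        assert (inh["category"] == "unassigned").mean() > 0.95
        assert (inh["direction"] == "P1=P2").mean() > 0.95

    def test_dominant_recovered_when_f1_matches_p1(self):
        """Pure-trans genes with full trans dominance put F1 on P1; the
        classifier should call dominance toward P1 for most of them."""
        sim, p1, p2 = self._sim(
            frac_cis=0, frac_trans=1.0, frac_both=0, frac_null=0, trans_dominance=1.0
        )
        con = inheritance_contrasts(p1, p2, sim.f1_totals)
        inh = classify_inheritance_table(con)
        frac_dom = (inh["category"] == "dominant_toward_P1").mean()
        assert frac_dom >= 0.70

    def test_additive_is_modal_at_half_dominance(self):
        sim, p1, p2 = self._sim(
            frac_cis=0, frac_trans=1.0, frac_both=0, frac_null=0, trans_dominance=0.5, seed=56
        )
        con = inheritance_contrasts(p1, p2, sim.f1_totals)
        inh = classify_inheritance_table(con)
        counts = inh["category"].value_counts()
        assigned = counts.drop("unassigned", errors="ignore")
        assert len(assigned) and assigned.idxmax() == "additive"
        assert (inh["category"].str.startswith("dominant")).mean() < 0.10

    def test_low_base_mean_gene_fails_parental_criteria(self):
        rng = np.random.default_rng(5)
        n = 50
        cols_p1 = [f"P1_rep{i}" for i in range(5)]
        cols_p2 = [f"P2_rep{i}" for i in range(5)]
        cols_f1 = [f"F1_rep{i}" for i in range(5)]
        p1 = pd.DataFrame(rng.poisson(1000, (n, 5)), columns=cols_p1)
        p2 = pd.DataFrame(rng.poisson(1000, (n, 5)), columns=cols_p2)
        f1 = pd.DataFrame(rng.poisson(1000, (n, 5)), columns=cols_f1)
        # one low-expression gene with a huge fold change
        p1.iloc[0] = rng.poisson(40, 5)
        p2.iloc[0] = rng.poisson(2, 5)
        f1.iloc[0] = rng.poisson(20, 5)
        con = inheritance_contrasts(p1, p2, f1)
        inh = classify_inheritance_table(con, parent_base_mean_min=15.0)
        g0 = inh.index[0]
        bm = con["p1_vs_p2"].loc[g0, "base_mean"]
        if bm <= 15.0:  # the engineered condition
            assert not inh.loc[g0, "sig_parents"]

    def test_partial_dominance_only_for_divergent_unassigned(self):
        sim, p1, p2 = self._sim(trans_dominance=0.8, seed=57)
        con = inheritance_contrasts(p1, p2, sim.f1_totals)
        inh = classify_inheritance_table(con)
        has_partial = inh["partial_category"] != "none"
        assert (inh.loc[has_partial, "category"] == "unassigned").all()
        assert (inh.loc[has_partial, "direction"] != "P1=P2").all()
        p1_side = inh["partial_category"] == "partial_dominant_P1"
        assert ((inh.loc[p1_side, "H"] > 0) & (inh.loc[p1_side, "H"] < 1)).all()


class TestSummaries:
    def _assignments(self):
        rows = [
            ("g1", "additive", "P1>P2", 0.8),
            ("g2", "additive", "P1<P2", -1.2),
            ("g3", "dominant_toward_P1", "P1>P2", 1.7),
            ("g4", "dominant_toward_P2", "P1<P2", -2.5),
            ("g5", "transgressive_up", "P1=P2", 0.1),
            ("g6", "additive", "P1>P2", 0.6),
            ("g7", "dominant_toward_P1", "P1>P2", 1.2),
            ("g8", "unassigned", "P1>P2", 0.9),
            ("g9", "additive", "P1>P2", 3.0),
            ("g10", "unassigned", "P1=P2", 0.0),
        ]
        df = pd.DataFrame(rows, columns=["gene_id", "category", "direction", "parental_lfc"])
        return df.set_index("gene_id", drop=False)

    def test_hand_tallied_direction_counts(self):
        out = direction_summaries(self._assignments())
        dc = out["direction_counts"]
        add_up = dc[(dc["category"] == "additive") & (dc["direction"] == "P1>P2")]
        assert add_up["n_genes"].iloc[0] == 3
        dom_dn = dc[(dc["category"] == "dominant_toward_P2") & (dc["direction"] == "P1<P2")]
        assert dom_dn["n_genes"].iloc[0] == 1

    def test_lfc_bins_hand_checked(self):
        out = direction_summaries(self._assignments())
        tab = out["inheritance_by_lfc"].set_index("lfc_bin")
        # |lfc| 0.8, 0.6 in bin 0.5-1; g1,g6 additive; none dominant
        assert tab.loc["0.5-1", "n_additive"] == 2
        assert tab.loc["0.5-1", "prop_dominant"] == 0.0
        # 1.2 (g2 additive), 1.7/1.2 dominant in 1-1.5 and 1.5-2
        assert tab.loc["1-1.5", "n_dominant"] == 1
        assert tab.loc[">2", "n_dominant"] == 1
        assert tab.loc[">2", "n_additive"] == 1

    def test_all_additive_means_zero_dominant_proportion(self):
        df = self._assignments()
        df = df[df["category"] == "additive"]
        out = direction_summaries(df)
        assert (out["inheritance_by_lfc"]["prop_dominant"] == 0.0).all()

    def test_empty_annotation_subset_ok(self):
        out = direction_summaries(
            self._assignments(), gene_sets=pd.Series(dtype=object)
        )
        assert (out["direction_counts"]["subset"] == "all").all()

    def test_mode_bins_reported_even_when_empty(self):
        modes = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "mode": ["cis"],
                "parental_lfc": [0.4],
            }
        ).set_index("gene_id", drop=False)
        out = direction_summaries(self._assignments(), modes=modes)
        tab = out["mode_by_lfc"].set_index("lfc_bin")
        assert tab.loc["<1", "n_cis"] == 1
        assert tab.loc["1-2", "n_genes"] == 0
        assert tab.loc[">2", "n_genes"] == 0
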