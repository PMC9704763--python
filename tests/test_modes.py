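"""Tests of the Fisher ratio test and the seven-way mode decision table."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from cistrans.modes import (
    classify_mode,
    classify_modes,
    decompose_effects,
    fisher_two_sided,
    ratio_test,
)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over the fixed margins,
    summing all tables whose exact hypergeometric probability does not
    exceed the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisher:
    def test_proportional_table_is_null(self):
        assert fisher_two_sided(np.array([[10, 10], [10, 10]])) == pytest.approx(1.0)

    def test_diagonal_table_exact_value(self):
        # margins (5,5)x(5,5): p = 2/C(10,5) = 2/252
        assert fisher_two_sided(np.array([[5, 0], [0, 5]])) == pytest.approx(2 / 252, abs=1e-12)

    def test_equal_large_ratios_not_significant(self):
        p = fisher_two_sided(np.array([[400, 100], [800, 200]]))
        assert p > 0.5

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided(np.array([[1, -1], [2, 3]]))

    @pytest.mark.parametrize(
        "table",
        [(3, 7, 6, 2), (0, 9, 9, 0), (12, 3, 4, 11), (1, 1, 1, 1), (8, 0, 5, 5)],
    )
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        assert fisher_two_sided(np.array([[a, b], [c, d]])) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )


class TestRatioTest:
    def _mats(self, f1p1, f1p2, pp1, pp2, reps=1):
        def m(vals, prefix):
            return pd.DataFrame(
                {f"{prefix}{i}": vals for i in range(reps)}, index=[f"g{j}" for j in range(len(vals))]
            )
        return m(f1p1, "a"), m(f1p2, "b"), m(pp1, "c"), m(pp2, "d")

    def _sf(self, mats):
        cols = [c for m in mats for c in m.columns]
        return pd.Series(1.0, index=cols)

    def test_equal_ratio_table_null(self):
        mats = self._mats([10], [10], [10], [10])
        res = ratio_test(*mats, self._sf(mats))
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_replicate_weighting_scales_smaller_group(self):
        # 2 F1 reps vs 4 parental reps: F1 sums are doubled
        f1p1 = pd.DataFrame({"a0": [6], "a1": [8]}, index=["g0"])
        f1p2 = pd.DataFrame({"b0": [3], "b1": [5]}, index=["g0"])
        pp1 = pd.DataFrame({f"c{i}": [10] for i in range(4)}, index=["g0"])
        pp2 = pd.DataFrame({f"d{i}": [10] for i in range(4)}, index=["g0"])
        sf = pd.Series(1.0, index=["a0", "a1", "b0", "b1", "c0", "c1", "c2", "c3", "d0", "d1", "d2", "d3"])
        res = ratio_test(f1p1, f1p2, pp1, pp2, sf)
        assert res["f1_p1"].iloc[0] == 28  # (6+8) * 4/2
        assert res["f1_p2"].iloc[0] == 16
        assert res["par_p1"].iloc[0] == 40

    def test_size_factor_normalization_applied(self):
        mats = self._mats([20], [20], [10], [10])
        sf = self._sf(mats)
        sf[["a0", "b0"]] = 2.0  # halves the F1 cells
        res = ratio_test(*mats, sf)
        assert res["f1_p1"].iloc[0] == 10
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_dispersion_deflates_rows_but_keeps_ratios(self):
        mats = self._mats([400], [100], [100], [100], reps=1)
        disp = pd.Series([0.05], index=["g0"])
        res = ratio_test(*mats, self._sf(mats), dispersion=disp)
        # row ratios preserved: 4:1 and 1:1
        assert res["f1_p1"].iloc[0] == pytest.approx(4 * res["f1_p2"].iloc[0], abs=4)
        assert res["par_p1"].iloc[0] == res["par_p2"].iloc[0]
        assert res["f1_p1"].iloc[0] < 400

    def test_half_even_rounding(self):
        mats = self._mats([1], [1], [1], [1])
        sf = self._sf(mats) * (1 / 2.5)  # cells become 2.5
        res = ratio_test(*mats, sf)
        assert res["f1_p1"].iloc[0] == 2  # 2.5 rounds half-even to 2


class TestDecisionTable:
    def test_decomposition_is_exact_arithmetic(self):
        assert decompose_effects(3.0, 0.5) == 2.5
        assert decompose_effects(0.0, 2.0) == -2.0
        assert decompose_effects(-4.0, -1.0) == -3.0

    @pytest.mark.parametrize(
        "trip,expected",
        [
            ((True, True, False), "cis"),
            ((True, False, True), "trans"),
            ((False, True, True), "compensatory"),
            ((False, False, False), "conserved"),
            ((True, False, False), "ambiguous"),
            ((False, True, False), "ambiguous"),
            ((False, False, True), "ambiguous"),
        ],
    )
    def test_non_directional_rows(self, trip, expected):
        assert classify_mode(*trip, cis_lfc=1.0, trans_lfc=1.0) == expected

    def test_all_significant_direction_split(self):
        assert classify_mode(True, True, True, cis_lfc=1.0, trans_lfc=2.0) == "synergism"
        assert classify_mode(True, True, True, cis_lfc=-1.0, trans_lfc=-3.0) == "synergism"
        assert classify_mode(True, True, True, cis_lfc=1.0, trans_lfc=-2.0) == "antagonism"
        assert classify_mode(True, True, True, cis_lfc=-0.5, trans_lfc=0.5) == "antagonism"

    def test_zero_component_is_ambiguous(self):
        assert classify_mode(True, True, True, cis_lfc=0.0, trans_lfc=1.0) == "ambiguous"

    def test_table_is_total_and_exclusive(self):
        """Every significance triple (with both direction cases) maps to
        exactly one of the seven modes."""
        seen = set()
        for trip in itertools.product([False, True], repeat=3):
            for cis, trans in ((1.0, 1.0), (1.0, -1.0)):
                mode = classify_mode(*trip, cis_lfc=cis, trans_lfc=trans)
                assert mode in {
                    "cis", "trans", "synergism", "antagonism",
                    "compensatory", "conserved", "ambiguous",
                }
                seen.add(mode)
        assert seen == {
            "cis", "trans", "synergism", "antagonism",
            "compensatory", "conserved", "ambiguous",
        }


class TestClassifyModes:
    def _de_row(self, gene, lfc, padj, base_mean=100.0, tested=True):
        return {
            "gene_id": gene, "base_mean": base_mean, "log2fc_raw": lfc,
            "log2fc_shrunk": lfc, "se": 0.1, "p_raw": padj, "p_adj": padj,
            "tested": tested,
        }

    def _frame(self, rows):
        df = pd.DataFrame(rows).set_index("gene_id", drop=False)
        df.index.name = None
        return df

    def test_low_expression_not_assessed(self):
        parents = self._frame([self._de_row("g1", 2.0, 0.001, base_mean=10.0)])
        ase = self._frame([self._de_row("g1", 2.0, 0.001)])
        ratio = self._frame([{"gene_id": "g1", "p_adj": 0.5}])
        res = classify_modes(parents, ase, ratio)
        assert res.loc["g1", "mode"] == "not_assessed"

    def test_missing_test_not_assessed(self):
        parents = self._frame([self._de_row("g1", 2.0, 0.001)])
        ase = self._frame([self._de_row("g2", 2.0, 0.001)])
        ratio = self._frame([{"gene_id": "g1", "p_adj": 0.5}])
        res = classify_modes(parents, ase, ratio)
        assert (res["mode"] == "not_assessed").all()

    def test_cis_and_trans_sum_to_parental(self):
        parents = self._frame([self._de_row("g1", 3.0, 0.001)])
        ase = self._frame([self._de_row("g1", 0.5, 0.001)])
        ratio = self._frame([{"gene_id": "g1", "p_adj": 0.02}])
        res = classify_modes(parents, ase, ratio)
        row = res.loc["g1"]
        assert row["cis_lfc"] + row["trans_lfc"] == pytest.approx(row["parental_lfc"], abs=1e-12)
        assert row["mode"] == "synergism"
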