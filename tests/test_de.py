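"""Unit and property tests for the NB differential-expression engine."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cistrans.de import (
    bh_adjust,
    estimate_dispersion,
    median_of_ratios,
    nb_wald_test,
    shrink_lfc,
)
from cistrans.simulate import SimConfig, simulate_counts


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 200, 30], "s2": [10, 200, 30]})
        sf = median_of_ratios(counts)
        np.testing.assert_allclose(sf.to_numpy(), [1.0, 1.0])

    def test_doubled_sample_ratio_is_two(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(200, size=500) + 1
        counts = pd.DataFrame({"s1": base, "s2": 2 * base})
        sf = median_of_ratios(counts)
        # geometric-mean reference puts the factors at 1/sqrt(2), sqrt(2)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0, rel=1e-9)
        np.testing.assert_allclose(sf.to_numpy(), [2**-0.5, 2**0.5], rtol=1e-9)

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(100, size=(50, 4)) + 1)
        perm = counts.sample(frac=1, random_state=2)
        pd.testing.assert_series_equal(median_of_ratios(counts), median_of_ratios(perm))

    def test_idempotence_after_normalization(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(100, size=(200, 4)) + 1).astype(float)
        sf = median_of_ratios(counts)
        renorm = counts / sf.to_numpy()[None, :]
        sf2 = median_of_ratios(renorm)
        np.testing.assert_allclose(sf2.to_numpy(), 1.0, atol=1e-9)

    def test_no_all_positive_gene_raises(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="pseudo"):
            median_of_ratios(counts)
        # the fallback still yields positive factors
        sf = median_of_ratios(counts, pseudo_reference=True)
        assert (sf > 0).all()


class TestDispersion:
    def test_constant_counts_hit_floor(self):
        counts = pd.DataFrame(np.full((5, 6), 50))
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion(counts, sf, trend_weight=0.0)
        np.testing.assert_allclose(alpha.to_numpy(), 1e-8)

    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.poisson(500, size=(300, 50)))
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion(counts, sf)
        assert float(alpha.median()) < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(12)
        mu, a = 500.0, 0.1
        lam = rng.gamma(1 / a, a * mu, size=(300, 50))
        counts = pd.DataFrame(rng.poisson(lam))
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion(counts, sf)
        frac_in_band = ((alpha > 0.05) & (alpha < 0.2)).mean()
        assert frac_in_band >= 0.90

    def test_no_replication_raises(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        groups = pd.Series(["x", "y"], index=["a", "b"])
        with pytest.raises(ValueError, match="replication"):
            estimate_dispersion(counts, pd.Series(1.0, index=["a", "b"]), groups)


class TestWald:
    def test_identical_groups_are_null(self, parental_groups):
        block = np.tile([[100], [300], [50]], (1, 4))
        counts = pd.DataFrame(
            np.hstack([block, block]),
            columns=[f"P1_{i}" for i in range(4)] + [f"P2_{i}" for i in range(4)],
        )
        res = nb_wald_test(counts, parental_groups(counts))
        np.testing.assert_allclose(res["log2fc_raw"], 0.0, atol=1e-9)
        assert (res["p_raw"] > 0.99).all()

    def test_label_swap_negates_lfc(self, small_sim, parental_groups):
        _, sim = small_sim
        counts = sim.parental
        g = parental_groups(counts)
        g_swapped = pd.Series(
            pd.Categorical(g.to_numpy(), categories=["P2", "P1"]), index=g.index
        )
        a = nb_wald_test(counts, g, shrink=False)
        b = nb_wald_test(counts, g_swapped, shrink=False)
        np.testing.assert_allclose(a["log2fc_raw"], -b["log2fc_raw"], atol=1e-9)
        np.testing.assert_allclose(a["p_raw"], b["p_raw"], atol=1e-12)

    def test_fourfold_change_detected(self, parental_groups):
        # 60 four-fold genes among 240 nulls, so normalization stays honest
        rng = np.random.default_rng(21)
        n, n_up, mu, a = 300, 60, 500.0, 0.05
        fold = np.ones(n)
        fold[:n_up] = 4.0
        lam1 = rng.gamma(1 / a, a * fold[:, None] * mu, size=(n, 5))
        lam2 = rng.gamma(1 / a, a * mu, size=(n, 5))
        counts = pd.DataFrame(
            np.hstack([rng.poisson(lam1), rng.poisson(lam2)]),
            columns=[f"P1_{i}" for i in range(5)] + [f"P2_{i}" for i in range(5)],
        )
        res = nb_wald_test(counts, parental_groups(counts))
        hit = (res["p_adj"] < 0.1) & (res["log2fc_raw"] > 0)
        assert hit.iloc[:n_up].mean() >= 0.95

    def test_base_mean_floor_excludes_genes(self, parental_groups):
        rng = np.random.default_rng(22)
        counts = pd.DataFrame(
            np.vstack([rng.poisson(5, size=(10, 10)), rng.poisson(500, size=(10, 10))]),
            columns=[f"P1_{i}" for i in range(5)] + [f"P2_{i}" for i in range(5)],
        )
        res = nb_wald_test(counts, parental_groups(counts), base_mean_floor=20.0)
        assert not res["tested"].iloc[:10].any()
        assert res["p_raw"].iloc[:10].isna().all()
        assert res["tested"].iloc[10:].all()

    def test_zero_group_reports_finite_strong_signal(self, parental_groups):
        counts = pd.DataFrame(
            [[500] * 5 + [0] * 5] * 3,
            columns=[f"P1_{i}" for i in range(5)] + [f"P2_{i}" for i in range(5)],
        )
        res = nb_wald_test(
            counts,
            parental_groups(counts),
            size_factors=pd.Series(1.0, index=counts.columns),
            dispersion=pd.Series(0.05, index=counts.index),
        )
        assert np.isfinite(res["log2fc_raw"]).all()
        assert (res["log2fc_raw"] > 5).all()
        assert (res["p_raw"] < 0.05).all()


class TestShrinkage:
    def _frame(self, lfc, se):
        n = len(lfc)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "log2fc_raw": lfc,
                "log2fc_shrunk": lfc,
                "se": se,
                "tested": True,
            }
        )

    def test_posterior_mean_matches_conjugate_formula(self):
        # tau^2 estimated from many genes with true prior variance 1
        rng = np.random.default_rng(31)
        true = rng.normal(0, 1.0, size=4000)
        se = np.full(4000, 1.0)
        obs = true + rng.normal(0, se)
        res = shrink_lfc(self._frame(obs, se))
        # with tau^2 ~= 1 and se = 1 the posterior mean is raw/2
        idx = np.argmin(np.abs(obs - 2.0))
        assert res["log2fc_shrunk"].iloc[idx] == pytest.approx(1.0, rel=0.1)

    def test_zero_raw_stays_zero_and_small_se_unshrunk(self):
        res = shrink_lfc(self._frame([0.0, 3.0, -1.5], [0.5, 1e-9, 1e-9]))
        assert res["log2fc_shrunk"].iloc[0] == 0.0
        assert res["log2fc_shrunk"].iloc[1] == pytest.approx(3.0, rel=1e-4)
        assert res["log2fc_shrunk"].iloc[2] == pytest.approx(-1.5, rel=1e-4)

    def test_sign_preserved_and_magnitude_never_grows(self, small_sim, parental_groups):
        _, sim = small_sim
        res = nb_wald_test(sim.parental, parental_groups(sim.parental))
        raw = res["log2fc_raw"].to_numpy()
        shr = res["log2fc_shrunk"].to_numpy()
        assert (np.sign(shr) == np.sign(raw)).all() or (shr[np.sign(shr) != np.sign(raw)] == 0).all()
        assert (np.abs(shr) <= np.abs(raw) + 1e-12).all()


class TestBH:
    def test_hand_computed_step_up(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_classic_mixed_vector(self):
        # sorted: .005*3/1=.015, .03*3/2=.045, .04*3/3=.04; running min
        # from the largest rank pulls .045 down to .04
        adj = bh_adjust(np.array([0.005, 0.04, 0.03]))
        np.testing.assert_allclose(adj, [0.015, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.2])), [0.2])

    def test_nan_propagates_without_joining_family(self):
        adj = bh_adjust(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], [0.02, 0.02])

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_adjusted_at_least_raw_and_capped(self, ps):
        arr = np.array(ps)
        adj = bh_adjust(arr)
        assert (adj >= arr - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        # step-up preserves the p-value ordering
        order = np.argsort(arr, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestNullCalibration:
    def test_type_one_error_near_nominal(self, null_sim, parental_groups):
        _, sim = null_sim
        res = nb_wald_test(sim.parental, parental_groups(sim.parental))
        frac = float((res["p_raw"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07


@pytest.mark.filterwarnings("ignore")
def test_lfc_agrees_with_independent_nb_engine(parental_groups):
    """Cross-check raw log2 fold changes against DESeq2 (pydeseq2)."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    sim = simulate_counts(
        SimConfig(n_genes=150, seed=2, mean_log_expression=(math.log(300), 0.8), min_mean=50)
    )
    counts = sim.parental
    meta = pd.DataFrame(
        {"condition": ["P1"] * 5 + ["P2"] * 5}, index=counts.columns
    )
    dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
    dds.deseq2()
    stat = DeseqStats(dds, contrast=["condition", "P1", "P2"], quiet=True)
    stat.summary()
    ref = stat.results_df["log2FoldChange"]
    mine = nb_wald_test(counts, parental_groups(counts))["log2fc_raw"]
    r = np.corrcoef(ref, mine)[0, 1]
    assert r > 0.99
    strong = ref.abs() > 0.8
    assert (np.sign(ref[strong]) == np.sign(mine[strong])).all()
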