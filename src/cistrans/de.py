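"""Negative-binomial differential expression engine.

Implements the statistical primitive used by every contrast in the
pipeline: median-of-ratios normalization, method-of-moments dispersion
estimation with trend shrinkage, a two-group negative-binomial Wald test,
empirical-Bayes normal-prior shrinkage of log2 fold changes, and
Benjamini-Hochberg adjustment.

The NB model is parameterized by mean mu and dispersion alpha with
variance = mu + alpha * mu**2, the standard RNA-seq convention.  Group
means are fitted by Newton iteration on the NB score equation with
per-sample size factors as multiplicative offsets; the fit is vectorized
across genes.  Wald statistics use the observed Fisher information with a
standard-normal reference, the convention of NB-GLM RNA-seq engines; the
trend-shrunken dispersions keep five-replicate designs near nominal
type-I levels (verified by the calibration tests).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DEResult",
    "median_of_ratios",
    "estimate_dispersion",
    "nb_wald_test",
    "shrink_lfc",
    "bh_adjust",
]

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


def median_of_ratios(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """DESeq-style size factors: per sample, the median ratio to a per-gene
    geometric-mean reference, computed over genes with all-positive counts.

    Factors are centered to geometric mean 1.  With ``pseudo_reference`` the
    reference uses only the samples where a gene is positive ("poscounts"
    fallback), for matrices with no gene expressed everywhere.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factor estimation needs at least 2 samples")
    x = counts.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(x), np.nan)
        ref = np.exp(np.nanmean(logx, axis=1))
        use = ~np.all(np.isnan(logx), axis=1)
    else:
        use = np.all(x > 0, axis=1)
        if not use.any():
            raise ValueError(
                "no gene has positive counts in every sample; "
                "re-run with pseudo_reference=True"
            )
        ref = np.exp(np.mean(np.log(x[use]), axis=1))
        ref_full = np.zeros(x.shape[0])
        ref_full[use] = ref
        ref = ref_full
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = x[use] / ref[use, None]
    factors = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("degenerate size factors; check for all-zero samples")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _trend_fit(mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit alpha_tr(mu) = a1/mu + a0 by least squares on genes with
    positive raw dispersion estimates; coefficients clipped at 0."""
    ok = (disp > 0) & (mean > 0)
    if ok.sum() < 2:
        med = float(np.median(disp[disp > 0])) if (disp > 0).any() else 0.0
        return 0.0, max(med, DISPERSION_FLOOR)
    X = np.column_stack([1.0 / mean[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, disp[ok], rcond=None)
    a1, a0 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
    if a1 == 0.0 and a0 == 0.0:
        a0 = DISPERSION_FLOOR
    return a1, a0


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: pd.Series | None = None,
    trend_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion on normalized counts.

    Method-of-moments estimate alpha = max(0, (s^2 - mu)/mu^2), with the
    variance pooled within groups when group labels are given, then shrunk
    toward a fitted mean-dispersion trend a1/mu + a0 with the given weight.
    Floored at 1e-8.
    """
    y = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    if groups is None:
        groups = pd.Series("all", index=counts.columns)
    labels = groups.loc[counts.columns].to_numpy()
    uniq = np.unique(labels)
    if counts.shape[1] - len(uniq) < 1:
        raise ValueError("dispersion is not estimable without replication")
    # pooled within-group variance around group means
    ss = np.zeros(y.shape[0])
    for g in uniq:
        cols = labels == g
        if cols.sum() < 2:
            continue
        sub = y[:, cols]
        ss += np.sum((sub - sub.mean(axis=1, keepdims=True)) ** 2, axis=1)
    df = counts.shape[1] - len(uniq)
    s2 = ss / df
    mu = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
    raw = np.clip(raw, 0.0, None)
    a1, a0 = _trend_fit(mu, raw)
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a1 / mu + a0, a0)
    alpha = (1.0 - trend_weight) * raw + trend_weight * trend
    alpha = np.clip(alpha, DISPERSION_FLOOR, None)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _nb_fit_group(
    y: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Newton solve of the NB score equation for a common mean
    mu per gene with sample offsets sf; returns (mu_hat, fisher_info).

    Score: U(mu) = sum_i sf_i (y_i - sf_i mu) / (sf_i mu (1 + alpha sf_i mu))
    Info:  I(mu) = sum_i sf_i^2 / (sf_i mu (1 + alpha sf_i mu))
    With equal size factors mu_hat is the plain normalized mean.
    """
    tot_sf = sf.sum()
    mu = np.maximum(y.sum(axis=1) / tot_sf, 1e-10)
    for _ in range(n_iter):
        m = sf[None, :] * mu[:, None]
        w = 1.0 / (m * (1.0 + alpha[:, None] * m))
        U = np.sum(sf[None, :] * (y - m) * w, axis=1)
        Info = np.sum(sf[None, :] ** 2 * w, axis=1)
        step = U / Info
        mu_new = np.maximum(mu + step, mu * 1e-3)
        if np.max(np.abs(mu_new - mu) / np.maximum(mu, 1e-10)) < 1e-12:
            mu = mu_new
            break
        mu = mu_new
    m = sf[None, :] * mu[:, None]
    Info = np.sum(sf[None, :] ** 2 / (m * (1.0 + alpha[:, None] * m)), axis=1)
    return mu, Info


def nb_wald_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    size_factors: pd.Series | None = None,
    dispersion: pd.Series | None = None,
    base_mean_floor: float = 0.0,
    shrink: bool = True,
    group_dispersion: dict | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test with log link.

    ``groups`` maps sample id -> group label; the log2 fold change is
    group[0]-over-group[1] in the sorted unique label order unless
    ``groups`` is categorical with an explicit order.  Genes with base mean
    (mean of normalized counts over the contrast's samples) below
    ``base_mean_floor`` are excluded from testing and from the BH family;
    they are returned with ``tested=False`` and NaN p-values.
    ``group_dispersion`` optionally overrides the per-gene dispersion for
    individual group labels (used when one group's samples are derived
    quantities, e.g. averaged pseudo-replicates, with a different
    mean-variance relation).

    Returns a DataFrame with columns gene_id, base_mean, log2fc_raw,
    log2fc_shrunk, se, p_raw, p_adj, tested.
    """
    groups = groups.loc[counts.columns]
    if isinstance(groups.dtype, pd.CategoricalDtype):
        levels = [l for l in groups.cat.categories if (groups == l).any()]
    else:
        levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    g1, g2 = levels
    if size_factors is None:
        size_factors = median_of_ratios(counts)
    size_factors = size_factors.loc[counts.columns]
    if dispersion is None:
        dispersion = estimate_dispersion(counts, size_factors, groups)
    alpha = dispersion.loc[counts.index].to_numpy(dtype=float)

    y = counts.to_numpy(dtype=float)
    sf = size_factors.to_numpy(dtype=float)
    norm = y / sf[None, :]
    base_mean = norm.mean(axis=1)

    out = {}
    mask1 = (groups == g1).to_numpy()
    mask2 = (groups == g2).to_numpy()
    mus, infos = {}, {}
    for key, label, mask in ((1, g1, mask1), (2, g2, mask2)):
        yk, sfk = y[:, mask], sf[mask]
        ak = alpha
        if group_dispersion and label in group_dispersion:
            ak = group_dispersion[label].loc[counts.index].to_numpy(dtype=float)
        # zero groups: pseudo-total 0.5 keeps the estimate finite; the
        # Wald se then comes from the information at that floor
        mu, info = _nb_fit_group(yk, sfk, ak)
        zero = yk.sum(axis=1) == 0
        if zero.any():
            mu = np.where(zero, 0.5 / sfk.sum(), mu)
            m = sfk[None, :] * mu[:, None]
            info = np.sum(sfk[None, :] ** 2 / (m * (1 + ak[:, None] * m)), axis=1)
        mus[key], infos[key] = mu, info

    lfc = (np.log(mus[1]) - np.log(mus[2])) / LN2
    var_log = 1.0 / (infos[1] * mus[1] ** 2) + 1.0 / (infos[2] * mus[2] ** 2)
    se = np.sqrt(var_log) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    tested = base_mean >= base_mean_floor
    p = np.where(tested, p, np.nan)
    padj = np.full_like(p, np.nan)
    padj[tested] = bh_adjust(p[tested])

    res = pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": base_mean,
            "log2fc_raw": lfc,
            "log2fc_shrunk": lfc,
            "se": se,
            "p_raw": p,
            "p_adj": padj,
            "tested": tested,
            "dispersion": alpha,
        }
    ).set_index("gene_id", drop=False)
    res.index.name = None
    if shrink:
        res = shrink_lfc(res)
    return res


def _estimate_tau2(lfc: np.ndarray, se: np.ndarray) -> float:
    """Marginal-likelihood estimate of the prior variance tau^2 under
    lfc_i ~ N(0, tau^2 + se_i^2)."""

    def nll(log_tau2: float) -> float:
        v = np.exp(log_tau2) + se**2
        return float(0.5 * np.sum(np.log(v) + lfc**2 / v))

    res = optimize.minimize_scalar(nll, bounds=(-30.0, 10.0), method="bounded")
    tau2 = float(np.exp(res.x))
    return tau2 if tau2 > 1e-12 else 0.0


def shrink_lfc(results: pd.DataFrame) -> pd.DataFrame:
    """Normal-prior empirical-Bayes shrinkage of raw log2 fold changes.

    The prior N(0, tau^2) has tau^2 estimated by marginal likelihood over
    the tested genes; each shrunk estimate is the posterior mean
    lfc * tau^2/(tau^2 + se^2).  Shrinkage preserves sign, never increases
    magnitude, and vanishes as se -> 0.
    """
    res = results.copy()
    ok = res["tested"].to_numpy() & np.isfinite(res["log2fc_raw"]) & np.isfinite(res["se"])
    lfc = res.loc[ok, "log2fc_raw"].to_numpy(dtype=float)
    se = res.loc[ok, "se"].to_numpy(dtype=float)
    if lfc.size == 0:
        return res
    tau2 = _estimate_tau2(lfc, se)
    if tau2 == 0.0:
        warnings.warn("degenerate prior variance; all fold changes shrunk to 0")
        res.loc[ok, "log2fc_shrunk"] = 0.0
        return res
    res.loc[ok, "log2fc_shrunk"] = lfc * tau2 / (tau2 + se**2)
    return res


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    NaN inputs propagate NaN and are not counted in the family size.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    pv = arr[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out
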