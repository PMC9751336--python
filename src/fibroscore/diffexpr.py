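"""Normalization and two-group differential tests at the study's thresholds.

Transcripts are normalized with median-of-ratios size factors and tested on
log2(count/s_j + 1); proteins are total-area normalized and tested on log2
intensities. Both layers use a moderated t statistic: the per-feature pooled
variance is shrunk toward the mean variance across features with a
configurable prior degrees of freedom (default 4), and the reference
distribution is t with residual + prior df. Decision rules are asymmetric on
purpose: transcripts are called on the raw p-value (p < 0.1) with linear
fold change beyond +/-2, proteins on the Benjamini-Hochberg FDR (< 0.1) with
fold change beyond +/-1.5.

The transcript test is a log-scale approximation of a negative-binomial
count test; its guarantees here are calibration and recovery on synthetic
truth, not numerical replication of any count-GLM package.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import validate_design

DE_COLUMNS = [
    "feature_id", "mean_control", "mean_treated",
    "log2fc", "signed_fc", "p_value", "fdr", "call",
]


@dataclass(frozen=True)
class DEThresholds:
    transcript_p: float = 0.1
    transcript_fc: float = 2.0
    protein_fdr: float = 0.1
    protein_fc: float = 1.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over genes positive in every sample of c_gj / geomean_g(c_g.).
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene is positive in all samples; median-of-ratios undefined "
            "(consider a pseudo-reference fallback)"
        )
    ref = x[positive]
    geomean = np.exp(np.log(ref).mean(axis=1))
    sf = np.median(ref / geomean[:, None], axis=0)  # median on the ratio scale
    return pd.Series(sf, index=counts.columns, name="size_factor")


def total_area_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its total signal equals the mean column sum."""
    sums = intensities.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"zero-sum column {bad!r}: total-area normalization undefined")
    return intensities * (sums.mean() / sums)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-free)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def signed_fold_change(log2fc) -> np.ndarray:
    """Linear fold change in the negative-reciprocal convention (+/-2 = 2-fold)."""
    lfc = np.asarray(log2fc, dtype=float)
    return np.where(lfc >= 0, np.exp2(lfc), -np.exp2(-lfc))


def estimate_variance_prior(s2: np.ndarray, resid_df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of log(s^2) under the hierarchical model
    (sample variances are scaled chi-squares around gene variances drawn from
    the prior); the prior df solves a trigamma equation by Newton iteration.
    Returns (prior_df, prior_variance); prior_df is inf when the observed
    log-variance spread is no wider than pure chi-square noise.
    """
    z = np.log(np.maximum(s2, 1e-300))
    excess = z.var(ddof=1) - float(special.polygamma(1, resid_df / 2.0))
    if excess <= 1e-8:
        d0 = np.inf
        log_s02 = z.mean() - float(special.polygamma(0, resid_df / 2.0)) + np.log(resid_df / 2.0)
    else:
        x = 0.5 + 1.0 / excess
        for _ in range(100):
            step = special.polygamma(1, x) * (1 - special.polygamma(1, x) / excess) / special.polygamma(2, x)
            x += step
            if abs(step) < 1e-10:
                break
        d0 = 2.0 * float(x)
        log_s02 = (
            z.mean()
            + float(special.polygamma(0, d0 / 2.0)) - np.log(d0 / 2.0)
            - float(special.polygamma(0, resid_df / 2.0)) + np.log(resid_df / 2.0)
        )
    return d0, float(np.exp(log_s02))


def moderated_t_test(
    log_values: pd.DataFrame,
    control_samples: list[str],
    treated_samples: list[str],
    prior_df: float | str = "auto",
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t test on log-scale values.

    Pooled within-group variance per feature is shrunk toward a prior
    variance with ``prior_df`` prior degrees of freedom; two-sided p from t
    with residual + prior df. By default both prior parameters are estimated
    from the spread of the per-feature variances (method of moments on
    log s^2), which keeps the null calibrated whether or not the true
    variances are homogeneous; pass a number to fix the prior df, in which
    case the prior variance is the mean of the per-feature variances.
    """
    n0, n1 = len(control_samples), len(treated_samples)
    if n0 < 2 or n1 < 2:
        raise ValueError("each group needs >= 2 replicates")
    x0 = log_values[control_samples].to_numpy(dtype=float)
    x1 = log_values[treated_samples].to_numpy(dtype=float)
    m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
    resid_df = n0 + n1 - 2
    ss = ((x0 - m0[:, None]) ** 2).sum(axis=1) + ((x1 - m1[:, None]) ** 2).sum(axis=1)
    s2 = ss / resid_df
    if float(s2.mean()) <= 0:
        raise ValueError("zero within-group variance everywhere; test undefined")
    if prior_df == "auto":
        d0, s2_prior = estimate_variance_prior(s2, resid_df)
    else:
        d0, s2_prior = float(prior_df), float(s2.mean())
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s2_prior)
        df_total = 1e6  # effectively a z-test against the common variance
    else:
        s2_mod = (d0 * s2_prior + resid_df * s2) / (d0 + resid_df)
        df_total = resid_df + d0
    se = np.sqrt(s2_mod * (1.0 / n0 + 1.0 / n1))
    tstat = (m1 - m0) / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=min(df_total, 1e6))
    return pd.DataFrame(
        {"mean_log_control": m0, "mean_log_treated": m1, "log2fc": m1 - m0,
         "t": tstat, "p_value": p},
        index=log_values.index,
    )


def de_test(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    source: str,
    layer: str,
    sample_size_factors: pd.Series | None = None,
    prior_df: float | str = "auto",
    thresholds: DEThresholds | None = None,
) -> pd.DataFrame:
    """Control-vs-treated test within one source, with the layer's call rule.

    Returns a table with columns ``feature_id, mean_control, mean_treated,
    log2fc, signed_fc, p_value, fdr, call`` sorted by feature id (BH ties are
    thereby reported in a deterministic order).
    """
    if layer not in ("transcript", "protein"):
        raise ValueError(f"unknown layer {layer!r}")
    thresholds = thresholds or DEThresholds()
    validate_design(matrix, design)
    sub = design[design["source"] == source]
    if sub.empty:
        raise ValueError(f"unknown source {source!r}")
    controls = sub.loc[sub["condition"] == "control", "sample_id"].tolist()
    treateds = sub.loc[sub["condition"] == "treated", "sample_id"].tolist()

    if layer == "transcript":
        sf = sample_size_factors if sample_size_factors is not None else size_factors(matrix)
        sf = sf.reindex(matrix.columns)
        norm = matrix.astype(float).div(sf, axis=1)
        logv = np.log2(norm + 1.0)
    else:
        norm = total_area_normalize(matrix.astype(float))
        if (norm.to_numpy() <= 0).any():
            raise ValueError("protein intensities must be strictly positive")
        logv = np.log2(norm)

    res = moderated_t_test(logv, controls, treateds, prior_df=prior_df)
    res = res.sort_index()
    norm = norm.loc[res.index]
    fdr = bh_adjust(res["p_value"].to_numpy())
    sfc = signed_fold_change(res["log2fc"].to_numpy())

    if layer == "transcript":
        sig = (res["p_value"].to_numpy() < thresholds.transcript_p) & (
            np.abs(sfc) > thresholds.transcript_fc
        )
    else:
        sig = (fdr < thresholds.protein_fdr) & (np.abs(sfc) > thresholds.protein_fc)
    call = np.where(~sig, "ns", np.where(res["log2fc"].to_numpy() > 0, "up", "down"))

    return pd.DataFrame(
        {
            "feature_id": res.index,
            "mean_control": norm[controls].mean(axis=1).to_numpy(),
            "mean_treated": norm[treateds].mean(axis=1).to_numpy(),
            "log2fc": res["log2fc"].to_numpy(),
            "signed_fc": sfc,
            "p_value": res["p_value"].to_numpy(),
            "fdr": fdr,
            "call": call,
        }
    ).reset_index(drop=True)


def de_calls(de: pd.DataFrame, direction: str | None = None) -> set[str]:
    """Feature ids called differential (optionally one direction only)."""
    if direction is None:
        keep = de["call"] != "ns"
    elif direction in ("up", "down"):
        keep = de["call"] == direction
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return set(de.loc[keep, "feature_id"])
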