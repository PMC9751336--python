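"""Term enrichment of gene sets and sign-consistency regulator calls.

Enrichment is the one-sided hypergeometric tail (optionally the EASE
variant, which decrements the observed overlap by one before taking the
tail). Regulator activation uses the sign-consistency statistic
z = (N+ - N-) / sqrt(N+ + N-) over a regulator's differentially expressed
targets, with an overlap-significance gate (Fisher/hypergeometric p of the
target-DEG overlap) before any activated/inhibited call; thresholds default
to the |z| > 3 and -log10(p) > 1 convention.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def enrich_terms(
    query_set,
    universe,
    term_sets: dict[str, dict],
    min_overlap: int = 1,
    ease: bool = False,
) -> pd.DataFrame:
    """Rank terms by hypergeometric over-representation of the query.

    Terms overlapping the query by fewer than ``min_overlap`` genes are
    excluded; the rest are BH-adjusted and sorted by (p, term_id).
    """
    query = set(query_set)
    uni = set(universe)
    stray = query - uni
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    N, n = len(uni), len(query)
    rows = []
    for term_id in sorted(term_sets):
        info = term_sets[term_id]
        members = set(info["genes"]) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        if k < min_overlap:
            continue
        k_eff = max(k - 1, 0) if ease else k
        p = float(stats.hypergeom.sf(k_eff - 1, N, K, n)) if k_eff > 0 else 1.0
        rows.append((term_id, info.get("label", term_id), K, k, p))
    out = pd.DataFrame(rows, columns=["term_id", "label", "term_size", "overlap", "p_value"])
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    else:
        out["fdr"] = []
    return out


def top_terms(enriched: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """The n smallest-p terms (ties already broken lexically by term_id)."""
    return enriched.head(n).reset_index(drop=True)


def regulator_activation(
    de_result: pd.DataFrame,
    edges: pd.DataFrame,
    z_threshold: float = 3.0,
    overlap_p_max: float | None = 0.1,
) -> pd.DataFrame:
    """Sign-consistency activation z per regulator with thresholded calls.

    Over a regulator's targets that are DEGs, N+ counts targets where the
    edge sign matches the fold-change sign, N- the rest;
    z = (N+ - N-)/sqrt(N+ + N-). Calls are strict: activated iff
    z > z_threshold, inhibited iff z < -z_threshold, and only when the
    hypergeometric overlap p of the regulator's targets with the DEG set is
    below ``overlap_p_max`` (None disables the gate). Regulators with no DEG
    target are reported untestable.
    """
    if edges.duplicated(["regulator", "target"]).any():
        raise ValueError("duplicate (regulator, target) rows")
    de = de_result.set_index("feature_id")
    universe = set(de.index)
    stray = set(edges["target"]) - universe
    if stray:
        raise ValueError(f"regulator targets outside the DE universe: {sorted(stray)[:5]}")
    degs = de.index[de["call"] != "ns"]
    deg_sign = np.sign(de.loc[degs, "log2fc"]).to_dict()
    N_universe, n_deg = len(universe), len(degs)

    rows = []
    for reg, grp in edges.groupby("regulator", sort=True):
        targets = grp["target"].tolist()
        signs = grp["sign"].to_numpy()
        hits = [(t, s) for t, s in zip(targets, signs) if t in deg_sign]
        n_t = len(targets)
        k = len(hits)
        if k == 0:
            rows.append((reg, n_t, 0, 0, 0, float("nan"), float("nan"), "untestable"))
            continue
        n_plus = sum(1 for t, s in hits if s * deg_sign[t] > 0)
        n_minus = k - n_plus
        z = (n_plus - n_minus) / np.sqrt(k)
        overlap_p = float(stats.hypergeom.sf(k - 1, N_universe, n_deg, n_t))
        call = "none"
        gated = overlap_p_max is not None and overlap_p >= overlap_p_max
        if not gated:
            if z > z_threshold:
                call = "activated"
            elif z < -z_threshold:
                call = "inhibited"
        rows.append((reg, n_t, k, n_plus, n_minus, float(z), overlap_p, call))
    return pd.DataFrame(
        rows,
        columns=["regulator", "n_targets", "n_deg_targets", "n_consistent",
                 "n_inconsistent", "z", "overlap_p", "call"],
    )
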