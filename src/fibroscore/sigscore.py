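"""Summed-z activation scoring of a marker-gene panel, with group tests.

The activation score of sample j is S_j = sum over panel genes g of
z_gj, where z_gj standardizes L_gj = log2(c_gj / s_j + 1) across all samples
jointly (sample standard deviation, n-1 denominator). Joint standardization
is what makes scores comparable across cell sources on one axis. Because each
z row sums to zero, the scores sum to zero over the analyzed sample set by
construction. Group differences are assessed by two-way fixed-effects ANOVA
(source, condition, interaction) followed by Tukey HSD on the
source x condition cell means.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import validate_design


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene panel must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene panel contains duplicates")


@dataclass
class ActivationResult:
    scores: pd.Series                 # per-sample S_j
    z_matrix: pd.DataFrame            # used genes x samples
    used_genes: list[str]
    dropped_genes: list[str]          # absent or zero-variance panel genes
    anova: pd.DataFrame | None = None
    tukey: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def log_normalized(counts: pd.DataFrame, size_factors: pd.Series | None = None) -> pd.DataFrame:
    """L = log2(count / s_j + 1); s_j = 1 when no size factors are given."""
    if size_factors is None:
        return np.log2(counts.astype(float) + 1.0)
    sf = size_factors.reindex(counts.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    return np.log2(counts.astype(float).div(sf, axis=1) + 1.0)


def scores_from_log(log_matrix: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """z-score each gene row jointly over all samples and sum per sample.

    Returns (scores, z matrix of used genes, zero-variance genes dropped).
    Zero-variance genes contribute 0 to every score.
    """
    if log_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for z-score standardization")
    means = log_matrix.mean(axis=1)
    sds = log_matrix.std(axis=1, ddof=1)
    zero_var = sds <= 0
    used = log_matrix.index[~zero_var]
    z = log_matrix.loc[used].sub(means[used], axis=0).div(sds[used], axis=0)
    scores = z.sum(axis=0)
    scores.name = "activation_score"
    return scores, z, list(log_matrix.index[zero_var])


def compute_activation_scores(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    panel: GenePanel,
    size_factors: pd.Series | None = None,
) -> ActivationResult:
    """Score each sample by the summed z of the panel genes' log expression."""
    validate_design(counts, design)
    present = [g for g in panel.genes if g in counts.index]
    absent = [g for g in panel.genes if g not in counts.index]
    if absent:
        warnings.warn(
            f"{len(absent)} panel gene(s) absent from the matrix: {absent[:5]}...",
            stacklevel=2,
        )
    if not present:
        raise ValueError("no panel gene overlaps the matrix features")
    L = log_normalized(counts.loc[present], size_factors)
    scores, z, zero_var = scores_from_log(L)
    used = [g for g in present if g not in set(zero_var)]
    if not used:
        raise ValueError("every overlapping panel gene has zero variance")
    # order scores by the sample sheet
    scores = scores.reindex(design["sample_id"])
    return ActivationResult(
        scores=scores,
        z_matrix=z,
        used_genes=used,
        dropped_genes=absent + zero_var,
    )


def test_score_differences(result: ActivationResult, design: pd.DataFrame) -> ActivationResult:
    """Two-way ANOVA (source x condition) plus Tukey HSD on the six cells.

    Mutates and returns ``result`` with ``anova`` and ``tukey`` tables.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = design.copy()
    df["score"] = result.scores.reindex(df["sample_id"]).to_numpy()
    if df["source"].nunique() < 2 or df["condition"].nunique() < 2:
        raise ValueError("two-way ANOVA needs >= 2 sources and both conditions")
    cells = df.groupby(["source", "condition"], observed=True).size()
    expected = df["source"].nunique() * df["condition"].nunique()
    if len(cells) < expected or (cells < 2).any():
        bad = [
            f"{s}:{c}"
            for (s, c), n in cells.items()
            if n < 2
        ] or ["missing cell"]
        raise ValueError(f"unbalanced or empty design cell(s): {bad}")

    model = ols("score ~ C(source) * C(condition)", data=df).fit()
    if model.mse_resid < 1e-12:
        raise ValueError(
            "zero residual variance: group tests degenerate (identical scores within cells)"
        )
    anova = sm.stats.anova_lm(model, typ=2)
    cell_labels = (df["source"] + ":" + df["condition"]).to_numpy()
    tk = pairwise_tukeyhsd(df["score"].to_numpy(), cell_labels)
    tukey = pd.DataFrame(
        tk.summary().data[1:],
        columns=[str(c) for c in tk.summary().data[0]],
    )
    tukey["p-adj"] = np.asarray(tk.pvalues, dtype=float)
    result.anova = anova
    result.tukey = tukey
    return result


def tukey_contrast(tukey: pd.DataFrame, cell_a: str, cell_b: str) -> float:
    """Adjusted p for a given pair of source:condition cells."""
    hit = tukey[
        ((tukey["group1"] == cell_a) & (tukey["group2"] == cell_b))
        | ((tukey["group1"] == cell_b) & (tukey["group2"] == cell_a))
    ]
    if hit.empty:
        raise KeyError(f"no Tukey contrast {cell_a} vs {cell_b}")
    return float(hit["p-adj"].iloc[0])
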