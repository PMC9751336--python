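"""Transcript-proteome integration: matching, correlations, clustering, PCA.

Fold-change correlations are computed on log2 fold changes (Pearson r on
signed linear fold changes would be discontinuous at +/-1). Sample-level
similarity uses Pearson correlation of log2 values with distance 1 - r and
average linkage; dendrograms export to Newick.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class FeatureMap:
    pairs: pd.DataFrame     # columns gene_id, protein_id
    coverage: float         # fraction of all proteins with a matched transcript


@dataclass
class FCCorrelation:
    r: float
    n: int
    defined: bool


@dataclass
class SampleClustering:
    corr: pd.DataFrame
    linkage: np.ndarray
    newick: str
    undefined_samples: list[str]


@dataclass
class PCAResult:
    coordinates: pd.DataFrame          # samples x components
    explained_fraction: np.ndarray


def match_features(transcript_ids, protein_ids, mapping: pd.DataFrame) -> FeatureMap:
    """Pair proteins with transcripts through the mapping table.

    Coverage is computed over *all* proteins, so unmapped proteins and
    proteins mapping to absent transcripts dilute it.
    """
    if mapping["protein_id"].duplicated().any():
        dup = mapping.loc[mapping["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise ValueError(f"duplicate protein_id {dup!r} in mapping")
    tset, pset = set(transcript_ids), set(protein_ids)
    keep = mapping["protein_id"].isin(pset) & mapping["gene_id"].isin(tset)
    pairs = mapping.loc[keep, ["gene_id", "protein_id"]].reset_index(drop=True)
    coverage = len(pairs) / len(pset) if pset else 0.0
    return FeatureMap(pairs=pairs, coverage=coverage)


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(stats.pearsonr(x, y).statistic)


def fc_correlation(
    de_transcript: pd.DataFrame,
    de_protein: pd.DataFrame,
    fmap: FeatureMap,
    restrict_to_dep: bool = False,
) -> FCCorrelation:
    """Pearson r between transcript and protein log2 fold changes.

    ``restrict_to_dep`` keeps only pairs whose protein call is not 'ns'.
    Fewer than 3 pairs after restriction is flagged undefined rather than
    returning a silent NaN.
    """
    t = de_transcript.set_index("feature_id")
    p = de_protein.set_index("feature_id")
    pairs = fmap.pairs
    pairs = pairs[pairs["gene_id"].isin(t.index) & pairs["protein_id"].isin(p.index)]
    if restrict_to_dep:
        dep = set(p.index[p["call"] != "ns"])
        pairs = pairs[pairs["protein_id"].isin(dep)]
    n = len(pairs)
    if n < 3:
        return FCCorrelation(r=float("nan"), n=n, defined=False)
    r = pearson(
        t.loc[pairs["gene_id"], "log2fc"].to_numpy(),
        p.loc[pairs["protein_id"], "log2fc"].to_numpy(),
    )
    return FCCorrelation(r=r, n=n, defined=True)


def location_prevalence(
    features, dep_features, location_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-location fractions for the full set and the DEP-restricted set.

    Features missing from the table are bucketed as 'other'. Each column
    sums to 1.
    """
    loc = location_table.set_index("feature_id")["location"]
    from .io import LOCATIONS

    def fractions(ids) -> pd.Series:
        ids = list(ids)
        assigned = loc.reindex(ids).fillna("other")
        frac = assigned.value_counts(normalize=True)
        return frac.reindex(LOCATIONS, fill_value=0.0)

    out = pd.DataFrame({"all": fractions(features)})
    out["dep"] = fractions(dep_features) if len(list(dep_features)) else 0.0
    out.index.name = "location"
    return out


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.10g}"

    return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"


def sample_correlation_clustering(
    matrix: pd.DataFrame, feature_subset=None, log_transform: bool = True
) -> SampleClustering:
    """Pairwise sample Pearson correlation and average-linkage clustering.

    Works on log2 values of the selected features; distance is 1 - r.
    Samples that are constant across the subset have undefined correlations
    (NaN) and are reported; clustering then refuses to proceed.
    """
    sub = matrix.loc[list(feature_subset)] if feature_subset is not None else matrix
    if sub.shape[0] < 2:
        raise ValueError("need >= 2 features for sample correlation")
    x = np.log2(sub.to_numpy(dtype=float)) if log_transform else sub.to_numpy(dtype=float)
    sds = x.std(axis=0)
    undefined = [str(c) for c, s in zip(sub.columns, sds) if s == 0]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr_df = pd.DataFrame(corr, index=sub.columns, columns=sub.columns)
    if undefined:
        return SampleClustering(corr=corr_df, linkage=np.empty((0, 4)),
                                newick="", undefined_samples=undefined)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    newick = _linkage_to_newick(Z, [str(c) for c in sub.columns])
    return SampleClustering(corr=corr_df, linkage=Z, newick=newick, undefined_samples=[])


def top_split(clustering: SampleClustering) -> tuple[set[str], set[str]]:
    """The two sample groups defined by the root of the dendrogram."""
    labels = list(clustering.corr.columns)
    assign = hierarchy.fcluster(clustering.linkage, t=2, criterion="maxclust")
    a = {l for l, k in zip(labels, assign) if k == 1}
    b = {l for l, k in zip(labels, assign) if k == 2}
    return a, b


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """SVD-based PCA of samples (observations) in feature space.

    The observation matrix (samples x features) is column-centered; scores
    are U * S and explained fractions are the normalized squared singular
    values.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 features")
    X = matrix.to_numpy(dtype=float).T       # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    total = float((S**2).sum())
    explained = (S**2) / total if total > 0 else np.zeros_like(S)
    k = n_components or min(len(S), 10)
    scores = U[:, :k] * S[:k]
    coords = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    return PCAResult(coordinates=coords, explained_fraction=explained[:k])
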