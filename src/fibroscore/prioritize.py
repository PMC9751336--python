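"""Target-prioritization cascade over upregulated differential proteins.

Filter the upregulated proteins for prior association with one of the four
fibrosis indications (pulmonary, cardiac, hepatic, renal), expand the
associated seed set one hop through high-confidence interaction edges
(combined score >= 0.7, inclusive, mirroring the 'high confidence' setting),
restricted to the upregulated candidates themselves (disconnected candidates
stay hidden), annotate drug availability, and assemble a deterministically
ranked panel.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .io import FIBROSIS_DISEASES


@dataclass
class DiseaseAssociation:
    genes: list[str]
    detail: pd.DataFrame    # qualifying (gene_id, disease, score) rows


@dataclass
class NetworkExpansion:
    added: list[str]
    partners: dict[str, list[str]]   # added gene -> seed partners


def intersect_sources(sets_by_source: dict[str, set], direction: str | None = None,
                      de_by_source: dict[str, pd.DataFrame] | None = None) -> dict[tuple, set]:
    """All 2^k - 1 disjoint Venn regions of per-source feature sets.

    Accepts either ready-made sets or DE tables plus a direction
    ('up'/'down'). Region keys are tuples of the member sources, sorted.
    """
    if de_by_source is not None:
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        sets_by_source = {
            src: set(de.loc[de["call"] == direction, "feature_id"])
            for src, de in de_by_source.items()
        }
    sources = sorted(sets_by_source)
    if len(sources) < 2:
        raise ValueError("need >= 2 sources for an intersection diagram")
    regions: dict[tuple, set] = {}
    for r in range(1, len(sources) + 1):
        for inside in combinations(sources, r):
            members = set.intersection(*(sets_by_source[s] for s in inside))
            for s in sources:
                if s not in inside:
                    members -= sets_by_source[s]
            regions[inside] = members
    return regions


def filter_disease_associated(
    upregulated: set, gda: pd.DataFrame, min_score: float = 0.0
) -> DiseaseAssociation:
    """Genes with >= 1 fibrosis-disease row scoring above ``min_score``.

    Any positive association counts by default: the source database keeps
    low-score rows and so does the cascade.
    """
    rows = gda[
        gda["gene_id"].isin(upregulated)
        & gda["disease"].isin(FIBROSIS_DISEASES)
        & (gda["score"] > min_score)
    ]
    detail = rows.sort_values(["gene_id", "disease"], kind="stable").reset_index(drop=True)
    return DiseaseAssociation(genes=sorted(set(detail["gene_id"])), detail=detail)


def expand_network(
    seed_set: set,
    candidate_set: set,
    network: pd.DataFrame,
    min_score: float = 0.7,
) -> NetworkExpansion:
    """One-hop high-confidence expansion restricted to the candidate set.

    A candidate outside the seeds is added when it shares at least one edge
    of combined score >= min_score with a seed member; everything else stays
    disconnected and hidden.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    seeds = set(seed_set)
    cands = set(candidate_set) - seeds
    strong = network[network["combined_score"] >= min_score]
    partners: dict[str, set] = {}
    for a, b in zip(strong["node_a"], strong["node_b"]):
        if a in cands and b in seeds:
            partners.setdefault(a, set()).add(b)
        if b in cands and a in seeds:
            partners.setdefault(b, set()).add(a)
    return NetworkExpansion(
        added=sorted(partners),
        partners={g: sorted(p) for g, p in sorted(partners.items())},
    )


def annotate_drugs(panel_members, drug_table: pd.DataFrame) -> pd.DataFrame:
    """Availability flag plus drug name/status list per panel member."""
    rows = []
    for g in sorted(set(panel_members)):
        hits = drug_table[drug_table["gene_id"] == g]
        rows.append(
            {
                "gene_id": g,
                "drug_available": bool(len(hits)),
                "drugs": ";".join(
                    f"{r.drug_name}({r.status})" for r in hits.itertuples()
                ),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "drug_available", "drugs"])


def build_panel(
    associated: DiseaseAssociation,
    expansion: NetworkExpansion,
    up_by_source: dict[str, set],
    drug_table: pd.DataFrame,
    network: pd.DataFrame,
    min_score: float = 0.7,
) -> pd.DataFrame:
    """Assemble the ranked target panel with provenance.

    Rank key: number of sources where upregulated (desc), max association
    score (desc), high-confidence degree to disease-associated members
    (desc), then gene id - a deterministic total order.
    """
    assoc_set = set(associated.genes)
    members = sorted(assoc_set | set(expansion.added))
    gda_max = associated.detail.groupby("gene_id")["score"].max()
    diseases = associated.detail.groupby("gene_id")["disease"].apply(
        lambda d: ";".join(sorted(d))
    )
    strong = network[network["combined_score"] >= min_score]
    degree = {g: 0 for g in members}
    for a, b in zip(strong["node_a"], strong["node_b"]):
        if a in degree and b in assoc_set:
            degree[a] += 1
        if b in degree and a in assoc_set:
            degree[b] += 1
    drugs = annotate_drugs(members, drug_table).set_index("gene_id")

    rows = []
    for g in members:
        n_up = sum(1 for s in sorted(up_by_source) if g in up_by_source[s])
        rows.append(
            {
                "gene_id": g,
                "provenance": "disease-associated" if g in assoc_set else "network-added",
                "max_gda_score": float(gda_max.get(g, 0.0)),
                "diseases": diseases.get(g, ""),
                "fibrosis_partners": ";".join(expansion.partners.get(g, [])),
                "sources_upregulated": ";".join(
                    s for s in sorted(up_by_source) if g in up_by_source[s]
                ),
                "n_sources_upregulated": n_up,
                "hc_degree_to_associated": degree[g],
                "drug_available": bool(drugs.loc[g, "drug_available"]),
                "drugs": drugs.loc[g, "drugs"],
            }
        )
    panel = pd.DataFrame(rows)
    if len(panel):
        panel = panel.sort_values(
            by=["n_sources_upregulated", "max_gda_score", "hc_degree_to_associated", "gene_id"],
            ascending=[False, False, False, True],
            kind="stable",
        ).reset_index(drop=True)
        panel.insert(0, "rank", range(1, len(panel) + 1))
    return panel


def venn_to_json(regions: dict[tuple, set]) -> dict[str, dict]:
    return {
        "&".join(k): {"n": len(v), "members": sorted(v)} for k, v in sorted(regions.items())
    }
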