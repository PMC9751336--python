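"""Seeded end-to-end driver: simulate/load -> score -> DE -> integrate ->
annotate -> prioritize, with a machine-readable run manifest.

Every artifact is TSV/JSON/GMT/Newick written with fixed float formatting,
so identical config + seed reproduces byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__, annotate, crossomics, diffexpr, io, prioritize, sigscore, synthdata


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, thresholds and seed of one pipeline run.

    Thresholds default to the study's printed decision rules: transcript
    p < 0.1 with |FC| > 2, protein FDR < 0.1 with |FC| > 1.5, network
    confidence >= 0.7, regulator |z| > 3.
    """

    outdir: str = "fibroscore_run"
    seed: int = 0
    simulate: bool = True
    # input paths (used when simulate is False)
    counts: str | None = None
    intensities: str | None = None
    samples: str | None = None
    mapping: str | None = None
    gda: str | None = None
    network: str | None = None
    locations: str | None = None
    drugs: str | None = None
    terms: str | None = None
    regulators: str | None = None
    panel: str | None = None
    # thresholds
    transcript_p: float = 0.1
    transcript_fc: float = 2.0
    protein_fdr: float = 0.1
    protein_fc: float = 1.5
    network_min_score: float = 0.7
    regulator_z: float = 3.0
    gda_min_score: float = 0.0
    use_size_factors: bool = True

    def __post_init__(self):
        for name in ("transcript_p", "transcript_fc", "protein_fdr",
                     "protein_fc", "regulator_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if not 0.0 <= self.network_min_score <= 1.0:
            raise ValueError("network_min_score must lie in [0, 1]")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        study = synthdata.simulate_all(synthdata.make_fixture_config(seed=config.seed))
        return study
    required = ("counts", "intensities", "samples", "mapping", "gda",
                "network", "locations", "drugs")
    missing = [k for k in required if getattr(config, k) is None]
    if missing:
        raise ValueError(f"simulate=False but input paths missing: {missing}")
    counts = io.read_matrix(config.counts, "counts")
    design = io.read_sample_sheet(config.samples)
    io.validate_design(counts, design)
    intensities = io.read_matrix(config.intensities, "intensities")
    io.validate_design(intensities, design)
    ann = synthdata.AnnotationBundle(
        gda=io.read_gda(config.gda),
        network=io.read_network(config.network),
        locations=io.read_locations(config.locations),
        drugs=io.read_drugs(config.drugs),
        term_sets=io.read_gmt(config.terms) if config.terms else {},
        regulators=io.read_regulators(config.regulators) if config.regulators else
        pd.DataFrame(columns=["regulator", "target", "sign"]),
    )
    return synthdata.SimulatedStudy(
        config=None, counts=counts, intensities=intensities, design=design,
        mapping=io.read_mapping(config.mapping), annotations=ann,
        truth=synthdata.GroundTruth(deg_sets={}, panel_response={}),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = diffexpr.DEThresholds(
        transcript_p=config.transcript_p, transcript_fc=config.transcript_fc,
        protein_fdr=config.protein_fdr, protein_fc=config.protein_fc,
    )
    artifacts: dict[str, Path] = {}
    summary: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrap

    study = stage("inputs")(lambda: _load_inputs(config))
    design = study.design
    sources = sorted(design["source"].unique())

    if config.simulate:
        paths = synthdata.write_study(study, out / "inputs")
        artifacts.update({f"input_{k}": Path(v) for k, v in paths.items()})

    # --- activation score ---------------------------------------------------
    def _score():
        panel_genes = (io.read_panel(config.panel) if config.panel
                       else io.read_panel(io.default_panel_path()))
        panel = sigscore.GenePanel(name="cf_activation", genes=tuple(panel_genes))
        sf = diffexpr.size_factors(study.counts) if config.use_size_factors else None
        res = sigscore.compute_activation_scores(study.counts, design, panel, sf)
        return sigscore.test_score_differences(res, design)

    activation = stage("activation_score")(_score)
    p = out / "activation_scores.tsv"
    score_tbl = design.copy()
    score_tbl["activation_score"] = activation.scores.to_numpy()
    score_tbl.to_csv(p, sep="\t", index=False, float_format="%.10g")
    artifacts["activation_scores"] = p
    p = out / "activation_tests.json"
    io.write_json(
        {
            "anova": {
                str(k): {"F": _nan_none(v["F"]), "p": _nan_none(v["PR(>F)"])}
                for k, v in activation.anova.iterrows()
            },
            "tukey": activation.tukey.astype(str).to_dict(orient="records"),
            "used_genes": activation.used_genes,
            "dropped_genes": activation.dropped_genes,
        },
        p,
    )
    artifacts["activation_tests"] = p
    summary["mean_score_by_group"] = {
        f"{s}:{c}": float(score_tbl.loc[(score_tbl["source"] == s) & (score_tbl["condition"] == c),
                                        "activation_score"].mean())
        for s in sources for c in ("control", "treated")
    }

    # --- differential expression -------------------------------------------
    sf = diffexpr.size_factors(study.counts)
    de_t: dict[str, pd.DataFrame] = {}
    de_p: dict[str, pd.DataFrame] = {}
    for src in sources:
        de_t[src] = stage(f"de_transcript[{src}]")(
            lambda s=src: diffexpr.de_test(study.counts, design, s, "transcript",
                                           sample_size_factors=sf, thresholds=thresholds)
        )
        de_p[src] = stage(f"de_protein[{src}]")(
            lambda s=src: diffexpr.de_test(study.intensities, design, s, "protein",
                                           thresholds=thresholds)
        )
        for layer, table in (("transcript", de_t[src]), ("protein", de_p[src])):
            p = out / f"de_{layer}_{src}.tsv"
            table.to_csv(p, sep="\t", index=False, float_format="%.10g")
            artifacts[f"de_{layer}_{src}"] = p
    summary["deg_counts"] = {
        src: {"up": int((de_t[src]["call"] == "up").sum()),
              "down": int((de_t[src]["call"] == "down").sum())}
        for src in sources
    }
    summary["dep_counts"] = {
        src: {"up": int((de_p[src]["call"] == "up").sum()),
              "down": int((de_p[src]["call"] == "down").sum())}
        for src in sources
    }

    # --- cross-omics integration -------------------------------------------
    fmap = crossomics.match_features(
        study.counts.index, study.intensities.index, study.mapping
    )
    summary["transcript_protein_coverage"] = fmap.coverage
    pooled_t = _pool_de(de_t)
    pooled_p = _pool_de(de_p)
    r_all = crossomics.fc_correlation(pooled_t, pooled_p, fmap, restrict_to_dep=False)
    r_dep = crossomics.fc_correlation(pooled_t, pooled_p, fmap, restrict_to_dep=True)
    summary["fc_correlation"] = {
        "r_all": _nan_none(r_all.r), "n_all": r_all.n,
        "r_dep": _nan_none(r_dep.r), "n_dep": r_dep.n,
    }

    dep_union = sorted({f for t in de_p.values() for f in diffexpr.de_calls(t)})
    prevalence = crossomics.location_prevalence(
        study.intensities.index, dep_union, study.annotations.locations
    )
    p = out / "location_prevalence.tsv"
    prevalence.to_csv(p, sep="\t", float_format="%.10g")
    artifacts["location_prevalence"] = p
    summary["ecm_membrane_prevalence"] = {
        "all": float(prevalence.loc[["extracellular space", "plasma membrane"], "all"].sum()),
        "dep": float(prevalence.loc[["extracellular space", "plasma membrane"], "dep"].sum()),
    }

    loc = study.annotations.locations.set_index("feature_id")["location"]
    ecm_dep = [f for f in dep_union
               if loc.get(f) in ("extracellular space", "plasma membrane")]
    if len(ecm_dep) >= 2:
        clust = crossomics.sample_correlation_clustering(study.intensities, ecm_dep)
        p = out / "sample_correlation.tsv"
        clust.corr.to_csv(p, sep="\t", float_format="%.10g")
        artifacts["sample_correlation"] = p
        if clust.newick:
            p = out / "sample_dendrogram.nwk"
            p.write_text(clust.newick + "\n")
            artifacts["sample_dendrogram"] = p

    pca_res = crossomics.pca(sigscore.log_normalized(study.counts, sf))
    p = out / "pca_coordinates.tsv"
    coords = pca_res.coordinates.copy()
    coords.index.name = "sample_id"
    coords.to_csv(p, sep="\t", float_format="%.10g")
    artifacts["pca_coordinates"] = p
    summary["pca_explained_fraction"] = [float(v) for v in pca_res.explained_fraction[:3]]

    # --- annotation ---------------------------------------------------------
    if study.annotations.term_sets:
        universe = list(study.counts.index)
        for src in sources:
            degs = diffexpr.de_calls(de_t[src])
            enriched = annotate.enrich_terms(degs & set(universe), universe,
                                             study.annotations.term_sets)
            p = out / f"enrichment_{src}.tsv"
            enriched.to_csv(p, sep="\t", index=False, float_format="%.10g")
            artifacts[f"enrichment_{src}"] = p
    if len(study.annotations.regulators):
        reg_calls = {}
        for src in sources:
            reg = annotate.regulator_activation(
                de_t[src], study.annotations.regulators, z_threshold=config.regulator_z
            )
            p = out / f"regulators_{src}.tsv"
            reg.to_csv(p, sep="\t", index=False, float_format="%.10g")
            artifacts[f"regulators_{src}"] = p
            reg_calls[src] = dict(zip(reg["regulator"], reg["call"]))
        summary["regulator_calls"] = reg_calls

    # --- prioritization -----------------------------------------------------
    gene_of = study.mapping.set_index("protein_id")["gene_id"]
    up_by_source = {
        src: {gene_of[f] for f in diffexpr.de_calls(de_p[src], "up") if f in gene_of.index}
        for src in sources
    }
    venn_up = prioritize.intersect_sources(up_by_source)
    down_by_source = {
        src: {gene_of[f] for f in diffexpr.de_calls(de_p[src], "down") if f in gene_of.index}
        for src in sources
    }
    venn_down = prioritize.intersect_sources(down_by_source)
    p = out / "venn_deps.json"
    io.write_json({"up": prioritize.venn_to_json(venn_up),
                   "down": prioritize.venn_to_json(venn_down)}, p)
    artifacts["venn_deps"] = p

    candidates = set().union(*up_by_source.values()) if up_by_source else set()
    assoc = prioritize.filter_disease_associated(
        candidates, study.annotations.gda, min_score=config.gda_min_score
    )
    expansion = prioritize.expand_network(
        set(assoc.genes), candidates, study.annotations.network,
        min_score=config.network_min_score,
    )
    panel_tbl = prioritize.build_panel(
        assoc, expansion, up_by_source, study.annotations.drugs,
        study.annotations.network, min_score=config.network_min_score,
    )
    p = out / "prioritized_panel.tsv"
    panel_tbl.to_csv(p, sep="\t", index=False, float_format="%.10g")
    artifacts["prioritized_panel"] = p
    members = set(panel_tbl["gene_id"]) if len(panel_tbl) else set()
    subgraph = study.annotations.network[
        study.annotations.network["node_a"].isin(members)
        & study.annotations.network["node_b"].isin(members)
        & (study.annotations.network["combined_score"] >= config.network_min_score)
    ]
    p = out / "panel_network.tsv"
    subgraph.to_csv(p, sep="\t", index=False, float_format="%.10g")
    artifacts["panel_network"] = p
    summary["prioritization"] = {
        "n_upregulated_dep_genes": len(candidates),
        "n_disease_associated": len(assoc.genes),
        "n_network_added": len(expansion.added),
        "panel_size": int(len(panel_tbl)),
        "n_drug_available": int(panel_tbl["drug_available"].sum()) if len(panel_tbl) else 0,
    }

    manifest = {
        "tool": "fibroscore",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "transcript_p": config.transcript_p,
            "transcript_fc": config.transcript_fc,
            "protein_fdr": config.protein_fdr,
            "protein_fc": config.protein_fc,
            "network_min_score": config.network_min_score,
            "regulator_z": config.regulator_z,
            "gda_min_score": config.gda_min_score,
        },
        "config": {k: v for k, v in dataclasses.asdict(config).items() if v is not None},
        "summary": summary,
        "artifacts": {k: {"path": str(v.relative_to(out)), "sha256": _sha256(v)}
                      for k, v in sorted(artifacts.items())},
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _pool_de(de_by_source: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Source-mean fold changes with the strongest call retained per feature."""
    frames = []
    for src in sorted(de_by_source):
        frames.append(de_by_source[src].assign(source=src))
    cat = pd.concat(frames, ignore_index=True)
    call_rank = {"up": 0, "down": 0, "ns": 1}
    agg = (
        cat.sort_values(["feature_id"], kind="stable")
        .groupby("feature_id", sort=True)
        .agg(
            log2fc=("log2fc", "mean"),
            call=("call", lambda c: min(c, key=lambda v: call_rank[v])),
        )
        .reset_index()
    )
    return agg


def _nan_none(x):
    import math

    x = float(x)
    return None if math.isnan(x) else x
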