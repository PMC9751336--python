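"""Seeded synthetic multi-omics study generator with a planted ground truth.

Emulates a 3-source x {control, treated} x 3-replicate fibroblast activation
study: negative-binomial transcript counts with per-sample library-size
variation, log-normal protein intensities whose fold changes are partially
coupled to the transcript fold changes, and the annotation tables the
downstream prioritization cascade consumes (gene-disease associations,
a confidence-scored interaction network, cell locations, drug availability,
term sets, signed regulator-target edges).

Every draw is derived from ``config.seed`` through independent named streams,
so identical configs reproduce every output bit for bit while the three
``simulate_*`` operations stay independently callable.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FIBROSIS_DISEASES, LOCATIONS, default_panel_path, read_panel

# rng stream tags (keep below 2**31 so seed sequences stay small ints)
_STREAM_COUNTS = 11
_STREAM_PROTEOME = 23
_STREAM_ANNOTATIONS = 37

_OTHER_DISEASES = ("cardiomyopathy", "hypertension", "carcinoma", "myocarditis")
_DRUG_STATUSES = ("approved", "phase3", "phase2", "preclinical")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: three fibroblast sources, two
    conditions, three replicates; gene baseline means mu_g are log-normal;
    counts are negative binomial with Var = mu + dispersion * mu^2; protein
    log2 fold changes for coupled proteins follow
    rho * transcript_lfc + sqrt(1 - rho^2) * lfc_magnitude * eps.
    """

    n_genes: int = 2000
    n_proteins: int = 1000
    sources: tuple[str, ...] = ("aHCF", "fHCF", "hiPSC-CF")
    n_replicates: int = 3
    nb_mean_log_mu: float = 5.5   # natural-log mean of gene baseline mu_g
    nb_mean_log_sd: float = 1.0
    dispersion: float = 0.05      # NB alpha, Var = mu + alpha mu^2
    frac_deg: float = 0.1         # fraction of non-panel genes planted per source
    frac_shared_deg: float = 0.6  # fraction of each source's DEGs common to all
    # (membership overlap is the generator's proxy for the convergent
    #  cross-source activation response; see docs/methods.md)
    lfc_magnitude: float = 2.0    # |log2FC| planted on DEGs
    panel_genes: tuple[str, ...] = ()          # empty = bundled 28-gene panel
    panel_response_lfc: float = 1.0            # treatment effect on panel genes
    panel_offset: float = 0.5                  # quiescence offset (log2) on controls
    preactivated_sources: tuple[str, ...] = ("aHCF", "fHCF")
    libsize_range: tuple[float, float] = (0.5, 2.0)
    coupling_rho: float = 0.8
    protein_noise_sd: float = 0.2              # log2-scale measurement noise
    protein_log2_mu: float = 17.0              # baseline log2 intensity level
    protein_log2_sd: float = 1.5
    mapping_coverage: float = 0.91             # fraction of proteins in mapping
    missing_rate: float = 0.0                  # optional proteome missingness
    # annotation-table shape
    assoc_frac: float = 0.25       # fraction of up-DEP genes given fibrosis rows
    module_size: int = 8           # non-associated up-DEPs wired to associated ones
    n_background_edges: int = 400
    n_background_gda: int = 40
    drug_frac: float = 0.3
    n_terms: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_proteins < 1:
            raise ValueError("n_genes and n_proteins must be positive")
        if self.n_proteins > self.n_genes:
            raise ValueError("n_proteins must not exceed n_genes (1:1 gene mapping)")
        if self.n_replicates < 2:
            raise ValueError("n_replicates < 2: group tests undefined")
        for name in ("frac_deg", "frac_shared_deg", "mapping_coverage",
                     "missing_rate", "assoc_frac", "drug_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if abs(self.coupling_rho) > 1:
            raise ValueError("|coupling_rho| must be <= 1")
        if self.protein_noise_sd < 0:
            raise ValueError("protein_noise_sd must be >= 0")
        if not set(self.preactivated_sources) <= set(self.sources):
            raise ValueError("preactivated_sources must be a subset of sources")
        if not (0 < self.libsize_range[0] <= self.libsize_range[1]):
            raise ValueError("libsize_range must be positive and ordered")

    def resolved_panel(self) -> tuple[str, ...]:
        if self.panel_genes:
            return tuple(self.panel_genes)
        return tuple(read_panel(default_panel_path()))


@dataclass
class GroundTruth:
    """Planted-effect ledger used by parameter-recovery tests.

    ``expected_panel`` is derived from planted truth plus the annotation
    tables by an independent brute-force reference (set filters and a one-hop
    neighbor scan), never by the pipeline under test.
    """

    deg_sets: dict[str, dict[str, float]]
    panel_response: dict[str, float]
    dep_sets: dict[str, dict[str, float]] = field(default_factory=dict)
    protein_gene: dict[str, str] = field(default_factory=dict)
    preactivated_sources: tuple[str, ...] = ()
    expected_panel: list[str] | None = None
    expected_associated: list[str] | None = None
    expected_added: list[str] | None = None

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnnotationBundle:
    gda: pd.DataFrame
    network: pd.DataFrame
    locations: pd.DataFrame
    drugs: pd.DataFrame
    term_sets: dict[str, dict]
    regulators: pd.DataFrame


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    counts: pd.DataFrame
    intensities: pd.DataFrame
    design: pd.DataFrame
    mapping: pd.DataFrame
    annotations: AnnotationBundle
    truth: GroundTruth


def gene_universe(config: SimulationConfig) -> list[str]:
    panel = config.resolved_panel()
    if len(panel) > config.n_genes:
        raise ValueError(
            f"panel has {len(panel)} genes but universe only {config.n_genes}"
        )
    fillers = [f"G{i:05d}" for i in range(config.n_genes - len(panel))]
    return list(panel) + fillers


def build_design(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{src}_{cond}_{rep}",
            "source": src,
            "condition": cond,
            "replicate": rep,
        }
        for src in config.sources
        for cond in ("control", "treated")
        for rep in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def _planted_deg_sets(config: SimulationConfig, rng: np.random.Generator,
                      genes: list[str]) -> dict[str, dict[str, float]]:
    panel = set(config.resolved_panel())
    eligible = np.array([g for g in genes if g not in panel])
    n_deg = int(round(config.frac_deg * len(eligible)))
    if n_deg == 0:
        return {src: {} for src in config.sources}
    n_shared = int(round(config.frac_shared_deg * n_deg))
    order = rng.permutation(eligible)
    shared = order[:n_shared]
    pool = order[n_shared:]
    shared_signs = np.where(np.arange(n_shared) % 2 == 0, 1.0, -1.0)
    deg_sets: dict[str, dict[str, float]] = {}
    offset = 0
    for src in config.sources:
        unique = pool[offset:offset + (n_deg - n_shared)]
        offset += n_deg - n_shared
        if len(unique) < n_deg - n_shared:
            raise ValueError("not enough eligible genes for the requested frac_deg")
        uniq_signs = rng.permuted(
            np.where(np.arange(len(unique)) % 2 == 0, 1.0, -1.0)
        )
        lfcs = {g: s * config.lfc_magnitude for g, s in zip(shared, shared_signs)}
        lfcs.update({g: s * config.lfc_magnitude for g, s in zip(unique, uniq_signs)})
        deg_sets[src] = lfcs
    return deg_sets


def simulate_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the count matrix, sample sheet and planted truth.

    Treated samples of each source carry the planted log2 fold changes on
    that source's DEGs and the panel treatment response on panel genes;
    control samples of pre-activated sources carry the +panel_offset
    quiescence shift on panel genes.
    """
    rng = np.random.default_rng([config.seed, _STREAM_COUNTS])
    genes = gene_universe(config)
    panel = list(config.resolved_panel())
    design = build_design(config)
    gene_index = {g: i for i, g in enumerate(genes)}

    mu = rng.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sd, len(genes))
    deg_sets = _planted_deg_sets(config, rng, genes)
    lo, hi = config.libsize_range
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), len(design)))

    delta = np.zeros((len(genes), len(design)))
    panel_rows = [gene_index[g] for g in panel]
    for j, row in design.iterrows():
        if row["condition"] == "treated":
            for g, lfc in deg_sets[row["source"]].items():
                delta[gene_index[g], j] += lfc
            delta[panel_rows, j] += config.panel_response_lfc
        elif row["source"] in config.preactivated_sources:
            delta[panel_rows, j] += config.panel_offset

    mean = mu[:, None] * np.exp2(delta) * libsize[None, :]
    if config.dispersion > 0:
        size = 1.0 / config.dispersion
        counts = rng.negative_binomial(size, size / (size + mean))
    else:
        counts = rng.poisson(mean)

    counts_df = pd.DataFrame(counts.astype(np.int64), index=pd.Index(genes, name="gene_id"),
                             columns=design["sample_id"].tolist())
    truth = GroundTruth(
        deg_sets=deg_sets,
        panel_response={g: config.panel_response_lfc for g in panel},
        preactivated_sources=tuple(config.preactivated_sources),
    )
    return counts_df, design, truth


def simulate_proteome(truth: GroundTruth, config: SimulationConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw protein intensities coupled to the planted transcript effects.

    Returns the intensity matrix and the gene<->protein mapping table
    (covering ``mapping_coverage`` of the proteins). Fills
    ``truth.dep_sets`` and ``truth.protein_gene`` in place.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PROTEOME])
    genes = gene_universe(config)
    design = build_design(config)
    prot_genes = sorted(rng.choice(np.array(genes), config.n_proteins, replace=False))
    proteins = [f"P_{g}" for g in prot_genes]
    truth.protein_gene = dict(zip(proteins, prot_genes))

    base = rng.normal(config.protein_log2_mu, config.protein_log2_sd, len(proteins))

    rho = config.coupling_rho
    dep_sets: dict[str, dict[str, float]] = {}
    for src in config.sources:
        gene_lfc = dict(truth.deg_sets.get(src, {}))
        for g, lfc in truth.panel_response.items():
            gene_lfc[g] = gene_lfc.get(g, 0.0) + lfc
        src_deps: dict[str, float] = {}
        for pid, g in zip(proteins, prot_genes):
            tl = gene_lfc.get(g, 0.0)
            if tl == 0.0:
                continue
            noise = 0.0
            if abs(rho) < 1.0:
                noise = np.sqrt(1 - rho**2) * config.lfc_magnitude * rng.standard_normal()
            src_deps[pid] = rho * tl + noise
        dep_sets[src] = src_deps
    truth.dep_sets = dep_sets

    delta = np.zeros((len(proteins), len(design)))
    pidx = {p: i for i, p in enumerate(proteins)}
    for j, row in design.iterrows():
        if row["condition"] == "treated":
            for pid, plfc in dep_sets[row["source"]].items():
                delta[pidx[pid], j] = plfc
    colshift = rng.uniform(np.log2(0.8), np.log2(1.25), len(design))
    noise = rng.normal(0.0, config.protein_noise_sd, delta.shape)
    log2_int = base[:, None] + delta + colshift[None, :] + noise
    intensities = np.exp2(log2_int)
    if config.missing_rate > 0:
        mask = rng.random(intensities.shape) < config.missing_rate
        intensities = np.where(mask, np.nan, intensities)

    intens_df = pd.DataFrame(intensities, index=pd.Index(proteins, name="protein_id"),
                             columns=design["sample_id"].tolist())
    n_map = int(round(config.mapping_coverage * len(proteins)))
    mapped = sorted(rng.choice(np.array(proteins), n_map, replace=False))
    mapping = pd.DataFrame(
        {"gene_id": [truth.protein_gene[p] for p in mapped], "protein_id": mapped}
    )
    return intens_df, mapping


def _upregulated_dep_genes(truth: GroundTruth, mapping: pd.DataFrame) -> list[str]:
    mapped = set(mapping["protein_id"])
    genes = {
        truth.protein_gene[pid]
        for deps in truth.dep_sets.values()
        for pid, plfc in deps.items()
        if plfc > 0 and pid in mapped
    }
    return sorted(genes)


def brute_force_expected_panel(truth: GroundTruth, mapping: pd.DataFrame,
                               gda: pd.DataFrame, network: pd.DataFrame,
                               min_score: float = 0.7) -> tuple[list[str], list[str]]:
    """Independent reference for the prioritized panel, from planted truth.

    Plain set filters plus an exhaustive one-hop edge scan; deliberately
    shares no code with the prioritize module.
    """
    candidates = _upregulated_dep_genes(truth, mapping)
    fibro = gda[gda["disease"].isin(FIBROSIS_DISEASES)]
    associated = sorted(set(candidates) & set(fibro["gene_id"]))
    added = set()
    aset = set(associated)
    for g in candidates:
        if g in aset:
            continue
        for _, e in network.iterrows():
            if e["combined_score"] < min_score:
                continue
            if (e["node_a"] == g and e["node_b"] in aset) or (
                e["node_b"] == g and e["node_a"] in aset
            ):
                added.add(g)
                break
    return associated, sorted(added)


def simulate_annotations(config: SimulationConfig, truth: GroundTruth,
                         mapping: pd.DataFrame) -> AnnotationBundle:
    """Draw the annotation tables and fill ``truth.expected_panel``.

    The gene-disease table gives fibrosis rows to ``assoc_frac`` of the
    planted upregulated-DEP genes (plus background rows on other genes);
    the network plants a high-confidence module wiring ``module_size``
    non-associated upregulated DEPs to associated ones, with all background
    edges drawn below the 0.7 confidence threshold.
    """
    rng = np.random.default_rng([config.seed, _STREAM_ANNOTATIONS])
    genes = gene_universe(config)
    up_dep = _upregulated_dep_genes(truth, mapping)

    n_assoc = int(round(config.assoc_frac * len(up_dep)))
    associated = sorted(rng.choice(np.array(up_dep), n_assoc, replace=False)) if n_assoc else []

    gda_rows = []
    for g in associated:
        n_dis = int(rng.integers(1, len(FIBROSIS_DISEASES) + 1))
        for d in rng.choice(np.array(FIBROSIS_DISEASES), n_dis, replace=False):
            gda_rows.append((g, d, round(float(rng.uniform(0.05, 0.9)), 3)))
    background_pool = sorted(set(genes) - set(up_dep))
    n_bg = min(config.n_background_gda, len(background_pool))
    for g in rng.choice(np.array(background_pool), n_bg, replace=False):
        d = str(rng.choice(np.array(FIBROSIS_DISEASES + _OTHER_DISEASES)))
        gda_rows.append((g, d, round(float(rng.uniform(0.01, 0.7)), 3)))
    gda = pd.DataFrame(gda_rows, columns=["gene_id", "disease", "score"])
    gda = gda.drop_duplicates(["gene_id", "disease"]).reset_index(drop=True)

    # interaction network: planted high-confidence module + sub-threshold noise
    edges: dict[tuple[str, str], float] = {}
    non_assoc = [g for g in up_dep if g not in set(associated)]
    module = list(rng.choice(np.array(non_assoc), min(config.module_size, len(non_assoc)),
                             replace=False)) if non_assoc and associated else []
    for g in module:
        partners = rng.choice(np.array(associated), int(rng.integers(1, 3)) if len(associated) > 1 else 1,
                              replace=False)
        for p in partners:
            key = tuple(sorted((g, str(p))))
            edges[key] = round(float(rng.uniform(0.85, 0.95)), 3)
    tries = 0
    while sum(1 for s in edges.values() if s < 0.7) < config.n_background_edges and tries < 20 * config.n_background_edges:
        tries += 1
        a, b = rng.choice(np.array(genes), 2, replace=False)
        key = tuple(sorted((str(a), str(b))))
        if key in edges:
            continue
        edges[key] = round(float(rng.uniform(0.15, 0.699)), 3)
    network = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(edges.items())],
        columns=["node_a", "node_b", "combined_score"],
    )

    # cell locations per protein. The convergent activation program (proteins
    # responding in every source) is concentrated in extracellular space and
    # plasma membrane, emulating the matrisome-centered remodeling signature;
    # source-specific responders sit near the background distribution.
    dep_proteins = {pid for deps in truth.dep_sets.values() for pid in deps}
    shared_responders = (
        set.intersection(*(set(d) for d in truth.dep_sets.values()))
        if truth.dep_sets else set()
    )
    proteins = sorted(truth.protein_gene)
    p_shared = np.array([0.40, 0.30, 0.13, 0.10, 0.07])
    p_dep = np.array([0.07, 0.05, 0.43, 0.30, 0.15])
    p_bg = np.array([0.08, 0.07, 0.45, 0.28, 0.12])
    loc_rows = []
    for pid in proteins:
        probs = (p_shared if pid in shared_responders
                 else p_dep if pid in dep_proteins else p_bg)
        loc_rows.append((pid, str(rng.choice(np.array(LOCATIONS), p=probs))))
    locations = pd.DataFrame(loc_rows, columns=["feature_id", "location"])

    drug_rows = []
    druggable_pool = sorted(set(associated) | set(module))
    for i, g in enumerate(druggable_pool):
        if rng.random() < config.drug_frac:
            for k in range(int(rng.integers(1, 3))):
                drug_rows.append((g, f"CPD-{i:03d}{chr(97 + k)}",
                                  str(rng.choice(np.array(_DRUG_STATUSES)))))
    drugs = pd.DataFrame(drug_rows, columns=["gene_id", "drug_name", "status"])

    term_sets = _simulate_terms(config, truth, rng, genes)
    regulators = _simulate_regulators(config, truth, rng, genes)

    associated_bf, added_bf = brute_force_expected_panel(truth, mapping, gda, network)
    truth.expected_associated = associated_bf
    truth.expected_added = added_bf
    truth.expected_panel = sorted(set(associated_bf) | set(added_bf))

    return AnnotationBundle(gda=gda, network=network, locations=locations,
                            drugs=drugs, term_sets=term_sets, regulators=regulators)


_TERM_LABELS = (
    "extracellular matrix organization", "cell adhesion", "cell migration",
    "angiogenesis", "collagen fibril organization", "wound healing",
    "TGF-beta signaling", "platelet degranulation", "actin cytoskeleton",
    "glycolysis", "RNA splicing", "DNA repair", "oxidative phosphorylation",
    "vesicle transport", "chromatin remodeling", "proteolysis",
    "lipid metabolism", "ion transport", "translation", "apoptosis",
)


def _simulate_terms(config, truth, rng, genes) -> dict[str, dict]:
    deg_union = sorted({g for d in truth.deg_sets.values() for g in d})
    terms: dict[str, dict] = {}
    for i in range(config.n_terms):
        label = _TERM_LABELS[i % len(_TERM_LABELS)]
        size = int(rng.integers(20, 80))
        if i < 5 and deg_union:  # response terms enriched in planted DEGs
            n_deg = min(int(round(0.6 * size)), len(deg_union))
            members = set(rng.choice(np.array(deg_union), n_deg, replace=False))
            members |= set(rng.choice(np.array(genes), size - n_deg, replace=False))
        else:
            members = set(rng.choice(np.array(genes), size, replace=False))
        terms[f"T{i:04d}"] = {"label": label, "genes": sorted(members)}
    return terms


def _simulate_regulators(config, truth, rng, genes) -> pd.DataFrame:
    deg_union: dict[str, float] = {}
    for d in truth.deg_sets.values():
        deg_union.update(d)
    up = sorted(g for g, l in deg_union.items() if l > 0)
    down = sorted(g for g, l in deg_union.items() if l < 0)
    rows = []
    def take(pool, n):
        n = min(n, len(pool))
        return list(rng.choice(np.array(pool), n, replace=False)) if n else []
    # a consistently "activated" and a consistently "inhibited" regulator
    for g in take(up, 20):
        rows.append(("REG_ACT", g, 1))
    for g in take(down, 10):
        rows.append(("REG_ACT", g, -1))
    for g in take(up, 20):
        rows.append(("REG_INH", g, -1))
    for g in take(down, 10):
        rows.append(("REG_INH", g, 1))
    for name in ("REG_NULL1", "REG_NULL2", "REG_NULL3"):
        for g in take(list(genes), 25):
            rows.append((name, g, int(rng.choice([1, -1]))))
    df = pd.DataFrame(rows, columns=["regulator", "target", "sign"])
    return df.drop_duplicates(["regulator", "target"]).reset_index(drop=True)


def simulate_all(config: SimulationConfig) -> SimulatedStudy:
    counts, design, truth = simulate_counts(config)
    intensities, mapping = simulate_proteome(truth, config)
    annotations = simulate_annotations(config, truth, mapping)
    return SimulatedStudy(config=config, counts=counts, intensities=intensities,
                          design=design, mapping=mapping, annotations=annotations,
                          truth=truth)


def make_fixture_config(seed: int = 0) -> SimulationConfig:
    """The bundled end-to-end fixture: small, strongly coupled, fast.

    Degenerate transcript-protein coupling (rho = 1) plants protein fold
    changes exactly at the transcript values, so the planted differential
    proteins are unambiguous and panel recovery is an exact check.
    """
    return SimulationConfig(n_genes=600, n_proteins=300, coupling_rho=1.0,
                            protein_noise_sd=0.15, seed=seed)


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write every table of a simulated study to ``outdir``; returns paths."""
    from pathlib import Path

    from .io import write_gmt, write_json, write_matrix, write_sample_sheet

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "intensities": out / "intensities.tsv",
        "samples": out / "samples.tsv",
        "mapping": out / "mapping.tsv",
        "gda": out / "gda.tsv",
        "network": out / "network.tsv",
        "locations": out / "locations.tsv",
        "drugs": out / "drugs.tsv",
        "terms": out / "terms.gmt",
        "regulators": out / "regulators.tsv",
        "truth": out / "truth.json",
    }
    write_matrix(study.counts, paths["counts"])
    write_matrix(study.intensities, paths["intensities"])
    write_sample_sheet(study.design, paths["samples"])
    study.mapping.to_csv(paths["mapping"], sep="\t", index=False)
    ann = study.annotations
    ann.gda.to_csv(paths["gda"], sep="\t", index=False, float_format="%.10g")
    ann.network.to_csv(paths["network"], sep="\t", index=False, float_format="%.10g")
    ann.locations.to_csv(paths["locations"], sep="\t", index=False)
    ann.drugs.to_csv(paths["drugs"], sep="\t", index=False)
    ann.regulators.to_csv(paths["regulators"], sep="\t", index=False)
    write_gmt(ann.term_sets, paths["terms"])
    write_json(study.truth.to_json(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}
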