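# Methods

## Study design being modeled

The package analyzes a two-condition multi-omics comparison of cardiac
fibroblasts (CF): three cell sources (adult primary `aHCF`, fetal primary
`fHCF`, hiPSC-derived `hiPSC-CF`), each measured quiescent (`control`) and
TGF-β1-activated (`treated`), with three biological replicates — 18 samples
per omics layer. Inputs are a gene-level count matrix, a protein intensity
matrix, a sample sheet, a gene↔protein mapping, and annotation tables
(gene–disease association scores, a confidence-scored interaction network,
cell locations, drug availability, GMT term sets, signed regulator–target
edges). All identifiers are opaque strings; tables are TSV with `#`
comments.

## CF activation score

For counts `c_gj` and optional size factors `s_j` (defaults: median-of-ratios
when run through the pipeline, `s_j = 1` otherwise),
`L_gj = log2(c_gj/s_j + 1)`; each panel gene is standardized to
`z_gj = (L_gj − mean_j L_g·)/sd_j(L_g·)` with the sample standard deviation
(n−1), and `S_j = Σ_g z_gj`. Choices that the procedure's verbal definition
leaves open, fixed here:

- **Log base 2, pseudocount 1.** The base is absorbed by standardization
  except through the pseudocount; base 2 matches fold-change conventions.
- **Joint standardization** across all samples of the analyzed set (all
  sources, both conditions). Scores of different sources are compared on
  one axis, which is only meaningful under a common standardization.
- Zero-variance or absent panel genes are dropped (recorded in
  `dropped_genes`) and contribute 0; an empty overlap is a hard error.

Consequences used as test invariants: each z row sums to zero, so
`Σ_j S_j = 0`; scores are invariant to per-gene positive-affine transforms
of `L`; with positive planted panel effects, treated means exceed control
means. Group differences use a two-way fixed-effects ANOVA
(`score ~ source * condition`, type-II sums of squares) followed by Tukey
HSD on the six source × condition cells. Degenerate inputs (empty or
single-replicate cells, zero residual variance) raise instead of returning
p = 0.

## Differential expression

**Normalization.** Transcripts: median-of-ratios size factors
`s_j = median_g(c_gj / geomean(c_g·))` over genes positive in every sample
(hard error if none exists); the median is taken on the ratio scale.
Proteins: each column scaled so its total equals the mean column sum
("total-area" normalization).

**Test.** Both layers use a two-group empirical-Bayes moderated t on log₂
values (`log2(count/s_j + 1)` for transcripts, `log2` of normalized
intensity for proteins). The per-feature pooled variance (df = n₀+n₁−2) is
shrunk toward a prior: `s²_mod = (d₀·s₀² + d·s²)/(d₀+d)`, with the p-value
from t on d+d₀ df. By default both prior parameters are estimated from the
data by method of moments on `log s²` (mean/variance matching with
digamma/trigamma terms; the trigamma equation is inverted by Newton
iteration; an infinite d₀ degenerates to a common-variance z-test). This
keeps the null calibrated whether true variances are homogeneous or not —
a fixed small prior df with a mean-variance prior is measurably
conservative when variances are near-homogeneous, which is exactly the
regime log counts of moderately-to-highly expressed genes produce.
A numeric `prior_df` can be fixed instead.

**Decision rules** (deliberately asymmetric, matching the study
conventions): transcripts are called at raw `p < 0.1` **and** linear fold
change beyond ±2.0; proteins at BH `FDR < 0.1` **and** fold change beyond
±1.5. The signed linear fold change uses the negative-reciprocal
convention: `signed_fc = 2^lfc` if `lfc ≥ 0` else `−2^(−lfc)`, so ±2 means
two-fold either way (equivalently |log₂FC| > 1). Benjamini–Hochberg is the
step-up with enforced monotonicity; output rows are sorted by feature id,
so ties are reported deterministically.

The transcript test is a log-scale approximation of a negative-binomial
count test; its guarantees are calibration (null rejection rate ≈ nominal)
and recovery on planted truth, not numerical replication of any count-GLM
package — the package's tests enforce exactly those guarantees.

Scale handling: p-values are exactly invariant to multiplying any sample's
counts by a constant when the size factors absorb the constant (the
pipeline path). When factors are re-estimated from the scaled matrix, a
global `c^(1/n)` rescaling of normalized counts survives (the
geometric-mean shift inherent to median-of-ratios) and interacts with the
+1 pseudocount; at count scales of ~100+ the residual p shift is < 0.02
and shrinks with depth.

## Cross-omics integration

- **Matching**: proteins pair with transcripts through the mapping table;
  coverage is the fraction of *all* proteins with a matched transcript.
- **Fold-change correlation**: Pearson r on (transcript log₂FC, protein
  log₂FC) pairs; the DEP restriction keeps pairs whose protein call is not
  `ns`. Correlations use log₂ fold changes — r on signed linear fold
  changes would be discontinuous at ±1. Fewer than 3 pairs is flagged
  undefined rather than returning NaN silently.
- **Sample clustering**: Pearson correlation of log₂ values over the chosen
  feature subset; distance 1 − r, average linkage (neither is pinned by the
  emulated workflow; both are documented fixed choices). Dendrograms export
  to Newick. Constant samples make correlations undefined and are reported.
- **PCA**: samples as observations, feature-centered, SVD scores `U·S`,
  explained fractions `σᵢ²/Σσ²`; computed on log₂ size-factor-normalized
  counts, centered but not scaled.

## Annotation

Term enrichment is the one-sided hypergeometric tail of the query/term
overlap within the declared universe, BH-adjusted, ranked by (p, term_id);
`min_overlap` excludes sparse overlaps, and an optional EASE variant
decrements the observed overlap by one (floor 0) before taking the tail.
The plain hypergeometric is the default.

Upstream-regulator activation reproduces the thresholded calling logic on
a documented surrogate statistic (the proprietary score of the original
tool is not reimplemented): over a regulator's targets that are DEGs,
`N⁺` counts sign-consistent targets (edge sign × fold-change sign = +1),
and `z = (N⁺ − N⁻)/√(N⁺+N⁻)`. Calls are strict — `activated` iff `z > 3`,
`inhibited` iff `z < −3` — and gated on the hypergeometric overlap p of
the regulator's targets with the DEG set (`−log10 p > 1`, i.e. p < 0.1;
the gate can be disabled). Regulators with no DEG target are reported
`untestable`. |z| ≤ √N and z is antisymmetric under flipping either all
edge signs or all fold-change signs.

## Target prioritization

Candidates are the genes of upregulated differential proteins (union over
sources, mapped through the gene↔protein table). The cascade:

1. **Disease filter**: keep candidates with ≥ 1 gene–disease row for
   {pulmonary, cardiac, hepatic, renal} fibrosis scoring above `min_score`
   (default 0 — any positive association counts, since curated databases
   keep low-score rows; configurable).
2. **Network expansion**: one hop only, restricted to the candidate set;
   a non-associated candidate joins when it shares an edge of combined
   score **≥ 0.7** (inclusive — 0.700 is "high confidence") with an
   associated gene. Disconnected candidates stay hidden. Raising the
   threshold can only shrink the expansion.
3. **Drug annotation**: membership join against the drug table.
4. **Ranking**: (sources upregulated ↓, max association score ↓,
   high-confidence degree to associated members ↓, gene id ↑) — a
   deterministic total order, invariant to input order.

Cross-source comparisons report all 2ᵏ−1 disjoint Venn regions; region
sizes always sum to the union size.

## Synthetic-data generator

The generator emulates the study design with planted, recoverable truth.
All randomness flows from `seed` through independent named streams, so
identical configs are byte-identical and the three `simulate_*` stages are
independently reproducible.

**Counts.** Gene baselines `μ_g` are log-normal (`ln μ ~ N(5.5, 1.0)`,
median ≈ 245 — moderately deep 3'-end-counting libraries). Counts are
negative binomial with `Var = μ + α μ²`, α = 0.05. Per-sample library sizes
are log-uniform in [0.5, 2] so size-factor estimation is non-trivially
exercised. Per source, 10% of non-panel genes carry a planted log₂ fold
change of exactly ±2 in treated samples (half up, half down). 60% of each
source's planted genes come from one common pool with common signs
(`frac_shared_deg`): with planted effects constrained to
{0, ±lfc_magnitude}, membership overlap is the generator's proxy for the
convergent cross-source activation response the design emulates; the real
study's thresholded Venn overlaps are smaller mainly because its weaker
sources under-threshold. Panel genes get a +1 log₂ treatment response in
every source, and `panel_offset` (+0.5 log₂ by default) on *control*
samples of designated "pre-activated" sources (default: both primary
sources), so basal-activation differences are reproducible by construction.

**Proteome.** Proteins map 1:1 to a random gene subset (1000 of 2000 by
default); the shipped mapping covers 91% of them, mirroring the typical
transcript coverage of a DIA proteome. Log₂ intensities are Gaussian
around a protein baseline (`N(17, 1.5)`) plus a per-sample loading factor
(log-uniform [0.8, 1.25]) and measurement noise (σ = 0.2 log₂ units, i.e.
~15% CV — typical SWATH precision). For proteins of responding genes, the
planted protein log₂FC is `ρ·t + √(1−ρ²)·lfc_magnitude·ε` with ρ = 0.8,
making ρ the target transcript–protein fold-change correlation (transcript
effects are ±lfc_magnitude, so the noise term is scaled to match their
spread). Non-responding genes' proteins have exactly zero planted effect,
so coupling exists only on differential proteins. No missing values by
default (DIA yields a complete matrix); an optional missingness rate
exists.

**Annotations.** 25% of upregulated-DEP genes receive fibrosis
gene–disease rows (scores U(0.05, 0.9)); background rows (fibrosis and
non-fibrosis diseases) go to genes outside the candidate set. The network
plants a module wiring 8 non-associated upregulated DEPs to associated
ones at scores 0.85–0.95; all 400 background edges are drawn strictly
below 0.7, so high-confidence expansion is exactly the planted module.
Cell locations: shared (convergent) responders are ECM/plasma-membrane
with probability 0.70, source-unique responders 0.12, background 0.15 —
reproducing the "prevalence roughly doubles-to-triples among DEPs"
structure. A drug table flags ~30% of panel-eligible genes. Term sets
(GMT) include five DEG-enriched "response" terms and random terms;
regulator tables include one coherently activating and one coherently
inhibiting regulator plus random-sign decoys.

**Truth ledger.** `GroundTruth` records planted DEG/DEP sets (exact
±lfc), the pre-activated sources, and `expected_panel`: the prioritized
panel derived from planted truth + annotation tables by an independent
brute-force reference (set filters and an exhaustive one-hop edge scan)
at generation time — never by the pipeline under test.

**Bundled fixture** (`make_fixture_config`): 600 genes, 300 proteins,
coupling ρ = 1 and σ = 0.15 — planted protein fold changes equal the
transcript values exactly, so every planted differential protein is
unambiguous and end-to-end panel recovery is an exact check. The fixture
pipeline runs in a few seconds.

## Problem sizes and numerical choices

Monte-Carlo guarantees in the test suite use: 100 random 28×18 matrices
for score-oracle equivalence (1e-9); 200+200 simulations (300-gene
universe) for the quiescence-offset contrast power/specificity; one
2000-gene null and 50 planted 2000-gene runs for calibration, FDR and
sensitivity; 50 full-design runs each for the correlation-restriction and
clustering-separation structure; 1000 random vectors for BH and 200 small
universes for the enrichment oracle. BH ties break by feature id;
dendrogram merge order follows SciPy's deterministic linkage; all floats
in artifacts are written with fixed formatting and manifests record
SHA-256 of every artifact, making reruns byte-comparable.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the emulated study — design
shape, count/intensity noise families, partial transcript–protein
coupling, a convergent ECM/membrane-biased response, a prioritization
cascade with known answers — so passing tests demonstrate that the
implementation computes its statistics correctly and recovers planted
truth under realistic noise. It does **not** model: dataset-specific
dispersion trends or GC/length biases, proteome missingness-by-intensity,
batch structure, correlated genes within pathways (genes are independent
given their planted effect), source-specific baselines in the proteome,
or database-version effects on association/network tables. Consequently
dataset-specific numbers from any real study (DEG/DEP counts, exact
correlation values, the 33-protein panel) are not reproduction targets;
the qualitative relations (treated > control scores; restriction to DEPs
raising the fold-change correlation; ECM/membrane enrichment among DEPs;
condition-driven clustering on that subset) are.

## Known limitations

- The transcript test is not a count-model GLM; at very low counts
  (μ ≲ 10) discreteness erodes calibration.
- The regulator statistic is a surrogate; only the thresholding logic and
  output schema follow the original tool.
- Enrichment treats genes as exchangeable (no term redundancy trimming,
  no gene-length bias correction).
- Multi-hop network expansion and shrunken fold changes are deliberately
  out of scope.
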