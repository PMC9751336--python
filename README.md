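# fibroscore

Cardiac fibrosis is driven by cardiac fibroblasts (CF) that convert from a
quiescent to an activated, matrix-secreting myofibroblast state under
TGF-β1. `fibroscore` implements, as a tested and reusable Python library,
the analysis workflow used to profile that conversion across several CF
sources (adult primary, fetal primary, and hiPSC-derived fibroblasts) at
the transcriptome and proteome level, and to prioritize candidate
anti-fibrotic targets:

- **CF activation score** — for sample *j* and a fixed marker panel *G*
  (28 genes, ACTA2 … VIM, bundled), the score is the summed z of log
  expression: *S<sub>j</sub> = Σ<sub>g∈G</sub> z<sub>gj</sub>* with
  *z<sub>gj</sub>* standardizing *L<sub>gj</sub> = log₂(c<sub>gj</sub>/s<sub>j</sub> + 1)*
  across all samples jointly. Group structure is tested by two-way ANOVA
  (source × condition) with Tukey HSD on the six cell means.
- **Differential expression** — transcripts: median-of-ratios size factors,
  moderated t on log₂ normalized counts, called at *p* < 0.1 and linear
  fold change beyond ±2; proteins: total-area normalization, moderated t on
  log₂ intensities, called at BH FDR < 0.1 and fold change beyond ±1.5.
- **Cross-omics integration** — transcript–protein matching, Pearson
  correlation of log₂ fold changes (all pairs vs. differential proteins
  only), cell-location prevalence, sample correlation clustering
  (1 − r, average linkage) on the ECM/membrane differential proteins, PCA.
- **Annotation** — hypergeometric term enrichment (GMT term sets, optional
  EASE variant) and upstream-regulator calls via the sign-consistency
  statistic *z = (N⁺ − N⁻)/√N* with the |z| > 3 / overlap-p gate convention.
- **Target prioritization** — filter upregulated differential proteins for
  prior association with pulmonary/cardiac/hepatic/renal fibrosis, expand
  one hop through high-confidence (≥ 0.7) interaction edges, annotate drug
  availability, and emit a deterministically ranked panel.

A seeded synthetic-data generator (`fibroscore.synthdata`) emulates the
3-source × {control, TGF-β-treated} × 3-replicate design with planted
ground truth (negative-binomial counts, coupled log-normal protein
intensities, annotation tables), so the whole pipeline is exercisable and
testable without any external download.

## Worked example

```python
import fibroscore as fs

study = fs.simulate_all(fs.make_fixture_config(seed=1))
manifest = fs.run_pipeline(fs.PipelineConfig(outdir="demo_run", seed=1))
print(manifest["summary"]["prioritization"])
```

prints

```
{'n_upregulated_dep_genes': 42, 'n_disease_associated': 10,
 'n_network_added': 8, 'panel_size': 18, 'n_drug_available': 6}
```

meaning: of the 42 genes whose proteins were upregulated on treatment, 10
carried a prior fibrosis association, 8 more were pulled in through
high-confidence interactions with those, and 6 of the resulting 18-member
ranked panel already have drugs. On the same run the fold-change
correlation between transcript and protein responses rises from r = 0.93
over all 273 matched pairs to r = 0.98 over the 61 differential-protein
pairs, and the ECM/plasma-membrane prevalence rises from 22% of all
proteins to 46% of differential proteins — the qualitative signatures of a
matrisome-centered activation response. Because the fixture plants its
truth, `study.truth.expected_panel` reproduces the 18 panel members
exactly.

The same steps are available from the shell:

```bash
fibroscore simulate --seed 1 --outdir sim/
fibroscore score --counts sim/counts.tsv --samples sim/samples.tsv --out scores
fibroscore de --layer transcript --matrix sim/counts.tsv --samples sim/samples.tsv \
    --source hiPSC-CF --out de_hipsc.tsv
fibroscore run --seed 1 --outdir demo_run/
```

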