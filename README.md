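# methanonet

Analysis pipeline for temperature-dependent structure and function of
methanogenic soil microbial communities, built for factorial
temperature-shift incubation experiments: soils pre-incubated at 25, 35
and 45 °C and then shifted to each of the three temperatures
(treatments such as `I45e25` — soil *I*, pre-incubated at 45 °C,
shifted to 25 °C).

From OTU count tables (16S rRNA, 97 % identity), sample metadata and
gas/isotope measurements it computes:

* **Alpha diversity** — rarefaction to a common depth per domain
  (`rrarefy`-style, without replacement), observed richness, Shannon H′
  (nats), bias-corrected Chao1, Fisher's α, Pielou's J, with
  Kruskal–Wallis + Dunn compact-letter displays per treatment.
* **Community structure** — Bray–Curtis dissimilarities, non-metric MDS
  (SMACOF with restarts, Kruskal stress-1), ANOSIM (999 permutations),
  Hellinger-transform PCA to select the discriminant OTUs (top 25
  archaeal / 50 bacterial absolute loadings on the first two axes), and
  complete-linkage heatmap matrices (log₁₀ percent abundance, floored
  at 0.1 %).
* **Co-occurrence networks** — per soil: abundance filtering (maximum
  within-domain relative abundance ≥ 0.1 % Bacteria / 1 % Archaea),
  Spearman correlations on rarefied absolute reads, edges with
  0.8 ≤ ρ ≤ 0.9 and Benjamini–Hochberg q < 0.01, multilevel (Louvain)
  modularity with direct-formula Q, Fruchterman–Reingold layout,
  module→temperature labelling, and a cross-soil shared-OTU report.
  Exports GraphML/GEXF.
* **Process measures** — apparent isotope fractionation
  α_app = (δ¹³CO₂ + 10³)/(δ¹³CH₄ + 10³); terminal-window pathway calls
  (α_app ≈ 1.08 → CH₄ exclusively from H₂/CO₂, ≈ 1.04 → mixed
  acetoclastic + hydrogenotrophic; threshold 1.06); OLS gas accumulation
  rates; ANOVA + Duncan's multiple range test on log₁₀ qPCR copy
  numbers; volatile-fatty-acid summaries with acetate accumulation
  flags.
* **Synthetic experiment generator** — a fully specified ground-truth
  world (3 soils × 36 samples, temperature assemblages, functional
  guilds, per-soil ecotypes, 45 °C hysteresis, multinomial read
  sampling, isotope and qPCR/VFA series) so every stage of the pipeline
  can be validated against planted structure.  See
  `docs/methods.md` for the model.

## Worked example

Simulate an experiment, build one soil's co-occurrence network and
classify the methanogenic pathway per vessel:

```bash
$ methanonet simulate --outdir demo --seed 2
wrote synthetic experiment (90 OTUs x 108 samples) to demo

$ methanonet network --otu-table demo/otu_table.tsv --metadata demo/metadata.tsv \
      --soil I --seed 2 --outdir demo
82 nodes, 590 edges, Q=0.654, major modules: [1, 2, 3]

$ methanonet isotopes --isotopes demo/isotopes.tsv --out demo/alpha.csv
$ head -4 demo/alpha.csv
sample_id,treatment_code,alpha_app_terminal,pathway
I25e25_r1,I25e25,1.0404017283811344,mixed
I25e25_r2,I25e25,1.0400563843530992,mixed
I25e25_r3,I25e25,1.0403253986651877,mixed
```

The network of the Italian-like soil resolves three major modules
(modularity Q = 0.654), one per incubation temperature; vessels shifted
within the moderate range carry α_app ≈ 1.04, i.e. CH₄ produced by both
acetoclastic and hydrogenotrophic methanogenesis, while 45 °C vessels
of the same soil reach α_app ≈ 1.08 (purely hydrogenotrophic, acetate
consumed by syntrophic acetate oxidizers instead).

The full per-soil pipeline (diversity → ordination → heatmap → network
→ process measures, with a reproducibility manifest) runs with
`methanonet run --seed 1 --outdir results`, or from Python via
`methanonet.pipeline.run(PipelineConfig(...))`.

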