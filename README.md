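# nmdpipe

Transcript-level classification of putative nonsense-mediated-decay (NMD)
targets and the downstream statistics used to compare them across genotypes:

- **transcript_models** — genome FASTA / GTF ingestion, spliced-mRNA
  coordinate maps, protein-coding biotype filter.
- **orf_annotation** — complete-ORF scanning (ATG→stop, three forward
  frames), longest-ORF CDS selection, 5′/3′ UTR derivation.
- **nmd_features** — PTC calls by the 50-nt rule (stop codon strictly more
  than 50 nt upstream of the final exon–exon junction), uORF detection in
  the 5′ UTR, and 3′ UTR length classes (short ≤ 350 nt, long ≥ 1500 nt).
- **expression_analysis** — cuffdiff-style status/zero-FPKM filtering,
  down/up/unchanged classes (default log2FC ≤ −1, p ≤ 0.1), Pearson χ²
  feature-enrichment tests, Wilcoxon rank-sum fold-change comparisons by
  3′ UTR class, restoration analysis across a WT / mutant-A / mutant-B /
  double-mutant design, and hypergeometric (Fisher/EASE) gene-set tests.
- **decay_kinetics** — comparative C_T (2^−ΔΔCt) quantification, log-linear
  first-order decay fits (half-life = ln 2 / k), two-way ANOVA genotype
  comparisons, reporter-intensity ratios.
- **survival_analysis** — Kaplan–Meier product-limit curves, the log-rank
  (Mantel–Cox) test, lifespan summaries with censoring.
- **synthetic** — generators for every input format with planted ground
  truth (feature-first transcript construction, four-genotype expression
  design, exponential decay curves, censored survival tables), so the whole
  pipeline is testable offline.

## CLI

```sh
nmdpipe simulate --seed 1 --outdir out/          # synthetic inputs + truth
nmdpipe annotate --gtf out/annotation.gtf --fasta out/genome.fa \
    --out out/features.tsv
nmdpipe enrich --features out/features.tsv --expression out/expression.tsv \
    --outdir out/enrichment/
nmdpipe halflife --decay out/decay.csv --out out/halflife.tsv \
    --anova-json out/anova.json
nmdpipe survive --survival out/survival.csv --outdir out/survival/
nmdpipe demo --seed 1 --outdir out/ --reproducible   # all of the above
```

Every output table begins with a provenance comment line (version, config
hash, seed); with `--reproducible` timestamps are suppressed so identical
configs yield byte-identical outputs. Key thresholds (`--ptc-distance`,
`--fc-threshold`, `--p-threshold`, `--restore-threshold`,
`--uorf-frame-match`) are flags with the defaults above.

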