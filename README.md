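# chipxpr

Integration of transcription-factor ChIP-seq peak sets with RNA-seq
expression, for studying how TF combinations redirect each other's
activity. The package implements the complete downstream analysis that
connects binding to regulation once peaks have been called and reads
have been counted:

- **Peak-set algebra** on summit-centred windows: two peaks are treated
  as the same binding event iff the *w* bp (default 300 bp) windows
  centred on their summits share ≥ 1 bp. This yields unique/common
  classifications for condition pairs and generalised Venn partitions
  (transitive merge) for three or more TF peak sets.
- **Peak-to-gene assignment**: nearest-TSS annotation with signed,
  orientation-aware distances; association of peak groups with
  expression clusters via a ±5 kb TSS window; genomic feature classes
  (promoter > exon > intron > downstream > intergenic).
- **Known-motif profiling**: IUPAC-consensus and PWM scanning of both
  strands across ±125 bp around each summit, per-peak occurrence
  histograms, positional frequency curves, and a motif-content partition
  of peaks (own motif only vs E-box-containing vs neither).
- **Differential expression**: a self-contained negative-binomial
  pipeline — median-of-ratios size factors, method-of-moments
  dispersion, Wald test on log2 fold change (t reference, n1+n2−2 df),
  Benjamini–Hochberg FDR — with the standard selection rule
  FDR ≤ 0.05 and |log2FC| ≥ 1.5, and PAM (k-medoids) clustering of
  z-scored condition-mean profiles, with optional subcluster splits.
- **Direction-of-regulation analysis**: per motif-class fractions of
  peaks assigned to up-, down- and non-regulated genes, and smoothed
  (Gaussian-kernel) curves of peak density versus signed TSS distance
  over ±30 kb — the view that separates promoter-proximal repression
  from distal co-activation.
- **GSEA**: weighted Kolmogorov–Smirnov enrichment score
  ES = max deviation of the running sum (hits weighted |r|^p / Σ|r|^p,
  misses −1/(N−N_set)), normalised to NES and FDR q by gene-set
  permutation.
- **A synthetic scenario generator** (`chipxpr.synthio`) that emulates a
  three-TF reprogramming experiment — a default factor A, a recruiter P
  that adds A binding at a new gene class, and a co-binder G that sits
  on A's summits without its own motif while repressing its own-motif
  promoter targets — with full ground truth for every peak, motif
  instance and expression cluster, enabling end-to-end validation.

## Worked example

```bash
chipxpr recover --seed 1 --outdir out/
```

generates the default synthetic scenario (2 × 2 Mb genome, 400 genes,
four peak sets across two induced conditions), runs the full pipeline,
and scores recovery of the planted structure. It prints:

```
cluster_ari             1.0000
cobound_common_fraction 1.0000
ebox_up_fraction        0.9500
n_de_recovered          118.0000
own_motif_down_fraction 1.0000
recruited_unique_fraction 1.0000
```

Reading: every peak planted as "recruited by P" was classified into the
GPA-condition-unique class; every co-binder peak placed on a partner
summit was classed common; peaks whose windows contain only the
co-binder's own motif sit at repressed genes (down fraction 1.0) while
E-box-containing co-bound peaks sit at activated genes (up fraction
0.95); and PAM clustering of the 118 recovered DE genes reproduces the
planted four-cluster structure exactly (adjusted Rand index 1.0).

The same run can be driven stepwise (`chipxpr simulate`, `chipxpr run
--config ... --outdir ...`) or from Python:

```python
from chipxpr import synthio
from chipxpr.pipeline import PipelineConfig, run, scenario_recovery

scenario = synthio.build_scenario(seed=1)
paths = synthio.write_scenario(scenario, "out/scenario")
report = run(PipelineConfig.from_yaml(paths["config"]))
print(scenario_recovery(scenario, report))
```

`report.tables` holds every stage output (DE tables, cluster labels,
pair/partition counts, motif histograms and positional curves,
direction tables and curves, the GSEA table) and `report.write(outdir)`
serialises them as TSV with a provenance block.

## File formats

ENCODE narrowPeak (10-column BED6+4, summit offset in column 10; offset
−1 falls back to the interval midpoint), GTF (gene + exon features) or
BED6 gene models, FASTA genomes, TSV count matrices (genes × samples
with a header row), and a plain-text motif format:

```
EBOX<TAB>AWCAGSTGKT          # IUPAC consensus [, max mismatches]
>PWM1<TAB>3.25               # PWM with log2-odds threshold
0.97 0.01 0.01 0.01          # one row per position: p(A) p(C) p(G) p(T)
...
```

All internal coordinates are 0-based half-open; GTF is converted at the
boundary. Chromosome names are taken verbatim and must agree across
inputs.

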