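# Methods

This note documents the models and procedures chipxpr implements, the
defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical conventions that matter
for reproducing results.

## Coordinate and overlap conventions

All intervals are 0-based half-open (BED convention); GTF input is
converted at the boundary and nowhere else. A peak's summit is an
absolute coordinate resolved from the narrowPeak column-10 offset, with
offset −1 mapped to the floor midpoint of the interval — a
deterministic fallback for callers that do not report summits.

The overlap rule is applied to *summit windows*, not peak intervals:
window = [summit − w/2, summit + w − w/2), default w = 300 bp, clipped
at chromosome bounds. "Overlap" means an intersection of length ≥ 1
under half-open arithmetic, so summits 299 bp apart overlap and summits
300 bp apart do not. For k-way partitions the pooled windows are merged
transitively (single linkage): a chain of pairwise-adjacent windows
collapses into one region labelled with every contributing set. This
matches the behaviour of merge-based peak tools and has a documented
consequence: class sizes counted as merged regions differ from class
sizes counted as contributing source peaks, so both are reported
(`n_regions` and `n_source_peaks` in the partition table).

## Peak-to-gene assignment

Each peak is assigned to the gene minimising |summit − TSS| on its
chromosome, ties broken by lexicographically smaller gene id so the
assignment is deterministic. Distances are signed in the gene's
orientation (negative = upstream). Cluster association counts a peak
for expression cluster c iff its summit lies within ±5 kb (inclusive)
of any member gene's TSS; a peak near genes of several clusters counts
once per cluster and the multiplicity is flagged, which is why group
fractions sum to ≤ 1. Genomic features are evaluated at the summit
with priority promoter > exon > intron > downstream > intergenic;
the promoter window defaults to TSS ± 3 kb and the downstream span to
3 kb past the gene end, both exposed in config, since annotation tools
differ on these definitions and hiding them would make feature
fractions irreproducible.

## Motif scanning

Motifs are IUPAC consensus strings matched exactly (optional mismatch
budget) or position probability matrices scored as log2-odds against a
uniform background with an explicit threshold. Both strands of a
±125 bp window around each summit are scanned (250 bp total, the span
conventionally used for motif analysis around ChIP summits). A
palindromic motif hits both strands at the same position; by default
such pairs are de-duplicated to a single hit, and turning the option
off restores per-strand counting. Hits are reported as signed offsets
of the hit start relative to the summit; an instance starting outside
the window is excluded even if it would partially overlap it.

The shipped motif models are *synthetic stand-ins*, not measured
matrices: an extended E-box `AWCAGSTGKT` (CAGSTG core with specific
flanks), a POU-homeodomain-like `ATGCATAWT`, and a zinc-finger-like
`AAATCACTGC`. The E-box stand-in deliberately uses a ~10 bp consensus
rather than the bare 6-mer core: a degenerate 6-mer occurs by chance
roughly once per kilobase of random sequence (≈ 20% of 250 bp scan
windows), which would drown motif-content partitions in noise, whereas
the 10-mer's chance rate is ~4 × 10⁻³ per window — representative of
the specificity of a motif recovered by de novo discovery. Users
substitute their own models through the motif file.

The motif-content partition classes peaks as `ebox_containing` (≥ 1
E-box hit, regardless of other content), `own_only` (≥ 1 own-motif hit,
no E-box), or `neither`. Peaks carrying both motifs go to the E-box
class because the E-box is read as the signature of bHLH co-binding;
this precedence is a declared choice where a dichotomy is genuinely
ambiguous.

## Differential expression

The DE stage is intentionally minimal and fully self-contained so that
its statistical behaviour is testable end to end:

1. **Normalisation** — median-of-ratios size factors: factor_j is the
   median over genes (with positive counts in every sample) of
   count_gj divided by the gene's geometric mean. This estimator
   assumes most genes are unchanged; the synthetic generator respects
   that assumption (see below).
2. **Dispersion** — method of moments per condition,
   α̂ = max(0, (s² − m)/m²), averaged across the two conditions and
   floored at 10⁻⁸. No shrinkage: with the generator's homogeneous
   dispersion there is nothing to pool toward.
3. **Effect and test** — log2FC from shrunken means (pseudo-mean +0.5);
   delta-method standard error
   Var(log2 x̄) ≈ (1/μ + α)/(n ln²2) per group; the Wald statistic is
   referred to a **t distribution with n1 + n2 − 2 df**. With n = 3
   per group the moment-based variance estimate is noisy and a normal
   reference is visibly anti-conservative (empirical type-I ≈ 0.12 at
   nominal 0.05); the t reference restores calibration (≈ 0.045,
   verified by simulation in the acceptance suite). Genes all-zero in
   both groups get p = 1, log2FC = 0, and a flag.
4. **Multiplicity** — Benjamini–Hochberg across genes.

Selection uses FDR ≤ 0.05 and |log2FC| ≥ 1.5 with the fold-change
boundary *inclusive*; a strict (>) mode is exposed in config because
conventions differ.

### Expression clustering

Condition-mean profiles of normalised counts are z-scored per gene
(constant rows map to zero) so clusters reflect expression pattern, not
level, then clustered with PAM (partitioning around medoids): a greedy
deterministic BUILD phase (ties to the lowest row index) followed by
SWAP until no single exchange lowers the total distance to medoids.
The objective is monotone non-increasing across SWAP iterations by
construction, and the whole procedure is deterministic — no random
restarts. Clusters are labelled by decreasing size. An optional
second-level PAM with k = 2 inside one named cluster produces the
familiar major-cluster/subcluster presentation (labels "1A"/"1B"). k is
a user choice; no internal model-selection criterion is applied.

## Direction of regulation

Each peak votes once through its nearest-TSS gene; per motif class the
fractions of peaks at up-, down- and non-regulated genes sum to 1.
Because several peaks can share a gene, both a peak-level and a
gene-level table are emitted. Distance curves are Gaussian-kernel
densities of signed TSS distances per (motif class × direction),
evaluated on a 200-point grid over ±30 kb and scaled so each curve
integrates to its stratum's peak count; bandwidth defaults to 2 kb.
Kernel and bandwidth are presentation choices, declared in config
rather than hidden, and curves near the grid edge lose the mass that
falls outside ±30 kb.

## GSEA

Genes are ranked by signal-to-noise, (m_a − m_b)/(s_a + s_b), with a
zero standard deviation replaced by 0.2·|mean| (the conventional
degenerate-variance fix), or by log2 fold change of means when only one
sample per phenotype exists; ties break by gene id. The enrichment
score walks the ranked list with hit increments |r|^p / Σ_set |r|^p
(p = 1 default; p = 0 recovers the classic KS statistic, which the test
suite cross-checks against a direct implementation) and miss decrements
1/(N − N_set); ES is the extremum of the running sum and lies in
[−1, 1]. The null is **gene-set permutation** — random sets of matching
size — because designs with 2–3 replicates per condition cannot support
phenotype permutation; NES divides ES by the mean magnitude of
sign-matched null scores, nominal p is the same-sign exceedance
fraction, and FDR q follows the standard sign-stratified pooling of
observed and null NES. Everything is deterministic under the supplied
seed.

## The synthetic scenario generator

`synthio` generates, from one integer seed, a genome (default 2
chromosomes × 2 Mb, i.i.d. uniform bases), 400 non-overlapping gene
models on an even grid (strand 50/50, TSS = start or end−1 by strand),
per-TF/condition narrowPeak files, a count matrix, and a truth table.
The planted structure emulates a three-TF reprogramming design:

- factor **A** binds the `neuronal_common` + `neuronal_only` classes in
  the A-only condition and `neuronal_common` + `hc_only` in the full
  (GPA) condition — so `hc_only` peaks are recruiter-dependent;
- factor **P** binds `hc_only` via its own motif in GPA;
- factor **G** copies 25% of A's GPA summits exactly (co-binding
  without its own motif — the planted instance under those summits is
  A's E-box) and binds its own motif at the promoters of the
  `downregulated` class. The 25% default makes G's peak set roughly
  half co-bound and half own-motif, the balance reported for this kind
  of co-binder.

Summits are drawn N(TSS − 50 bp in gene orientation, 20 bp); one
concrete instance of the owning TF's motif is written into the
background **in place** (no insertions, coordinates stable) at a
uniform position fully inside the ±125 bp scan window, with planted
instances kept non-overlapping so every instance is recoverable by the
scanner at 100% sensitivity. narrowPeak intervals are summit ±200 bp
with plausible score/signal/p/q fields.

Counts are negative binomial with per-gene log-normal baselines
(median ≈ 200, log-sd 0.7), dispersion α = 0.1, 3 replicates per
condition, and class-wise planted log2 fold changes of ±3 (|effect| 8×)
per condition: `neuronal_common` up in both induced conditions,
`neuronal_only` up only in A-only, `hc_only` up only in GPA,
`downregulated` down in both — the four planted expression patterns a
k = 4 clustering should recover, with a 280-gene background class
carrying no effect. The background dominates (70% of genes) because
median-of-ratios normalisation is anchored on unchanged genes; a
generator that makes most genes DE breaks the normalisation's core
assumption and with it every downstream fold change, which is also why
real differential-expression fractions (on the order of 10–15% of the
transcriptome) look the way they do.

**What the generator does not emulate:** read-level noise and peak
caller behaviour (peaks are placed, not called), chromatin
accessibility, GC or repeat structure in the background sequence,
correlated replicates or batch effects, gene-length and library-size
biases, overlapping genes and alternative TSSs, and motif affinity
gradients (instances are planted at full consensus match). Passing the
recovery tests therefore demonstrates that the analysis logic is
correct and well calibrated on data whose generative process matches
its assumptions — not that any particular biological dataset will
yield comparably clean structure.

## Problem sizes and determinism

The default scenario (400 genes, ~280 peaks, 4 Mb genome) runs the full
pipeline in a few seconds; the DE calibration simulations use 10,000
null genes for type-I error and 200 planted 8-fold genes for power,
sizes at which binomial noise on the reported rates is ~2% or less.
All randomness flows from explicit seeds through numpy Generators;
regenerating a scenario or re-running a pipeline with the same config
and seed reproduces byte-identical outputs, and the report's
provenance block records the config digest, seed, and every tunable.

## Known limitations

- The DE stage is a two-group test only: no GLM designs, no dispersion
  shrinkage, no transcript-level inference.
- Motif scanning uses a uniform background; no p-value calibration
  against genomic composition, and no de novo discovery.
- Nearest-TSS assignment is a proximity heuristic; no enhancer–gene
  looping or regulatory-domain model.
- GSEA omits leading-edge extraction and multi-phenotype designs.
- Transitive window merging can chain distinct binding events into one
  region in peak-dense regions; the dual region/source-peak counts
  make this visible but do not resolve it.
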