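# rer-escape

Tools for finding **reprogramming-escape regions (RERs)**: genomic spans whose
H3K4me3 histone mark persists through both genome-wide epigenetic
reprogramming windows of the mammalian life cycle — the erasure that follows
fertilization and the second wave in primordial germ cells (PGCs). Given
per-stage ChIP-seq peak sets (sperm, six early-embryo stages, two PGC stages),
the package

1. intersects all stages per base to extract the persistent fragments,
2. classifies each fragment as a presumptive **promoter** (mean H3K4me3 >
   mean H3K4me1) or **enhancer** (the reverse),
3. assigns genomic features (TSS-proximal within ±1 kb / intronic /
   intergenic) and associates genes whose TSS window the fragment overlaps,
4. scans fragment sequences for transcription-factor motifs (e.g. the GC-rich
   SP1/SP2/SP3 and AT-rich SRY families) with **exact** PWM p-values and keeps
   sites whose mean per-base conservation exceeds 0.70, and
5. tests associated genes for differential expression with a strict
   \>2-fold-change filter plus an empirical-Bayes **moderated t** and
   Benjamini–Hochberg FDR < 0.1, alongside hierarchical expression clustering
   and TSS meta-profiles with bootstrap confidence bands.

It is aimed at epigenomics analysts who have stage-wise peak calls (BED /
narrowPeak), signal and conservation tracks (bedGraph), a gene table, a
genome FASTA, motif models (MEME minimal format) and expression matrices —
and at method developers, via a synthetic-data generator that emits all of
these formats with machine-readable planted truth.

## The core operations

**Persistence intersection.** For stage peak sets $S_1,\dots,S_N$ the RERs
are the maximal fragments of $\bigcap_i \mathrm{cov}(S_i)$ (per-base AND),
computed by a single boundary sweep per chromosome and split wherever any
stage's coverage ends. Fragment semantics matter: intersecting wide
embryo-stage peaks (median ≈ 2 kb) with narrow PGC peaks (median ≈ 250 bp)
makes the result *more numerous and narrower* than the input sets.

**Exact motif p-values.** A PWM is converted to log2-odds against the
background, scores are discretized onto an integer lattice (step =
max column range / grid), and the null score distribution is built by
position-wise convolution — so each site's p-value $P(\text{score} \ge s)$
under i.i.d. background is exact at lattice resolution, as in FIMO.

**Moderated t.** Per-gene residual variances $s_g^2$ (df $d_g$) are shrunk
toward a prior $(d_0, s_0^2)$ estimated by moments matching of $\log s_g^2$
against a scaled-F model:
$\tilde s_g^2 = (d_0 s_0^2 + d_g s_g^2)/(d_0 + d_g)$,
$\tilde t_g = \widehat{\Delta}_g / (\tilde s_g \sqrt{1/n_A + 1/n_B})$ on
$d_0 + d_g$ degrees of freedom (the limma statistic; the test suite
cross-checks it against limma's `eBayes` through Rscript).

## Worked example

Generate a synthetic bundle and run the whole analysis:

```bash
rer-escape simulate --out demo --seed 1
rer-escape run --config demo/pipeline.yaml
```

The second command prints the intersection summary:

```json
{"n_early_regions": 55, "n_rers": 78,
 "early_width_stats": {"median_width": 1312.0, ...},
 "width_stats": {"median_width": 231.0, ...}, ...}
```

Reading it: the seven sperm/embryo stages share 55 persistent regions
(median 1312 bp); adding the two narrow-peak PGC stages *splits* them into
78 fragments with the median width dropping to 231 bp — the signature of
per-base persistence through both reprogramming windows. The full report
(`demo/results/report.json`) continues: 94.87% of fragments classify as
promoters, 92.31% lie within 1 kb of a TSS, 47 genes are associated, 35
motif sites survive the conservation filter, and 15 of the 47 associated
genes are called differentially expressed between the two sample groups —
all of which match the bundle's planted truth exactly.

Each stage is also available as a standalone subcommand (`rers`, `annotate`,
`scan`, `de`) over the documented file formats.

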