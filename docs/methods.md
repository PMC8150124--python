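# Methods

## Problem and model

Histone H3K4me3 marks are largely erased twice in the mammalian life cycle:
after fertilization and again during primordial-germ-cell (PGC)
development. A *reprogramming-escape region* (RER) is a genomic span whose
H3K4me3 signal is present in sperm and at every surveyed stage of both
windows. Operationally this package defines an RER as a maximal fragment of
the per-base intersection of N stage-wise peak sets: a base belongs to an
RER iff every stage's (normalized) peak set covers it, and fragments split
wherever any stage's coverage ends.

Fragment (per-base AND) semantics — rather than reporting a whole source
peak whenever all stages overlap it — is a deliberate choice: when wide
early-embryo peaks (median ≈ 2 kb) are intersected with narrow PGC peaks
(median ≈ 250 bp), one wide region typically contains several narrow peaks,
so the escape set becomes simultaneously **more numerous** and **much
narrower** than the embryo-only set. Only fragment semantics produces that
joint behaviour; whole-peak reporting could never shrink the median below
the narrowest input peak containing each overlap.

Coordinates are 0-based half-open (BED convention) everywhere internally;
chromosome names are compared by exact string match. The production
intersection is a boundary sweep (O(total intervals · log) per chromosome);
a dense per-base bitmap implementation exists only as a test oracle.
Provenance records, per stage, the first source interval by coordinate that
overlaps each fragment — a deterministic tie-break for the rare case where
several pre-normalization source peaks cover one fragment.

## Annotation

* **Promoter/enhancer**: a region is a presumptive promoter when its
  length-weighted mean H3K4me3 intensity strictly exceeds its mean H3K4me1
  intensity, an enhancer in the reverse case. Mean (length-normalized)
  signal is used rather than total signal so the label is invariant to
  region width; the comparison is scale-equivariant, so joint rescaling of
  both tracks never flips a label. Ties default to *promoter*, because the
  regions are defined by H3K4me3 presence in the first place; the tie label
  is configurable.
* **Feature category** uses the region **midpoint**: TSS-proximal if the
  midpoint lies within ±`tss_window` (default 1000 bp) of any TSS, else
  intronic if inside any gene body, else intergenic. The midpoint rule makes
  the three categories a partition (counts always sum to n), which
  any-overlap would not. Exonic non-TSS bases are folded into the gene-body
  category.
* **Gene association** uses **any-overlap** of the region with the closed
  window [tss − w, tss + w]: association feeds gene-level analyses, so
  recall is preferred over partition cleanliness. Many-to-many links are
  allowed (divergent promoters yield two genes); per region, genes sort by
  TSS distance then id.
* **TSS meta-profile**: rows are region–TSS pairs, columns strand-oriented
  bins (default 50 bp across ±1 kb), entries the covered fraction of each
  bin. The confidence band is a percentile (2.5, 97.5) bootstrap over row
  resampling, default 1000 resamples, seeded from the config.

## Motif scanning

PWMs (probability matrices over A,C,G,T with a background, default uniform)
are converted to log2-odds with a FIMO-style pseudocount (default
0.01 · background; a zero probability with zero pseudocount gives −inf,
which the p-value machinery rejects). Site p-values are **exact under the
i.i.d. background model**: per-column scores are discretized onto an integer
lattice with step = max(column range)/grid (default grid 1000) and the null
distribution of the lattice window score is built by position-wise
convolution. Observed windows are scored on the same lattice, so dynamic
programming and exhaustive 4^w enumeration agree exactly, and empirical
calibration on background sequence holds to Monte-Carlo error. Both strands
are scanned (reverse complement = matrix flipped in both axes); windows
containing N are skipped; hits at p ≤ 1e-4 (default) are reported without
multiple-testing correction, because the downstream filter is conservation,
not FDR.

Conservation per site is summarized as the **mean** per-base score over the
site span (uncovered bases count 0; `min` available via config); a site is
retained iff its summary is strictly greater than 0.70.

## Expression statistics

* **Fold-change filter**: ratio of linear-scale group means with an ε = 0.1
  offset guarding empty denominators; a gene passes iff max(FC, 1/FC) is
  *strictly* greater than the threshold (default 2), matching
  "more-than-2-fold" semantics exactly at the boundary.
* **Moderated t**: data are log2(x + 0.1) unless already logged. The prior
  (d0, s0²) is estimated by moments matching of log s² against a scaled-F
  model (inverse-trigamma step; d0 = ∞ when the sample variance of log s²
  falls below the sampling noise floor), the posterior variance blends prior
  and per-gene variance, and the statistic is referred to t on d0 + d_g df.
  Forcing d0 = 0 recovers the ordinary pooled t; d0 = ∞ shrinks fully to
  s0². No intensity trend or sample weights are fitted — the constant-prior
  statistic is the scope here. The test suite cross-checks t, p, d0 and s0²
  against limma's `eBayes` via Rscript on simulated data.
* **DE rule**: default order is filter-then-test — the moderated test and
  the BH adjustment run only on genes passing the fold filter; a `joint`
  order (test everything, intersect afterwards) is available because the
  original sequencing of the two filters is ambiguous. A gene is called iff
  FC > 2 (strict) and BH q < 0.1, both thresholds configurable.
* **Clustering**: genes are z-scored, distance = 1 − Pearson correlation,
  average linkage, tree cut to exactly k = 4 clusters; labels are
  renumbered in order of first appearance so output is deterministic given
  input order. This is the conventional expression-heatmap default; the
  original choice of algorithm behind the four published clusters is not
  recorded, so the method is exposed in config rather than asserted.
* **With/without-region comparison** pools per-gene mean expression across
  stage columns before a classical pooled-variance Student's t (Welch via
  flag); per-stage testing was considered and left out of the default
  because the pooled contrast is what a single box-plot comparison shows.
* **Enrichment**: one-sided hypergeometric tail per term (the Fisher-exact
  enrichment p), BH across terms. Term maps are caller-supplied; no GO
  database is bundled.

## Synthetic data

The generator emulates the study conditions: nine stage labels (sperm, five
preimplantation stages + ICM, two PGC stages); wide embryo peaks (log-normal,
median 2000 bp) and narrow PGC peaks (median 250 bp); a fixed composition of
persistent loci carrying 1–3 narrow "cores" each (30/12/8 by default, so 50
loci yield 78 cores deterministically); embryo-window decoys (omitted from
≥1 early stage) and PGC-window decoys (present through the first window,
lost in the second — the early-escape-only regions); 40 independent
background peaks per stage; promoter labels Bernoulli(0.964); feature
categories drawn at the published proportions (92.83 / 2.79 / 3.98%); planted
GC-rich (SP-like, 10-mer) and AT-rich (SRY-like, 9-mer) consensus sites with
per-base conservation 0.9 (plus deliberately weak 0.3 sites to exercise the
filter); and two expression matrices — a stage matrix with four planted
block profiles (amplitude 2, noise sd 0.5) on the associated genes over a
higher baseline, and a two-group matrix (4 vs 4 samples) with 15 planted DE
genes at |log2 effect| = 2 and noise sd 0.5.

Recovery is guaranteed by construction: every stage's peak contains each
core and the final PGC stage's peak *equals* the core, pinning the nine-way
AND to the core exactly; decoys omitted from any stage can never survive a
per-base AND; planted entities occupy disjoint 15 kb placement blocks so
background peaks and filler genes cannot contaminate the truth. Chance
nine-way persistence of independent background peaks is negligible at the
default densities (expected persistent bases ≪ 1 per genome).

What the generator does **not** emulate: read-level noise, fragment-size and
mappability artefacts, peak-caller boundary jitter correlated across stages,
real genome composition and repeat structure, PhastCons granularity, and
expression count distributions (values are Gaussian on the log scale).
Passing the planted-truth suites therefore demonstrates algorithmic
correctness of each stage on its defined inputs, not robustness to upstream
measurement error.

## Numerical choices and degenerate inputs

Score-lattice step = max column range / grid; p-values are monotone on the
lattice by construction. A motif wider than its sequence yields an empty
result, not an error. Uncovered track bases are 0 in every mean. Equal
constant groups give t = 0, p = 1. BH rejects p outside (0, 1]. Clustering
rejects constant rows (undefined correlation). The intersection of book-ended
intervals merges before intersection, so zero-width fragments cannot arise;
`min_width` (default 1 bp) discards sub-threshold fragments.

## Problem sizes

Default bundles use a 3 Mb two-chromosome genome, 50 persistent loci
(78 cores), 15 decoys, ~110 genes and 100k-window calibration runs; the
planted-truth suite aggregates 20 seeded bundles. These sizes give stable
recall/calibration statistics while keeping a full test run around ten
seconds.

## Known limitations

Single-threaded; no bigWig/BAM input (text formats only); the gene-table
reader is annotation-agnostic and does not parse full GTF attributes; the
moderated t omits limma's trend and robust options; enrichment requires a
user-supplied term map; conservation summaries other than mean/min are not
implemented.
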