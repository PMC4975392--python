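# Methods

## Design of the analysis

The pipeline targets pooled-library MeDIP-seq designs: each condition
is a single sequencing library made by pooling biological replicates
before immunoprecipitation, so no replicate-level dispersion can be
estimated and all inference is count-based between two libraries.
That constraint drives the statistical choices below and is the main
limitation of the whole design: Fisher's exact test on pooled counts
treats biological variability as zero, so its p-values are
anti-conservative for biological claims.  The fold-change filter
(≥ 2 or ≤ 0.5) is what keeps calls interpretable.

All genomic coordinates are 0-based half-open (BED convention)
internally; BED12 gene models arrive in that convention already, and
chromosome names match by exact string, with no aliasing.

## Reference peak set

Per-sample peak calls merge by single-linkage over the ≥ 1 bp overlap
relation; half-open intervals that merely touch do not merge.  The
result is disjoint, sorted, and stable under re-merging, with
`peak_00001`-style identifiers assigned in coordinate order and the
contributing samples recorded per peak.  Reads are assigned to the
unique REF peak with the largest overlap; since REF is disjoint only
boundary-spanning reads are ambiguous, and those break ties to the
leftmost peak.  Library size is the total number of supplied read
intervals (per-million *mapped* reads), not reads-in-peaks; each
supplied interval counts as one unit regardless of read pairing.

## Feature windows and peak annotation

Per transcript: promoter = 3 kb upstream of the TSS, downstream = 5 kb
past the transcript end, TSS window = ±1 kb, all strand-mirrored and
clipped to chromosome bounds; introns are the per-transcript complement
of exons; exon windows are unioned across a gene's transcripts so
isoform-shared exons are not double counted.  Each peak gets exactly
one label by precedence promoter > exon > intron > downstream >
intergenic (≥ 1 bp overlap qualifies).  Promoter-first reflects the
usual emphasis on promoter methylation; the ordering is a convention,
not a statistical claim, and UTR and repeat windows take part in
region-level quantification but not in the 5-way annotation.
The downstream annotation width (5 kb) is a config knob
(`downstream_bp`), as the appropriate width is genuinely ambiguous.

Region-class RPKM counting is independent per class — a read may count
toward exon *and* whole-gene, because the classes overlap by
construction — but at most once within a class (largest-overlap
instance, ties to the leftmost).

## CpG islands

The searcher follows the classic sliding-window procedure: a 200 bp
seed window steps 1 bp until GC % and ObsCpG/ExpCpG criteria are met;
the candidate extends in 200 bp jumps while successive windows qualify,
then extends 1 bp at a time while the trailing 200 bp window still
qualifies (without this fine step, island tails shorter than one jump
would be clipped); the whole candidate is then trimmed 1 bp at a time
until it satisfies both criteria over its full extent.  When both ends
are trimmable, the end whose removal raises GC % more goes first, right
end on ties — an arbitrary but deterministic rule.  Candidates
separated by < 100 bp merge when the merged span still qualifies
(`merge=False` reports raw candidates), and candidates shorter than
500 bp are discarded.  N bases count toward window length but never
toward C, G or CpG, and N-runs of at least one scan window split the
sequence into independent segments so islands cannot span assembly
gaps.  Every reported island provably satisfies all three criteria;
the test suite checks completeness against an exhaustive window scan.

Defaults (GC ≥ 55 %, O/E ≥ 0.65, length ≥ 500, window 200, gap 100)
are exposed in `IslandParams`.

## Differential methylation

For each REF peak and comparison, the 2×2 table is
(reads in peak, all other reads) × (treatment library, control
library) — the standard margin construction for unreplicated pooled
designs.  The two-sided rule is minimum-likelihood summation (sum of
all hypergeometric outcomes no more probable than the observed one);
the tail-doubling variant is available behind a flag.  BH correction
spans all REF peaks of a comparison.  Fold change uses pseudocounted
RPM, (rpm_t + c)/(rpm_c + c) with c = 0.5 RPM by default, so
zero-count peaks remain callable; "2-fold" is symmetric (≥ 2 or
≤ 0.5) since both hyper- and hypomethylation matter.  CRMs are the
direction-agnostic intersection of the two treatment DMR sets, with a
concordance flag.

Region-level comparisons are paired two-sided t-tests across region
instances on log₂(RPKM+1), with BH correction pooled across every
(class × comparison) test emitted together.  A zero-variance nonzero
shift reports a p floor of 1e-300 rather than NaN; classes with fewer
than two instances are skipped with a warning.

## Pathway and GO statistics

A peak associates with a transcript when it overlaps the gene span, the
3 kb promoter or the 5 kb downstream window; associations propagate
transcript → KO → pathway, and a peak can serve many pathways.
Pathways need ≥ 5 linked peaks (`min_peaks`): a signed-rank test on
fewer pairs cannot reach p ≤ 0.05 two-sided.  The signed-rank test
drops zero differences, average-ranks ties, and computes the exact
two-sided p — P(|W − E[W]| ≥ |w − E[W]|) over all sign assignments,
evaluated by a subset-sum recursion over doubled ranks — for up to 25
nonzero pairs, switching to a normal approximation with tie correction
and 0.5 continuity correction beyond that.  The test runs on RPM pairs
(not log RPM): a log transform changes difference ranks, and raw RPM is
the scale on which the median-ratio criterion is defined.  The median
RPM ratio is the median of per-peak pseudocounted ratios by default;
the ratio-of-pathway-medians reading is available via `median_mode`
since the construction is genuinely ambiguous.

GO enrichment: foreground = genes linked to ≥ 1 DMR (union of the two
treatment-vs-control comparisons), background = genes linked to ≥ 1
REF peak.  Annotations propagate to all is_a ancestors before
counting (part_of edges are not followed — the smallest defensible
closure); each term annotated in the background is scored with the
hypergeometric upper tail, and BH correction spans those terms.  Three
reporting tiers: enriched (p ≤ 0.05, ratio ≥ 1.3), table tier (adds
FDR < 0.2), figure tier (ratio ≥ 1.5).

## Synthetic data generator

The generator emulates the study's input data at desk scale, with every
stage drawing from its own RNG stream keyed by (seed, stage) so stages
are independently reproducible.

* **Genome** — two 500 kb chromosomes of ~40 % GC background; 300
  genes (2–8 exons of 80–150 bp, introns 200–800 bp) packed without
  overlap; 100 repeats per class; 60 CpG islands of 700–1200 bp built
  CG-rich (GC ≥ 60 %, O/E ≥ 0.8 — margin above the 55/0.65 detection
  thresholds) and verified at generation time.  After assembly the
  background is rescanned and any accidental qualifying 500 bp window
  is rewritten, so the planted islands are provably the only ones.
* **Methylome** — 3 000 peak loci of 100–200 bp, packed with a 60 bp
  guard gap (so ±25 bp call jitter can never merge neighbours) into
  precedence-resolved feature pools sampled with probabilities
  promoter 0.08 / exon 0.12 / intron 0.39 / downstream 0.03 /
  intergenic 0.38.  The miniature genome is far denser in genes than a
  real one (≈ 3.3 kb per gene), so 3 kb promoter windows blanket most
  of it: quota a pool cannot hold spills into remaining space, and the
  realized label mix is promoter-heavy with essentially no intergenic
  peaks.  This is a deliberate fidelity trade-off — the placement
  probabilities are honoured as far as the geometry permits — and it
  means recovery tests say nothing about annotation *proportions* on
  real genomes, only about the correctness of the labelling itself.
* **Differential truth** — 10 % of loci are DMRs at folds 2–8 (half in
  both treatment comparisons, forming the CRM truth; a quarter each in
  only one).  Hyper/hypo directions are assigned by greedy
  intensity-mass balancing so per-condition totals stay matched:
  otherwise hypermethylation (×f) adds more mass than hypomethylation
  (÷f) removes and RPM renormalisation drags every null peak downward.
  DMR loci are chosen so their linked genes stay ≤ 25 % of all genes,
  keeping GO enrichment of DMR genes a recoverable signal rather than
  a near-complete background.
* **Pathway/GO truth** — one KO per gene on 1–2 of 30 pathways; the two
  smallest pathways with ≥ 20 linked peaks get coordinated shifts
  (×0.5 and ×2) in the 5-day condition; 5 of 150 ontology terms are
  planted with annotations concentrated on DMR-linked genes and kept
  childless so ancestor propagation cannot dilute them.
* **Reads** — per peak and sample, counts are Poisson with rate
  lib_size · 0.95 · intensity / Σintensity (baseline intensity
  LogNormal(0, 0.5)); reads are 50 bp, uniform within their peak; 5 %
  of the library is uniform genomic background.  Per-sample peak calls
  are loci whose sampled count reaches 10, with ±25 bp boundary jitter,
  which makes the per-sample peak sets disagree slightly and exercises
  REF merging.

What the generator does **not** emulate: sequence evolution, CpG-level
methylation, fragment-length or GC bias, mappability, sequencing error,
replicate variability.  Passing recovery tests therefore demonstrate
the pipeline's correctness under idealized Poisson sampling, not
robustness to real-data artefacts.

## Problem sizes and numerical conventions

Tests and the acceptance script run three simulation scales: a small
study (2 × 120 kb, 600 peaks) for unit-level checks, the default study
above, and a recovery study (1 900 peaks, 200 000-read libraries,
fold fixed at 4) sized so the mean depth is ~100 reads per peak with
over 1 000 null peaks for the false-call-rate estimate.  The
100-repetition pathway-recovery check simulates a 20-peak pathway at
≥ 50 reads/peak directly rather than re-running the full pipeline per
repetition.

TSV outputs render floats at 6 significant digits with NaN as `NA` and
deterministic row order, so identical runs are byte-identical.
Clustering uses Euclidean distance with average linkage (exposed in
config) on log₂(RPM+1); dendrograms export as Newick.  Fisher, BH,
hypergeometric-tail and linkage computations delegate to
scipy/statsmodels; the Wilcoxon signed-rank statistic is implemented
here because a tie-aware exact two-sided distribution is needed, and it
is verified against full 2ⁿ sign enumeration in the tests.
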