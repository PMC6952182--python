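# Methods

This note documents the statistical models implemented in `accessome`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Coordinate conventions and accessome construction

All internal coordinates are 0-based half-open (BED convention); GFF3 input
(1-based inclusive) is converted at parse time so a single convention exists
everywhere. The accessome is built by pooling all input peak sets, merging
overlapping *and* book-ended intervals (end == next start), and removing
merged regions of length ≤ 50 bp — i.e. length 51 is the minimum retained.
Merging is unstranded, as ATAC-seq peaks carry no strand. Peak IDs are
`chrom:start-end`, assigned in (chrom, start) order, so identical inputs
always produce identical IDs. Merging is idempotent and invariant to the
order of the inputs (property-tested).

## Feature annotation

The TSS is anchored at the start of the annotated 5′UTR. This matters in
*Ciona*, where spliced-leader trans-splicing replaces the 5′ end of roughly
half of all mRNAs, so the mRNA 5′ end is not the transcription start; the
annotated 5′UTR is the best proxy. Transcripts without a 5′UTR fall back to
the transcript span boundary. Window widths: TSS ±107 bp (a TSS-cluster-
derived core-promoter half-width, taken as given), promoter = 1 kb upstream
of the TSS split into proximal and distal 500 bp windows (on the minus
strand the promoter lies at coordinates greater than the TSS), TTS ±200 bp
around the 3′UTR end boundary. Introns are the transcript span minus its
exons; all windows are clipped to chromosome bounds.

Classification is multi-label — a peak carries every feature it overlaps by
≥ 1 bp, and a peak touching nothing is intergenic — because each feature is
tested for enrichment independently. A single `primary_label` is also
reported using the precedence TSS > promoter > 5′UTR > exon > 3′UTR > TTS >
intron, for distribution summaries.

Peak–gene association uses the union span of all transcripts of a gene
extended ±10 kb on both sides; the distance is 0 for overlapping peaks and
otherwise the signed gap (negative upstream in genome coordinates). The
span-based dialect is the superset of per-anchor (TSS/TTS-only)
association and is the one shared by every downstream module, so
"associated with" always means the same thing.

Feature enrichment is an exact two-tailed binomial test with k = peaks
overlapping the feature, n = total peaks and p₀ = the feature's genome
fraction. The two-sided p-value is minimum-likelihood summation (the total
probability of all outcomes no more probable than the observed one), which
is well defined for asymmetric nulls; doubling one tail is not used. The
same engine serves the gene-class peak-count test (p₀ = the class's share of
genes — a documented choice, as the original null construction is not fully
specified) and the intersection-independence test below.

## Differential accessibility

Counts are modelled per peak as NB(μ, α) with Var = μ + αμ², log link and a
log size-factor offset. Size factors are median-of-ratios, falling back to
library-size scaling when fewer than 100 peaks have all-positive counts.
Libraries with fewer than 500,000 total fragments are removed before
modelling (strict inequality); a design cell left with fewer than two
replicates is an error.

Dispersion: a per-peak method-of-moments estimate from cell-pooled residual
variances, shrunk toward a mean–dispersion trend fitted by Huber robust
regression of log α on log mean. Two numerical details matter at small
replicate numbers. First, because the pooled variance estimate behaves like
Var·χ²_d/d, its logarithm is biased low by ψ(d/2) − log(d/2); this bias is
removed before the trend fit and shrinkage. Second, the per-peak component
and the trend are combined on the log scale with weight d/(d + prior_df),
prior_df = 10 — the same moderation logic as variance shrinkage in moderated
linear models, giving the trend more weight when residual degrees of freedom
are few. Without both corrections the null rejection rate at α = 0.05 ran
near 0.085 in 4-vs-4 simulations; with them it is calibrated (validated by
simulation in the test suite). The empirical-Bayes machinery of dedicated
count packages is deliberately not replicated; behaviour is validated by
type-I calibration and planted-effect recovery, not by matching another
package's output.

Both designs of a nested pair are fitted by IRLS vectorized across peaks
(the design matrix is shared; the working weights μ/(1 + αμ) are per-peak),
the LRT statistic 2(ℓ_full − ℓ_reduced) is referred to χ² with df equal to
the design rank difference, and FDR is Benjamini–Hochberg over tested peaks.
All-zero peaks and non-converged fits are NA and excluded from the
correction. Reported log₂ fold changes are raw coefficient differences for
the named pairwise contrast — no shrinkage — because the set definitions
downstream threshold on them and a shrunken estimate would change set
membership; since the LRT tests the whole factor, each pairwise contrast of
interest is reported as its own table.

The four standard designs: (1) condition factor among 10 hpf samples vs
intercept; (2) perturbation + time factor among 15–20 hpf samples vs time
only; (3) control time course vs constant accessibility; (4) lineage + time
vs time only against the outgroup lineage. RPKM
(count / (peak kb × library millions)) with Spearman correlation over the
differential peaks provides the replicate-concordance QC.

Known numerical limits: the log₂FC invariance under joint doubling of counts
and library sizes is exact only at α = 0 — at fixed dispersion the variance
weights shift slightly (observed ≤ 2×10⁻³ per unit log₂FC) — and the
χ²-based LRT is asymptotic, so mild miscalibration is expected below ~3
replicates per cell.

## Peak-set and gene-set algebra

All printed thresholds are strict inequalities: a peak at log₂FC = −0.5
exactly is excluded. The six accessibility sets are unions/intersections of
thresholded contrasts; *de novo* elements are those closed at 10 vs 18 hpf
in controls minus the FGF-MAPK-opened set, and *primed* elements are the
FGF-MAPK-opened set minus those still closed at 10 vs 18 hpf, which makes
primed ∩ de novo empty by construction. Expression gene sets use the same
grammar (sign, |log₂FC| threshold, FDR or raw-p threshold, combine rule);
microarray-era comparisons threshold the unadjusted p-value, sequencing-era
ones the FDR, exactly as each definition states.

Primed/de novo elements are split into cardiac- vs pharyngeal-muscle(ASM)-
accessible classes by the sign of the 18 hpf perturbation responses (strict
signs; log₂FC = 0 fails both rules), then elements associated with a
conflicting program (ASM elements near cardiac or MAPK-inhibited genes,
cardiac elements near ASM or MAPK-activated genes) are removed, so an
element's accessibility cannot be attributed to an earlier-expressed
neighbour.

The intersection-independence test treats each set's universe fraction as an
independent marginal: for an intersection pattern the null probability is
the product of the constituent fractions, and the observed intersection
count is referred to the exact two-tailed binomial. For a single set the
observed count equals n·p₀, so the p-value is 1.

## Peak-level GSEA

A gene set maps to the set of all peaks associated with any member gene.
Peaks are ranked by a contrast's log₂FC and the classic weighted
Kolmogorov–Smirnov running sum is computed: member steps add |stat|^w
normalized by the member total, non-member steps subtract 1/(N − m); the ES
is the signed extremum. The weight exponent defaults to 1 (the cited
implementation's default); w = 0 — the literal "running tally of whether or
not" reading — is supported and recorded in the output. Sets smaller than 5
members in the ranking are skipped; there is no upper size limit by
default.

The permutation null shuffles membership labels over the ranked list (peak
permutation, not phenotype permutation): each of the 10,000 default
permutations draws m random positions. NES divides the observed ES by the
mean |ES| of same-sign permutations (the standard sign-split normalization);
p-values count same-sign permutations at least as extreme, with the +1
correction so that finite permutation counts never yield p = 0. With a fixed
seed results are bit-reproducible. The adaptive multilevel p-value refinement
of the cited implementation is out of scope.

## Motif toolkit

PWMs are probability matrices with a pseudocount of 0.8 split by the
background composition (a common default; recorded in each PWM's
provenance). Scores are log₂(p_PWM/p_bg) summed over positions. The match
threshold for a p-value cutoff (default 5×10⁻⁵) is found by exact dynamic
programming over the background score distribution on a discretized grid
(granularity 10⁻³ bits, configurable — the only source of threshold
tolerance, and scanning uses the same integer grid, so threshold comparisons
are exact). A matrix for which no score is rare enough (e.g. a uniform PWM)
returns +∞ with a warning: no position can match. Background nucleotide
frequencies are computed from the full accessome sequence set. Both strands
are scanned; ambiguous bases (N) score zero and cannot create a match; a
motif's occupancy of a peak is binary (any hit), matching the peak-level
unit of the enrichment test.

Motif enrichment of a peak set versus the accessome is one-tailed
hypergeometric on occupancy counts; the odds ratio is in-set odds over
whole-accessome odds, [a/(n−a)] / [m/(N−m)], with a Haldane 0.5 continuity
correction (flagged) when a zero cell makes the ratio undefined; a
relative-risk variant is available behind a flag. FDR is BH across motifs.

Motif→TF assignment resolves a many-to-many candidate catalog so every
assigned motif maps to exactly one TF: all motifs with exactly one remaining
candidate are assigned; associations pointing at TFs that now own a motif
are dropped (a motif left with no candidates stays unassigned); this
propagates to a fixed point; if ambiguous motifs remain, the one with the
fewest remaining candidates (ties by motif ID) is assigned to its
lexicographically smallest TF and propagation restarts. The escalating
fewest-candidates-first order reproduces the documented two-TF, three-TF,…
stages, and the explicit tie-break makes the procedure deterministic, which
the original description leaves open. Assignment terminates on any finite
catalog (each step removes a motif from the pool); TFs that never receive a
motif are reported unassigned.

## Deviation Z-scores

Peaks are resized to 200 bp around their centers (floor midpoint, clipped at
chromosome bounds) before GC computation. A motif's observed accessibility
in a sample is the summed fragment count over motif-bearing peaks; its
expectation redistributes the motif's grand total across samples in
proportion to library size, so the raw deviation (obs − exp)/exp is zero for
a sample that behaves like the pooled average, and the library-size-weighted
mean deviation is exactly zero for every motif. Deviations are exactly
invariant under a common rescaling of all samples' counts and library
sizes; rescaling a single sample is *not* an exact invariance of this
formula, because the grand motif fraction reweights.

Backgrounds: peaks are ranked into equal-frequency bins (10 per dimension by
default) of GC content and mean normalized accessibility, and each
iteration (50 by default, the cited tool's default; at least 2 are required
for a standard deviation) replaces every peak by one sampled with
replacement from its own 2-D bin. Equal-frequency binning guarantees every
peak's bin is non-empty. Background deviations are computed with the
background matrix's own column totals as library sizes — this is what makes
a motif covering every peak deviate exactly zero in every iteration
(degenerate case: background sd 0, Z-score NA, flagged). The Z-score is
(raw − mean_bg)/sd_bg and is invariant to the order of background
iterations. Differential deviations between sample groups use a Welch
t-test (two groups) or one-way ANOVA (more), BH-corrected, reported
significant at FDR < 0.01. In the pipeline, deviations are computed on the
peaks pre-selected as differential (FDR < 0.05) in the 10 hpf design, with
that pre-selection exposed as an input filter.

## Synthetic data

The generator emulates the *design* of a lineage-resolved developmental
ATAC-seq study, not its sequence content: an i.i.d. background genome at
GC 0.36 (tunicate-like), non-overlapping gene models with exons and UTRs,
non-overlapping peaks spread along each chromosome, NB fragment counts with
planted effects, and sharp 8-bp motifs planted into chosen truth sets.

Defaults, chosen once as a desk-scale emulation: 4 chromosomes × 400 kb;
160 genes; 800 peaks of 120–260 bp (≈9.5% genome coverage, mirroring the
study-scale proportion); three replicates per design cell over the cells
(B7.5 control at 6/10/18 hpf; receptor-blocked and MAPK-activated at
10 hpf; receptor-blocked and ectopic-MAPK at 18 hpf; mesenchyme controls at
10/18 hpf); NB dispersion 0.1; planted |log₂FC| = 2; per-peak base means
log-uniform on [400, 2000] so library totals clear the 500,000-read filter;
library factors log-uniform on [1.0, 2.5], with one deliberately shallow
replicate (factor 0.05) that the filter must remove. Planted set sizes put
the 6→10 hpf closing:opening ratio at 200:109 ≈ 65% closing, the
study-scale proportion. Planted motifs: a Forkhead-like consensus in the
FGF-MAPK-opened set, a T-box-like consensus in the closing (naive-mesoderm)
set and an EBF-like consensus in the de novo ASM set, at insertion rate 1.0,
with two never-planted decoys; planted PWMs put probability 0.997 on the
consensus base so a sampled site is almost always scannable. DE tables are
generated from the gene-set truth (genes near planted peak classes) with
planted log₂FCs of ±2 and null genes drawn from N(0, 0.25).

What passing on synthetic data does and does not show: the generator draws
counts from exactly the NB family the DA model assumes, sequences are
i.i.d., peaks never overlap features ambiguously, and motif instances are
planted rather than evolved — so the tests validate the statistical
machinery and its calibration, not robustness to real-data pathologies
(GC-dependent amplification bias, overlapping genes, copy-number variation,
repeat-driven multi-mapping, dispersion outliers). All randomness flows from
a single seed through integer NumPy streams, so bundles are byte-identical
across runs.

## Pipeline

Stage order is accessome → annotate → da → sets → gsea/motifs/deviations,
with dependencies enforced (enabling a stage without its prerequisites is an
error naming the stage). Each stage writes its reports under its own
subdirectory, write-once; `manifest.json` records the package version, every
threshold actually applied, the seed, and SHA-256 checksums of all inputs
and outputs, so two runs with the same config and seed can be verified
identical by comparing manifests. Configuration is YAML with every default
overridable; logging goes to stderr and a file.

## Problem sizes used in validation

The test suite and the acceptance script use the default 800-peak bundle for
end-to-end runs, 2,000-peak simulations for LRT calibration and recovery,
10,000 permutations for the planted-set GSEA check and 1,000 for the
200-set uniformity check, exhaustive 4^L enumeration up to L = 8 for PWM
thresholds, and 1,000 random catalogs for assignment termination — sizes at
which every oracle comparison is exact or statistically stable.
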