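# Methods

This note documents the statistical models, the synthetic-data generators,
the numerical choices, and the known limitations of `osn-identity`.

## Scientific setting

Each mature olfactory sensory neuron (OSN) expresses a single odorant
receptor (OR) gene; the set of neurons expressing the same OR is an *OSN
population*. The package quantifies (i) whether cells of the same
population are transcriptomically closer to each other than to cells of
other populations, (ii) whether between-population transcriptomic distances
are better predicted by the genomic proximity of the OR genes (shared
cis-regulatory context) or by the sequence similarity of the receptors
themselves, and (iii) whether odorant-evoked expression changes reflect
transcription or mRNA stability (exon–intron split analysis, EISA).

## Population distance model

Cells are embedded by PCA of library-size-normalized, log-transformed
counts (counts scaled to 10⁴ per cell, natural log, pseudocount 1; genes
centred and unit-scaled, zero-variance genes dropped). The number of
retained components is chosen by kneedle elbow detection on the explained
standard deviation of the top 50 components (sensitivity S = 1, convex,
decreasing; offline, no smoothing). When no knee exists (e.g. a flat or
linear decrease) the fallback returns min(15, n) with a warning.

Pairwise Euclidean distances over the selected components split into
*intra* (same population) and *inter* (different population) sets. The
effect size is Cohen's d,

    d = (mean(intra) − mean(inter)) / s_pooled,

with Bessel-corrected variances pooled by degrees of freedom; d < 0 means
same-receptor neurons are closer. The reference distribution is obtained by
reshuffling population labels over all cells (default 1000 permutations),
collecting the same-shuffled-label distances per permutation, and computing
one Cohen's d of the observed intra (and inter) set against each permuted
set. The intra and inter distributions are additionally compared by a
two-sided two-sample Kolmogorov–Smirnov test (asymptotic p for large
samples, exact below n = 30).

*Caveat — dependence of pairwise distances.* Distances sharing a cell are
correlated, and the KS test treats them as i.i.d. samples. With many cells
per population this makes the KS test anticonservative under the null
(measured ≈8–14% rejection at α = 0.05). The calibration check in the
acceptance suite therefore uses a design with many small populations
(300 populations, ≈1.3 cells each), where intra pairs are nearly disjoint
and the nominal level is approximately attained. Interpretation of KS p
values on deeply sampled populations should lean on the permutation null
instead.

Population-level (centroid) distances are arithmetic means per population
in the selected PC space, restricted to populations with ≥ 10 cells; the
cell-level analyses use populations with ≥ 3 cells. A subsampling analysis
(`size_bin_robustness`) bins populations by size into equal-frequency bins
and repeatedly (default 10,000 iterations; tests and the acceptance script
use fewer) compares inter-population distances of the smallest-size and
largest-size bins, subsampled to ⌈n/3⌉ cells per population.

## Receptor assignment and multiplet filtering

A cell's population is the receptor gene with the highest log-normalized
expression (exact ties broken lexicographically and logged). The
"is expressed" cutoff is median − 3·MAD of the top-receptor levels; MAD is
scaled by 1.4826 by default (normal consistency, the default of common
statistical environments), with an unscaled option. Cells whose top
receptor falls below the cutoff are removed (`below_cutoff`); cells with a
second receptor at or above the cutoff are removed as putative multiplets
(`multireceptor`). The cutoff direction is downward because the filter
removes low-expressing cells. Note that a doublet formed from two cells of
the *same* population expresses one receptor and is invisible to this
filter by construction; recall is therefore evaluated on cross-population
doublets.

## OR gene clusters (Jenks threshold)

Gene anchors are strand-aware start-codon coordinates (leftmost CDS base on
+, rightmost on −); for a multi-exon CDS the anchor is the first position,
in translation order, of the last coding exon. All coordinates are 1-based
closed, as in GTF. Distances between position-adjacent genes per chromosome
are partitioned by a k = 3 Jenks natural-breaks optimization (exact dynamic
programming, O(n²k), ties broken toward the smaller lowest class). The
intra-cluster distance group is the class(es) below the selected internal
break; the clustering threshold is intra mean + 3·SD (Bessel-corrected),
and clusters are maximal runs of adjacent genes with gaps below the
threshold.

With k = 3 there are two internal breaks and the optimizer can spend them
either subdividing the intra-cluster tail or subdividing the inter-cluster
gaps; a fixed choice of break is therefore unstable (≈86–88% exact cluster
recovery on simulated layouts). The default `intra_break="auto"` picks the
internal break with the largest relative separation between the classes it
divides (the break sitting in the dominant value gap), which recovers the
simulated true clusters in ≥99% of layouts; `"lower"` and `"upper"` remain
selectable.

## Miyata amino-acid difference

The replacement matrix derives from the classic two-property formulation:
for residues a, b with polarity p and side-chain volume v,

    d(a, b) = sqrt[ (Δp/σ_Δp)² + (Δv/σ_Δv)² ],

where σ_Δp and σ_Δv are the standard deviations of the pairwise property
differences over the 190 unordered residue pairs. The resulting table
(frozen to `data/miyata1979.tsv`, 4 decimals) reproduces the classic anchor
values (Leu–Ile 0.14, Lys–Arg 0.38); a user-supplied 20×20 TSV is accepted
as an alternative.

Pair scoring over a gapped alignment: substituted columns contribute the
matrix entry; a residue aligned to a gap (insertion) contributes the mean
of that residue's scores against the 19 other residues; gap–gap columns
contribute nothing; the pair difference is the column sum. Ambiguous
residues (X/B/Z/…) are treated as gaps with a warning. Alignments are first
trimmed to the window from the modal first-methionine column (leftmost on
ties; the alternative reading — the column with maximal overall M
frequency — is logged when it differs) through the last column with < 90%
gaps.

## Association analyses

The three distance worlds are joined into one table with a row per
unordered population pair (populations present in all sources; genomic
distance defined only for same-cluster pairs). Analyses:

- binned transcriptomic-distance distributions over genomic or amino-acid
  bins (equal-width default; equal-frequency available), with Spearman ρ
  computed over the raw pairs in the first three bins;
- close/distant thresholds: genomic-close = 95th percentile of
  neighbouring same-cluster distances, sequence-similar = 5th percentile of
  same-class amino-acid differences (linear-interpolation percentiles);
- the four-way category comparison (near/far × similar/dissimilar;
  same-cluster pairs beyond the close threshold are excluded) by two-sided
  continuity-corrected Wilcoxon rank-sum tests with Bonferroni correction
  over the tested category pairs;
- per-bin proportions of close pairs across equal-width transcriptomic
  distance bins;
- the enhancer-set comparison: distances among populations whose OR genes
  are targets of one cis-regulatory element versus the remaining pairs of
  the same gene cluster.

The number of bins behind "the first three bins" is not canonical; it is a
configuration parameter (the acceptance script uses 5 bins, giving
first-bin samples of a few hundred pairs at its simulation scale).

## Synthetic-data generators

The generators produce data with the statistical structure the analyses
assume, plus ground truth for every stage. They do **not** model ambient
RNA, batch effects, integration artifacts, or dorsoventral zonation; pass
rates on these data bound what the code does, not what real tissue shows.

**OR family.** A birth process duplicates a uniformly chosen receptor until
`n_receptors`; each new edge gets an exponential branch length (mean 0.12).
With probability `cis_duplication_prob` (default 0.85) the duplicate is
inserted adjacent to its parent in the same genomic cluster, else it founds
a new cluster on a random chromosome — making genomic proximity confounded
with sequence similarity, as in the real repertoire. Intra-cluster gaps are
uniform jitter in (0.2, 1.8)·mean spacing (default mean 25 kb): a bounded
distribution keeps every intra gap below the mean + 3·SD threshold, so the
generator's own cluster partition is recoverable in principle (an earlier
exponential-spacing draw put ~2% of intra gaps beyond the threshold, making
ground truth ill-defined). Inter-cluster gaps are ≥ 5 Mb. Sequences evolve
by Poisson substitutions (rate per site per unit branch length, default 1);
class I/II labels come from the two clades at the root split.

**Single-cell counts.** Population expression programs are per-gene
log-offsets: sqrt(c)·(Brownian diffusion along the family tree, root state
zero, branch lengths as variance increments) + sqrt(1−c)·(independent
normal), each scaled to marginal SD `program_scale`; c is
`sequence_coupling`. Cells per population are negative-binomial
(mean 8.4, dispersion 1.2 — chosen so that a 1141-receptor family yields
≈9.5k cells, ≈950 observed populations and ≈790 populations with ≥3 cells,
the scale of the study data). Counts are NB (variance = μ + μ²·dispersion,
Gamma–Poisson sampling) around library size × gene weight; the chosen
receptor gene receives a per-cell lognormal share of the library (mean
`receptor_expression_rate`, log-SD 0.8 — receptor expression varies
strongly between cells, which is what makes the MAD cutoff sit well below
the median). Doublets are element-wise sums of two distinct single cells
drawn uniformly, appended after generation and labelled by their
larger-library source. All randomness flows from one seed through numpy
`SeedSequence` spawning (programs / cell counts / count noise / doublets),
so stages are independently reproducible.

**Exposure counts.** Gene baseline rates are lognormal; a per-gene intron
fraction is Beta-distributed around `intron_fraction` (default 0.3).
Transcriptionally modulated genes multiply both intron and exon rates in
exposed samples by 2^(±fc); post-transcriptionally modulated genes multiply
exon rates only. Exon and intron counts are NB draws; transcript counts are
their sum, so transcript ≥ exon holds by construction.

## Exposure analysis

Low-expression filtering takes the first interior local minimum between the
two largest modes of a Gaussian KDE (Silverman bandwidth, 512-point grid)
of log1p counts, mapped back to the count scale; a unimodal density falls
back to the 1st percentile of nonzero counts with a warning. Size factors
are median-of-ratios (per sample, median over all-nonzero genes of
count / geometric mean across samples).

The DE stage is a deliberately simplified NB Wald test: per gene, an NB GLM
(log link, condition covariate, log-size-factor offsets) with
method-of-moments dispersion floored at 0.01, a two-tailed Wald test
against the composite null |log2FC| ≤ 0.5, and BH adjustment. It stands in
for the pipeline topology of heavier DE machinery (no dispersion shrinkage,
no fold-change shrinkage); genes with very low counts are underpowered and
that is expected behaviour.

EISA: intron counts = transcript − exon, clipped at zero with a clip count
(overlapping-gene artifacts). Per gene and feature (exonic/intronic), fold
changes are normalized exposed counts over the mean normalized control
count. Significance is a two-sided two-sample t test per gene per feature
with BH across genes within feature. The default tests log1p-normalized
counts: expression effects are multiplicative and displayed on a log2
scale, and the log transform stabilizes the NB variance — on simulated
truth the linear-scale test recovers ≈0.90 of gene classes versus ≈0.92 on
the log scale at n = 3 vs 3; `log_scale=False` restores the linear mode.
Classification: *transcriptional* if both features are significant with the
same direction; *post-transcriptional* if the exonic feature is significant,
the intronic is not, and the gene clears the intronic power guard (> 14
intronic reads in total — genes below it cannot distinguish the two
mechanisms and are classed `none`); otherwise *none*.

## Sizes used by tests and the acceptance script

The test suite and `scripts/acceptance.py` run all stochastic analyses at
reduced scale: 200 replicate datasets of 300×~1.3-cell populations for null
calibration; 100 seeds for effect recovery and sequence-coupling sign
tests; a 220-receptor, ~1800-cell simulation for the four-category
comparison; 100 (tests) / 50 (script) layouts for cluster recovery; 200 to
2000 genes for the exposure analyses; a 300-receptor, ~2500-cell dataset
with 200 permutations for the script's headline distance statistics. These
sizes are the package's choices for quick, reproducible characterization;
all thresholds and replicate counts of the statistical properties
themselves are fixed by the checks they implement.

## Known limitations

- The KS test on overlapping pairwise distances is anticonservative (see
  above); the permutation Cohen's d is the robust readout.
- The Miyata matrix is recomputed from the published property table, not
  transcribed from the original article; entries match classic anchor
  values to ~0.02.
- The NB Wald stage is not a DESeq2 reimplementation; its dispersions are
  moment estimates and its p values differ from shrinkage-based tools,
  particularly at low counts.
- The four-way category comparison on synthetic data reproduces the
  qualitative sequence-driven pattern only when centroid sampling noise is
  realistic (≥10-cell centroid rule); with noise-free centroids a Brownian
  program model makes even within-"similar" sequence gradients detectable.
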