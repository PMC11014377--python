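# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `agingtx`. Throughout, the two
conditions are "young adult" (6m) and "aged" (24m), and all genomic
coordinates are 0-based half-open internally (GTF conversion happens only
at the file boundary).

## Normalization

Raw counts pass through a fixed chain: (1) features whose aggregate raw
count is ≤ 5 are removed — the aggregation is the mean across all samples
by default (a symmetric choice; `max` and `total` are config options);
(2) quantile normalization equalizes every sample's empirical
distribution, with ties receiving the mean of the rank-means they span;
(3) row-wise median centering divides each feature by its own median
(rows with median zero fall back to their smallest positive value and are
flagged). Tie averaging means the "every sorted column identical" and
idempotence properties hold exactly only for tie-free data; both are
asserted on continuous inputs, and tie semantics are asserted on a worked
example.

Expression-scale stages (differential expression, the usage-filter
cutoffs, isoform detection at the > 2 threshold) consume the
quantile-normalized matrix. The median-centered matrix — where every
feature lives on a common ~1 scale — feeds the co-expression network,
which only uses correlations. Feeding median-centered values into
pseudocounted fold changes would annihilate real effects, so the pipeline
keeps the two artifacts separate.

## Differential expression

The engine is pluggable: anything mapping (young, aged) count blocks to
per-feature (log₂FC, p) works. log₂FC is always
log₂((mean₂₄ₘ+1)/(mean₆ₘ+1)); direction labels are `up` iff padj ≤ α and
log₂FC ≥ τ, `down` symmetric, `ns` otherwise, with α = 0.05, τ = 0.58 and
both thresholds inclusive. Benjamini–Hochberg adjustment runs within each
feature level (genes and isoforms separately).

The default engine is a t-test on log₂(x+1) with empirical-Bayes variance
moderation: per-feature pooled variances s² are squeezed toward the
common mean s₀² with prior weight d₀ estimated by method of moments from
the spread of the s² (clipped to [1, 100]), and the t statistic gets
d + d₀ degrees of freedom. At four samples per group a per-feature Welch
t has six degrees of freedom and a true log₂FC of 1 at NB dispersion 0.1
yields a median p around 0.05 — no per-feature test can recover such
effects after multiplicity adjustment, which is precisely why count-based
DE tools moderate. A plain Welch engine is retained for comparison. The
moderated engine preserves the group-swap symmetry (log₂FC negates, p
unchanged) and is calibrated under the null (checked against the 99%
binomial band at 1000 features).

The usage (DTU) test applies the same moderation scheme on
logit-transformed isoform fractions, with boundary shrinkage
ε = 1/(2 × median gene count). An isoform switch is a within-gene pair
with significant opposite-signed dIF.

## Co-expression modules

Signed adjacency a_ij = ((1+ρ_ij)/2)^β on Pearson correlations of
normalized log-scale expression; TOM
ω_ij = (Σ_{u∉{i,j}} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij) with
k_i = Σ_{u≠i} a_iu; average-linkage clustering on 1−TOM with a *static*
cut at `cut_height` (deterministic and fully specified, unlike dynamic
tree cutting) and min-size pruning into the unassigned label M0. Module
labels M1…Mk order by decreasing size with first-member tie-breaking, so
the partition is invariant to gene input order. The eigengene is the
first principal component of the module's standardized expression,
unit-variance over samples and sign-aligned with the module mean profile.
Module age direction is a paired t across member genes (young mean vs
aged mean), BH across modules.

Full-study defaults are β = 18, min_size = 300, cut_height = 0.85; the
desk-scale preset (β = 6, min_size = 20) matches the simulated designs
used in the tests. TOM dissimilarity is not a metric; only range and
symmetry are asserted.

## Splicing events

Two isoforms of a gene are compared strand-aware on their exon chains:

| event | rule | carrier |
|---|---|---|
| ATSS/ATTS | transcript 5′/3′ end differs by more than the 10-nt tolerance | isoform with the more internal end |
| A5/A3 | overlapping introns sharing exactly one boundary, flanking exons overlapping | isoform whose splice site lies inside the other's intron |
| ES/MES | one (≥ two consecutive) internal exon(s) of one isoform inside a single intron of the other, flanking junctions shared | the skipping isoform |
| MEE | one exclusive internal exon per isoform inside the same inter-junction window, mutually non-overlapping | isoform with the 5′-most exclusive exon (positional convention — the event is intrinsically mutual) |
| IR | an exon spanning the other isoform's intron with both flanking exon boundaries matched | the retaining isoform |

The A5/A3 "flanking exons overlap" condition is what keeps exon skipping
from mis-reporting as an acceptor shift. A pair may carry several events;
swapping the pair preserves every event type and (except MEE) swaps the
carrier. The event-asymmetry statistic counts, per type, switch pairs
where exactly one member carries the event and tests the fraction carried
by the aged-up member against 0.5 with a two-sided exact binomial, BH
across types.

Functional consequences per switch pair: longest-ORF prediction
(ATG to first in-frame stop, 5′-most on ties, N matches nothing);
NMD sensitivity by the canonical 50-nt rule (stop strictly more than
50 nt upstream of the last exon–exon junction in transcript coordinates;
single-exon transcripts are "not applicable"); coding potential as an
ORF ≥ 300 nt heuristic (threshold configurable); peptide similarity as
global-alignment identity (match +1, mismatch 0, linear gap −1). Domain
(PFAM) analysis is out of scope.

## RBP/SF motif scoring

Motifs are IUPAC consensus strings (U→T); scanning is single-strand with
overlapping matches, and N in a sequence matches nothing. Binding
probability is occurrences per region length × 10,000, summed over a
protein's motifs. Group contrasts compare B between down-, up- and
non-significantly changed transcripts (binding probability is a sequence
property, so the group definition carries the age information): one-way
ANOVA per protein, Tukey HSD pairwise, log₂ fold changes with a
pseudocount equal to the protein's smallest positive B. That pseudocount
is deliberately data-scaled; on data where B is quantized to a few values
it is conservative.

## RNA dynamics

With synthesis k₁, processing k₂ and degradation k₃, steady state gives
premature ∝ k₁/k₂ and mature ∝ k₁/k₃, so PT = mature/premature estimates
k₂/k₃. Genes with a zero premature count in any sample are excluded.
Genome-wide comparisons use a two-sided KS test on per-gene group-mean
log₂ PT and a Wilcoxon signed-rank on the paired per-gene differences.

The gene-level caller fits log₂(mature) ~ log₂(premature) across genes on
control (6m) means, translates that line through each gene's own control
point, and predicts the aged mature level from the aged premature level;
the residual divided by the control-fit residual SD (ddof = 2; a MAD
option exists) gives a z-score, a two-sided normal p, and BH calls at
padj ≤ α. Replicates are collapsed to group means before fitting. The
caller is invariant to a global depth rescaling applied to both matrices.
Permutation enrichment re-runs the caller under permuted age labels and
reports (1 + #{permutations ≥ observed})/(B+1). Note the combinatorial
floor: with 4+4 samples the true split recurs among permutations with
probability 2/70, so empirical p below ~0.03 is unreachable; designs with
6+6 samples are used where small empirical p matters.

## Cohort-context rules

Cell-type specificity: gene g is specific to cell type c iff
expr(g,c) > threshold × (expr(g,c′)+1) for every other type (pseudocount
against zero division; threshold 4, or 5 for denser marker sets); the
rule makes lists mutually exclusive by construction. Region assignment:
a gene goes to the single region whose count strictly exceeds the median
of its counts in the other regions, and stays unassigned when several
regions qualify — taken literally, this leaves many genes unassigned,
which is documented behavior. Composition change works on per-sample
percentages (summing to 100) with Welch t across ages and BH across cell
types. Over-representation is a one-sided hypergeometric tail within a
caller-declared background.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed:
two age groups × 4 replicates, 500 genes with 1–4 isoforms each, five
modules of 40 genes, NB dispersion φ = 0.1 (variance μ + φμ²,
gamma–Poisson sampling), isoform baselines lognormal around 2^6.5 ≈ 90
counts, module age effects ±0.75 log₂, 30% of multi-isoform genes given
bidirectional switches of ±1 log₂ with equalized pair baselines, and 20%
of module-free genes given whole-gene age effects of ±2 log₂ (emulating
the clearly changed genes a bulk study reports; at ±1 and n = 4 such
genes are statistically invisible after adjustment, which would make the
end-to-end run vacuous). Identical seeds give byte-identical outputs, and
gene counts are exactly the sums of their isoform counts.

Module structure comes from one latent factor per module, drawn per
sample with loading 1.0, orthogonalized across modules *and* against the
age contrast. At eight samples, i.i.d. latents correlate with each other
(E|ρ| ≈ 0.3, merging planted blocks) and with the age split (random
module-level pseudo-shifts of SD ≈ 0.7, scrambling planted directions);
orthogonalization keeps the stated one-factor model while making blocks
and directions well-defined at realistic sample counts.

Transcript models: six exons of 120–180 nt with 400–600 nt introns, one
reference isoform per gene, and each alternative isoform derived from the
reference by exactly one planted event (the eight types cycled). The
planted event always sits on the alternative isoform, and the generator's
switch truth marks the reference as aged-up — so the generated data carry
a maximal planted event-direction asymmetry, which the binomial stage
should (and does) flag. CDS covers roughly the middle half of each
transcript with length divisible by three, leaving UTRs long enough to
host motifs.

Sequences are built per segment: UTR bases i.i.d. at the GC target, CDS
codons with the first two positions at the GC target and wobble positions
at the GC3 target (stop codons and internal ATG/stop collisions
resampled; the terminal stop is chosen to respect GC3), then exact-count
UTR flips rebalance whole-cDNA GC. Motifs are planted as non-overlapping
concrete realizations at the requested per-10-kb density in the 3′UTR
(whole cDNA when no CDS), and chance occurrences elsewhere are scrubbed
by minimal point mutations, so realized counts equal planted counts
exactly.

Premature/mature counts are Poisson at depth × k₁/k₂ and depth × k₁/k₃
per sample, with k₃ of planted PT-regulated genes scaled (default halved)
in the aged group only. Rate spreads are deliberately modest (k₂, k₃
lognormal with ~0.18 log₂ SD, k₁ spanning 1.5 decades): the caller's
tolerance is the population residual SD (s ≈ 0.26 at these spreads), and
decade-wide kinetic heterogeneity would put a 2× stability shift below
the method's resolution by construction. This is the main respect in
which the generator is idealized relative to real transcriptomes, where
kinetic rates vary over orders of magnitude and the same caller needs far
larger shifts; passing tests demonstrate correctness of the machinery,
not field sensitivity.

Other idealizations worth keeping in mind: counts are NB without
sample-level library-size or batch effects, module latents are exactly
orthogonal, splicing events occur singly per isoform pair, and sequences
are i.i.d.-composition with planted motifs rather than genomic. None of
these affect the statistics under test, but they mean the measured
sensitivities are upper bounds for real data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale designs chosen for precision per
unit work: 1000–1500 features for calibration and sensitivity, 200 genes
for module recovery, 1 Mb of sequence for motif-density recovery, 1000
genes at depth 10⁵ for PT recovery, 300–1000 label permutations, and a
500-gene default bundle for the end-to-end run. Detection in the
sensitivity measurements is at BH padj ≤ 0.1 with realized FDR reported
alongside. Degenerate inputs are handled deterministically: zero-variance
features with equal means give p = 1, fractions constant at a boundary
are flagged with p = 1, collinear PT input raises with advice, empty
results return empty tables rather than erroring. BH is implemented once
(`bh_adjust`, step-up with monotonicity enforcement, verified against a
brute-force implementation) and used everywhere.
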