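# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical conventions the implementation commits to.

## Cohort matching

PCA standardises dosages per site to mean zero and variance
`2p(1-p)` (Patterson convention); without the frequency scaling the leading
axes are dominated by common variants. Missing genotypes are imputed to
the site mean before centring. Coordinates are the projections onto the
top-k axes (`U·S` of the SVD of the standardised matrix) and
`explained_fraction` is eigenvalue over trace.

Two subset-matching procedures are provided because the matching problem
admits two natural readings: scoring each candidate *set* of k wild
individuals by the Euclidean distance between its centroid and the captive
centroid (default, `score="centroid"`, exhaustive over all C(n, k)
subsets), or ranking each wild *individual* by its mean distance to the
captive samples and keeping the k closest (`score="per-individual"`, one
pass). Centroid scoring subsumes the per-individual reading as a set-level
criterion and is O(1) per subset, so the exhaustive enumeration of
21,474,180 subsets (28 choose 11) is tractable. Ties are broken by mean
captive-to-member distance, then lexicographic sample ids, which makes the
winner independent of input order.

DST between two individuals is `(#IBS2 + 0.5·#IBS1) / #co-called sites`;
with dosages this is `mean(2 - |a-b|)/2`. The group comparison permutes
labels within the pooled pair of groups and uses the two-sided statistic
(mean within-group DST) − (mean between-group DST) with the +1-corrected
p-value, so p ∈ [1/(n_perm+1), 1]. LD is genotypic (dosage-correlation)
r² over pairwise-complete samples — the standard unphased surrogate,
since phase is never available here.

## Sweep scan

Windows are 40 kb advancing in 20 kb steps, 0-based half-open, starting at
step multiples; the last window truncates at the chromosome end and per-bp
θπ always divides by the *actual* window span (the convention of the
common windowed-diversity tools), not by callable sites. Site diversity
uses the unbiased pairwise estimator `2c(n-c)/(n(n-1))` on called allele
counts; a group contributes nothing at sites where it has fewer than two
called alleles.

F<sub>ST</sub> follows Weir & Cockerham (1984): per-site variance
components a (among populations), b (among individuals within populations)
and c (within individuals), window estimate Σa/Σ(a+b+c), negative values
retained. Sites with fewer than two called genotypes in either population
are excluded from the sums.

Selected regions are the joint empirical tails: captive-direction =
ratio ≤ 5% quantile AND F<sub>ST</sub> ≥ 95% quantile; wild-direction uses
the right ratio tail. Quantiles are computed over windows with
*non-missing* ratio and F<sub>ST</sub> only; windows with zero wild
diversity get a missing ratio rather than infinity, so a handful of empty
wild windows cannot dominate the right tail. Comparisons are inclusive,
which makes the degenerate all-identical case deterministic (everything or
nothing flagged, depending on tail mass). The robustness flag requires at
least one SNP in the window with |freq_captive − freq_wild| ≥ 0.6,
boundary included.

The association scan is the classic allele-based 1-df χ² without
continuity correction; Fisher's exact test is substituted whenever an
expected cell is below 5, and monomorphic sites get p = 1. Composition
enrichment (repeat coverage, GC) uses a two-sided permutation test whose
null placements are length- and chromosome-matched uniform draws.

## GO statistics

Over-representation is the upper-tail hypergeometric `P(X ≥ k)` with BH
adjustment (statsmodels step-up; the test suite pins it against a
brute-force step-up oracle). Selection strength per term is a permutation
test of the observed mean F<sub>ST</sub> (and mean θπ ratio) of the term's
genes against equal-size random gene sets; the gene-level statistic is the
unweighted mean of the 40-kb windows overlapping the gene body. Directions
are one-sided by construction — elevated F<sub>ST</sub>, reduced
captive/wild ratio — encoding "selection in captivity"; two-sided variants
are available by flag. Null draws are cached per term size so a map with
many same-size terms costs one null sample. A term needs at least three
genes with statistics; both p-values must be ≤ 0.01 for the significant
flag.

## Hi-C structure

*Resolution.* The smallest window size in which more than 80% of bins
carry more than 1000 cis contacts, evaluated by aggregating base-bin row
sums.

*Balancing.* Knight–Ruiz Newton iteration (inner conjugate-gradient
solves) on the unmasked submatrix; all-zero rows are masked first. On
non-convergence the routine falls back to symmetric iterative proportional
scaling with a warning. The bias vector is rescaled so the balanced matrix
preserves the raw total count — this keeps balanced values on a count-like
scale, which the downstream Poisson tests rely on. Contract: unmasked
row-sum coefficient of variation < 1e-6.

*Expected model.* E(d) is the mean balanced count per diagonal (d ≥ 1),
smoothed by a moving average in log space and then forced non-increasing
with a running minimum. The same curve feeds the O/E transform, TAD
intactness, clique and PEI expectations.

*Compartments.* Pearson correlation matrix of the O/E columns, leading
eigenvector, sign oriented so Spearman(PC1, gene density) > 0; A ⇔
PC1 > 0. O/E is applied before the correlation because raw-count
correlation is dominated by distance decay; the raw variant remains
switchable. The AB-index of a fine bin is
(C_A − C_B)/(C_A + C_B) over balanced contacts to fine bins in A- vs
B-labelled coarse bins, excluding the bin's own parent coarse bin; bins
with no compartment-assigned contact mass are masked.

*TADs.* The directionality index contrasts a bin's upstream (A) and
downstream (B) contact sums inside a 2-Mb window:
`DI = sign(B−A)·((A−E)²/E + (B−E)²/E)`, E = (A+B)/2, zero when A+B = 0.
The DI track is signed-log transformed (`sign·log1p|DI|`) before a 3-state
Gaussian HMM (hmmlearn, 10 seeded EM restarts, best likelihood kept); the
raw DI is χ²-like and heavy-tailed, and without the transform the Gaussian
states split by magnitude instead of sign. States are ordered by mean into
upstream-bias / none / downstream-bias; a new domain starts where the
state switches from upstream-bias (domain end) to downstream-bias (next
domain start), and segments shorter than 3 bins are dropped. A uniform
matrix yields a single whole-chromosome domain.

*Intactness.* log2(Σ observed / Σ expected) over intra-TAD bin pairs at
distance ≥ 1. The notion is deliberately simple — monotone in how much a
domain's internal contact mass exceeds the background decay — and exactly
testable (obs = exp ⇒ 0; doubling ⇒ +1).

*Cliques.* Non-adjacent TAD pairs only (index separation ≥ 2; adjacent
pairs are trivially enriched by decay). Pair significance is the
upper-tail Poisson probability of the rounded observed inter-TAD sum given
the decay expectation, BH across pairs, edges at q < 1e-4 ("< 0.01%").
Maximal cliques via Bron–Kerbosch with pivoting (networkx `find_cliques`);
each TAD reports the size of the largest maximal clique containing it.

*PEIs.* Candidates pair each TSS bin with every other bin of its TAD
(±1 Mb fallback with a warning when a promoter lies outside all TADs);
Poisson upper tail against E(d), BH at q < 0.05, and calls closer than
60 kb are discarded regardless of significance. This is a deliberately
simplified within-TAD expected model, not a hierarchical domain-fit: with
strong intra-TAD enrichment the chromosome-wide decay underestimates the
within-TAD background, so PEI calls on heavily TAD-enriched maps are
anti-conservative and should be read as candidates.

## Integration

Window values are mapped onto structure bins by overlap-weighted mean
(midpoint and unweighted variants by flag); the correlation is Spearman
with exact tie handling and needs ≥ 10 mapped pairs; constant inputs
return missing with a warning. For the GO-expression stage each factor
defines a regulated class by an inclusive percentile (default bottom 25%
for AB-index, intactness and enhancer count, top 25% for clique size —
wide enough that a typical term keeps ≥ 3 genes per class); a term is
retained only if, in all four classes, its member genes' TPM differs from
the all-gene background at P ≤ 0.01 (two-sided rank-sum). The background
is all genes (switchable to genes outside the term). The conjunctive gene
filter uses inclusive 5%/95% thresholds and drops genes with any missing
factor.

## Synthetic data: what it emulates and what it does not

Genotypes follow the Balding–Nichols model (ancestral frequency
Uniform(0.05, 0.95), population frequencies Beta-distributed around it
with parameter F), because it is the simplest two-population model whose
F parameter the Weir–Cockerham estimator should recover — giving an exact
oracle for the F<sub>ST</sub> machinery. Defaults mirror the matched
study design: 11 + 11 diploids, 20,000 SNPs on a 20-Mb chromosome,
F = 0.1. Sweeps are frequency shifts of the captive population toward
fixation (default shift 0.7 in the planted-recovery checks) — not
coalescent sweeps; the scan detects frequency differentiation and
diversity loss, which is what the shift produces. There is no linkage,
recombination map, demography or sequencing error; passing the recovery
tests shows the windows/tails/filters machinery is correct, not that the
scan is powered on real short-term-bottleneck data.

Contact maps are Poisson draws around a multiplicative expected model:
power-law decay (exponent 1), compartment checkerboard (±60% same/cross
block factor), ×3 intra-TAD enrichment, ×8 clique TAD pairs, ×10 loops,
base count 300 at the diagonal. Poisson noise matches the Poisson
significance tests downstream, making their calibration testable; real
Hi-C over-dispersion is not modelled, so the clique/PEI q-values on real
data would be anti-conservative.

Expression is log-normal: per-gene baseline log2 TPM ~ Normal(5, 1), with
Normal(0, 0.3) per-sample noise, normalised to 1e6 per sample. The
between-gene spread (sd 1 log2, configurable) is deliberately narrow so a
planted twofold (−1 log2) shift on a ~50-gene term is an unambiguous
signal for the retention logic; real transcriptomes have a much wider
spread and correspondingly lower power at that effect size. Planted
"down" terms are additionally placed into the regulated class of all four
factors, emulating a term that is coordinately regulated by the chromatin
hierarchy. With no planted effects all shifts are zero and the stage's
null behaviour (zero retained terms) is what the calibration tests check.
The GO "ontology" is a flat synthetic term map — no DAG, no propagation.

## Numerical conventions and edge cases

- Seeds fully determine every generator and every permutation test; each
  generator draws from its own seed stream so outputs do not depend on
  call order.
- VCF positions are 1-based; everything internal is 0-based half-open.
- The depth filter defaults to site-level INFO/DP (a cohort-summed depth
  threshold of 50 is far above any per-sample depth at ~5× coverage);
  per-genotype FORMAT/DP filtering is available via `depth_mode`.
- Missing genotypes are excluded from allele counts, so per-site n varies.
- Permutation p-values always carry the +1 correction; Poisson tails are
  evaluated at the rounded balanced count.
- Degenerate inputs fail loudly: zero total PCA variance, fully masked
  matrices, sub-minimum window counts, groups below minimum size.

## Problem sizes used by the test suite and acceptance script

Recovery and calibration runs use one 20-Mb chromosome at 20k SNPs for the
popgen layer; 500 bins at 100 kb for compartments; 200–240 bins at 25 kb
(20–30 TADs) for TAD/clique calling; 300 bins at 10 kb for PEIs; 200–500
genes for the expression layer; 100–200 replicates for null calibration.
These sizes were chosen so each check exercises the full code path with
comfortable statistical margins.
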