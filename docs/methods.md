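# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `snppop`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A dataset is a sample × variant matrix of diploid genotype codes counting
copies of a per-variant "B" allele (0/1/2, −1 missing), with population
labels on samples and (chromosome, bp position, allele pair) on variants.
The B allele is fixed at read time as the **minor** allele (ties broken to
the lexicographically later character), so the B-allele frequency is
`mean(codes)/2` and MAF = min(p, 1−p) everywhere downstream. A
`canonicalized()` view restores this convention for programmatically built
matrices; canonical datasets round-trip exactly through the PED/MAP
writer/reader (a property test asserts this for arbitrary shapes and
missingness).

Merging resolves variants by (chromosome, position). Right-hand alleles are
mapped onto the left strand either directly or by reverse complement;
palindromic A/T and C/G variants are dropped because strand is
unrecoverable, and irreconcilable allele pairs are dropped and counted.
Sample IDs occurring in both inputs act as merge controls: their genotype
concordance is reported and the left copy kept. Without a shared control the
concordance is reported as 1.0 by convention.

## Quality control

Variants are filtered before samples (call rate strictly > 0.95 on both, so
a sample dragged down by a failing variant is re-scored after that variant
is gone); the MAF filter is strictly > 0.05. LD pruning is the greedy
windowed scheme: windows of 50 consecutive surviving variants advancing by
10, removing, within a window, the lower-MAF member of the worst pair with
r² > 0.2 (tie → the later position) until the window is clean, with passes
repeated to stability. Tie-breaking is fixed for determinism; tool versions
differ here and the exact surviving set is not canonical across software.
ROH analysis deliberately consumes the call-rate-filtered but **not**
MAF-filtered data — monomorphic stretches are evidence of autozygosity, not
noise.

## Diversity and inbreeding

Expected homozygosity uses the unbiased small-sample correction
He = 1 − 2p(1−p)·2n/(2n−1); with 5–15 samples per population the plug-in
estimator visibly biases F_IS. F_IS = 1 − (1−Ho)/(1−He) on homozygosities
(equivalently 1 − Hobs/Hexp on heterozygosities). The per-sample excess
homozygosity is F_HOM = (O−E)/(L−E) with O the observed homozygous count, E
the HWE expectation over that sample's called variants, L the called count —
the conventional definition of the cited statistic, which its source does
not spell out. Per-marker F_ST is the Weir–Cockerham (1984) two-level
estimator; the global value is the ratio of summed components Σa/Σ(a+b+c),
the standard recommendation over averaging per-marker ratios. Variants
monomorphic over all populations have undefined θ and are excluded from the
mean. A test pins the implementation to an independent textbook
transcription at 1e−12.

## LD and effective population size

r² is the squared Pearson correlation of genotype codes over
pairwise-complete samples (composite LD; no phasing anywhere in the
package). The decay analysis enumerates **all** intra-chromosomal pairs up
to 1 Mb — a decay curve needs the full pair set, not only adjacent pairs —
and bins them by distance. Physical distance maps to recombination fraction
at 1 cM/Mb.

N_e inversion uses E[r²_adj] = 1/(α + 4N_e c): for each target generation
t ∈ 1..50 the pairs with c within ±20% of c_t = 1/(2t) are averaged,
corrected by −1/n (n = genotyped individuals; the correction appropriate for
composite LD on unphased genotypes, with 1/(2n) available as an option
nowhere needed here), and inverted as N_e = (1/4c̄)(1/r²_adj − α). α
defaults to 1 (no mutation correction; 2.2 is the conventional
mutation-adjusted alternative). The relative ±20% bin keeps pair counts
usable across t where fixed-width bins starve the small-c end; points with
empty bins or non-positive adjusted r² are omitted with a warning. With a
1 Mb pair horizon the most recent resolvable generation is t = 50 (c =
0.01 M), which is why the recovery benchmark reads the t = 50 point; the
thin partial bins at nominally more recent t carry a handful of pairs and
are reported but not trusted. The forward-simulation benchmark (constant
N = 50, 20 × 1 Mb chromosomes at 1 cM/Mb, 30 sampled, 150 generations of
burn-in from linkage equilibrium) recovers N within a factor of 1.5 as the
median over 10 seeds; single seeds scatter roughly two-fold, which is the
intrinsic noise of ~10⁴ informative pairs, not an estimator defect.

## Runs of homozygosity

Windows of 50 variants slide across each sample/chromosome; a window is
"homozygous" with 0 heterozygotes and ≤5 missing calls; each variant's hit
fraction is the share of overlapping windows that were homozygous, and
variants with hit fraction ≥ 0.05 are eligible. (We read the tool's "overlap
ratio 0.05" as this per-variant hit-fraction threshold; the alternative
reading — the pool-overlap parameter of segment grouping — concerns
consensus ROH, which is out of scope.) Candidate segments are **maximal
non-heterozygous runs that contain at least one eligible variant**, split
where adjacent variants are more than 1,000 kb apart; the run's first/last
variant positions are the segment bounds. Anchoring bounds to the run rather
than to window hits avoids the well-known edge trimming of pure
window-voting implementations, makes the caller equivalent to an exhaustive
maximal-run reference scan (asserted exactly on ≤500-variant inputs with the
threshold set to one window), and recovers implanted segment bounds to
within one inter-SNP spacing. Filters: length ≥ 1,000 kb, ≥ 20 SNPs, ≤ 150
kb/SNP. F_ROH divides by 2,265,770 kb of pig autosome; length classes are
lower-inclusive ([1,4), [4,8), [8,12), ≥12 Mb), so the per-class shares sum
exactly to the total. Segment length ℓ (Morgans) dates the common ancestor
to g = 1/(2ℓ) generations via the exponential length distribution of
autozygous tracts.

## Population structure

PCA standardizes each variant by the 2p-centred, sqrt(2p(1−p))-scaled
convention and eigendecomposes the n × n sample covariance; missing entries
impute to the column mean (zero after centring) and are counted. Monomorphic
variants are a hard error directing the caller to the MAF filter. IBS is the
mean of (2 − |g_i − g_j|)/2 over pairwise-complete variants; neighbor lists
sort by IBS distance with lexicographic tie-breaks. Pairwise F_ST uses the
same W&C machinery restricted to each population pair, with a
label-permutation p-value (count of permuted θ ≥ observed, +1 correction);
"Slatkin" linearization θ/(1−θ) stands in for the AMOVA-based statistic of
haplotype software, which unphased genotypes cannot feed — a deliberate,
documented substitution. Pairwise F_ST and Nei distances are computed on the
dense (MAF-filtered, unpruned) panel: pruning removes correlated
high-differentiation markers and visibly attenuates differentiation. Nei's
(1972) standard distance D = −ln(Jxy/√(JxJy)) sums both alleles per variant;
Jxy = 0 caps at a configurable ceiling. Neighbor joining is the Saitou–Nei
algorithm with negative branch lengths clamped to zero and the excess moved
to the sister branch; on additive matrices it recovers the generating tree
exactly (and matches scikit-bio's implementation, used as the test oracle).
The kNN population network symmetrizes per-sample k-nearest-neighbor edges
into an undirected graph — a plain replacement for superparamagnetic
clustering, which is out of scope.

## Admixture

Genotypes are binomial: g_ij ~ Bin(2, Σ_k q_ik f_kj), Q rows on the simplex,
F in (0,1) clipped to [1e−6, 1−1e−6]. Fitting is the classic multiplicative
EM (expected allele-copy assignments, closed-form M-step), which shares its
stationary points with the quasi-Newton scheme of dedicated tools and is
monotone in log-likelihood (asserted on every run). Defaults: tol 1e−6 on
relative log-likelihood change, max 2,000 iterations, 5 random restarts
(Dirichlet(1) Q rows, Uniform(0.05, 0.95) F) keeping the best likelihood;
missing genotypes drop out of all sums. Cross-validation masks 10% of
non-missing entries per fold (genotype hold-out rather than individual
hold-out, making the cited tool's CV concept explicit), refits, and scores
held-out entries by binomial deviance between g and 2p̂; the k minimizing
the mean over folds is selected, and the benchmark recovers k = 3 on a
three-deme panel. Component labels are arbitrary, so comparisons align
columns by Hungarian assignment on negative Q-column correlations (dot
product fallback for constant columns); a test checks the assignment against
exhaustive permutation search through k = 5.

## Selection scan

Standardized genotype columns are regressed on the leading K = 3 PC score
vectors (QR-orthonormalized, so per-PC simple regressions are exact); each
variant's K z-scores get a Mahalanobis distance under a robust covariance:
coordinate-wise median location, MAD scale, and comedian
(median-of-cross-products) off-diagonals clipped to ±0.99 of the scale
bound. The comedian was chosen over a minimum-covariance-determinant
estimator because it is deterministic and tuning-free; its scale bias is
absorbed by the genomic-inflation rescaling λ_GC = median(d²)/median(χ²_K),
after which d²/λ is tested against χ²_K. Benjamini–Hochberg (statsmodels)
controls FDR at α = 0.05; a test pins the flag set to the textbook step-up
rule. The scan runs on the dense MAF-filtered panel, optionally with PC
scores from the pruned panel (the pipeline does exactly that): outlier scans
need dense coverage, structure estimation prefers pruned markers. F_ST flags
use the strict threshold > 0.5. Candidate windows are ±500 kb around each
flagged marker, clamped at zero, merged when overlapping, and written as
0-based half-open BED.

## Synthetic data: what it emulates and what it does not

*Balding–Nichols*: deme frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) around
ancestral p ~ U(0.05, 0.95), genotypes binomial, uniform missingness. This
realizes a target F_ST in expectation; single variants scatter widely, so
**implanted outlier variants are redrawn (up to 500 times) until their
realized among-deme frequency variance reaches the requested level** — an
implant whose draw happens to be undifferentiated would be an outlier in
name only and no method could or should detect it. Detection power is
therefore measured against implants that actually carry the implanted
signal.

*Forward Wright–Fisher*: diploid random mating (selfing possible at rate
1/N), Poisson crossovers at 1 cM/Mb, no mutation, standing variation started
at linkage equilibrium with frequencies U(0.1, 0.9). After ~3N generations
of burn-in the r²–c relation matches 1/(1 + 4Nc) closely (the empirical
check behind the α = 1 default). Because there is no mutational input, the
site-frequency spectrum is drift-flattened and a large fraction of variants
fix over long runs — fine for LD, F_ST, ROH-background and N_e testing,
wrong for SFS-based inference, which this package does not attempt.

*Implants and mixtures*: ROH implanting collapses heterozygotes to a random
homozygote inside stated intervals (missing calls stay missing; overlapping
intervals merge with a warning); admixture mixing draws g ~ Bin(2, Σ q_k
f_k) from source deme frequencies with the truth Q retained.

All generators are pure functions of (config, seed). None of them emulate
genotyping-chip ascertainment bias, genuine pedigree structure, or
chip-specific missingness patterns, so passing recovery tests demonstrates
estimator correctness under the stated models, not robustness to real-chip
artefacts.

## Problem sizes

The test and acceptance workloads are sized for a desktop: 5,000-variant
panels for F_ST/scan calibration, 2,000 variants × 60 samples for admixture
recovery, 20 × 1 Mb chromosomes × 10 seeds for N_e recovery, and ≤500-variant
inputs for the exhaustive oracles. These sizes hold every recovery tolerance
quoted above with margin; larger panels only tighten them.

## Known limitations

- Haplotype-based statistics (phased r², iHS/XP-EHH, AMOVA F_ST) are out of
  scope; everything runs on unphased genotype codes.
- The N_e trajectory inherits the pair-distance horizon: with 1 Mb pairs,
  generations more recent than t = 50 are unobservable.
- Permutation p-values for pairwise F_ST are exchangeable-label tests; with
  very unequal population sizes their resolution is limited by the
  permutation count (default 1,000).
- The kNN network is a descriptive display, not a clustering with a model
  behind it.
- Monomorphic variants are excluded from PCA/scan by contract; datasets
  should pass the MAF filter first.
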