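# Methods

This note documents the models, numerical choices, and limitations behind
`transbalance`. Everything quantitative stated here is computed by the test
suite, the `analysis/` drivers, or `scripts/acceptance.py`.

## Coalescent simulator (`simdata`)

**Model.** Two populations with piecewise-constant haploid sizes merge into
a constant-size ancestor at the split time; optional ancient migration is
active inside a window that must pre-date the split. Both study species are
highly selfing and all published allele counts are haploid (out of 81 and
23), so samples are modeled as haploid lineages and a pair in a population
of size N coalesces at rate 1/N — hence E[π] = 2Nμ and
E[S] = 2Nμ·L·a₍n−1₎, which the test suite checks against Monte-Carlo
standard errors and cross-validates against msprime. The within-genus
divergence of the first species (5.84 Mya) is represented as a size-change
epoch, not a third population.

**Waiting times.** Events are drawn by hazard integration: a single Exp(1)
variate is spent by accumulating ∫λ(t)dt across rate breakpoints (epoch
boundaries, the split, the migration window, the balanced-locus origin).
Nothing is redrawn at a breakpoint, so two models with identical event
rates consume identical random streams — this is why the gene-flow model
with both rates at zero is byte-identical to the no-gene-flow model under
the same seed, a property the tests assert.

**Mutation.** Finite-sites with multiple hits allowed: the ancestral
sequence is drawn i.i.d. from a configurable base composition, each site's
rate is μ (default 7×10⁻⁹/bp/generation) times a CpG multiplier when the
ancestral trinucleotide centred on the site contains a CG overlapping the
focal base. Recurrent mutation — the main neutral source of shared SNPs —
therefore arises naturally and preferentially at CpG sites. The CpG
multiplier defaults to 3.5, an order-of-magnitude literature value for
plant CpG transition enrichment; it is configurable and nothing downstream
depends on its exact value (the neutral calibration is re-run under
whatever value is configured).

**Balanced locus.** Balancing selection is represented genealogically, not
by forward simulation: every lineage carries one of two allelic classes
with fixed frequencies (f, 1−f) in both species and the ancestor;
coalescence is confined within (species, class) at rate scaled by
1/(f·N(t)); lineages may switch classes at an exchange rate; classes merge
only at the locus origin, which must pre-date the species split. With zero
exchange, no cross-class coalescence can occur before the origin (asserted
on recorded genealogies), which is exactly what produces trees that cluster
by allele across the species boundary. The balanced column itself is
emitted as a two-allele column matching the class labels. This is a
mechanistic stand-in: it generates the topological signal of long-term
balancing selection without modeling selection coefficients.

**Orthologue sets.** Genes are concatenations of independent 100-bp
coalescent tiles (free recombination between tiles, none within — windows
are only 100 bp and the genome-average recombination rate implies ~3.5 bp
unbroken tracts over the divergence time, so within-window recombination is
ignored). A configurable fraction of genes embeds a balanced tile; the
truth table records them. Note the expected *fixed-difference* fraction
under the fitted model is ≈ 0.16, the Jukes–Cantor-saturated value of
2μ(T + N_anc): the split-time term alone (2μT = 0.112) matches the ~10%
headline number of the real alignment, and the ancestral-coalescence term
adds the rest. The tests assert the coalescent expectation; the *slope* of
divergence in T equals 2μ exactly, with the ancestral term cancelling.

## Shared-SNP filters (`orthoshare`)

Quality thresholds (MQ ≥ 20, QD ≥ 2, ReadPosRankSum ≥ −8, DP ≥ 3,
FS ≤ 30) are set intersections and order-independent; records with missing
annotations fail conservatively. DP is applied as a site-level (mean)
annotation, matching how site filters are applied by standard genotypers.
The SNP-density rule (no more than three SNPs within any 10 bp) removes
*all* SNPs in a violating window and is applied to post-threshold
survivors; it is idempotent. Mappability follows the k-mer-uniqueness
definition: a position is uniquely mappable iff every 50-mer overlapping it
occurs exactly once in the genome (both strands) at ≤ 2 mismatches,
implemented by pigeonhole seeding (m+1 exact seed segments must contain one
exact seed for any ≤ m-mismatch match) and verified against an exhaustive
pairwise oracle on small genomes. Degenerate bases never match anything.
Shared SNPs are columns bi-allelic in both species with the identical
allele pair and MAF > 0.05 in each; MAF = min(c, n−c)/n at full precision,
rounded only for presentation.

## Demographic inference (`demog`)

The joint SFS is folded *jointly*: cell (i, j) merges with its complement
(n_A−i, n_C−j). Per-species folding would map fixed inter-species
differences onto the monomorphic cell and destroy the divergence-time
signal; joint folding keeps them distinct while avoiding any
ancestral-allele polarization (an unfolded mode exists when an outgroup is
available).

Expected cell probabilities come from Monte-Carlo coalescent simulation
with branch-length accumulation: per genealogy, a site is monomorphic with
probability exp(−μL_tot), otherwise its single mutation lands on a branch
with probability proportional to length. Including the monomorphic mass is
essential: conditional-on-polymorphic cell probabilities are exactly
invariant to rescaling all sizes and times together (branch-length ratios
are scale-free), so without the known mutation rate anchoring the (0,0)
cell the absolute scale of N and T is unidentifiable. The composite
log-likelihood is Σ m_ij ln p̂_ij over cells, ignoring polymorphic cells
observed fewer than 6 times; unobserved cells receive a probability floor
of 1/(10·n_sims). Optimization is multi-start Nelder–Mead on log₁₀
parameters with common random numbers (one simulation seed per fit), which
makes the Monte-Carlo objective deterministic and the fit reproducible;
parameters with zero-width bounds are held fixed and consume no randomness,
so the gene-flow template with its migration rates pinned reproduces the
no-gene-flow fit exactly under the same seed (the nesting check). The
reduced-scale recovery harness (n = 10+10, 50,000 sites, three free
parameters, 3 starts × 20,000 simulations per evaluation) recovers the
split time and both current sizes to within a few percent — comfortably
inside the ±25% acceptance band — in about half a minute. Confidence
intervals use a gene-level block bootstrap (genes resampled with
replacement, percentile intervals); its machinery is validated by a
coverage test with an analytic estimator.

## The scan (`tspscan`)

Windows are 100 bp at 1-bp steps; a window is valid iff ≥ 95 columns per
species are effectively aligned (A/C/G/T in every retained sample); samples
missing > 20% of a window are dropped from that window's tree. "Strong LD
in both species" is evaluated per SNP pair (haploid r² from haplotype
counts, r² > 0.5 in both species); a window qualifies when at least one
pair passes, and every SNP in a passing pair becomes a qualifying SNP.
Distances are Kimura two-parameter with pairwise deletion; saturated pairs
fall back to p-distance, and windows whose distances remain undefined are
unresolved. Neighbor joining is the standard Saitou–Nei agglomeration with
first-minimum tie-breaking in input order (verified against scikit-bio's
implementation); negative branch lengths are clamped at zero and
zero-length internal edges are treated as polytomies, so a variation-free
window yields a star tree and can never classify as an allelic tree.

Classification: *species tree* if some supported bipartition splits the
samples exactly by species; otherwise *allelic tree* if some supported
bipartition exactly equals the allele partition of a qualifying shared SNP
with both species represented on both sides; otherwise unresolved. The
exact-bipartition rule is stricter than merely rejecting species monophyly
(fewer false positives); the looser interpretation can be recovered by
inspecting the window's bipartitions directly. Bootstrap support (1000
column resamples) is available for final candidates and off by default in
scans.

## Neutrality calibration (`calibrate`)

The survival probability is reported in two variants, deliberately side by
side: the constant-size formula P = e^(−T/2N_A)·e^(−T/2N_C) evaluated at
the current sizes (≈ 1.5×10⁻¹⁷ under the fitted no-gene-flow model), and
the piecewise generalization replacing each T/2N with Σ Δt_i/2N_i up to the
split (≈ 1.8×10⁻⁴). These disagree by thirteen orders of magnitude because
the ancestral epochs are large; the formula follows the diploid-style 2N
convention as printed, while the simulator uses the haploid 1/N rate — the
two conventions are documented rather than silently mixed. The mass
simulation is consistent with the *piecewise* value: genuine neutral
trans-species genealogies (deep shared two-haplotype structure with normal
cross-species divergence) pass the full criteria chain at a rate on the
order of 10⁻⁵ per window, so runs of 10⁵ windows typically show 0–2 such
windows depending on the seed. An expected neutral TSP count below one per
genome therefore holds under the constant-size variant but not under the
piecewise variant; both numbers are reported and the tension is left
visible. The expected unbroken tract length uses the two-sided
approximation 2/(r·2T) ≈ 3.5 bp at r = 3.6×10⁻⁸/bp and T = 8×10⁶,
labeled as such.

The mass simulation chunks windows with per-chunk derived seeds (splitmix
mixing, kept below 2³¹) and flushes a manifest for resumability; the
criteria-chain counts are monotone non-increasing by construction and by
test.

## Statistics (`stats`)

π is the mean pairwise per-site difference with *pairwise* deletion (each
pair compared over its own jointly called sites); it satisfies the
frequency identity π = Σ 2p(1−p)·n/(n−1)/L on complete data, asserted in
tests. Gene-level π for candidates averages over exactly the allelic-tree
windows, never all windows. The π-vs-background test is one-sided
(greater) Wilcoxon–Mann–Whitney against simulated neutral windows — the
background is all simulated neutral windows of matching length — with
Benjamini–Hochberg correction; two-sided tests are used elsewhere
(structure chi-square without continuity correction, per-factor divergence
scans). Exact rank-sum enumeration is used for combined n ≤ 20 without
ties, the tie-corrected normal approximation otherwise.

## Ecology (`eco`)

Spatial thinning is randomized greedy removal of the most-crowded sample
(haversine distances on a 6371-km sphere) until all pairs are ≥ 5 km apart,
best of n repetitions. The niche model is an explicit Gaussian
environmental envelope — per-factor means and variances from the group's
samples, independence across factors, cell suitability the product of
factor densities normalized over the landscape, with an optional
high-probability (≥ 0.5 of maximum) support restriction. This replaces
Maxent deliberately: the inference the study design rests on is the
*contrast* between the observed Warren's I and its permutation
distribution, which is preserved; absolute I values from a different niche
model are not comparable and are not treated as reproduction targets.
Warren's I = 1 − ½Σ(√p₁−√p₂)² = 1 − H² (the squared Hellinger distance
identity is property-tested). Four permutation strategies are implemented:
label permutation (the identity test proper), pooled resampling at real or
equalized group sizes, and within-group resampling (a robustness check
where a *non*-significant result is the expected outcome). Both the
one-sample t-test p (as used in the source study) and the cleaner
permutation-rank p are reported; the null calibration test uses the rank p,
which is exact by construction.

## Synthetic data: what passing tests do and do not show

The generator reproduces the statistical structure the scan exploits —
realistic divergence/diversity ratios under the fitted demography, CpG
recurrent-mutation hotspots, balanced loci with trans-species allelic
classes, correlated ecological factor blocks with known group effects — but
not alignment error, genotyping error beyond the modeled annotations,
segmental duplication, population structure within species, or real
climate rasters. Passing tests therefore validate the *machinery and its
calibration*, not the biological conclusions about any particular gene;
the genome-wide counts of the real study (which depend on the real 80+22
panels) are out of scope by design.

## Problem sizes

Default test/acceptance scales: 10⁵ neutral windows for the false-positive
chain, 200 balanced windows for power, 50,000 sites at n = 10+10 for
demographic recovery, 2,500/1,200 replicates for the π/S expectation
checks, 40 harness repetitions × 100 permutations for the ecological null.
These sizes keep the full suite at a few minutes on one CPU while leaving
every Monte-Carlo band at ≥ 3 standard errors.
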