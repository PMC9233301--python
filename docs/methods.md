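# Methods

`hapshare` reconstructs recent population structure and demographic history
from phased SNP genotypes through haplotype sharing: chunk painting of every
individual against every other, community detection on the resulting
coancestry network, identity-by-descent (IBD) segments and the recent
effective population size they imply, and runs of homozygosity (ROH) with
two inbreeding coefficients.  A forward pedigree simulator with exact
ground-truth IBD makes every stage testable at desk scale.  This note
records the models, the parameters that matter, the numerical conventions,
and what the validation does and does not show.

## Forward pedigree simulator (`simdata`)

**Model.**  Discrete non-overlapping generations.  Each subpopulation of
diploid size `N(s, g)` holds exactly `floor(N/2)` females; every generation
females are paired to males by a random perfect matching (monogamy), each
child picks a uniformly random mother within its subpopulation and receives
the mother's partner as father, except that (a) with the probability given
by the migration-matrix row of the child's subpopulation the father is drawn
from another subpopulation, and (b) with probability `cousin_mating_rate` a
female's partner is replaced by one of her male first cousins (her own
assigned partner when she has none; fallbacks are counted, not errors).
A subpopulation with size 0 that later becomes non-empty is founded through
its migration row (used for admixed-cohort scenarios).

Monogamy is deliberate.  With independent per-child parent draws almost all
siblings are half-siblings, so "first cousins" would carry kinship 1/32
instead of the textbook 1/16 and consanguinity scenarios would be
unrealistically weak.  The pairing scheme keeps the per-generation
coalescence probability of two lineages in distinct individuals at exactly
`1/(2N)` (verified analytically and by the spectrum goodness-of-fit test),
so census size equals diploid effective size.

**Transmission.**  Gametes recombine under the Haldane model: crossover
count per chromosome ~ Poisson(length_cM/100), positions uniform in cM, no
interference.  This matches the exponential segment-length model used for
Ne fitting.  Founder haplotypes are unrelated and uniquely labelled, so IBD
is defined exactly: two final haplotypes are IBD wherever their ancestry
mosaics carry the same founder label.  `truth_ibd` intersects mosaics,
merges touching intervals maximally, and filters by genetic length;
self-pairs (an individual's two haplotypes) measure autozygosity.

**Genotypes.**  Sites sit on a regular cM grid (`(k+0.5)·L/S`), with bp
positions from the fixed cM→bp factor of the chromosome spec (default
1 cM = 1 Mb).  Founder allele frequencies are drawn from `maf_law`
(default uniform on [0.02, 0.5], mimicking an array-like site-frequency
spectrum after MAF filtering).  Genotype errors flip single alleles;
phase-switch errors swap an individual's haplotypes from a site onward,
resetting at chromosome starts.

**What the simulator does not emulate:** linkage-disequilibrium structure in
the founders (founder alleles are independent across sites), mutation,
crossover interference and recombination hotspots, genotype-missingness
patterns, sex chromosomes, and overlapping generations.  Passing tests
therefore validate the analysis logic and its statistical behaviour under
the stated pedigree model, not robustness to every artefact of real array
data.

## Chunk painting (`paint`)

Painting attributes every site of a recipient haplotype to the donor
haplotype carrying the longest identical interval covering that site,
excluding both haplotypes of the recipient's own individual.  A chunk is a
maximal run of sites with the same donor; chunkcounts accumulate one per
chunk and chunklengths the chunk's genetic span, both aggregated to donor
and recipient individuals and summed over chromosomes.  This deterministic
longest-covering-match rule reproduces the ChromoPainter-style contract
(counts plus lengths with exact row conservation) while remaining
oracle-checkable; the likelihood-based painting with estimated Ne/θ is
intentionally out of scope.

Numerical conventions:

- Site length ownership: each site owns the half-open interval between the
  midpoints to its neighbours, clamped at chromosome ends, so each
  chunklengths row sums to exactly 2 × total map length (two haplotypes per
  recipient).
- Donor ties (equal covering length in sites) are broken by a pure seeded
  function: site `k` of chromosome `c` owns
  `r_k = splitmix64(splitmix64(seed + c·0x632BE59BD9B4E019) + k)` and donor
  `h`'s key is `splitmix64(r_k + h·0x9E3779B97F4A7C15)`; the largest key
  wins.  Unbiased across seeds, reproducible, and independently
  implementable by the brute-force oracle used in the tests.  A
  `split-equally` mode divides each tied site's length by the tie
  multiplicity instead.
- Sites where no donor carries the recipient's allele (possible only when
  every other haplotype differs there) inherit the neighbouring chunk's
  donor, preferring the left.
- `chunks_per_region` is stored for compatibility with downstream tools but
  performs no c-factor rescaling; the PCA normalises rows explicitly.

`maximal_matches` reports set-maximal matches (maximal identical intervals
not strictly contained in a longer interval with any other donor), the
candidates from which per-site longest covering matches are drawn.

Coancestry PCA: rows normalised to sum 1, columns centred, SVD; the first k
left vectors scaled by singular values, each component's sign fixed so its
largest-magnitude loading is positive.

## Coancestry network and recursive Leiden (`community`)

Nodes are individuals; edge weights are symmetrised chunkcounts
`(c_ij + c_ji)/2`, kept only when strictly between the band bounds (defaults
2 and 25).  The low-pass removes deep, uninformative relationships; the
high-pass removes close relatives whose edges otherwise dominate community
structure — at desk scale this same band is what prevents family clusters
from masquerading as populations.

Leiden community detection (weighted RBConfiguration quality, resolution 1
by default) is applied recursively on induced subgraphs to a maximum depth
(default 4), never subdividing communities below `min_size` (default 100;
desk-scale tests use 20).  Recursion additionally requires the proposed
sub-partition to be supported by the data: its modularity must exceed by
`min_gain` (default 0.1) the modularity Leiden attains on degree-preserving
rewirings of the same subgraph with shuffled weights (3 nulls, seeded).
Without this stopping rule modularity optimisation invents communities in
homogeneous subgraphs — an Erdős–Rényi-like block of 150 nodes "splits"
into half a dozen noise clusters — and no planted structure survives four
recursion levels.  All seeds derive from the function's `seed` argument.

## Cluster profiles (`profiles`)

- **Copying vectors**: per cluster, the mean of its members' received
  chunklengths aggregated by donor cluster, normalised to sum 1.
- **nnls sharing profile** β for a target cluster: X holds each target
  individual's chunklengths received from each of the P other clusters
  (the self-cluster donor column is removed — every *other* cluster is a
  source); Y is the P×P matrix of mean donations between source clusters
  (diagonal retained).  β solves min‖x̄ − Yᵀβ‖², β ≥ 0, then is normalised
  to proportions.  No uncertainty is attached (no bootstrap on β).
- **TVD** between copying vectors: `0.5·Σ|a_i − b_i|`.
- **Hudson FST**, ratio of averages: per-site numerator
  `(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`, denominator
  `p1(1−p2) + p2(1−p1)`; summed separately over sites before dividing.
  Sites monomorphic in both groups are skipped.

## IBD segments (`ibd`)

Detection is exact haplotype matching, appropriate for phased panels with
low error: a positional Burrows–Wheeler transform is built site by site and
all maximal pairwise matches spanning at least `min_cM` (default 1 cM) are
reported via the divergence-array block scan, in time linear in panel size
plus output.  The site-count threshold fed to the scan is derived from the
map as the minimum number of sites any interval of `min_cM` can contain, so
no qualifying match is missed under irregular site spacing.  Segment length
is `cM(last site) − cM(first site)`; within-individual matches are excluded;
pairs are canonicalised (a < b).

Merging rejoins consecutive same-pair, same-phase segments when the gap is
shorter than 0.6 cM and contains at most one discordant site, applied
transitively left to right.  "Discordant" is evaluated at the haplotype
level (the two haplotypes carry different alleles), a documented divergence
from genotype-level discordance counting in the external merge utility this
rule mirrors; on phased simulator data the two coincide for isolated errors.

Sharing summaries give, per individual, the mean over same-cluster partners
of the per-partner total segment length and segment count (zero-sharing
partners contribute zeros; singleton clusters yield missing values).  Group
comparisons use the Mann–Whitney U test (exact enumeration when m·n ≤ 200
and tie-free, normal approximation with tie correction otherwise).

## Recent effective population size (`demography`)

Two haplotypes coalesce g generations ago with probability
`P(g) = (1/2Ne(g))·Π_{h<g}(1 − 1/2Ne(h))`; conditional on g, segment
lengths are exponential with rate 2g per Morgan.  The expected number of
segments of length ≥ u per haplotype pair is `Σ_g P(g)·2gL·e^(−2gu)` in the
edge-free form, or per chromosome `e^(−2gu)·(2g(C−u)+1)` in the
finite-chromosome form the fitter uses.  Both are *marginal*
approximations: observed maximal segments concatenate adjacent IBD of
different coalescence depths, which inflates the extreme length tail by an
amount that grows with the genome-wide IBD fraction.  At the fitting
threshold (> 4 cM, within-cluster segments only) and desk-scale IBD
fractions of a few percent this bias is well inside the estimator's
tolerance; the simulator goodness-of-fit test is run at a pair count where
Monte-Carlo error dominates it.

`fit_ne` minimises the Poisson deviance between observed per-bin counts
(default 25 log-spaced bins from 4 cM plus an open tail) and the cohort
expectation (`2n(n−1)` haplotype pairs) over a piecewise-constant log10-Ne
trajectory with knots every 5 generations, Ne ∈ [10, 10⁸], plus a squared
smoothness penalty on adjacent knots with weight
`λ = smoothing × total count / 100`.  Scaling λ with the total count makes
the point estimate exactly invariant to rescaling counts and pair numbers.
The default `smoothing = 1` was calibrated on closed-form and
simulation self-recovery (constant-Ne trajectories recovered within ±25%,
typically ±15%) while preserving bottleneck recovery (a 2000→200→2000
trajectory is recovered with the dip localised to the correct 5-generation
knot and depth within a factor of 2).  Initialisation is the constant Ne
matching the total segment count (bisection); L-BFGS-B refines the knots.

Confidence bands resample individuals with replacement (weights multiply
into pair counts and segment multiplicities), refit, and take the
per-generation log-spread.  Because segments of different pairs share
pedigree events, bin counts are over-dispersed relative to Poisson by an
order of magnitude; the band half-width is therefore
`1.96·sqrt(φ)·sd(log Ne_boot)` with `φ = max(1, deviance/dof)` from the
point fit (quasi-likelihood inflation).  Bands are clipped to contain the
point estimate.  Reporting defaults to generations 5/15/30, configurable
(e.g. 30/15/10).

## ROH and inbreeding (`inbreeding`)

The ROH scan re-implements the PLINK windowed procedure with its published
defaults: 50-SNP windows pass with ≤ 1 heterozygote and ≤ 5 missing calls; a
SNP is a run candidate when ≥ 5% of windows covering it pass (the external
tool's default for the unstated hit threshold, configurable); maximal
candidate runs are split at inter-SNP gaps > 1000 kb and reported when they
hold ≥ 50 SNPs, span ≥ 1500 kb and average ≥ 1 SNP per 50 kb.  No LD pruning
is applied to the ROH site set.

`F_ROH` is the summed length of ROH strictly longer than 1.5 Mb divided by
the genome constant 2,879,248,291 bp (the human autosomal total; simulated
genomes pass their own total).  `F_SNP = (O_HOM − E_HOM)/(N − E_HOM)` with
`E_HOM = Σ_i [1 − 2p_i(1−p_i)·n_i/(n_i−1)]` over the group's polymorphic
sites, frequencies computed within the individual's cluster group (the
grouping is a configurable table; each leaf is its own group by default).
The sample-size correction matches the conventional heterozygosity
expectation.  Zero means random mating; positive values consanguinity;
negative values inbreeding avoidance.  Note that at a cousin-marriage rate
c the expected group mean is approximately `c/16·(1+3F̄)` — about 0.02 at
c = 0.3 — so distinguishing moderate consanguinity from zero requires
cohorts of several hundred individuals.

## QC, pruning and PCA (`io`)

Site QC drops strand-ambiguous (A/T, G/C) SNPs, sites with > 5%
missingness, MAF < 2%, and Hardy–Weinberg exact-test p < 1e−6 (Wigginton
enumeration, mid-p off), then individuals with > 5% missingness.  LD
pruning slides a 1000-SNP window by 50, removing the later site of any pair
with r² > 0.2 (deterministic, order-stable; missing values mean-imputed for
the correlation).  Allele-frequency PCA centres by 2p̂, scales by
√(2p̂(1−p̂)), mean-imputes missing entries and takes the SVD, with the same
sign convention as the coancestry PCA.

Coordinates: bp are 1-based inclusive as in VCF; site-index intervals are
half-open; cM intervals are closed at segment ends.  Genetic positions come
from PLINK `.map` files by linear interpolation with constant extrapolation
beyond the map ends.

## Pipeline, seeds, problem sizes

`run_pipeline` executes simulate/load → QC → paint → network → Leiden →
profiles → IBD detect/merge → sharing → Ne → ROH/F, writing every declared
table plus a JSON manifest of versions, seeds and stage counts.  Every
randomised stage draws its seed from the single global seed via
`SeedSequence(seed, spawn_key=(stage,))`, so reruns are bit-identical.  The
CLI subcommands are thin wrappers over the same functions on files.

Validation problem sizes were chosen once as desk-scale study conditions:
the deep panel for IBD/Ne validation is one population of 500 diploids for
50 generations, 200 sampled, 2 × 100 cM chromosomes at 30 sites/cM; cluster
recovery uses 4 × 150 diploids with 0.1%/generation migration over 20
generations; the admixture profile uses a 70/30 cohort of 200 founded 5
generations before sampling on 4 × 100 cM chromosomes; inbreeding regimes
use 1000 diploids (15 generations; cousin rate 0 or 0.3) and a 100-diploid
bottleneck held 50 generations; the sharing gradient uses sizes
{100, 500, 2000} over 30 generations.  `scripts/acceptance.py` recomputes
all headline quantities from scratch at these sizes under a caller-supplied
seed.

## Known limitations

- Painting is exact-match (non-probabilistic); it does not model genotype
  error within chunks, and low-diversity regions inflate chance matches on
  sparse maps.
- IBD detection requires error-free phased input for exactness; robustness
  to error comes only from the merge rule, not from within-segment mismatch
  tolerance.
- The segment-length model ignores concatenation of adjacent IBD classes
  and crossover interference; Ne estimates in regimes with very high IBD
  fractions (tiny Ne, deep G) inherit that bias.
- The Leiden stopping rule tests against a degree-preserving null; genuinely
  weak but real substructure below the `min_gain` margin is left unsplit.
- F_SNP group means carry a small negative finite-sample shift when the
  cohort contains strong family structure, since allele frequencies are
  estimated from correlated copies.
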