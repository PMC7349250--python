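# Methods

This note records the statistical models implemented, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that were genuinely open.

## Genotype representation and QC

Genotypes are held as an allele-dosage matrix (samples × variants,
codes 0/1/2 for copies of the alternate allele, −1 for missing), with
1-based VCF coordinates; all physical distances are simple base-pair
position differences. Only biallelic SNPs are admitted; multiallelic or
non-SNP records are skipped at ingestion with a logged count. Half-calls
(`0/.`) are treated as missing — the conservative convention for GBS
data, where a half-call usually reflects low depth rather than a typed
haploid.

The marker filter cascade runs **call rate → monomorphism → MAF**, each
variant attributed to the first test it fails, so the report's
categories are disjoint and sum exactly to the input count. The order
itself is a convention (the underlying survey protocols do not state
one); putting call rate first means a variant with no calls at all is
never evaluated for MAF, whose value would be undefined. "Monomorphic"
is operationalised as *fewer than two distinct dosage values among
non-missing calls*; the corner case of a site where every call is
heterozygous (allele frequency 0.5 but a single dosage value) is
removed under this rule — such sites are genotypically uninformative
and, in real data, usually paralog-collapse artifacts. Defaults
MAF ≥ 0.05 and call rate ≥ 0.95 follow standard GBS practice. Filtering
is idempotent by construction.

## Diversity and Tajima's D

Per site: MAF, observed heterozygosity (heterozygous fraction of
non-missing calls), expected heterozygosity 2p(1−p). Genome-wide values
are unweighted means over variants.

Tajima's D is computed genome-wide (one global value; a per-window
variant exists behind `tajima_d_windows`), as surveys of this kind
report a single D. θ_π uses the allele-frequency form per site,
c(n_k − c)/C(n_k, 2) with c the alternate-allele count and n_k the
non-missing allele count, summed over sites — algebraically identical
to averaging pairwise sequence differences, and independent of phase
because per-site differences only depend on allele counts. θ_W sums
1/a₁(n_k) over segregating sites, reducing to S/a₁(n) with complete
data. Missing calls therefore shrink n_k per site instead of being
imputed. The variance uses the full Tajima (1989) constant cascade
(a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) evaluated at n = 2 × samples; with
missing data this is an approximation (the exact variance for
site-specific n has no standard closed form). D is reported as NaN,
with a warning, when S = 0 — an undefined value, not zero.

Note on interpretation: a MAF-ascertained panel (every GBS panel after
QC) has its low-frequency classes truncated, which pushes D positive.
The worked example shows D ≈ +1.7 on a *neutral, constant-size*
simulated population purely because of the MAF ≥ 0.05 floor. Positive D
on ascertained data is therefore not, by itself, evidence of a
bottleneck or balancing selection; the pipeline keeps pre- and post-QC
computations available so the user can see the shift.

## Linkage disequilibrium

Two r² estimators:

- **phased**: direct haplotype counting, r² = D²/(P_A P_a P_B P_b),
  D = P_AB − P_A P_B (equivalently (P_AB P_ab − P_Ab P_aB)² over the
  same denominator).
- **composite** (default): squared Pearson correlation of dosage
  vectors over pairwise-complete samples (Rogers–Huff). This is the
  standard surrogate for unphased genotype data; at Hardy–Weinberg
  proportions it estimates the same quantity as the phased form, and
  the test suite checks the two agree within 0.05 mean absolute
  difference on simulated random-mating data, and exactly when every
  individual is homozygous. An EM haplotype-frequency estimator is
  deliberately out of scope.

Pairs with fewer than 3 complete cells or a site monomorphic on the
complete cells are undefined: excluded and counted, never zero-filled.
Pair enumeration is within-chromosome (decay with physical distance is
meaningless across chromosomes) using a vectorised pairwise-complete
correlation over per-chromosome blocks. Decay bins are half-open
[lo, hi); the default 12-bin scheme spans 0–40 kb up to 50–92 Mb. Bin
SD is the population SD (ddof = 0), so a single-pair bin reports 0
rather than an undefined value; pairs outside every bin are tallied.

## LD-based historical Ne

Per distance bin: c from the bin's mean physical distance via a mapping
function (linear with 1 cM/Mb default — capped at 0.5 — or Haldane
0.5(1 − e^(−2d)) or Kosambi 0.5·tanh(2d)); sample-size adjustment
r²_adj = r̄² − 1/(βn) (β = 2 phased, β = 1 unphased); then

    N_t = (1/r²_adj − α) / (4c),   t = 1/(2c).

α ∈ {1, 2, 2.2}: 1 is the pure-drift Sved form (and makes the inversion
the exact algebraic inverse of E[r²] = 1/(1 + 4N_e c), a property the
tests exploit); 2 (default) corrects for mutation and is appropriate
for sequence-derived panels. Generations t = 1/(2c) are reported both
to two decimals and rounded half-to-even, and labelled approximate —
the dating is a plug-in convention, not an estimate with error bars.
Bins with fewer than `min_pairs` (default 50) pairs, non-positive
adjusted r², or non-positive N_t are dropped with a warning, never
clamped: clamping would fabricate history. Trajectories list the most
recent epoch (largest distance, largest c) first.

For raw pair input, the default binning is 20 equal-count bins between
40 kb and 20 Mb; the short-range floor avoids the strong-LD /
ascertainment regime where Sved's approximation is worst.

The published worked examples this package reproduces (deep-history
bins at 811,669 / 617,213 / 438,785 bp) are matched within 1% by
α = 2, linear mapping, and the printed r̄² treated as already adjusted —
the unique setting consistent with those rows; subtracting 1/(βn) again
does not reproduce them. The most-recent-epoch headline value of that
survey is not reproducible from its printed inputs under any mapping
tried here; the reproduction is therefore limited to the rows whose
arithmetic closes.

## Differentiation, relatedness, PCA

**FST** is Weir–Cockerham (1984) θ with multi-locus combination as a
ratio of summed components Σa/Σ(a+b+c), computed per population pair
(r = 2) with per-site sample sizes from the non-missing calls. Negative
estimates are reported as computed: weakly differentiated herds sit at
the estimator's noise floor, and truncation at zero would bias every
comparison upward. A fixed-difference pair of populations gives exactly
θ = 1; a panmictic split is centred on 0.

**Nei's (1972) standard distance** D = −ln(J_xy/√(J_x J_y)) with the J
terms averaged over loci and summed over both alleles; exported as TSV
and as a NEXUS DISTANCES block so network tools (SplitsTree-style) can
consume it directly. Network construction itself is out of scope.

**Relatedness** is the unadjusted Yang A_jk (the SNP
genetic-relationship matrix with allele frequencies estimated from the
sample itself): off-diagonal (x_j − 2p)(x_k − 2p)/(2p(1−p)) averaged
over pairwise-complete polymorphic sites, diagonal
(x² − (1+2p)x + 2p²)/(2p(1−p)). Pairs with fewer than `min_sites`
(default 100) usable sites are flagged NaN. Because p is estimated from
the same sample, off-diagonals are mechanically centred slightly below
zero (≈ −1/(n−1)); the tests account for this.

**PCA** standardises dosage columns (per-site mean imputation of
missing calls, for the decomposition only; constant columns dropped)
and uses a full SVD. Discriminant analysis (DAPC) and K-means are
deliberately replaced by plain PCA coordinates plus exports: the
discriminant step adds a trained transformation with free parameters
that a reusable pipeline should not hard-code.

## The Wright–Fisher generator

Forward-time, discrete generations, N diploids per generation from a
configurable schedule; offspring draw two parents uniformly (selfing
allowed); per-gamete recombination is Poisson crossovers at
`rec_per_bp` within chromosomes with free assortment between them;
mutation is infinite-sites at `mu_per_bp` with uniform positions
(collisions redrawn, so every site stays biallelic). Runs start
mutation-free and burn in 10N generations to approach mutation–drift
equilibrium (the suite verifies mean diversity matches θ/(1+θ) within
Monte-Carlo error). One seeded generator drives the whole run; a fixed
seed yields byte-identical VCF output. An optional terminal split
partitions the population into closed subpopulations for the last k
generations — the minimal model of recently separated herds. Desk-scale
bounds are enforced (≤ 500 diploids, ≤ 500 scheduled generations,
≤ 10 Mb genome).

Forward simulation (rather than coalescent) was chosen so arbitrary
size schedules — bottlenecks included — map one-to-one onto
per-generation sizes, and so every sampled individual carries exact
known haplotypes for oracle tests.

What the generator does **not** emulate: sequencing error, depth-driven
GBS missingness structure (only uniform random missingness), selection,
gene conversion, migration beyond clean splits, and real recombination
maps. Passing tests on this generator therefore validate the
*estimators* under their model assumptions, not robustness to real GBS
artifacts.

### Scenario sizes used by the test suite

Chosen so the full suite runs in minutes while keeping each test in the
statistical regime its method assumes:

- **Study-like fixture**: 250 ancestral diploids, five subpopulations
  split one generation before sampling (expected pairwise
  FST ≈ t/(2N_sub) ≈ 0.01), 50 sampled diploids, 15 × 240 kb
  chromosomes, μ = 3×10⁻⁷/bp, export MAF floor 0.05. Many short,
  independently assorting chromosomes are essential: with the same
  genome length in 3 long chromosomes, the multi-locus FST of one
  realisation swings several-fold because all loci share a handful of
  genealogies. The MAF floor makes the fixture an *ascertained* panel,
  like distributed GBS data sets, so re-running QC retains ~100%.
- **Ne recovery**: constant N = 100, 50 sampled diploids, one 5 Mb
  chromosome carrying 1 Morgan of map (rec 2×10⁻⁷/bp, a scaled-down
  stand-in for the hundreds of Morgans a genome-wide panel spans; at a
  literal 1 cM/Mb a 5 Mb genome is 0.05 Morgans — a single genealogy —
  and no LD-based estimator is consistent there, as a coalescent
  cross-check confirms). With α = 2, β = 1, adjustment on, the median
  N_t over bins with t ≤ 50 recovers the truth within 30% in 10/10
  seeded replicates.
- **Differentiation signal**: two subpopulations of 50, divergence
  t ∈ {5, 20, 50} (expected θ ≈ t/100 = 0.05…0.5, well separated at
  3 replicates each), ten 50 kb chromosomes.

## Numerical conventions

- Undefined statistics (D with S = 0, r² on monomorphic sites, FST with
  no shared polymorphic sites, flagged A_jk pairs) are NaN plus a log
  message — never silently zero.
- Distance bins are half-open [lo, hi) everywhere; a pair at exactly
  40,000 bp belongs to the 40–60 kb bin.
- Generation rounding is half-to-even (numpy convention).
- Linear map c is capped at 0.5; zero physical distance is a fatal
  error (co-located sites carry no recombination information).
- Matrix invariants (strictly increasing positions per chromosome,
  dosage code domain, unique sample ids, report accounting balance) are
  validated at construction, not at use.

## Known limitations

- The Tajima variance constants assume complete data; with missingness
  the reported D is approximate (components are exact).
- Composite r² assumes Hardy–Weinberg proportions; under strong
  inbreeding it diverges from haplotype r².
- The Ne trajectory is a sequence of independent per-bin inversions, as
  in the SNeP-style method it follows: no smoothing, no confidence
  intervals, and the t = 1/(2c) dating inherits all the caveats of that
  convention.
- The simulator's desk-scale bounds make genome-wide ascertainment
  effects (e.g., the real ~37-chromosome layout) representable only in
  miniature.
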