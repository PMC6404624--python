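# Methods

This note documents the models, numerical choices and simulation design
behind `epiarm`, at the level a user fitting their own data (or auditing the
test suite) needs.

## Units of testing

Markers are assigned to chromosome arms by the centromere interval:
positions strictly below the interval go to the short arm (S), strictly
above to the long arm (L), and positions inside the closed interval are
centromeric and excluded from every arm marker set.  Coordinates are 1-based
inclusive bp.  The closed-interval exclusion is a deliberate conservative
choice: markers inside an annotated centromere cannot be assigned to an arm
without arbitrariness, and they are few.  Arm labels follow the grammar
`<homeolog group><subgenome><S|L>` (e.g. `4BL`); the parsing pattern is
configurable so non-wheat genomes with a different naming scheme work.

## Kernels

Additive kinship is the allele-frequency-scaled cross-product
`K = WW′ / (2 Σ_j p_j(1−p_j))`, with dosage columns mean-imputed for missing
calls and centered at `2p_j`; allele frequencies come from the analyzed
lines themselves.  Monomorphic markers are dropped with a warning.  On fully
inbred material the diagonal of K averages about 2 (the scaling assumes
Hardy–Weinberg heterozygosity that inbreds lack); nothing downstream
requires diagonal 1, and no trace normalization is applied by default (an
optional mean-diagonal-1 rescale exists).  Epistatic kernels are plain
Hadamard products of additive kinships — order 2 for arm pairs, order 3 for
homeologous triplets — which are positive semidefinite by the Schur product
theorem.  The background additive kernel uses every non-centromeric marker
outside the tested arms; the background epistatic kernel is its
self-Hadamard square, the standard genome-wide additive-by-additive
covariance.  That self-Hadamard definition is a configuration point, since
reasonable alternatives exist (e.g. subtracting within-arm terms).

During a scan, leave-arms-out backgrounds are assembled from cached per-arm
cross-product numerators, `K_bg = Σ_keep d_a K_a / Σ_keep d_a` with
`d_a = 2Σ_{j∈a} p_j q_j`.  Because imputation and allele frequencies are
per-marker quantities, this is algebraically identical to recomputing the
kinship on the marker complement (a unit test asserts the equality), and it
turns the per-pair background cost from O(lines² × markers) into O(lines²).

## REML and BLUP

The mixed model is `y = Xβ + Σ_k Z g_k + ε` with `g_k ~ N(0, σ²_k K_k)` and
i.i.d. residual.  X holds an intercept and treatment contrasts for
environments (first environment in sorted order as reference); genuinely
collinear columns are dropped with a warning.  The restricted likelihood is
maximized over the nonnegative components by:

- **EM warmup** (3 iterations by default): the rank-aware EM update
  `σ²_new = σ² + (σ⁴ / r_k)(y′PM_kPy − tr(PM_k))`, with `M_k = Z K_k Z′` and
  `r_k = rank(K_k)`, which provably never decreases the restricted
  likelihood (the residual update uses r = n);
- **average-information steps** thereafter: `Δ = AI⁻¹ s` over the active
  components, with step halving until the likelihood does not decrease, and
  fallback to an EM step if halving fails.  Components pinned at the floor
  with non-positive scores are held out of the AI system, which keeps it
  well conditioned near the boundary;
- **boundary handling**: components are projected to a floor of
  `1e−12 · var(y)` during iteration; at convergence any component below
  `1e−8 · var(y)` is reported as exactly 0 with an all-zero BLUP vector and
  a boundary flag.  Convergence is `|Δ logREML| < 1e−6` or 200 iterations;
  a non-convergent fit is returned flagged, never silently.

All per-iteration algebra runs at the line level through the Woodbury
identity `V⁻¹ = σe⁻²(I − ZΓ(σe²I + DΓ)⁻¹Z′)` with `Γ = Σ σ²_k K_k` and
`D = Z′Z` diagonal, so a fit costs O(m³) per iteration in the number of
lines m, independent of replication across environments.  BLUPs are
`ĝ_k = σ²_k K_k Z′Py`.  The optimizer was validated against closed forms
(fixed-effects-only REML, balanced one-way ANOVA) and an independent 1-D
profiled-restricted-likelihood oracle based on the eigendecomposition of a
single kernel; agreement is at the 1e−5 level on the log-likelihood.

## Tests and summaries

Likelihood ratio statistics are `D = max(0, 2(logL_alt − logL_null))`
referred to the χ² upper tail with df equal to the number of added
components (2 for the additive step, 1 for each interaction step).  A
printed formula with the opposite sign appears in some descriptions of this
procedure; the positive-sign version is the one consistent with the χ²
reference distribution and is what is implemented.  When the tested
component sits on the zero boundary the p-value is reported as exactly 1:
under the null, variance components are estimated at zero a large fraction
of the time, so the null p-value distribution is a mixture of a point mass
at 1 and an approximately uniform part — stochastically larger than uniform,
hence conservative.  No 50:50 boundary mixture correction is applied by
default, matching the plain-χ² convention of regional heritability mapping;
both choices are available.

h² for a component is its variance estimate divided by the sum of all
genetic components of the fullest fitted model (backgrounds + arms +
interactions), so the h² values of one fit sum to 1 over the genetic terms.
This is a component-scale (not phenotypic-scale) proportion: kernels with
different diagonal means contribute different phenotypic variance per unit
of σ² (about 2× for additive and 4× for epistatic kernels on inbreds; see
`simdata.realized_scale`).

ρ is the Pearson correlation across lines between `g_Ai ∘ g_Ai′` and the
interaction BLUP, with p from the usual t-transform on n−2 df.  If exactly
one additive variance is zero, the remaining additive BLUP is correlated
with the interaction BLUP instead (`single_arm` mode); if both are zero the
statistic is undefined and reported as 0 with p = 1.  Requesting ρ for a
zero interaction component is an error by contract.

Bonferroni control divides α by the number of tests *attempted* in the scan
run (861 for a full wheat scan, 42 for homeologs only), not the number that
converged — deliberately conservative.

## Centromere localization

The density of GBS marker positions is estimated with a Gaussian KDE on a
512-point grid spanning [min − 3h, max + 3h]; the default bandwidth is the
Silverman-style rule `0.9·min(sd, IQR/1.34)·n^(−1/5)`.  Stationary points
are sign changes of the first differences of the gridded density; plateaus
of exactly-zero differences collapse to their midpoint.  The second
stationary point from the low-coordinate end — the interior minimum between
the two arm density peaks of a well-behaved two-armed chromosome — defines
the estimate, whose start/end are the flanking grid positions.  Fewer than
three stationary points (a unimodal or monotone density) is an error, not a
guess.  The rule is brittle when the density has small wiggles before the
centromeric dip, so the smoothing scale matters: the recovery study in the
test suite uses a bandwidth of 10% of the chromosome length, i.e. smoothing
matched to the scale of the structure sought, rather than the Silverman
default, which under-smooths flat arm plateaus at a few thousand markers.
Estimation is applied only to chromosomes lacking an annotated interval.

## The synthetic-data generator

`simdata` emulates, at desk scale, a multi-environment trial of fully
inbred lines from an allopolyploid breeding program.  The standard scenario
used throughout the tests:

- **Genome**: 1 homeolog group × 3 subgenomes (chromosomes 1A/1B/1D, six
  arms), 600 Mbp chromosomes, centromere spanning the middle 10%.
- **Markers**: 250 per arm, positions uniform within arms; marker density
  inside the centromere reduced by 90% (the methylation-depletion signal the
  centromere locator uses).  Target allele frequencies are uniform on
  [0.1, 0.9].
- **Population**: 400 lines, each a mosaic of 6 founder haplotypes with a
  2% switch probability between adjacent markers, restarting at arm
  boundaries — about 5 long LD blocks per arm, independent across arms.
  This mimics a narrow elite pool with long-range LD, the regime arm-level
  testing targets: arm kinships then carry strong, arm-specific relatedness
  variation, which is exactly what makes a Hadamard interaction kernel
  distinguishable from the background.  (With many founders or short LD
  blocks the interaction kernels collapse toward the identity and the
  signal is absorbed by the other terms; an optional biparental
  family-structure mode exists but is off by default, because family blocks
  shared across all arms make the pair kernels collinear.)  Genotypes are
  homozygous 0/2; a heterozygosity rate option exists and defaults to 0.
- **Effects**: background additive (σ² = 0.15, genome-wide kinship),
  background epistatic (0.05, its self-Hadamard), each arm additive (0.10),
  optional arm-pair interactions, residual σ² = 1.  Variances are
  component-scale parameters of the kernels, the same scale on which the
  model reports them and on which h² proportions are computed; an injected
  interaction of 0.2 is therefore 20% of the total genetic variance
  (components summing to 1.0).  Interaction effect vectors can be drawn
  three ways: `independent` (from N(0, σ²K_i⊙K_i′)), or `positive_product` /
  `negative_product` (±λ times the elementwise product of the two arm
  additive effects, scaled to the target variance) to create
  greater-than-additive or less-than-additive architectures for the ρ
  tests.
- **Design**: 3 environments with fixed environment effects, per-line
  inclusion probability 0.9 per environment (unbalanced, every line observed
  at least once), ~2.7 observations per line.

The truth record stores every drawn effect vector, the component-scale
parameters and the realized variances.  `background_excludes` lets the
generator draw the backgrounds from the same leave-arms-out kernels a scan
fits, producing a correctly specified model for parameter-recovery studies;
by default backgrounds are genome-wide, so scans on simulated data include
the mild background mismatch real analyses face.

What the generator does **not** emulate: coalescent/recombination-realistic
LD, GBS read-level error, non-MCAR missingness, genotype-by-environment
interaction, or selection. Passing tests therefore demonstrate the
statistical machinery under the stated generative assumptions, not
performance guarantees on any particular empirical population.

## Validation suite (sizes and what they show)

- REML vs independent oracle: 20 seeded single-kernel datasets, n = 100;
  log-likelihood agreement within 1e−4.
- Interaction variance recovery: one fixed 400-line genome, 100 phenotype
  replicates, correctly specified backgrounds; the mean estimate must lie
  within 2 Monte-Carlo SEs of the simulated 0.2.
- Type-I and conservatism: 200 null replicates; nominal-0.05 rejection of
  the interaction LRT ≤ 7%, ECDF of null p-values never above uniform by
  more than the one-sided 95% KS distance, and ≥ 25% of null fits on the
  boundary (the point mass at p = 1).
- Detection ranking: 25 independent full simulations (fresh genome each);
  the injected pair must have the uniquely smallest interaction p-value in
  ≥ 80% of them.
- Centromere recovery: 100 replicates of a 1,230-marker chromosome with a
  90% density dip over 8% of its length; the estimate must overlap the true
  depleted region ≥ 95% of the time, and ablating the dip must destroy
  recovery.
- ρ sign: 100 replicates with a `negative_product` interaction; among
  replicates with an estimable interaction variance, ρ must be negative in
  ≥ 90%.

Replicate counts and population sizes were chosen so the whole suite runs
in minutes on one CPU; fixed genomes are reused across phenotype replicates
where the claim under test is conditional on the genotypes.

## Known limitations

- The likelihood surface for an interaction component is flat when the
  population's relatedness is diffuse; in such designs the component is
  estimated at zero even when truly present (conservatism, not error).
- The "second stationary point" centromere rule depends on the smoothing
  bandwidth; it is not robust to multimodal arm densities.
- No FDR alternatives to Bonferroni, no GxE kernels, no heterogeneous
  residual variances, no sparse/large-n solvers (designs up to a few
  thousand lines are comfortable).
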