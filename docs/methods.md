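# Methods

This note documents the models implemented in ocskit, the choices made
where a definition was genuinely open, and what the test suite's synthetic
data does and does not establish about real data.

## Pedigree quantities

All pedigree quantities are exact recursions over a *prepared* pedigree:
topologically sorted, with founder rows added for every referenced parent,
and repaired.  The repair policy is this package's own: an id used as both
sire and dam has all parental links to it severed; recorded sex
contradicting parental usage is corrected to the usage; cycles are broken
by severing the parent link of the later-born (tie: later file order)
individual.  Every repair is logged and returned on the pedigree object.
Added founder rows inherit the breed label of the offspring that references
them — the usual registry assumption — but carry no birth year, so when a
native base year is in force they are conservatively relabelled "unknown"
(see below).

**Kinship (tabular method).**  Founders are unrelated and non-inbred by
default (self-kinship ½); a founder kinship matrix may be supplied instead.
Self-kinship uses with-replacement sampling of the two alleles, so
f(i, i) = ½(1 + F_i) and offspring inbreeding equals parental kinship
exactly — this identity is asserted over whole pedigrees in the tests.

**Native base population.**  Given the breed of interest and a base year,
founders of that breed born *after* the base year — or with missing birth
year — are relabelled "unknown".  Treating undated founders as post-base
is a deliberate conservative choice: nativity that cannot be verified must
not inflate native contributions.

**Breed composition.**  Founder contributions are aggregated per origin
class (native = founders of the breed of interest, one class per foreign
breed, "unknown" for unknown-origin founders).  A genome half descending
through a missing parent link goes to "unknown", consistent with the
native-kinship recursions, where such alleles are non-native.

**Native kinship components.**  Both matrices are exact pair recursions
with founder base cases: for the both-native probability f_N, a founder
row against any earlier (hence unrelated) individual factorizes as
nat(a)·N(j); for the joint IBD-and-native probability f_IBD&N, founders
are unrelated to everything earlier, so the off-diagonal base case is 0
and the diagonal is ½·nat(a).  Interior rows use the same ½-parent
averaging as the kinship; diagonals use with-replacement sampling, where
the same-allele draw (probability ½) is always IBD and is native with
probability N(i).  Native founders are unrelated and non-inbred by
construction.  The ratio f_IBD&N / f_N is reported only where f_N > 0.

**Pedigree completeness.**  Equivalent complete generations are computed
by the O(n) recursion equiGen(i) = ½[1 + equiGen(s)] + ½[1 + equiGen(d)]
with missing-parent terms 0, which ties out exactly with the definition as
the sum over generations of the proportion of known ancestors.

## Segment quantities

Identity is defined at genotyped markers: a shared segment is a maximal
run of marker-wise identity between two haplotypes, qualified by
`min_snp` ≥ 20 markers (guards against chance identity) and `min_l` ≥
1.0 Mb measured first-to-last marker position (short segments reflect old
ancestry; raise `min_l` to restrict to recent inbreeding, e.g. 2.5 Mb for
dense panels).  Runs never cross chromosome boundaries.  Positions are
accepted in Mb, or in bp with automatic conversion when the maximum
position exceeds 10 000.

Genome mass is carried by *half-interval marker weights* (the interval
between midpoints of adjacent markers; end markers carry their single half
interval), so a chromosome's weights sum to its first-to-last length.
Segment *qualification* uses first-to-last run length, while all
accumulated shared lengths — in f_SEG, in the native masks, and in the
native-kinship numerators — use marker weights.  This single measure makes
the identities exact that would otherwise hold only approximately:
f_SEG&N ≤ f_SEG elementwise, and
f_N(i, i) = ½·N_SEG(i) + ½·(both-haplotype-native length)/G.
Self-kinship again samples with replacement:
f_SEG(i, i) = ½ + (shared length of i's two haplotypes)/(2G).

**Haplotype origin.**  No standard estimator exists for the frequency of
"the segment containing a marker" in a reference breed; this package
defines freq_B(h, m) as the fraction of breed-B haplotypes sharing a
qualifying segment with focal haplotype h that covers marker m.  This
makes the classification threshold `ub_freq` directly interpretable as a
haplotype frequency (default 0.01: a segment clearly present in a
non-endangered breed need not be conserved).  The marker's origin is the
argmax breed if its frequency reaches `ub_freq`, else native; ties go to
the first breed in sorted label order.  Note the resolution limit:
frequencies are multiples of 1/|B|, so `ub_freq` below 1/|B| is equivalent
to "any single carrier".

## Population means and the kinship bound

Class contributions are estimated from parent ages at offspring birth.
For each sex, the weight of the age-a class (a ≥ 1) is the survival sum
S(a) = Σ_{k≥a} p(k) of the parent-age distribution — the fraction of that
class's lifetime reproduction still ahead — and the age-0 class has weight
1.  Weights are normalized within sex; the cohort share r0 is the mean of
the two sexes' age-0 shares, and each sex's non-juvenile classes are
rescaled to total (1 − r0)/2, enforcing equal non-juvenile sex totals.
With no age information (discrete generations) r0 = ½ and each sex's
single class carries ¼.  The generation interval is approximated as
L = 1/(4 c_m1) + 1/(4 c_f1) from the age-1 class contributions; both the
estimator and this formula are this package's reconstruction of standard
practice and are oracle-tested against their own definitions.

Individual weights are v_i = (class contribution)/(class size), rescaled
over the classes actually present so r0 + Σv = 1.  Current means use
ṽ = v/(1 − r0); ratio parameters (native kinships) are always ratios of
weighted quadratic forms, never averages of per-pair ratios.  A phen table
whose newest cohort is its only cohort is treated as a table of already-
born adults (everyone age 1) rather than as juveniles.

The admissible kinship increase is defined on the (1 − f) scale:
ub = f + (1 − f)/(2 Ne L).  On this scale the per-generation guarantee
Δf_g ≤ 1/(2 Ne) composes exactly over years, which plain additive
increments do not.

## Optimization

Predicted means are affine (traits), convex-quadratic (kinships; kinship
matrices are PSD up to rounding), or rational (native kinships) in the
contribution vector.  Rational *constraints* are implemented as the
quadratic difference num(u) − b·den(u) ≤ 0, valid whenever the native
denominator is positive and smooth everywhere.  The rational *objective*
is non-convex in general; the interior-point backend therefore rejects it,
and the recommended paths are multi-start SQP and Dinkelbach fractional
programming, whose parametric subproblems min N(c) − λD(c) drive λ
monotonically to the optimal ratio (convergence tolerance 1e-10 on the
parametric value).

The correction terms l(c) — accounting for, e.g., drift at finite cohort
size — default to zero.  An opt-in surrogate (`correction="self"`) adds
the linear term r0²/(2 N0) Σ c_i F_ii, charging each candidate its
self-kinship in proportion to its use; it is a documented placeholder, not
a derived result.

Validity is never taken from the solver: every returned solution is
rechecked from scratch (constraints at relative tolerance 1e-6, sex sums
1e-8, bounds 1e-8), and infeasible outcomes come with a diagnostic
explaining which constraints the equal-contribution point already
violates.  Uniform-female mode fixes each female age class's total
contribution (proportional to its class contribution, normalized to ½)
split equally among its members, and removes those variables from the
decision vector.  Solutions are deterministic given backend, tuning, and
seed.  The interior-point backend approaches linear-program vertices only
asymptotically (barrier tolerance 1e-12); its solutions can sit ~1e-4
inside the vertex, which the validator tolerates and the tests account
for.

The brute-force backend enumerates per-sex simplex grids (6 divisions,
then 3 local refinements quartering the step) and is intended as a test
oracle for at most five free candidates.

## Mate allocation

The allocation is an exact integer program (HiGHS branch-and-bound) on the
transportation polytope with optional per-mating caps n_ij ≤ ub_n_off and
per-herd sire caps Σ_{j∈h} n_ij ≤ α N_h.  Without caps the constraint
matrix is totally unimodular, so the LP relaxation is already integral.
Ties between equal-cost plans are resolved by a second solve that
maximizes a geometrically decaying bonus on early (sire, dam) pairs
subject to optimal cost — exact lexicographic preference over the first 40
pairs, deterministic beyond.  Offspring counts use largest-remainder
rounding of 2 c_i N0 within each sex, so each sex totals N0 exactly and
every count is within 1 of its target.

## Synthetic data: what it emulates, what it does not

The generator models a small endangered cattle-like breed: 40 native and
12 foreign founders, 30 offspring per year over 6 years, sires used at
ages 1–4 (progeny-tested bulls breed older, which produces the
characteristic flatter male age-contribution profile), dams at ages 1–3,
and a 10% chance per offspring that its sire is a fresh foreign migrant —
planting the historic introgression the native-kinship machinery is built
to detect.  Haplotypes descend from breed-specific allele-frequency
profiles (Beta(2,2) per marker) through Poisson recombination at
0.01 Morgan/Mb on 2 chromosomes × 120 markers at 0.5 Mb spacing (test
fixtures scale these sizes up or down); breeding values follow the
additive model with Mendelian-sampling s.d. √0.5.  True per-marker origins
are recorded through meiosis, giving construction-known truth for the
origin-classification tests, and the tagged gene-dropping oracle estimates
every pedigree probability by simulation with standard errors.

Not emulated: genotyping error and missingness (haplotypes are perfect and
phased), mutation, selection pressure on the simulated EBVs, variable
recombination maps, overlapping herd structure, and reference panels with
realistic haplotype sharing (foreign founders are unrelated, so reference-
breed frequencies are multiples of 1/|B|).  Passing tests therefore
establish the *estimators and optimizers are correct for their
definitions*, not that those definitions are robust to phasing error or
unrepresentative reference panels; on real data the usual caveats apply —
incomplete pedigrees bias pedigree estimates downward, and thin reference
panels bias segment-based foreign contributions downward.

## Problem sizes used by the checks

The acceptance script simulates ~220 individuals with 300 markers, runs
the full pipeline, re-measures backend correctness on eight 4-candidate
instances against brute force (1% criterion), and checks 30 gene-dropping
pairs at 100 000 replicates against the exact recursions (3 SE).  The test
suite uses a 200+-individual pedigree at 200 000 replicates for the same
check, 10-individual fixtures for the naive per-pair segment oracles, and
5×8 instances for exhaustive mate-allocation enumeration.  These sizes
were chosen so each oracle has clear statistical power while the whole
suite remains quick to run.

## Known limitations

* The exact drift/finite-size correction terms l(c) are not implemented;
  predictions are exact in expectation only as cohort size grows.
* Lower bounds on kinship-type parameters are not supported (they would be
  non-convex); lower bounds are available for linear parameters such as
  native contribution and traits.
* The brute-force oracle's grid refinement can miss optima in pathological
  feasible regions; it is a test oracle, not a production solver.
* `haplotype_origin` scans all focal × reference haplotype pairs; for
  panels far beyond ~10⁴ markers × hundreds of haplotypes a compiled scan
  would be preferable.
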