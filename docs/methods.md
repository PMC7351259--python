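# Methods

## Problem and encoding

The package searches a case-control genotype matrix for order-*m* SNP
barcodes: *m* distinct SNP indices, each with one fixed genotype code in
{1, 2, 3}. A chromosome in the evolutionary search *is* a barcode; every
operator treats the (SNP index, genotype) pair at slot *j* as a unit
("paired slots"), so a chromosome has m slots / 2m elements. Fitness is
`F = controls carrying − cases carrying`, an integer in
[−max(n_cases, n_controls), +max(...)]; it deliberately searches in the
protective direction (OR < 1). Risk-direction search is the same problem
with labels swapped (`F` is antisymmetric under label exchange), so no
separate mode is provided.

## Cohort simulation

The bundled panel is a 26-SNP growth-factor-pathway table with
per-genotype case/control counts, 5000 per group, transcribed verbatim
from the published distribution. The generator does **not** draw i.i.d.
multinomial samples: for each SNP and each group it lays out the exact
multiset of genotype codes implied by the counts and assigns it to samples
by a seeded permutation. Consequences:

- per-SNP, per-group marginal counts are *exact*, so every single-SNP
  statistic recomputed from a generated cohort equals the one computed
  from the table;
- SNP columns are mutually independent by construction (one child RNG
  stream per (master seed, SNP index, group), so columns and groups are
  reproducible independently);
- the cohort has **no linkage disequilibrium, no Hardy-Weinberg structure
  and no planted interaction** — only marginal frequency differences.
  Passing searches therefore demonstrate that the optimizer finds the
  combinatorial optimum of this fitness on realistic marginals, not that
  it detects epistasis in LD-structured real data.

Rescaling counts to a different group size uses largest-remainder
(Hamilton) rounding with ties to the lower genotype index: each scaled
count is within one unit of its exact proportional value and the total is
preserved. (The source's own single worked rescaling example is internally
inconsistent at ±1; the packaged table uses the printed final counts
verbatim, so the rounding rule never touches the study-size cohort.)

## Taguchi refinement

The orthogonal array L_n(2^(n−1)), n = 2^k, is built by the parity
construction: run *i*, column *j* has level 1 + popcount(i AND rev_k(j))
mod 2, where rev_k is bit reversal of the column number — this ordering
reproduces the canonical L4/L8/… layouts. Columns are pairwise balanced
(strength 2).

One combine takes two same-order parents, assigns factor j = slot j
(level 1 = parent 1's slot, level 2 = parent 2's), uses the smallest array
with at least m columns, evaluates each run's composed candidate (after
duplicate repair, below), converts fitness to the sign-preserving square
η = ±y², sums factor effects per level, and returns the level-wise argmax
composition, itself evaluated — exactly n_runs + 1 evaluations.

Numerical boundary of the refinement, documented because tests rely on
it: for fitness additive over slots the composed child equals the
brute-force argmax over all 2^m parent-slot selections *exactly* when
m = 2 (the single other factor is balanced within each level) and, in
extensive random checks, always for 0/1 hidden-target counting
contributions; for m ≥ 3 with general-valued additive contributions the
squared SNR is a nonlinear response on a strength-2 design and the
prediction can occasionally miss the argmax (order-percent frequency).
This is a property of the published η rule, not an implementation
artifact; η = y (linear) would be exact but is not what the method
specifies. Factor-granularity alternative Q = 2m (SNP and genotype
elements as separate factors) was evaluated and performs clearly worse as
a search operator; Q = m paired slots is used.

## Search loop

Both GA and HTGA: initialize M random barcodes; each iteration fills a
mating pool of size M by binary tournament (ties to the first drawn),
crosses each sequential pair with probability p_c — uniform crossover
swapping whole slots — and passes the pair through unchanged otherwise, so
the offspring pool always holds M members; HTGA then performs
round(0.5 · M · p_c) Taguchi combines on pairs drawn without replacement
from the offspring pool (falling back to the mating pool while the
offspring pool has fewer than two members — only possible in degenerate
configurations), appending each refined child; every pool member is then
mutated element-wise (SNP elements redraw from the SNPs unused in that
barcode; genotype elements redraw uniformly from {1, 2, 3}); finally the
top M **distinct** chromosomes of parents ∪ offspring survive
(fitness-descending, ties by the deterministic barcode order; duplicates
pad only if fewer than M distinct exist).

Duplicate-free replacement is the one deliberately non-obvious choice.
With duplicates allowed, elitism fills the population with copies of the
incumbent within tens of iterations; a strong local optimum sharing no
slot with the global one (which this fitness landscape does produce) then
becomes effectively inescapable at p_m = 0.05, and the search stalls in a
large fraction of runs. Keeping only distinct chromosomes preserves
mid-rank barcodes that share slots with the optimum as building blocks
for crossover and Taguchi mixing; on the study-sized cohort this turns
order-2 convergence from ~half of runs into essentially all runs at the
same evaluation budget. It is the standard diversity device in this
algorithm family.

All stochastic steps consume a single master generator seeded from the
run configuration, in the fixed order above, so a (seed, config, cohort)
triple reproduces a run bit for bit. Termination is the fixed iteration
count only; the per-iteration best is recorded and is non-decreasing by
elitism.

Defaults follow the study settings: M = 50, T = 1000 iterations,
p_c = 0.3, p_m = 0.05.

## Swarm baselines

The published comparison named PSO and chaotic PSO but described no
discrete encoding, so the baselines here are this package's own
construction and their results characterize *a* reasonable PSO on this
problem, not any specific prior implementation. Each particle holds a
continuous vector of length 2m (m SNP coordinates in [1, n_snps], m
genotype coordinates in [1, 3]); decoding rounds, clamps and repairs
duplicate SNPs before every evaluation. Global-best topology; velocities
clamped to half the coordinate range; inertia decreases linearly from
w_max = 0.9 to w_min = 0.4 (plain) or is modulated by a logistic map
z ← 4z(1 − z) started away from its fixed points {0, ¼, ½, ¾, 1}
(chaotic); c₁ = c₂ = 2.

## Degenerate inputs and tie-breaks

- Duplicate-SNP repair (crossover, Taguchi composition, swarm decoding):
  scan slots left to right, replace a repeated SNP index by a uniform draw
  from the indices unused in the whole barcode, keep the genotype.
- Factor-effect ties choose level 1 (parent 1). Equal-fitness barcodes
  order by (sorted SNP indices, genotype codes).
- Mutation of a full-order barcode (m = n_snps) keeps SNP slots (no unused
  index exists) and still redraws genotypes.
- A zero cell makes OR/CI undefined and a zero margin makes the p-value
  undefined; both are reported as N/A, never continuity-corrected, to
  match how reference rows are conventionally displayed.

## Statistics

OR = (TP·TN)/(FP·FN) computed in exact rational arithmetic before
floating; 95% CI by the Woolf log-odds method; p by Pearson chi-square
with 1 df and no continuity correction. The CI and p-value methods are
inferences — the study names neither — adopted because they reproduce the
published intervals (2 dp) and p-values (3 dp) from the published counts;
the test suite pins this. Single-SNP associations use genotype 1
(homozygous major) as the reference row. No multiple-testing correction
is applied across barcode orders, matching the original analysis.

## Problem sizes in the test suite

Most tests run on a 200-per-group cohort; search-quality checks
(exhaustive-oracle equivalence at order 2, HTGA-vs-GA comparison at
order 5) use the full 5000-per-group cohort with the study parameters and
10 seeded runs per condition, and the acceptance script uses 10 runs at
order 2 on a freshly seeded study-size cohort. The published barcode
*statistics* are reproduced from the printed match counts; the published
barcodes themselves depend on the authors' unrecorded simulation draw and
are not a reproduction target — the exhaustive oracle on our own seeded
cohort defines ground truth for search quality.

## Known limitations

- No LD, haplotype structure or genotype-calling error in the simulator.
- The swarm baselines' discrete encoding is ours; published baseline
  rankings should not be read as replicated.
- The Taguchi prediction is exact only under the conditions stated above;
  in the full loop it is a heuristic refinement, which is its intended
  role.
- Exhaustive validation is feasible only for m ≤ 3 on 26 SNPs (the
  candidate-budget guard refuses larger enumerations by default).
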