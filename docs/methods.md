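# Methods

`jumpcross` implements three probabilistic models of chromosomal
crossover, Monte-Carlo meiosis under each, and a small linkage-mapping
toolkit operating on phase-known family tables.  This note records the
models, the conventions and parameter choices, and the design decisions
taken where the design was genuinely open.

## Models

### Mendelian cross enumeration

Crosses are enumerated exactly under the two classical laws: each
parent contributes one of its two alleles with probability 1/2
(segregation), independently across genes (independent assortment).
All probabilities are `fractions.Fraction` values, so ratio statements
(3:1, 1:1, 1:0, 9:3:3:1) are identities, not tolerance comparisons.
Phenotypes follow complete dominance only — a genotype is dominant at a
gene iff it carries at least one copy of the declared dominant allele.
Codominance, epistasis, sex linkage and mutation are out of scope.
Genotypes are compared as unordered allele pairs here; phase matters
only in the crossover modules.

### Uniform 1-crossover model

A chromosome carries `n` genes; a single crossover site `X` is uniform
on `{0, 1, ..., n-1}`, where `X = 0` means no crossover and `X = s`
(`s >= 1`) separates gene `s` from gene `s+1`.  The recombination
probability of genes `i < j` is exactly `(j - i)/n`.  The start
chromosome of the recombination process is chromosome I with
probability `q` (default 1/2).

Two indexing conventions would both give `r = d/n` (the "no crossover"
outcome can be coded as site 0 or as site n).  The package fixes the
site-0 convention above and enforces it with brute-force enumeration
oracles in the test suite; the choice is an artifact convention, not a
claim about any particular presentation of the model.

The model's instructive deficiencies are exposed as functions rather
than prose: `u1_inherit_prob` shows that segregation holds exactly only
at `q = 1/2` (any bias propagates undamped into early genes), and
`u1_independence_gap` computes `|P(A_i ∩ A_j) − P(A_i)P(A_j)|` by exact
enumeration, which vanishes only for pairs at distance `n/2`.

### Uniform 2-crossover model

The first crossover `X1` is uniform on sites `{1..n}` with site `n`
meaning "no crossover"; the second, given `X1`, is uniform on
`{X1..n}` — deliberately dependent, since the second crossover cannot
precede the first.  `X2 = X1` is allowed and counts as a cancelled
double crossover; the test suite verifies that forbidding it (strictly
later second crossover) changes the recombination probability by at
most O(1/n).  Genes 1 and `1+d` recombine iff exactly one crossover
lands in `{1..d}`:

    r_n(d) = Σ_{s=1}^{d} (1/n) (n − d)/(n − s + 1),

computed in exact rationals.  For large `n` with `x = d/n` fixed,
`r_n(d) → (1 − x) ln(1/(1 − x))`, a non-monotone function maximised at
`x* = 1 − 1/e ≈ 0.632` with value `1/e`.  `u2_argmax` finds this
numerically (bounded scalar minimisation, `xatol = 1e-10`); the
stationarity identity `ln(1 − x*) + 1 = 0` is asserted in tests.  The
model is anchored at gene 1, as in the counterexample it exists to
express; a general-pair version and `k > 2` crossovers are non-goals.

### Jumping model (two-state Markov chain)

States are the two chromosomes of the pair; one time step corresponds
to one inter-gene interval; a transition (crossover) occurs with
probability `p ∈ (0, 1)` per step.  With `λ = 1 − 2p`, two genes `d`
steps apart recombine (odd number of transitions) with probability

    r(d) = (1 − λ^d)/2.

Three independent routes to this quantity are kept in the package and
cross-checked to 1e-12: the closed form, the parity recurrence
`O_k = (1 − p) O_{k−1} + p (1 − O_{k−1})`, and the off-diagonal of the
iterated matrix power of `[[1−p, p], [p, 1−p]]`.  The closed form is
used everywhere else; matrix powers are computed by plain iterated
multiplication precisely so they remain an independent oracle (an
eigen-decomposition route would share the `λ` algebra with the closed
form).

`p < 1/2` gives the linkage regime (r strictly increasing, bounded by
1/2, asymptotic independence in distance); `p > 1/2` the hotspot
regime, where r alternates: above 1/2 at odd distances and exactly the
mirrored value `r_{1−p}(d)` at even distances.  `p = 0` and `p = 1` are
rejected as degenerate chains (the source never switches, or switches
deterministically; their boundary behaviour is `r ≡ 0` and a 0/1
alternation).

Distance counts inter-gene steps: gene `i` to gene `j` is `d = j − i`.
In the limit `p → 0` with `m = p d` fixed, `r → (1 − e^{−2m})/2` —
Haldane's map function, with `m` the expected number of crossovers
between the loci (Morgan's distance).  The inverse map
`m = −ln(1 − 2r)/2` is defined for `r < 1/2` only; estimates at or
above 1/2 must go through mode diagnosis instead.

## Simulation

`simulate_sources` draws the per-gene source chromosome vector for all
three models, vectorised over meioses; `sample_gamete` wraps a single
draw into a `GameteRecord` (alleles, sources, net crossover sites).
Only odd-parity source switches are observable at gene resolution, so
recorded sites are net switch points; a cancelled double crossover
within one interval leaves no site.

For markers at integer coordinates the jumping model is advanced one
interval at a time with switch probability `(1 − λ^t)/2` for a gap of
`t` steps — the exact parity distribution of `t` unit Bernoulli(p)
steps, equivalent in distribution to simulating every unit step but
independent of the gap sizes in cost.

Determinism: every stochastic entry point takes either a
`numpy.random.Generator` or a seed; replicate streams are derived with
`numpy.random.SeedSequence.spawn`, so fixed seeds reproduce outputs
bit for bit.

### Blending vs Mendelian population simulation

Both arms hold the population size fixed with non-overlapping
generations; each offspring draws two distinct parents uniformly at
random (the simplest scheme preserving constant size — the mating
scheme is an artifact choice).  The blending arm starts from half
trait-0, half trait-1 individuals and averages parental traits exactly
(rationals of the form `k/2^t`); the Mendelian arm mirrors it with half
0/0 and half 1/1 homozygotes at a single biallelic gene, each offspring
receiving one uniformly chosen allele per parent.

Counting "types" needs care.  Discrete genotypes are compared exactly.
For the continuous blending trait, exact-value equality is the wrong
notion: almost every average of a distinct parent pair is a fresh
rational, so under exact equality the blending arm *gains* distinct
values even as its variance decays to nothing, and the classical
convergence claim would be invisible.  What collapses is
*distinguishability*: the population's trait spread shrinks roughly
geometrically, and beyond some generation no measurement could tell two
individuals apart.  `count_types` therefore counts values
distinguishable at a declared phenotype resolution (default `1e-9`,
far below any initial trait spacing of the simulation; single-linkage
chaining on the sorted values).  Trait arithmetic itself stays exact,
so the count is reproducible and platform-independent, and
`resolution=0` recovers exact-value counting for callers who want it.
With the default resolution the blending arm collapses to a single type
around generation 60–70 at population 100, while the Mendelian arm
retains between 2 and 3 genotypes after 100 generations, eroded only by
drift.

## Linkage mapping

Source assignment is possible exactly where the transmitting parent is
heterozygous; homozygous-parent meioses are excluded from the
denominator (the source is unidentifiable — standard practice).
Paternal and maternal meioses are pooled for the headline `r̂` per gene
pair (per-parent counts are available for diagnostics).  An offspring
allele absent from the parent raises a named non-Mendelian error; the
TSV parser deliberately does not perform this check (separation of
parsing from genetics).

Ordering converts each `r̂ < 1/2` to a Morgan distance and scores every
permutation (up to reversal) by the additivity residual — the summed
absolute difference between each non-adjacent pair's direct distance
and the sum of adjacent distances along the path.  Exhaustive search is
exact and affordable at the intended scale; the default bound is 8
genes.  `r̂ = 1/2` exactly is treated as unlinked: such pairs carry no
ordering information and are flagged as undetermined rather than mapped
(their Morgan distance is infinite).

When some `r̂ > 1/2`, `diagnose_mode` produces both competing readings:

* **relabelling** — the recorded phase of some genes is wrong.  The
  search flips genes in both parents simultaneously (the modelled error
  is wrong prior knowledge of which allele is which — a property of the
  gene's labelling, not of one parent), which maps each pooled estimate
  involving a flipped gene to `1 − r̂`.  All `2^g` flip subsets are
  scored; the smallest set removing every estimate above 1/2 wins, the
  table is re-estimated after the flip (an independent re-count, also
  verifying the flip's involution), and ordering proceeds normally.
* **hotspot** — the estimates are taken at face value (three genes).
  The middle gene is the one whose two adjacent estimates compose to
  the outer estimate under `r1 + r2 − 2 r1 r2`; consistency is judged
  at 3 binomial standard errors (first-order error propagation through
  the composition).  The observed double-crossover fraction is reported
  against the no-interference product `r̂1 r̂2`.

Pairwise data alone cannot separate the two readings — on clean hotspot
data the relabelled table is also internally consistent, and vice
versa.  The verdict is therefore `undetermined` whenever both branches
pass, and the CLI's `--assume-hotspot` / `--assume-relabel` flags let
the user supply the missing outside knowledge.  Consistency tolerances
are 3 binomial standard errors throughout: sampling noise is the only
noise source in scope.

## Synthetic data

`generate_family` is the package's data source: two phase-known parents
(default fully heterozygous `0|1`, the fully informative
configuration) and `N` offspring, each receiving one paternal and one
maternal gamete drawn independently under the jumping model at the
declared positions, `p`, and `q`.  It emulates the structure of a
phase-known nuclear-family genotyping table.  It does **not** emulate
genotyping error, missing data, phase-unknown parents, crossover
interference, or sex-specific recombination rates — passing tests
demonstrate correct inference under the model's own assumptions, not
robustness to real-data artifacts.  Default study conditions used in
tests: `p = 0.05` with 1000–2000 offspring for order recovery and
parameter recovery, `p = 0.9` for hotspot fixtures, `p = 0.1` for
relabelling and double-crossover fixtures, Monte-Carlo grids at
5×10^4 meioses with agreement judged at 3 binomial standard errors.

## Numerical choices

* Exact rational arithmetic for all finite-`n` model quantities and
  Mendelian distributions; floats only in limit forms, Markov closed
  forms and estimates.
* Algebraic identities are asserted at 1e-12; limit-based statements at
  1e-6 (or the explicitly derived bound).
* `r(d)` in floating point saturates at exactly 1/2 once `λ^d`
  underflows below the rounding threshold; monotonicity is strict only
  up to that point.
* The family TSV parser is hand-written to report line-numbered errors
  for the bespoke dialect; all array work, optimisation and random
  generation go through numpy/scipy.
* Ties in the order search are broken lexicographically; ties in the
  flip search by fewer flips, then lexicographically.

## Problem sizes

The test suite and examples run at deliberately modest scale — up to
5×10^4 meioses per Monte-Carlo grid point, families of up to 10^4
offspring, a population of 100 over 100 generations with 100 replicates
— chosen as the smallest sizes at which the binomial tolerances are
informative.  The full suite completes in well under a minute.

## Known limitations

* Two-state chain only: no chromatid-level (four-strand) accounting, no
  interference beyond the Markov assumption, no position-dependent `p`.
* Complete dominance only in the phenotype map.
* Phase-known parents are required; phase-unknown pedigrees, LOD-score
  and multipoint likelihood methods are out of scope.
* Ordering is exhaustive and limited to small gene counts by design.
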