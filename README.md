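# jumpcross

Probabilistic models of chromosomal crossover and recombination, with a
linkage-mapping toolkit — a library for teaching and exploring the
mathematics behind Mendel's laws, genetic linkage, recombination
hotspots, and genetic map construction.

During meiosis the chromosome serving as the allele source switches at
essentially arbitrary positions (crossovers); two genes *recombine*
when their transmitted alleles derive from different chromosomes of the
pair, which happens iff an odd number of crossovers falls between them.
The recombination fraction `r` of a gene pair is therefore a distance
proxy, and counting recombinant offspring is how the first genetic maps
were built.  `jumpcross` implements this story end to end:

* **Mendelian crosses** (`jumpcross.mendel`) — exact enumeration under
  segregation and independent assortment, with complete-dominance
  phenotypes; the 3:1 and 9:3:3:1 ratios come out as exact rationals.
* **Uniform 1-crossover model** (`jumpcross.uniform`) — one uniform
  crossover site gives `r = d/n`, plus computable demonstrations of the
  model's flaws: segregation holds only for an unbiased start
  (`q = 1/2`), independent assortment fails on a chromosome, and the
  natural 2-crossover extension has the non-monotone large-n law
  `r(x) = (1 − x) ln 1/(1 − x)`, maximal at `x = 1 − 1/e` (≈63% of the
  chromosome length).
* **The jumping model** (`jumpcross.markov`) — crossover as a two-state
  Markov chain with per-step probability `p`.  With `λ = 1 − 2p`,

      r(d) = (1 − λ^d) / 2,

  which is monotone and bounded by 1/2 for `p < 1/2` (linkage, with
  asymptotic independent assortment) and alternates around 1/2 for
  `p > 1/2` (hotspots).  As `p → 0` with `m = p·d` fixed it converges
  to Haldane's map function `r = (1 − e^{−2m})/2`, where `m` is
  Morgan's distance (expected crossover count).
* **Meiosis and population simulation** (`jumpcross.simulate`) —
  seeded, vectorised gamete sampling under all three models, and the
  blending-vs-Mendelian population simulation showing why discrete
  alleles preserve variation while trait averaging erases it.
* **Families and mapping** (`jumpcross.families`,
  `jumpcross.mapping`) — a minimal phase-known family TSV dialect, a
  synthetic-family generator, recombination-fraction estimation from
  offspring gametes, gene ordering by Morgan-distance additivity, and
  the diagnosis of estimates above 1/2 as either a phase-labelling
  error or a hotspot.

## Worked example

Mapping a synthetic three-gene family (from
`examples/linkage_mapping_example.py`):

```text
--- normal linkage (p = 0.05 per step, genes at 0, 1, 2) ---
  r(AB) = 0.045 (179/4000 informative meioses)
  r(AC) = 0.092 (367/4000 informative meioses)
  r(BC) = 0.052 (208/4000 informative meioses)
  inferred order: A-B-C (or its reversal)
  adjacent Morgan distances: [0.0469, 0.0549]
```

The two adjacent estimates sit near the simulated per-step crossover
probability 0.05, the outer pair near the parity composition
`0.045 + 0.052 − 2·0.045·0.052 ≈ 0.092`, and the additivity of Morgan
distances picks B as the middle gene.  With a hotspot-strength
`p = 0.9` the adjacent estimates jump to ≈0.9 while the outer pair
drops to ≈0.18 — the same family is then explained either by flipping
one gene's phase labels or by double crossovers (observed 0.809 vs
expected `r1·r2 = 0.808`), and `diagnose_mode` reports both readings.

From Python:

```python
from jumpcross import TwoStateChain, recomb_prob, morgan_m_from_r

chain = TwoStateChain(p=0.1)
recomb_prob(chain, 3)        # 0.244  = (1 - 0.8^3)/2
morgan_m_from_r(0.244)       # 0.3385 Morgans between the two loci
```

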