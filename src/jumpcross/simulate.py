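"""Monte-Carlo meiosis under the three crossover models, plus the
blending-vs-Mendelian population simulation.

A gamete is produced by walking along the chromosome and tracking which
chromosome of the parental pair is the current allele source.  The three
models differ only in how source switches (crossovers) are placed:

* ``uniform1`` — one site uniform on ``{0, ..., n-1}`` (0 = none);
* ``uniform2`` — ``X1`` uniform on ``{1..n}`` (site ``n`` = none) and
  ``X2 | X1`` uniform on ``{X1..n}``; ``X2 = X1`` cancels;
* ``jumping`` — an independent switch with probability ``p`` at every
  inter-gene step (the two-state Markov chain).

The population simulation contrasts blending inheritance (offspring
trait = average of two parents' traits, kept as exact rationals) with
Mendelian inheritance of a discrete allele pair, reproducing the
classical argument that blending would erase variation within a few tens
of generations while discrete alleles preserve it.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence, Union

import numpy as np

from .markov import TwoStateChain, recomb_prob
from .uniform import Uniform1Params, Uniform2Params

__all__ = [
    "PhasedGenotype",
    "GameteRecord",
    "PairwiseREstimate",
    "PopulationState",
    "CrossoverParams",
    "simulate_sources",
    "sample_gamete",
    "simulate_gametes",
    "empirical_r",
    "simulate_population",
    "count_types",
    "TRAIT_RESOLUTION",
    "BLENDING",
    "MENDELIAN",
    "CHROM_I",
    "CHROM_II",
]

CHROM_I = "I"
CHROM_II = "II"
BLENDING = "blending"
MENDELIAN = "mendelian"

#: Two trait values closer than this are counted as the same phenotype
#: "type" in the blending arm.  Trait arithmetic itself is exact; the
#: resolution only enters the distinct-type count, which is otherwise
#: ill-defined for a continuously divisible trait (see docs/methods.md).
TRAIT_RESOLUTION = Fraction(1, 10**9)

CrossoverParams = Union[Uniform1Params, Uniform2Params, TwoStateChain]


@dataclass(frozen=True)
class PhasedGenotype:
    """Phase-known diploid genotype: an ordered allele pair per gene.

    ``alleles[k] = (allele on chromosome I, allele on chromosome II)``.
    """

    alleles: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise ValueError("a genotype needs at least one gene")
        if any(len(pair) != 2 for pair in self.alleles):
            raise ValueError("each gene carries exactly two phased alleles")

    @property
    def n_genes(self) -> int:
        return len(self.alleles)

    def flip_gene(self, k: int) -> "PhasedGenotype":
        """Swap the chromosome assignment of gene ``k`` (0-based)."""
        pairs = list(self.alleles)
        a, b = pairs[k]
        pairs[k] = (b, a)
        return PhasedGenotype(tuple(pairs))


@dataclass(frozen=True)
class GameteRecord:
    """One meiotic product.

    ``sources[k]`` is the parental chromosome (``"I"``/``"II"``) that
    contributed gene ``k``'s allele; ``crossover_sites`` lists the
    1-based inter-gene sites at which the source switches (site ``s``
    lies between genes ``s`` and ``s+1``).  Only net (odd-parity)
    switches are observable at the gene resolution, so a cancelled
    double crossover within one interval leaves no site.
    """

    alleles: tuple[str, ...]
    sources: tuple[str, ...]
    crossover_sites: tuple[int, ...]

    def __post_init__(self) -> None:
        expected = tuple(
            s + 1
            for s in range(len(self.sources) - 1)
            if self.sources[s] != self.sources[s + 1]
        )
        if expected != tuple(self.crossover_sites):
            raise ValueError(
                f"crossover sites {self.crossover_sites} inconsistent with "
                f"source vector {self.sources}"
            )


@dataclass(frozen=True)
class PairwiseREstimate:
    """Estimated recombination fraction for one gene pair.

    ``r_hat`` is ``recombinant / informative``, or ``None`` when there
    are no informative meioses (e.g. a parent homozygous at one gene).
    """

    pair: tuple
    informative: int
    recombinant: int

    def __post_init__(self) -> None:
        if not 0 <= self.recombinant <= self.informative:
            raise ValueError(
                f"recombinant count {self.recombinant} outside "
                f"0..{self.informative}"
            )

    @property
    def r_hat(self) -> float | None:
        if self.informative == 0:
            return None
        return self.recombinant / self.informative

    def standard_error(self) -> float | None:
        """Binomial standard error of ``r_hat``."""
        r = self.r_hat
        if r is None:
            return None
        return (r * (1.0 - r) / self.informative) ** 0.5


def _resolve_q(params: CrossoverParams, q: float | None) -> float:
    if q is not None:
        return q
    return float(getattr(params, "q", 0.5))


def simulate_sources(
    params: CrossoverParams,
    n_genes: int,
    n_meioses: int,
    rng: np.random.Generator,
    *,
    steps: Sequence[int] | None = None,
    q: float | None = None,
) -> np.ndarray:
    """Vectorised source-chromosome simulation.

    Returns an ``(n_meioses, n_genes)`` uint8 array with 0 for
    chromosome I and 1 for chromosome II.  ``steps`` (jumping model
    only) gives the number of unit Markov steps per inter-gene interval,
    so markers at integer coordinates can be simulated directly; the
    switch probability across an interval of ``t`` steps is the parity
    value ``(1 - (1-2p)^t) / 2``.
    """
    if n_genes < 2:
        raise ValueError(f"need at least 2 genes, got {n_genes}")
    if n_meioses < 1:
        raise ValueError(f"need at least 1 meiosis, got {n_meioses}")
    start = (rng.random(n_meioses) >= _resolve_q(params, q)).astype(np.uint8)

    if isinstance(params, TwoStateChain):
        if steps is None:
            steps = [1] * (n_genes - 1)
        if len(steps) != n_genes - 1:
            raise ValueError(
                f"expected {n_genes - 1} interval step counts, got {len(steps)}"
            )
        if any(t < 1 for t in steps):
            raise ValueError("interval step counts must be >= 1")
        flip_p = np.array([recomb_prob(params, int(t)) for t in steps])
        flips = (rng.random((n_meioses, n_genes - 1)) < flip_p).astype(np.int64)
        cum = np.zeros((n_meioses, n_genes), dtype=np.uint8)
        cum[:, 1:] = (np.cumsum(flips, axis=1) % 2).astype(np.uint8)
        return start[:, None] ^ cum

    if steps is not None:
        raise ValueError("interval step counts apply to the jumping model only")

    gene_idx = np.arange(1, n_genes + 1)
    if isinstance(params, Uniform1Params):
        if params.n != n_genes:
            raise ValueError(
                f"params declare n={params.n} genes but {n_genes} requested"
            )
        x = rng.integers(0, n_genes, n_meioses)
        # gene k is past the crossover iff 1 <= X <= k-1
        crossed = (x[:, None] >= 1) & (x[:, None] <= gene_idx[None, :] - 1)
        return start[:, None] ^ crossed.astype(np.uint8)

    if isinstance(params, Uniform2Params):
        n = params.n
        if n != n_genes:
            raise ValueError(f"params declare n={n} genes but {n_genes} requested")
        x1 = rng.integers(1, n + 1, n_meioses)
        # X2 | X1 uniform on {X1, ..., n}; site n means "no crossover"
        x2 = x1 + np.floor(rng.random(n_meioses) * (n - x1 + 1)).astype(np.int64)
        c1 = x1[:, None] <= gene_idx[None, :] - 1
        c2 = x2[:, None] <= gene_idx[None, :] - 1
        return start[:, None] ^ (c1 ^ c2).astype(np.uint8)

    raise TypeError(f"unsupported crossover model parameters: {params!r}")


def _record_from_sources(parent: PhasedGenotype, src_row: np.ndarray) -> GameteRecord:
    sources = tuple(CHROM_I if s == 0 else CHROM_II for s in src_row)
    alleles = tuple(
        pair[int(s)] for pair, s in zip(parent.alleles, src_row)
    )
    sites = tuple(
        k + 1
        for k in range(len(src_row) - 1)
        if src_row[k] != src_row[k + 1]
    )
    return GameteRecord(alleles, sources, sites)


def sample_gamete(
    parent: PhasedGenotype,
    params: CrossoverParams,
    rng: np.random.Generator,
    *,
    steps: Sequence[int] | None = None,
    q: float | None = None,
) -> GameteRecord:
    """Draw a single gamete from a phase-known parent."""
    src = simulate_sources(params, parent.n_genes, 1, rng, steps=steps, q=q)
    return _record_from_sources(parent, src[0])


def simulate_gametes(
    parent: PhasedGenotype,
    params: CrossoverParams,
    n_meioses: int,
    rng: np.random.Generator,
    *,
    steps: Sequence[int] | None = None,
    q: float | None = None,
) -> list[GameteRecord]:
    """Draw ``n_meioses`` gametes as full :class:`GameteRecord` objects."""
    src = simulate_sources(params, parent.n_genes, n_meioses, rng, steps=steps, q=q)
    return [_record_from_sources(parent, row) for row in src]


def empirical_r(
    gametes: Sequence[GameteRecord] | np.ndarray, i: int, j: int
) -> PairwiseREstimate:
    """Empirical recombination fraction between genes ``i < j`` (1-based).

    Accepts either a list of :class:`GameteRecord` or a raw source
    matrix from :func:`simulate_sources`.  All simulated meioses are
    informative (sources are known by construction).
    """
    if isinstance(gametes, np.ndarray):
        if gametes.size == 0:
            raise ValueError("no gametes supplied")
        n_genes = gametes.shape[1]
        if not 1 <= i < j <= n_genes:
            raise ValueError(f"need 1 <= i < j <= {n_genes}, got ({i}, {j})")
        rec = int(np.count_nonzero(gametes[:, i - 1] != gametes[:, j - 1]))
        total = gametes.shape[0]
    else:
        if len(gametes) == 0:
            raise ValueError("no gametes supplied")
        n_genes = len(gametes[0].sources)
        if not 1 <= i < j <= n_genes:
            raise ValueError(f"need 1 <= i < j <= {n_genes}, got ({i}, {j})")
        rec = sum(1 for g in gametes if g.sources[i - 1] != g.sources[j - 1])
        total = len(gametes)
    return PairwiseREstimate((i, j), total, rec)


# ---------------------------------------------------------------------------
# Blending vs Mendelian population simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationState:
    """Snapshot of a simulated population.

    ``individuals`` holds exact-rational trait values in [0, 1]
    (blending mode) or unordered single-gene genotypes encoded as the
    allele-1 dose 0/1/2 (Mendelian mode).
    """

    mode: str
    individuals: tuple

    def __post_init__(self) -> None:
        if self.mode not in (BLENDING, MENDELIAN):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.individuals) == 0:
            raise ValueError("population is empty")
        if self.mode == BLENDING and any(
            not 0 <= t <= 1 for t in self.individuals
        ):
            raise ValueError("blending traits must lie in [0, 1]")


def count_types(
    pop: PopulationState | Sequence,
    *,
    resolution: Fraction | float | None = None,
) -> int:
    """Number of distinct individual types in a population.

    Discrete genotypes are compared exactly.  Continuous (blending)
    traits are compared at a finite resolution: sorted values whose
    consecutive gaps are at most ``resolution`` chain into one type
    (default :data:`TRAIT_RESOLUTION`).  Pass ``resolution=0`` to force
    exact-value counting.
    """
    if isinstance(pop, PopulationState):
        values = pop.individuals
        if pop.mode == MENDELIAN:
            return len(set(values))
        if resolution is None:
            resolution = TRAIT_RESOLUTION
    else:
        values = tuple(pop)
        if len(values) == 0:
            raise ValueError("population is empty")
    if resolution is None or all(not isinstance(v, (int, float, Fraction)) for v in values):
        return len(set(values))
    res = Fraction(resolution)
    if res == 0:
        return len(set(values))
    ordered = sorted(Fraction(v) for v in values)
    groups = 1
    for prev, cur in zip(ordered, ordered[1:]):
        if cur - prev > res:
            groups += 1
    return groups


def _pick_parent_pairs(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two distinct uniformly random parents for each of ``n`` offspring."""
    first = rng.integers(0, n, n)
    second = rng.integers(0, n - 1, n)
    second = second + (second >= first)
    return first, second


def blending_generation(
    traits: Sequence[Fraction], rng: np.random.Generator
) -> list[Fraction]:
    """One non-overlapping generation of blending inheritance."""
    n = len(traits)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    first, second = _pick_parent_pairs(n, rng)
    half = Fraction(1, 2)
    return [(traits[a] + traits[b]) * half for a, b in zip(first, second)]


def mendelian_generation(
    genotypes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One generation of single-gene Mendelian inheritance.

    Genotypes are allele-1 doses (0, 1, 2); each offspring receives one
    uniformly chosen allele from each of two distinct parents.
    """
    n = len(genotypes)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    first, second = _pick_parent_pairs(n, rng)

    def draw(g: np.ndarray) -> np.ndarray:
        coin = rng.integers(0, 2, len(g))
        return np.where(g == 1, coin, g // 2)

    return draw(genotypes[first]) + draw(genotypes[second])


def simulate_population(
    mode: str,
    pop_size: int,
    steps: int,
    reps: int,
    seed: int,
    *,
    resolution: Fraction | float | None = None,
) -> np.ndarray:
    """Mean distinct-type count per generation, averaged over ``reps``.

    Both arms start from a half/half split: traits {0, 1} for blending,
    homozygotes {0/0, 1/1} for the Mendelian single-gene arm.  Each
    generation replaces the population with ``pop_size`` offspring, each
    from two distinct uniformly drawn parents.  Returns an array of
    length ``steps + 1`` (index 0 = initial population).
    """
    if mode not in (BLENDING, MENDELIAN):
        raise ValueError(f"unknown mode {mode!r}")
    if pop_size < 2:
        raise ValueError(f"population size must be >= 2, got {pop_size}")
    if steps < 1 or reps < 1:
        raise ValueError("steps and reps must be >= 1")

    totals = np.zeros(steps + 1)
    for child_seq in np.random.SeedSequence(seed).spawn(reps):
        rng = np.random.default_rng(child_seq)
        if mode == BLENDING:
            traits: list[Fraction] = [Fraction(0)] * (pop_size // 2) + [
                Fraction(1)
            ] * (pop_size - pop_size // 2)
            totals[0] += count_types(traits, resolution=resolution or TRAIT_RESOLUTION)
            for t in range(1, steps + 1):
                traits = blending_generation(traits, rng)
                totals[t] += count_types(
                    traits, resolution=resolution or TRAIT_RESOLUTION
                )
        else:
            geno = np.array(
                [0] * (pop_size // 2) + [2] * (pop_size - pop_size // 2),
                dtype=np.int64,
            )
            totals[0] += len(np.unique(geno))
            for t in range(1, steps + 1):
                geno = mendelian_generation(geno, rng)
                totals[t] += len(np.unique(geno))
    return totals / reps
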