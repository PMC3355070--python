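"""Exact enumeration of Mendelian crosses.

Implements the two classical laws for crosses of diploid parents:

* **segregation** — each parent contributes one of its two alleles with
  probability 1/2;
* **independent assortment** — contributions at different genes are
  independent (an idealisation; the crossover modules quantify how it
  fails for linked genes).

All probabilities are exact :class:`fractions.Fraction` values, so the
classical 3:1 and 9:3:3:1 ratios come out as identities rather than
floating-point approximations.  Phenotypes follow complete dominance: a
genotype shows the dominant phenotype iff it carries at least one copy
of the gene's dominant allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Iterable, Mapping, Sequence

__all__ = [
    "UnorderedGenotype",
    "CrossDistribution",
    "IncompatibleCrossError",
    "genotype",
    "cross_single_gene",
    "cross_multi_gene",
    "phenotype_ratio",
    "DOMINANT",
    "RECESSIVE",
]

#: Phenotype labels under complete dominance.
DOMINANT = "dominant"
RECESSIVE = "recessive"


class IncompatibleCrossError(ValueError):
    """Raised when the two parents of a cross do not cover the same genes."""


@dataclass(frozen=True)
class UnorderedGenotype:
    """An unordered allele pair at one gene.

    ``Aa`` and ``aA`` are the same genotype: the allele pair is stored
    sorted, because at this level phase (which allele sits on which
    chromosome) is not modelled.  Phase-aware genotypes live in
    :mod:`jumpcross.simulate`.
    """

    gene: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError("a diploid genotype carries exactly two alleles")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def heterozygous(self) -> bool:
        return self.alleles[0] != self.alleles[1]

    def __str__(self) -> str:  # e.g. "A:Aa"
        return f"{self.gene}:{''.join(self.alleles)}"


def genotype(gene: str, a: str, b: str) -> UnorderedGenotype:
    """Convenience constructor for an unordered genotype."""
    return UnorderedGenotype(gene, (a, b))


@dataclass(frozen=True)
class CrossDistribution:
    """Exact offspring-genotype distribution of a cross.

    ``outcomes`` maps a tuple of per-gene :class:`UnorderedGenotype`
    (one entry per gene, in the parents' gene order) to its exact
    probability.  Identical genotype vectors are merged, so the
    probabilities are positive and sum to exactly 1.
    """

    genes: tuple[str, ...]
    outcomes: Mapping[tuple[UnorderedGenotype, ...], Fraction]

    def __post_init__(self) -> None:
        total = sum(self.outcomes.values(), Fraction(0))
        if total != 1:
            raise ValueError(f"cross probabilities sum to {total}, not 1")
        if any(p <= 0 for p in self.outcomes.values()):
            raise ValueError("cross probabilities must be positive")

    def marginal(self, gene: str) -> "CrossDistribution":
        """Marginal single-gene distribution (oracle hook for tests)."""
        idx = self.genes.index(gene)
        merged: dict[tuple[UnorderedGenotype, ...], Fraction] = {}
        for combo, prob in self.outcomes.items():
            key = (combo[idx],)
            merged[key] = merged.get(key, Fraction(0)) + prob
        return CrossDistribution((gene,), merged)


def _single_gene_outcomes(
    p1: UnorderedGenotype, p2: UnorderedGenotype
) -> dict[UnorderedGenotype, Fraction]:
    quarter = Fraction(1, 4)
    merged: dict[UnorderedGenotype, Fraction] = {}
    for a, b in product(p1.alleles, p2.alleles):
        child = UnorderedGenotype(p1.gene, (a, b))
        merged[child] = merged.get(child, Fraction(0)) + quarter
    return merged


def cross_single_gene(
    p1: UnorderedGenotype, p2: UnorderedGenotype
) -> CrossDistribution:
    """Cross two parents at one gene.

    Enumerates the 2x2 grid of equally likely allele contributions
    (probability 1/4 per cell, by segregation) and merges identical
    offspring genotypes.
    """
    if p1.gene != p2.gene:
        raise IncompatibleCrossError(
            f"cannot cross gene {p1.gene!r} with gene {p2.gene!r}"
        )
    merged = _single_gene_outcomes(p1, p2)
    return CrossDistribution((p1.gene,), {(g,): p for g, p in merged.items()})


def cross_multi_gene(
    p1: Sequence[UnorderedGenotype], p2: Sequence[UnorderedGenotype]
) -> CrossDistribution:
    """Cross two parents at several genes under independent assortment.

    The offspring distribution is the product of the per-gene crosses;
    for two double heterozygotes each of the 16 raw assortments has
    probability 1/16 before merging.
    """
    genes1 = tuple(g.gene for g in p1)
    genes2 = tuple(g.gene for g in p2)
    if genes1 != genes2:
        raise IncompatibleCrossError(
            f"parents cover different genes: {genes1} vs {genes2}"
        )
    if not genes1:
        raise IncompatibleCrossError("cross requires at least one gene")
    if len(set(genes1)) != len(genes1):
        raise IncompatibleCrossError(f"duplicate genes in cross: {genes1}")

    per_gene = [_single_gene_outcomes(a, b) for a, b in zip(p1, p2)]
    outcomes: dict[tuple[UnorderedGenotype, ...], Fraction] = {}
    for combo in product(*(m.items() for m in per_gene)):
        key = tuple(g for g, _ in combo)
        prob = Fraction(1)
        for _, p in combo:
            prob *= p
        outcomes[key] = outcomes.get(key, Fraction(0)) + prob
    return CrossDistribution(genes1, outcomes)


def phenotype_ratio(
    dist: CrossDistribution, dominant: Mapping[str, str]
) -> dict[tuple[str, ...], Fraction]:
    """Collapse a genotype distribution to phenotypes under complete dominance.

    Parameters
    ----------
    dist:
        Offspring genotype distribution.
    dominant:
        Per-gene dominant allele.  A genotype is ``dominant`` at a gene
        iff it carries at least one copy of that allele.

    Returns
    -------
    dict
        Maps phenotype vectors, e.g. ``("dominant", "recessive")``, to
        exact probabilities.
    """
    missing = [g for g in dist.genes if g not in dominant]
    if missing:
        raise KeyError(f"no dominant allele declared for gene(s) {missing}")
    ratios: dict[tuple[str, ...], Fraction] = {}
    for combo, prob in dist.outcomes.items():
        pheno = tuple(
            DOMINANT if dominant[g.gene] in g.alleles else RECESSIVE
            for g in combo
        )
        ratios[pheno] = ratios.get(pheno, Fraction(0)) + prob
    return ratios
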