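"""Phase-known family tables: container, TSV dialect, and the seeded
synthetic-family generator.

A family records two phase-known parents and their offspring at a set of
named genes.  Each offspring is stored as the pair of gametes it
received: ``(paternal allele, maternal allele)`` per gene.  The TSV
dialect is deliberately minimal (the phase-known two-allele-per-gene
layout has no direct PED/VCF encoding)::

    #genes<TAB>A<TAB>B<TAB>C
    dad<TAB>father<TAB>0|1<TAB>0|1<TAB>0|1
    mom<TAB>mother<TAB>0|1<TAB>0|1<TAB>0|1
    kid1<TAB>offspring<TAB>0|0<TAB>1|0<TAB>0|1

For parents, ``a|b`` is phase-known with the left allele on chromosome
I.  For offspring, ``a|b`` is (paternal-gamete allele | maternal-gamete
allele).  Malformed rows are rejected with their line number.

The generator draws offspring under the jumping model: genes sit at
strictly increasing integer coordinates, each inter-gene interval spans
``coordinate gap`` Markov steps with per-step crossover probability
``p``, and each offspring receives one independently sampled paternal
and maternal gamete.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .markov import TwoStateChain
from .simulate import PhasedGenotype, simulate_sources

__all__ = [
    "FamilyTable",
    "FamilyParseError",
    "SynthSpec",
    "generate_family",
    "read_family_tsv",
    "write_family_tsv",
    "family_to_tsv",
    "family_from_tsv",
]

#: Allele tokens accepted by the TSV parser.
DEFAULT_ALPHABET = frozenset({"0", "1"})

ROLE_FATHER = "father"
ROLE_MOTHER = "mother"
ROLE_OFFSPRING = "offspring"


class FamilyParseError(ValueError):
    """Malformed family TSV; the message names the offending line."""


@dataclass(frozen=True)
class FamilyTable:
    """Two phase-known parents plus offspring gametes at shared genes."""

    gene_names: tuple[str, ...]
    father: PhasedGenotype
    mother: PhasedGenotype
    offspring: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    offspring_ids: tuple[str, ...] = ()
    father_id: str = "father"
    mother_id: str = "mother"

    def __post_init__(self) -> None:
        n = len(self.gene_names)
        if n < 1:
            raise ValueError("a family table needs at least one gene")
        if len(set(self.gene_names)) != n:
            raise ValueError(f"duplicate gene names: {self.gene_names}")
        for label, parent in ((ROLE_FATHER, self.father), (ROLE_MOTHER, self.mother)):
            if parent.n_genes != n:
                raise ValueError(
                    f"{label} covers {parent.n_genes} genes, table declares {n}"
                )
        for k, (pat, mat) in enumerate(self.offspring):
            if len(pat) != n or len(mat) != n:
                raise ValueError(f"offspring {k} does not cover all {n} genes")
        if self.offspring_ids and len(self.offspring_ids) != len(self.offspring):
            raise ValueError("offspring_ids length mismatch")

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}; table has {self.gene_names}")

    def flip_gene_phase(self, gene: str) -> "FamilyTable":
        """Swap the assumed chromosome labels of one gene in both parents.

        Models a correction of wrong prior knowledge of which allele
        sits on which chromosome; offspring data are untouched.
        """
        k = self.gene_index(gene)
        return replace(
            self,
            father=self.father.flip_gene(k),
            mother=self.mother.flip_gene(k),
        )


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic family under the jumping model.

    ``positions`` are strictly increasing integer coordinates in
    inter-gene steps; adjacent genes at gap ``t`` are separated by ``t``
    Markov steps.  Default parents are heterozygous ``0|1`` at every
    gene (the fully informative configuration).
    """

    gene_names: tuple[str, ...]
    positions: tuple[int, ...]
    p: float
    n_offspring: int
    q: float = 0.5
    seed: int = 0
    father: PhasedGenotype | None = None
    mother: PhasedGenotype | None = None

    def __post_init__(self) -> None:
        if len(self.gene_names) != len(self.positions):
            raise ValueError("one position per gene required")
        if len(self.gene_names) < 2:
            raise ValueError("need at least 2 genes")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError(f"positions must strictly increase: {self.positions}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie in (0, 1), got {self.p}")
        if self.n_offspring < 1:
            raise ValueError("need at least one offspring")

    def parent(self, which: str) -> PhasedGenotype:
        explicit = self.father if which == ROLE_FATHER else self.mother
        if explicit is not None:
            if explicit.n_genes != len(self.gene_names):
                raise ValueError(f"{which} does not cover all genes")
            return explicit
        return PhasedGenotype(tuple(("0", "1") for _ in self.gene_names))


def generate_family(spec: SynthSpec) -> FamilyTable:
    """Draw a synthetic phase-known family, deterministic under the seed."""
    chain = TwoStateChain(spec.p, spec.q)
    steps = [b - a for a, b in zip(spec.positions, spec.positions[1:])]
    n_genes = len(spec.gene_names)
    father = spec.parent(ROLE_FATHER)
    mother = spec.parent(ROLE_MOTHER)

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    pat_src = simulate_sources(chain, n_genes, spec.n_offspring, rng, steps=steps)
    mat_src = simulate_sources(chain, n_genes, spec.n_offspring, rng, steps=steps)

    offspring = []
    for o in range(spec.n_offspring):
        pat = tuple(
            father.alleles[k][int(pat_src[o, k])] for k in range(n_genes)
        )
        mat = tuple(
            mother.alleles[k][int(mat_src[o, k])] for k in range(n_genes)
        )
        offspring.append((pat, mat))
    ids = tuple(f"o{k + 1}" for k in range(spec.n_offspring))
    return FamilyTable(
        tuple(spec.gene_names), father, mother, tuple(offspring), ids
    )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------


def _parse_allele_pair(
    token: str, lineno: int, alphabet: frozenset[str]
) -> tuple[str, str]:
    parts = token.split("|")
    if len(parts) != 2 or not all(parts):
        raise FamilyParseError(
            f"line {lineno}: expected 'a|b' allele pair, got {token!r}"
        )
    for allele in parts:
        if allele not in alphabet:
            raise FamilyParseError(
                f"line {lineno}: allele {allele!r} outside declared alphabet "
                f"{sorted(alphabet)}"
            )
    return parts[0], parts[1]


def family_from_tsv(
    text: str, *, alphabet: Iterable[str] = DEFAULT_ALPHABET
) -> FamilyTable:
    """Parse the family TSV dialect from a string."""
    alphabet = frozenset(alphabet)
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#genes\t"):
        raise FamilyParseError("line 1: expected header '#genes<TAB>...'")
    genes = tuple(lines[0].rstrip("\n").split("\t")[1:])
    if len(genes) < 1 or any(not g for g in genes):
        raise FamilyParseError("line 1: header declares no valid gene names")
    n = len(genes)

    father = mother = None
    father_id = mother_id = ""
    offspring: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    ids: list[str] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != n + 2:
            raise FamilyParseError(
                f"line {lineno}: expected {n + 2} fields "
                f"(id, role, {n} genes), got {len(fields)}"
            )
        ind_id, role = fields[0], fields[1]
        pairs = [
            _parse_allele_pair(tok, lineno, alphabet) for tok in fields[2:]
        ]
        if role == ROLE_FATHER or role == ROLE_MOTHER:
            genotype = PhasedGenotype(tuple(pairs))
            if role == ROLE_FATHER:
                if father is not None:
                    raise FamilyParseError(f"line {lineno}: duplicate father row")
                father, father_id = genotype, ind_id
            else:
                if mother is not None:
                    raise FamilyParseError(f"line {lineno}: duplicate mother row")
                mother, mother_id = genotype, ind_id
        elif role == ROLE_OFFSPRING:
            offspring.append(
                (tuple(p for p, _ in pairs), tuple(m for _, m in pairs))
            )
            ids.append(ind_id)
        else:
            raise FamilyParseError(
                f"line {lineno}: unknown role {role!r} (expected father, "
                f"mother or offspring)"
            )
    if father is None or mother is None:
        missing = [
            name
            for name, parent in ((ROLE_FATHER, father), (ROLE_MOTHER, mother))
            if parent is None
        ]
        raise FamilyParseError(f"missing required parent row(s): {missing}")
    return FamilyTable(
        genes, father, mother, tuple(offspring), tuple(ids), father_id, mother_id
    )


def family_to_tsv(family: FamilyTable) -> str:
    """Serialise a family table to its canonical TSV form."""
    lines = ["#genes\t" + "\t".join(family.gene_names)]
    for ind_id, role, genotype in (
        (family.father_id, ROLE_FATHER, family.father),
        (family.mother_id, ROLE_MOTHER, family.mother),
    ):
        cells = "\t".join(f"{a}|{b}" for a, b in genotype.alleles)
        lines.append(f"{ind_id}\t{role}\t{cells}")
    for k, (pat, mat) in enumerate(family.offspring):
        ind_id = family.offspring_ids[k] if family.offspring_ids else f"o{k + 1}"
        cells = "\t".join(f"{p}|{m}" for p, m in zip(pat, mat))
        lines.append(f"{ind_id}\t{ROLE_OFFSPRING}\t{cells}")
    return "\n".join(lines) + "\n"


def read_family_tsv(
    path: str | Path, *, alphabet: Iterable[str] = DEFAULT_ALPHABET
) -> FamilyTable:
    """Read a family table from a TSV file."""
    return family_from_tsv(Path(path).read_text(), alphabet=alphabet)


def write_family_tsv(family: FamilyTable, path: str | Path) -> None:
    """Write a family table to a TSV file (canonical, byte-stable form)."""
    Path(path).write_text(family_to_tsv(family))
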