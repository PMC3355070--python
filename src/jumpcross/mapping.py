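"""Linkage mapping from phase-known family tables.

The pipeline follows the classical three steps:

1. **source assignment** — for every offspring gamete, decide which
   parental chromosome contributed each allele (possible exactly when
   the parent is heterozygous at the gene);
2. **recombination-fraction estimation** — for each gene pair, pool
   paternal and maternal meioses and estimate ``r_hat`` as the fraction
   of informative meioses whose two source assignments differ;
3. **ordering** — convert each ``r_hat < 1/2`` to a Morgan distance via
   the inverse Haldane map and pick, by exhaustive search, the gene
   permutation under which distances are most nearly additive.

Estimates above 1/2 cannot be mapped directly and admit two competing
readings, both produced by :func:`diagnose_mode`: either the assumed
phase labels of some genes are simply wrong (relabelling restores all
``r_hat`` below 1/2), or the genes sit in a recombination hotspot, in
which case the jumping model requires the outer pair's ``r_hat`` to
equal the parity composition ``r1 + r2 - 2 r1 r2`` of the adjacent ones
and predicts the double-crossover rate ``r1 * r2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

from .families import FamilyTable
from .markov import combine_r, morgan_m_from_r
from .simulate import CHROM_I, CHROM_II, PairwiseREstimate, PhasedGenotype

__all__ = [
    "MapResult",
    "DoubleCrossoverReport",
    "NonMendelianError",
    "HotspotSignalError",
    "transmitted_sources",
    "count_recombinants",
    "count_recombinants_by_parent",
    "estimate_all_r",
    "infer_order",
    "diagnose_mode",
    "double_crossover_rate",
    "MODE_NORMAL",
    "MODE_HOTSPOT",
    "MODE_RELABELLED",
    "MODE_UNDETERMINED",
]

MODE_NORMAL = "normal"
MODE_HOTSPOT = "hotspot"
MODE_RELABELLED = "relabelled"
MODE_UNDETERMINED = "undetermined"

AMBIGUOUS = None


class NonMendelianError(ValueError):
    """An offspring allele could not have come from the stated parent."""


class HotspotSignalError(ValueError):
    """Raised when ordering is attempted on estimates above 1/2."""


@dataclass(frozen=True)
class MapResult:
    """Outcome of gene ordering or mode diagnosis.

    ``orders`` holds the winning gene order and its reversal (order is
    identifiable only up to reversal from pairwise data).  ``distances``
    are Morgan distances between adjacent genes of ``orders[0]`` when
    defined.  ``diagnostics`` carries residuals and branch reports.
    """

    orders: tuple[tuple[str, ...], ...]
    distances: tuple[float, ...]
    mode: str
    diagnostics: dict

    def __post_init__(self) -> None:
        for order in self.orders:
            if len(set(order)) != len(order):
                raise ValueError(f"order repeats a gene: {order}")


@dataclass(frozen=True)
class DoubleCrossoverReport:
    """Observed vs expected double-crossover fraction around a middle gene."""

    middle: str
    outer: tuple[str, str]
    informative: int
    double_recombinant: int
    expected: float

    @property
    def observed(self) -> float:
        return self.double_recombinant / self.informative


def transmitted_sources(
    parent: PhasedGenotype,
    gamete_alleles,
    gene_names=None,
) -> tuple[str | None, ...]:
    """Source chromosome of each transmitted allele.

    Returns ``"I"``/``"II"`` per gene where the parent is heterozygous
    and ``None`` (ambiguous) where it is homozygous.  An allele the
    parent does not carry raises :class:`NonMendelianError` naming the
    gene.
    """
    if len(gamete_alleles) != parent.n_genes:
        raise ValueError(
            f"gamete covers {len(gamete_alleles)} genes, parent has "
            f"{parent.n_genes}"
        )
    out: list[str | None] = []
    for k, (allele, pair) in enumerate(zip(gamete_alleles, parent.alleles)):
        if allele not in pair:
            name = gene_names[k] if gene_names else f"#{k + 1}"
            raise NonMendelianError(
                f"gene {name}: offspring allele {allele!r} not carried by "
                f"parent with alleles {pair[0]}|{pair[1]}"
            )
        if pair[0] == pair[1]:
            out.append(AMBIGUOUS)
        elif allele == pair[0]:
            out.append(CHROM_I)
        else:
            out.append(CHROM_II)
    return tuple(out)


def _meiosis_sources(family: FamilyTable) -> list[tuple[str, tuple[str | None, ...]]]:
    """All meioses of a family as (parent label, source vector)."""
    meioses = []
    for pat, mat in family.offspring:
        meioses.append(
            ("father", transmitted_sources(family.father, pat, family.gene_names))
        )
        meioses.append(
            ("mother", transmitted_sources(family.mother, mat, family.gene_names))
        )
    return meioses


def count_recombinants_by_parent(
    family: FamilyTable, g: str, h: str
) -> dict[str, PairwiseREstimate]:
    """Per-parent recombinant counts for one gene pair (diagnostics)."""
    gi, hi = family.gene_index(g), family.gene_index(h)
    if gi == hi:
        raise ValueError(f"need two distinct genes, got {g!r} twice")
    counts = {"father": [0, 0], "mother": [0, 0]}
    for parent, sources in _meiosis_sources(family):
        sg, sh = sources[gi], sources[hi]
        if sg is AMBIGUOUS or sh is AMBIGUOUS:
            continue
        counts[parent][0] += 1
        if sg != sh:
            counts[parent][1] += 1
    return {
        parent: PairwiseREstimate((g, h), informative, recombinant)
        for parent, (informative, recombinant) in counts.items()
    }


def count_recombinants(family: FamilyTable, g: str, h: str) -> PairwiseREstimate:
    """Pooled (paternal + maternal) recombinant count for a gene pair.

    A meiosis is informative iff the transmitting parent is heterozygous
    at both genes; it is recombinant iff the two source chromosomes
    differ.  Homozygous-parent meioses are excluded from the
    denominator.
    """
    per_parent = count_recombinants_by_parent(family, g, h)
    informative = sum(e.informative for e in per_parent.values())
    recombinant = sum(e.recombinant for e in per_parent.values())
    return PairwiseREstimate((g, h), informative, recombinant)


def estimate_all_r(family: FamilyTable) -> list[PairwiseREstimate]:
    """One pooled estimate per unordered gene pair, in gene order."""
    if len(family.gene_names) < 2:
        raise ValueError("need at least 2 genes to estimate recombination")
    return [
        count_recombinants(family, g, h)
        for g, h in combinations(family.gene_names, 2)
    ]


def _estimate_lookup(estimates) -> tuple[tuple[str, ...], dict]:
    lookup: dict[frozenset, PairwiseREstimate] = {}
    genes: list[str] = []
    for est in estimates:
        key = frozenset(est.pair)
        if len(key) != 2:
            raise ValueError(f"estimate pair must name two genes, got {est.pair}")
        if key in lookup:
            raise ValueError(f"duplicate estimate for pair {est.pair}")
        lookup[key] = est
        for g in est.pair:
            if g not in genes:
                genes.append(g)
    expected = len(genes) * (len(genes) - 1) // 2
    if len(lookup) != expected:
        raise ValueError(
            f"{len(genes)} genes need {expected} pairwise estimates, got "
            f"{len(lookup)}"
        )
    return tuple(genes), lookup


def _order_residual(order, morgan: dict) -> float:
    """Additivity residual: sum over non-adjacent pairs of
    |direct Morgan distance - sum of adjacent distances on the path|."""
    residual = 0.0
    for i in range(len(order)):
        for j in range(i + 2, len(order)):
            key = frozenset((order[i], order[j]))
            if morgan.get(key) is None:
                continue
            path = 0.0
            defined = True
            for k in range(i, j):
                adj = morgan.get(frozenset((order[k], order[k + 1])))
                if adj is None:
                    defined = False
                    break
                path += adj
            if defined:
                residual += abs(morgan[key] - path)
    return residual


def infer_order(estimates, max_genes: int = 8) -> MapResult:
    """Infer the gene order (up to reversal) by Morgan-distance additivity.

    Every ``r_hat`` must be below 1/2 — larger values signal either a
    phase-labelling error or a hotspot and must go through
    :func:`diagnose_mode` first.  Pairs with ``r_hat`` exactly 1/2 are
    unlinked: they carry no ordering information and are excluded from
    the residual (and flagged in the diagnostics).

    The residual of an order is the summed absolute violation of
    additivity, ``|m(outer) - sum of m(adjacent)|`` over all
    non-adjacent pairs; the order (and its reversal) minimising it wins.
    Exhaustive search, hence the ``max_genes`` bound.
    """
    genes, lookup = _estimate_lookup(estimates)
    if len(genes) > max_genes:
        raise ValueError(
            f"{len(genes)} genes exceed the exhaustive-search bound "
            f"{max_genes}"
        )
    unlinked = []
    morgan: dict[frozenset, float | None] = {}
    for key, est in lookup.items():
        r = est.r_hat
        if r is None:
            raise ValueError(
                f"pair {tuple(est.pair)} has no informative meioses; "
                f"cannot order"
            )
        if r > 0.5:
            raise HotspotSignalError(
                f"pair {tuple(est.pair)} has r_hat={r:.3f} > 1/2; run "
                f"diagnose_mode to resolve hotspot vs phase relabelling"
            )
        if r == 0.5:
            unlinked.append(tuple(est.pair))
            morgan[key] = None
        else:
            morgan[key] = morgan_m_from_r(r)

    if len(genes) == 2:
        best = tuple(genes)
        residuals = {best: 0.0}
    else:
        residuals = {}
        for perm in permutations(genes):
            if perm[0] > perm[-1]:  # each order once; reversal is equivalent
                continue
            residuals[perm] = _order_residual(perm, morgan)
        best = min(residuals, key=lambda o: (residuals[o], o))

    distances = tuple(
        float("nan")
        if morgan[frozenset((a, b))] is None
        else morgan[frozenset((a, b))]
        for a, b in zip(best, best[1:])
    )
    diagnostics = {
        "residual": residuals[best],
        "residuals_by_order": {o: v for o, v in residuals.items()},
        "unlinked_pairs": unlinked,
    }
    return MapResult(
        orders=(best, tuple(reversed(best))),
        distances=distances,
        mode=MODE_NORMAL,
        diagnostics=diagnostics,
    )


def double_crossover_rate(
    family: FamilyTable, middle: str, outer: tuple[str, str]
) -> DoubleCrossoverReport:
    """Observed double-crossover fraction vs the no-interference product.

    Counts meioses informative at all three genes that are recombinant
    in *both* adjacent intervals, and compares the fraction with the
    product of the two adjacent ``r_hat`` (the Markov chain has no
    crossover interference, so the intervals recombine independently).
    """
    g1, g2 = outer
    mi = family.gene_index(middle)
    i1, i2 = family.gene_index(g1), family.gene_index(g2)
    if len({mi, i1, i2}) != 3:
        raise ValueError("middle and outer genes must be three distinct genes")
    informative = 0
    double = 0
    for _, sources in _meiosis_sources(family):
        s1, sm, s2 = sources[i1], sources[mi], sources[i2]
        if AMBIGUOUS in (s1, sm, s2):
            continue
        informative += 1
        if s1 != sm and sm != s2:
            double += 1
    if informative == 0:
        raise ValueError("no meioses informative at all three genes")
    r1 = count_recombinants(family, g1, middle).r_hat
    r2 = count_recombinants(family, middle, g2).r_hat
    return DoubleCrossoverReport(
        middle=middle,
        outer=(g1, g2),
        informative=informative,
        double_recombinant=double,
        expected=r1 * r2,
    )


def _relabel_search(estimates, genes):
    """Smallest per-gene phase-flip set minimising pairs with r_hat > 1/2.

    Flipping a gene's phase in both parents turns every pooled estimate
    involving that gene from r_hat into 1 - r_hat (informative count
    unchanged).  Exhaustive over the 2^g flip subsets.
    """
    _, lookup = _estimate_lookup(estimates)
    best = None
    for mask in range(2 ** len(genes)):
        flipped = frozenset(g for k, g in enumerate(genes) if mask >> k & 1)
        bad = 0
        for key, est in lookup.items():
            r = est.r_hat
            if r is None:
                continue
            if len(key & flipped) == 1:
                r = 1.0 - r
            if r > 0.5:
                bad += 1
        candidate = (bad, len(flipped), tuple(sorted(flipped)))
        if best is None or candidate < best:
            best = candidate
    return best  # (bad pairs, flip count, flips)


def diagnose_mode(estimates, family: FamilyTable, *, n_se: float = 3.0) -> MapResult:
    """Confront the two readings of recombination estimates above 1/2.

    **Relabelled**: assume the phase labels of some genes were recorded
    backwards.  Search all per-gene flips (applied to both parents) for
    the smallest set removing every ``r_hat > 1/2``, re-estimate on the
    flipped table and order the genes normally.

    **Hotspot**: take the estimates at face value (three genes).  The
    middle gene is the one for which the parity composition of its two
    adjacent estimates reproduces the outer pair's estimate within
    ``n_se`` binomial standard errors; the double-crossover fraction is
    then compared against the no-interference product of the adjacent
    estimates.

    Both branches are always reported in ``diagnostics``.  ``mode`` is
    the branch label when exactly one is internally consistent and
    ``"undetermined"`` otherwise — pairwise data alone cannot separate a
    hotspot from a phase-labelling error, so the caller must bring
    outside knowledge (see the CLI's ``--assume-*`` flags).
    """
    genes, lookup = _estimate_lookup(estimates)
    r_values = [e.r_hat for e in lookup.values() if e.r_hat is not None]
    if not any(r > 0.5 for r in r_values):
        raise ValueError(
            "diagnose_mode requires at least one r_hat > 1/2; use "
            "infer_order directly"
        )

    diagnostics: dict = {}

    # --- relabel branch -------------------------------------------------
    bad, _, flips = _relabel_search(estimates, genes)
    relabel_consistent = bad == 0
    relabel_report: dict = {"flips": flips, "pairs_above_half": bad}
    relabel_result = None
    if relabel_consistent and flips:
        flipped_family = family
        for g in flips:
            flipped_family = flipped_family.flip_gene_phase(g)
        reestimates = estimate_all_r(flipped_family)
        relabel_report["estimates"] = reestimates
        try:
            relabel_result = infer_order(reestimates)
            relabel_report["order"] = relabel_result.orders[0]
            relabel_report["residual"] = relabel_result.diagnostics["residual"]
        except (HotspotSignalError, ValueError) as exc:  # pragma: no cover
            relabel_consistent = False
            relabel_report["error"] = str(exc)
    diagnostics["relabel"] = relabel_report

    # --- hotspot branch -------------------------------------------------
    hotspot_report: dict = {}
    hotspot_consistent = False
    hotspot_order = None
    if len(genes) == 3:
        candidates = {}
        for middle in genes:
            a, b = sorted(g for g in genes if g != middle)
            e1 = lookup[frozenset((a, middle))]
            e2 = lookup[frozenset((middle, b))]
            eo = lookup[frozenset((a, b))]
            if None in (e1.r_hat, e2.r_hat, eo.r_hat):
                continue
            predicted = combine_r(e1.r_hat, e2.r_hat)
            var_pred = (1 - 2 * e2.r_hat) ** 2 * e1.standard_error() ** 2 + (
                1 - 2 * e1.r_hat
            ) ** 2 * e2.standard_error() ** 2
            tol = n_se * math.sqrt(var_pred + eo.standard_error() ** 2)
            candidates[middle] = {
                "predicted_outer": predicted,
                "observed_outer": eo.r_hat,
                "residual": abs(predicted - eo.r_hat),
                "tolerance": tol,
                "consistent": abs(predicted - eo.r_hat) <= tol,
            }
        hotspot_report["candidates"] = candidates
        passing = [m for m, c in candidates.items() if c["consistent"]]
        if len(passing) == 1:
            middle = passing[0]
            outer = tuple(sorted(g for g in genes if g != middle))
            hotspot_consistent = True
            hotspot_order = (outer[0], middle, outer[1])
            hotspot_report["middle"] = middle
            dco = double_crossover_rate(family, middle, outer)
            hotspot_report["double_crossover"] = dco
    else:
        hotspot_report["note"] = (
            "hotspot middle-gene identification is defined for 3 genes; "
            f"table has {len(genes)}"
        )
    diagnostics["hotspot"] = hotspot_report

    # --- verdict --------------------------------------------------------
    if relabel_consistent and not hotspot_consistent:
        mode = MODE_RELABELLED
    elif hotspot_consistent and not relabel_consistent:
        mode = MODE_HOTSPOT
    else:
        mode = MODE_UNDETERMINED

    if relabel_result is not None:
        orders = relabel_result.orders
        distances = relabel_result.distances
    elif hotspot_order is not None:
        orders = (hotspot_order, tuple(reversed(hotspot_order)))
        distances = ()
    else:
        orders = ()
        distances = ()
    return MapResult(
        orders=orders, distances=distances, mode=mode, diagnostics=diagnostics
    )
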