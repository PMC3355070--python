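"""Uniform 1- and 2-crossover models of recombination.

The uniform 1-crossover model places ``n`` genes on a chromosome pair and
draws a single crossover site ``X`` uniformly from ``{0, 1, ..., n-1}``:
``X = 0`` means no crossover, and ``X = s`` (``s >= 1``) separates gene
``s`` from gene ``s+1``.  Two genes at ``d`` inter-gene steps apart then
recombine with probability exactly ``d/n`` — the linkage property in its
simplest (linear) form.

The model has known deficiencies, each exposed here as a computable
quantity:

* segregation is fragile — the probability of inheriting a given allele
  depends on the start-chromosome bias ``q`` and equals 1/2 only at
  ``q = 1/2`` (:func:`u1_inherit_prob`);
* independent assortment fails on one chromosome — only gene pairs whose
  recombination probability is exactly 1/2 are independent
  (:func:`u1_independence_gap`);
* the natural 2-crossover generalisation breaks linkage: its large-n
  recombination probability ``(1-x) ln(1/(1-x))`` is not monotone in the
  relative distance ``x`` and peaks at ``x = 1 - 1/e`` (about 63% of the
  chromosome length) with value ``1/e`` (:func:`u2_argmax`).

Finite-``n`` quantities use exact rational arithmetic; only the large-n
limit forms return floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Union

from scipy.optimize import minimize_scalar

__all__ = [
    "Uniform1Params",
    "Uniform2Params",
    "u1_recomb_prob",
    "u1_inherit_prob",
    "u1_independence_gap",
    "u2_recomb_prob_exact",
    "u2_recomb_prob_limit",
    "u2_argmax",
]

ProbabilityLike = Union[Fraction, float, int, str]


def _as_fraction(value: ProbabilityLike, name: str) -> Fraction:
    frac = Fraction(value)
    if not 0 <= frac <= 1:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return frac


@dataclass(frozen=True)
class Uniform1Params:
    """Parameters of the uniform 1-crossover model.

    ``n`` is the number of genes on the chromosome; ``q`` the probability
    that the recombination process starts on chromosome I of the pair.
    """

    n: int
    q: Fraction = Fraction(1, 2)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need at least 2 genes, got n={self.n}")
        object.__setattr__(self, "q", _as_fraction(self.q, "q"))


@dataclass(frozen=True)
class Uniform2Params:
    """Parameters of the uniform 2-crossover model (gene count only)."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"need at least 3 genes, got n={self.n}")


def _check_pair(n: int, i: int, j: int) -> None:
    if not (1 <= i <= n and 1 <= j <= n):
        raise ValueError(f"gene indices must lie in 1..{n}, got ({i}, {j})")
    if i >= j:
        raise ValueError(f"need i < j, got ({i}, {j})")


def u1_recomb_prob(params: Uniform1Params, i: int, j: int) -> Fraction:
    """Recombination probability of genes ``i < j``: exactly ``(j-i)/n``.

    Of the ``n`` equally likely crossover sites, the ``j - i`` sites
    ``{i, ..., j-1}`` fall strictly between the two genes and flip their
    relative source; all others (including the no-crossover site 0)
    leave the pair parental.
    """
    _check_pair(params.n, i, j)
    return Fraction(j - i, params.n)


def u1_inherit_prob(params: Uniform1Params, i: int) -> Fraction:
    """Probability that gene ``i``'s allele comes from chromosome I.

    Equals ``q (1 - r) + (1 - q) r`` with ``r = (i-1)/n`` the probability
    that a crossover falls between the (hypothetical) start of the
    chromosome and gene ``i``: the allele is inherited from chromosome I
    either when the process starts there and no crossover intervenes, or
    when it starts on chromosome II and one does.  At ``q = 1/2`` the two
    terms cancel to exactly 1/2 for every gene — but any bias in ``q``
    propagates undamped, which is the model's segregation fragility.
    """
    if not 1 <= i <= params.n:
        raise ValueError(f"gene index must lie in 1..{params.n}, got {i}")
    r = Fraction(i - 1, params.n)
    return params.q * (1 - r) + (1 - params.q) * r


def _u1_source_is_I(start_is_I: bool, x: int, gene: int) -> bool:
    # Site x separates gene x and gene x+1; genes <= x keep the start
    # chromosome, genes > x take the other (x = 0: no crossover).
    crossed = 1 <= x < gene
    return start_is_I ^ crossed


def u1_independence_gap(params: Uniform1Params, i: int, j: int) -> Fraction:
    """Absolute deviation from independent assortment for genes ``i < j``.

    Let ``A_k`` be the event that gene ``k``'s allele derives from
    chromosome I.  Returns ``|P(A_i and A_j) - P(A_i) P(A_j)|`` by exact
    enumeration over the start chromosome and the crossover site.  The
    gap vanishes (at ``q = 1/2``) only for pairs whose recombination
    probability is exactly 1/2, i.e. at distance ``n/2`` — every other
    pair on the chromosome violates independent assortment.
    """
    _check_pair(params.n, i, j)
    n, q = params.n, params.q
    site_p = Fraction(1, n)
    p_i = p_j = p_ij = Fraction(0)
    for start_is_I, start_p in ((True, q), (False, 1 - q)):
        if start_p == 0:
            continue
        for x in range(n):
            w = start_p * site_p
            a_i = _u1_source_is_I(start_is_I, x, i)
            a_j = _u1_source_is_I(start_is_I, x, j)
            if a_i:
                p_i += w
            if a_j:
                p_j += w
            if a_i and a_j:
                p_ij += w
    return abs(p_ij - p_i * p_j)


def u2_recomb_prob_exact(params: Uniform2Params, d: int) -> Fraction:
    """Exact recombination probability of gene 1 and gene ``1+d``.

    Convention: crossover sites ``{1, ..., n}`` with site ``n`` meaning
    "no crossover"; the first crossover ``X1`` is uniform on ``{1..n}``
    and the second, given ``X1``, uniform on ``{X1, ..., n}`` (the two
    are deliberately dependent — the second cannot precede the first).
    ``X2 = X1`` is a cancelled double crossover.  The pair recombines iff
    exactly one of the two crossovers lands in ``{1, ..., d}``; since
    ``X2 >= X1`` that requires ``X1 = s <= d`` and ``X2 > d``, giving

        sum_{s=1}^{d} (1/n) * (n - d) / (n - s + 1).
    """
    n = params.n
    if not 1 <= d <= n - 1:
        raise ValueError(f"distance must lie in 1..{n - 1}, got {d}")
    total = Fraction(0)
    for s in range(1, d + 1):
        total += Fraction(n - d, n * (n - s + 1))
    return total


def u2_recomb_prob_limit(x: float) -> float:
    """Large-``n`` limit of the 2-crossover recombination probability.

    For relative distance ``x = d/n`` in (0, 1) the exact sum converges
    to ``(1 - x) ln(1/(1 - x))`` (harmonic-series asymptotics).  The
    function is *not* monotone in ``x`` — the model's failure of the
    linkage property.
    """
    if not 0.0 < x < 1.0:
        raise ValueError(f"relative distance must lie in (0, 1), got {x}")
    return (1.0 - x) * math.log(1.0 / (1.0 - x))


def u2_argmax() -> tuple[float, float]:
    """Numerically maximise the large-``n`` 2-crossover limit.

    Returns ``(x_star, p_max)``.  Analytically ``x_star = 1 - 1/e``
    (about 63% of the chromosome length) and ``p_max = 1/e``: under this
    model gene 1 is *most* likely to recombine with a gene roughly 63%
    of the chromosome away, and less likely with genes beyond — contrary
    to any sane notion of linkage.
    """
    res = minimize_scalar(
        lambda x: -u2_recomb_prob_limit(x),
        bounds=(1e-9, 1.0 - 1e-9),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(-res.fun)
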