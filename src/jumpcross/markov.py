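"""The jumping model: crossover as a two-state Markov chain.

Each state of the chain is one chromosome of a homologous pair; "time"
runs along the chromosome, one step per inter-gene interval.  A
transition between states in one step is a crossover and happens with
probability ``p``; staying put has probability ``1 - p``.  Two genes at
``d`` steps apart recombine iff the chain makes an odd number of
transitions over those ``d`` steps, which has the closed form

    r(d) = (1 - lambda^d) / 2,      lambda = 1 - 2p.

The single parameter ``p`` yields both recombination regimes:

* ``p < 1/2`` (*linkage* mode): ``r(d)`` increases strictly with
  distance and saturates at 1/2, so distant genes assort independently
  while near genes are co-inherited;
* ``p > 1/2`` (*hotspot* mode): ``lambda < 0`` and ``r(d)`` alternates —
  above 1/2 at odd distances, and at even distances exactly equal to the
  linkage-mode value with ``p`` replaced by ``1 - p``.

Shrinking the step size (``p -> 0`` with ``m = p d`` fixed) recovers
Haldane's map function ``r = (1 - e^{-2m})/2``, with ``m`` the expected
number of crossovers between the loci — Morgan's definition of genetic
distance.

Closed forms are evaluated via ``lambda``; :func:`matrix_power` (plain
iterated multiplication) is kept as an independent oracle for the same
quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TwoStateChain",
    "transition_matrix",
    "matrix_power",
    "recomb_prob",
    "recomb_prob_recurrence",
    "inherit_prob",
    "joint_source_prob",
    "source_independence_gap",
    "combine_r",
    "morgan_r_from_m",
    "morgan_m_from_r",
    "mode_classify",
    "LINKAGE",
    "INDEPENDENT",
    "HOTSPOT",
]

LINKAGE = "linkage"
INDEPENDENT = "independent"
HOTSPOT = "hotspot"

#: Tolerance for row-stochasticity / symmetry validation of 2x2 matrices.
_MAT_TOL = 1e-12


@dataclass(frozen=True)
class TwoStateChain:
    """Jumping-model parameters.

    ``p`` is the per-step crossover probability, strictly inside (0, 1)
    (the endpoints are degenerate chains: the source chromosome either
    never switches or switches deterministically every step).  ``q`` is
    the probability that the gamete starts on chromosome I at gene 1.
    ``lam = 1 - 2p`` is the chain's second eigenvalue and drives every
    closed form.
    """

    p: float
    q: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"crossover probability must lie in (0, 1), got {self.p}")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"start probability must lie in [0, 1], got {self.q}")

    @property
    def lam(self) -> float:
        return 1.0 - 2.0 * self.p


def transition_matrix(chain: TwoStateChain) -> np.ndarray:
    """One-step transition matrix ``[[1-p, p], [p, 1-p]]``."""
    p = chain.p
    return np.array([[1.0 - p, p], [p, 1.0 - p]])


def _validate_stochastic(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (2, 2):
        raise ValueError(f"expected a 2x2 matrix, got shape {mat.shape}")
    if np.any(mat < -_MAT_TOL):
        raise ValueError("transition probabilities must be nonnegative")
    rows = mat.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-9):
        raise ValueError(f"rows must sum to 1, got {rows}")
    return mat


def matrix_power(mat: np.ndarray, d: int) -> np.ndarray:
    """``d``-step transition matrix by iterated multiplication.

    Deliberately the naive product (not eigen-decomposition or
    squaring): entry ``(a, b)`` of the result is the probability of
    moving from chromosome ``a`` to chromosome ``b`` in exactly ``d``
    steps, and this routine serves as the independent cross-check for
    the closed forms above.
    """
    if d < 0:
        raise ValueError(f"step count must be nonnegative, got {d}")
    mat = _validate_stochastic(mat)
    out = np.eye(2)
    for _ in range(d):
        out = out @ mat
    return out


def recomb_prob(chain: TwoStateChain, d: int) -> float:
    """Probability of recombination at ``d`` inter-gene steps.

    Odd-transition-count probability ``(1 - (1 - 2p)^d) / 2``; equals
    the off-diagonal entry of the ``d``-th matrix power.
    """
    if d < 0:
        raise ValueError(f"distance must be nonnegative, got {d}")
    return (1.0 - chain.lam**d) / 2.0


def recomb_prob_recurrence(chain: TwoStateChain, d: int) -> float:
    """Same quantity via the parity recurrence (independent route).

    Iterates ``O_k = (1 - p) O_{k-1} + p (1 - O_{k-1})`` from
    ``O_0 = 0``: after one more step the transition count is odd iff it
    was odd and the chain stayed, or was even and the chain jumped.
    """
    if d < 0:
        raise ValueError(f"distance must be nonnegative, got {d}")
    odd = 0.0
    for _ in range(d):
        odd = (1.0 - chain.p) * odd + chain.p * (1.0 - odd)
    return odd


def inherit_prob(chain: TwoStateChain, i: int) -> float:
    """Probability that gene ``i``'s allele derives from chromosome I.

    ``q (1 - r) + (1 - q) r`` with ``r = recomb_prob(chain, i - 1)``.
    Unlike the uniform 1-crossover model, any start bias ``q != 1/2`` is
    forgotten geometrically: the chain mixes to its 1/2-1/2 steady state
    and the probability converges to 1/2 for distant genes.
    """
    if i < 1:
        raise ValueError(f"gene index must be >= 1, got {i}")
    r = recomb_prob(chain, i - 1)
    return chain.q * (1.0 - r) + (1.0 - chain.q) * r


def joint_source_prob(chain: TwoStateChain, i: int, j: int) -> float:
    """P(genes ``i`` and ``j`` both sourced from chromosome I), ``i < j``.

    Marginalise the start state, propagate ``i - 1`` steps to gene
    ``i``, then ``j - i`` further steps to gene ``j``.
    """
    if not 1 <= i < j:
        raise ValueError(f"need 1 <= i < j, got ({i}, {j})")
    m_i = matrix_power(transition_matrix(chain), i - 1)
    m_ij = matrix_power(transition_matrix(chain), j - i)
    at_i = chain.q * m_i[0, 0] + (1.0 - chain.q) * m_i[1, 0]
    return at_i * m_ij[0, 0]


def source_independence_gap(chain: TwoStateChain, i: int, j: int) -> float:
    """|joint - product of marginals| for the chromosome-I source events.

    Decays like ``lam^(j-i)``: the jumping model restores independent
    assortment asymptotically in distance.
    """
    joint = joint_source_prob(chain, i, j)
    return abs(joint - inherit_prob(chain, i) * inherit_prob(chain, j))


def combine_r(r1: float, r2: float) -> float:
    """Compose recombination fractions of adjacent intervals.

    ``r1 + r2 - 2 r1 r2``: the outer pair recombines iff exactly one of
    the two intervals does (a double crossover cancels).  For
    jumping-model values this reproduces ``r(d1 + d2)`` exactly, since
    ``1 - 2 combine_r = (1 - 2 r1)(1 - 2 r2)`` multiplies the lambdas.
    Values above 1/2 (hotspot mode) are legal inputs.
    """
    for name, r in (("r1", r1), ("r2", r2)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {r}")
    return r1 + r2 - 2.0 * r1 * r2


def morgan_r_from_m(m: float) -> float:
    """Haldane map function: recombination fraction at Morgan distance ``m``.

    ``m`` is the expected number of crossovers between the two loci;
    ``r = (1 - e^{-2m}) / 2`` is the limit of the jumping model as the
    per-step crossover probability shrinks with ``m = p d`` held fixed.
    """
    if m < 0:
        raise ValueError(f"map distance must be nonnegative, got {m}")
    return (1.0 - math.exp(-2.0 * m)) / 2.0


def morgan_m_from_r(r: float) -> float:
    """Inverse Haldane map: ``m = -ln(1 - 2r) / 2`` for ``0 <= r < 1/2``.

    ``r >= 1/2`` has no finite map distance (unlinked or hotspot data);
    such estimates must go through mode diagnosis first.
    """
    if not 0.0 <= r < 0.5:
        raise ValueError(
            f"recombination fraction must lie in [0, 0.5) for a finite "
            f"map distance, got {r}"
        )
    return -0.5 * math.log(1.0 - 2.0 * r)


def mode_classify(chain: TwoStateChain) -> str:
    """Recombination regime of the chain.

    ``linkage`` for ``p < 1/2`` (r strictly increasing, bounded by 1/2),
    ``independent`` at ``p = 1/2`` (every distance gives exactly 1/2),
    ``hotspot`` for ``p > 1/2`` (r alternates around 1/2 with parity of
    the distance).
    """
    if chain.p < 0.5:
        return LINKAGE
    if chain.p == 0.5:
        return INDEPENDENT
    return HOTSPOT
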