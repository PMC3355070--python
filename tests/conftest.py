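"""Shared fixtures for the jumpcross test suite."""

import numpy as np
import pytest

from jumpcross import PhasedGenotype, SynthSpec, generate_family


@pytest.fixture
def rng():
    """Fresh, fixed-seed generator per test."""
    return np.random.default_rng(np.random.SeedSequence(20240917))


@pytest.fixture
def het_parent():
    """Fully heterozygous 0|1 parent over 6 genes."""
    return PhasedGenotype(tuple(("0", "1") for _ in range(6)))


@pytest.fixture
def linked_family():
    """Three equally spaced genes, tight linkage (p = 0.05), 2000 offspring."""
    spec = SynthSpec(("A", "B", "C"), (0, 1, 2), p=0.05, n_offspring=2000, seed=11)
    return generate_family(spec)


@pytest.fixture
def hotspot_family():
    """Three genes inside a hotspot (per-step crossover probability 0.9)."""
    spec = SynthSpec(("A", "B", "C"), (0, 1, 2), p=0.9, n_offspring=2000, seed=3)
    return generate_family(spec)
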