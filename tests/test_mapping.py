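"""Linkage mapping: source assignment, recombinant counting, gene
ordering by Morgan-distance additivity, and the hotspot-vs-relabelling
diagnosis."""

import numpy as np
import pytest

from jumpcross import (
    FamilyTable,
    HotspotSignalError,
    NonMendelianError,
    PairwiseREstimate,
    PhasedGenotype,
    SynthSpec,
    TwoStateChain,
    combine_r,
    count_recombinants,
    count_recombinants_by_parent,
    diagnose_mode,
    double_crossover_rate,
    empirical_r,
    estimate_all_r,
    generate_family,
    infer_order,
    morgan_m_from_r,
    recomb_prob,
    simulate_sources,
    transmitted_sources,
)

HET = ("0", "1")


def _family(gene_names, offspring, father=None, mother=None):
    n = len(gene_names)
    father = father or PhasedGenotype((HET,) * n)
    mother = mother or PhasedGenotype((HET,) * n)
    return FamilyTable(tuple(gene_names), father, mother, tuple(offspring))


def test_transmitted_sources_basic_cases():
    parent = PhasedGenotype((("0", "1"), ("0", "0"), ("1", "0")))
    assert transmitted_sources(parent, ("1", "0", "1")) == ("II", None, "I")
    assert transmitted_sources(parent, ("0", "0", "0")) == ("I", None, "II")


def test_transmitted_sources_rejects_impossible_allele():
    parent = PhasedGenotype((("0", "1"),))
    with pytest.raises(NonMendelianError, match="gene A"):
        transmitted_sources(parent, ("2",), gene_names=("A",))
    with pytest.raises(ValueError):
        transmitted_sources(parent, ("0", "1"))


def test_count_recombinants_hand_tallied_family():
    """8 offspring, 16 meioses; exactly 4 recombinant by construction."""
    parental = (("0", "0"), ("0", "0"))  # both gametes I,I at both genes
    recomb_pat = (("0", "1"), ("0", "0"))  # paternal gamete I,II
    offspring = [parental] * 4 + [recomb_pat] * 4
    fam = _family(("A", "B"), offspring)
    est = count_recombinants(fam, "A", "B")
    assert (est.informative, est.recombinant) == (16, 4)
    assert est.r_hat == 0.25
    per_parent = count_recombinants_by_parent(fam, "A", "B")
    assert per_parent["father"].recombinant == 4
    assert per_parent["mother"].recombinant == 0


def test_homozygous_parent_gives_no_informative_meioses():
    father = PhasedGenotype((("0", "0"), ("0", "1")))
    mother = PhasedGenotype((("0", "0"), ("0", "0")))
    fam = _family(("A", "B"), [(("0", "0"), ("0", "0"))] * 5, father, mother)
    est = count_recombinants(fam, "A", "B")
    assert est.informative == 0
    assert est.r_hat is None


def test_count_recombinants_validation(linked_family):
    with pytest.raises(KeyError):
        count_recombinants(linked_family, "A", "Z")
    with pytest.raises(ValueError):
        count_recombinants(linked_family, "A", "A")


def test_count_recombinants_agrees_with_source_based_estimate(rng):
    """Counting from offspring alleles must reproduce the estimate taken
    directly from the simulated source vectors (two code paths)."""
    chain = TwoStateChain(0.2)
    pat = simulate_sources(chain, 4, 500, rng)
    mat = simulate_sources(chain, 4, 500, rng)
    parent = PhasedGenotype((HET,) * 4)
    offspring = [
        (
            tuple(HET[s] for s in pat[k]),
            tuple(HET[s] for s in mat[k]),
        )
        for k in range(500)
    ]
    fam = _family(("A", "B", "C", "D"), offspring)
    stacked = np.vstack([pat, mat])
    for g, h, i, j in [("A", "B", 1, 2), ("A", "D", 1, 4), ("B", "C", 2, 3)]:
        from_alleles = count_recombinants(fam, g, h)
        from_sources = empirical_r(stacked, i, j)
        assert from_alleles.informative == from_sources.informative
        assert from_alleles.recombinant == from_sources.recombinant


def test_estimate_all_r_counts_pairs(linked_family):
    ests = estimate_all_r(linked_family)
    assert [tuple(e.pair) for e in ests] == [("A", "B"), ("A", "C"), ("B", "C")]
    fam2 = _family(("A", "B"), [(("0", "0"), ("0", "0"))])
    assert len(estimate_all_r(fam2)) == 1


def test_adjacent_estimates_recover_simulation_p(linked_family):
    """r(adjacent) estimates from the generated family fall within 3
    binomial SE of the true per-step value p = 0.05."""
    ests = {tuple(e.pair): e for e in estimate_all_r(linked_family)}
    for pair in (("A", "B"), ("B", "C")):
        est = ests[pair]
        se = (0.05 * 0.95 / est.informative) ** 0.5
        assert abs(est.r_hat - 0.05) <= 3 * se


def _estimates_from_r(r_by_pair, informative=1000):
    return [
        PairwiseREstimate(pair, informative, round(r * informative))
        for pair, r in r_by_pair.items()
    ]


def test_infer_order_from_consistent_triplet():
    """r(AC) = combine(r(AB), r(BC)) pins B in the middle."""
    ests = _estimates_from_r(
        {("A", "B"): 0.25, ("B", "C"): 0.25, ("A", "C"): 0.375}
    )
    result = infer_order(ests)
    assert result.orders == (("A", "B", "C"), ("C", "B", "A"))
    assert result.mode == "normal"
    assert result.distances == pytest.approx(
        (morgan_m_from_r(0.25), morgan_m_from_r(0.25))
    )
    # the winner's additivity residual undercuts every other order
    residuals = result.diagnostics["residuals_by_order"]
    assert all(
        residuals[o] >= result.diagnostics["residual"] for o in residuals
    )


def test_infer_order_two_genes_trivial():
    ests = _estimates_from_r({("A", "B"): 0.1})
    result = infer_order(ests)
    assert result.orders == (("A", "B"), ("B", "A"))
    assert result.diagnostics["residual"] == 0.0


def test_infer_order_flags_unlinked_pair():
    ests = _estimates_from_r({("A", "B"): 0.5})
    result = infer_order(ests)
    assert ("A", "B") in result.diagnostics["unlinked_pairs"]
    assert np.isnan(result.distances[0])


def test_infer_order_guards():
    with pytest.raises(HotspotSignalError):
        infer_order(_estimates_from_r({("A", "B"): 0.9}))
    with pytest.raises(ValueError):
        infer_order([PairwiseREstimate(("A", "B"), 0, 0)])
    many = {
        (f"g{i}", f"g{j}"): 0.01 * (j - i)
        for i in range(9)
        for j in range(i + 1, 9)
    }
    with pytest.raises(ValueError):
        infer_order(_estimates_from_r(many))
    with pytest.raises(ValueError):
        infer_order(_estimates_from_r({("A", "B"): 0.1, ("A", "C"): 0.2}))


def test_four_gene_order_recovered_from_simulation():
    spec = SynthSpec(
        ("N", "E", "W", "S"), (0, 1, 2, 3), p=0.05, n_offspring=5000, seed=21
    )
    result = infer_order(estimate_all_r(generate_family(spec)))
    assert ("N", "E", "W", "S") in result.orders


def test_three_gene_order_recovery_rate():
    """With 1000 offspring at p = 0.05 the true order is recovered (up
    to reversal) in at least 19 of 20 seeded replicates."""
    hits = 0
    for seed in range(20):
        spec = SynthSpec(("A", "B", "C"), (0, 1, 2), p=0.05, n_offspring=1000, seed=seed)
        result = infer_order(estimate_all_r(generate_family(spec)))
        hits += ("A", "B", "C") in result.orders
    assert hits >= 19


def test_double_crossover_rate_matches_no_interference_product():
    spec = SynthSpec(("A", "B", "C"), (0, 1, 2), p=0.1, n_offspring=10_000, seed=13)
    fam = generate_family(spec)
    report = double_crossover_rate(fam, "B", ("A", "C"))
    assert report.informative == 20_000
    ests = {tuple(e.pair): e.r_hat for e in estimate_all_r(fam)}
    assert report.expected == ests[("A", "B")] * ests[("B", "C")]
    se = (0.01 * 0.99 / report.informative) ** 0.5
    assert abs(report.observed - 0.01) <= 3 * se  # p^2 = r(1)^2


def test_double_crossover_requires_informative_meioses():
    fam = _family(
        ("A", "B", "C"),
        [(("0", "0", "0"), ("0", "0", "0"))],
        father=PhasedGenotype((("0", "0"),) * 3),
        mother=PhasedGenotype((("0", "0"),) * 3),
    )
    with pytest.raises(ValueError):
        double_crossover_rate(fam, "B", ("A", "C"))
    with pytest.raises(ValueError):
        double_crossover_rate(fam, "B", ("A", "B"))


def test_zero_double_crossovers_reported_as_zero():
    parental = (("0", "0", "0"), ("0", "0", "0"))
    recomb_last = (("0", "0", "1"), ("0", "0", "0"))  # single crossover B|C
    fam = _family(("A", "B", "C"), [parental] * 6 + [recomb_last] * 2)
    assert double_crossover_rate(fam, "B", ("A", "C")).observed == 0.0


def test_diagnose_requires_a_signal_above_half(linked_family):
    with pytest.raises(ValueError):
        diagnose_mode(estimate_all_r(linked_family), linked_family)


def test_diagnose_hotspot_identifies_unique_middle_gene(hotspot_family):
    """At p = 0.9 per step, r(AB) and r(BC) sit near 0.9 while r(AC)
    drops to the mirrored even-distance value 0.18; only B satisfies the
    parity-composition consistency check as the middle gene."""
    ests = estimate_all_r(hotspot_family)
    result = diagnose_mode(ests, hotspot_family)
    hotspot = result.diagnostics["hotspot"]
    passing = [m for m, c in hotspot["candidates"].items() if c["consistent"]]
    assert passing == ["B"]
    assert hotspot["middle"] == "B"
    dco = hotspot["double_crossover"]
    # the hotspot reading must explain the outer pair via double crossovers
    lookup = {tuple(e.pair): e.r_hat for e in ests}
    assert dco.expected == lookup[("A", "B")] * lookup[("B", "C")]
    se = (dco.expected * (1 - dco.expected) / dco.informative) ** 0.5
    assert abs(dco.observed - dco.expected) <= 3 * se


def test_diagnose_relabel_branch_restores_low_recombination():
    """A family simulated at p = 0.1 whose gene-A phase labels were
    recorded backwards shows r(AB), r(AC) near 0.9; the flip search
    finds exactly {A} and restores all estimates below 1/2."""
    spec = SynthSpec(("A", "B", "C"), (0, 1, 2), p=0.1, n_offspring=2000, seed=5)
    truth = generate_family(spec)
    garbled = truth.flip_gene_phase("A")
    ests = estimate_all_r(garbled)
    lookup = {tuple(e.pair): e.r_hat for e in ests}
    assert lookup[("A", "B")] > 0.5 and lookup[("A", "C")] > 0.5

    result = diagnose_mode(ests, garbled)
    relabel = result.diagnostics["relabel"]
    assert relabel["flips"] == ("A",)
    assert relabel["pairs_above_half"] == 0
    restored = {tuple(e.pair): e for e in relabel["estimates"]}
    original = {tuple(e.pair): e for e in estimate_all_r(truth)}
    for pair, est in restored.items():
        assert est.recombinant == original[pair].recombinant
    assert relabel["order"] in (("A", "B", "C"), ("C", "B", "A"))


def test_diagnose_reports_both_branches_when_data_cannot_decide(hotspot_family):
    """Pairwise data alone cannot separate a hotspot from a phase
    relabelling: both branches are internally consistent here and the
    verdict stays undetermined."""
    result = diagnose_mode(estimate_all_r(hotspot_family), hotspot_family)
    assert result.mode == "undetermined"
    assert result.diagnostics["relabel"]["pairs_above_half"] == 0
    assert result.diagnostics["hotspot"]["middle"] == "B"


def test_phase_flip_is_an_involution(hotspot_family):
    flipped_twice = hotspot_family.flip_gene_phase("B").flip_gene_phase("B")
    assert flipped_twice == hotspot_family


def test_consistency_check_uses_parity_composition():
    """The hotspot check encodes r_outer = r1 + r2 - 2 r1 r2 with the
    true jumping-model values: at p = 0.9, combine(0.9, 0.9) = 0.18."""
    chain = TwoStateChain(0.9)
    assert combine_r(recomb_prob(chain, 1), recomb_prob(chain, 1)) == pytest.approx(
        recomb_prob(chain, 2), abs=1e-12
    )
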