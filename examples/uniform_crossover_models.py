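"""The uniform 1-crossover model and why its 2-crossover extension fails.

Shows the linear recombination law r = d/n, the fragility of
segregation to the start-chromosome bias q, the independence gap, and
the non-monotone large-n 2-crossover curve with its maximum at 63% of
the chromosome length.
"""

from fractions import Fraction

from jumpcross import (
    Uniform1Params,
    Uniform2Params,
    u1_independence_gap,
    u1_inherit_prob,
    u1_recomb_prob,
    u2_argmax,
    u2_recomb_prob_exact,
    u2_recomb_prob_limit,
)

params = Uniform1Params(10)
print("uniform 1-crossover, n = 10 genes:")
for i, j in [(3, 6), (1, 10)]:
    print(f"  r(gene {i}, gene {j}) = {u1_recomb_prob(params, i, j)}  (= d/n)")

biased = Uniform1Params(10, Fraction(9, 10))
print(
    f"\n  start bias q = 9/10 -> P(inherit gene 2 from chromosome I) = "
    f"{u1_inherit_prob(biased, 2)} (segregation law broken; 1/2 only at q = 1/2)"
)
print(
    f"  independence gap for genes (1, 10): {u1_independence_gap(params, 1, 10)}"
    " (0 would mean independent assortment)"
)

print("\nuniform 2-crossover:")
print(f"  exact r at n=4, d=2: {u2_recomb_prob_exact(Uniform2Params(4), 2)}")
print(f"  large-n limit at x=0.5: {u2_recomb_prob_limit(0.5):.4f}")
x_star, p_max = u2_argmax()
print(
    f"  maximum r = {p_max:.4f} at x = {x_star:.4f} "
    f"(~{100 * x_star:.0f}% of the chromosome)"
)
print(
    "\nThe 2-crossover curve decreases beyond that point, so more distant\n"
    "genes would recombine *less* -- the model breaks the linkage property."
)
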