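"""The jumping model: closed-form recombination, hotspot alternation,
and the Haldane/Morgan map limit."""

from jumpcross import (
    TwoStateChain,
    combine_r,
    mode_classify,
    morgan_m_from_r,
    morgan_r_from_m,
    recomb_prob,
    source_independence_gap,
)

cold = TwoStateChain(0.1)
print(f"p = 0.1 ({mode_classify(cold)} mode): r(d) = (1 - 0.8^d)/2")
for d in (1, 2, 3, 10, 100):
    print(f"  d = {d:>3}: r = {recomb_prob(cold, d):.4f}")
print(
    f"  interval composition: combine_r(r(1), r(1)) = "
    f"{combine_r(recomb_prob(cold, 1), recomb_prob(cold, 1)):.4f} = r(2)"
)
print(
    f"  independence gap genes (1, 2): {source_independence_gap(cold, 1, 2):.4f}; "
    f"genes (1, 101): {source_independence_gap(cold, 1, 101):.2e}"
)

hot = TwoStateChain(0.9)
print(f"\np = 0.9 ({mode_classify(hot)} mode): r alternates with distance parity")
for d in (1, 2, 3, 4):
    print(f"  d = {d}: r = {recomb_prob(hot, d):.4f}")
print("  even distances equal the p = 0.1 values; odd distances exceed 1/2.")

m = 0.2
print(f"\nHaldane map at m = {m} Morgans: r = {morgan_r_from_m(m):.6f}")
print(f"  inverse: m(r) = {morgan_m_from_r(morgan_r_from_m(m)):.6f}")
p = 1e-4
print(
    f"  jumping model at p = {p}, d = {round(m / p)} steps: "
    f"r = {recomb_prob(TwoStateChain(p), round(m / p)):.6f} "
    "(the discrete chain converges to Haldane's map as p -> 0)"
)
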