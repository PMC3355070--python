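"""Exact Mendelian cross enumeration: the 3:1 and 9:3:3:1 ratios.

Crosses two heterozygotes at one gene, then two double heterozygotes at
two genes, and prints the exact genotype and phenotype distributions.
"""

from jumpcross import cross_multi_gene, cross_single_gene, genotype, phenotype_ratio

mono = cross_single_gene(genotype("A", "A", "a"), genotype("A", "A", "a"))
print("Aa x Aa genotypes:")
for combo, prob in sorted(mono.outcomes.items(), key=str):
    print(f"  {combo[0]}: {prob}")
print("phenotypes:", dict(phenotype_ratio(mono, {"A": "A"})))

parents = [genotype("A", "A", "a"), genotype("B", "B", "b")]
di = cross_multi_gene(parents, parents)
print("\nAaBb x AaBb phenotypes (9:3:3:1):")
for pheno, prob in sorted(phenotype_ratio(di, {"A": "A", "B": "B"}).items()):
    print(f"  {','.join(pheno)}: {prob}")

print(
    "\nEach probability is exact: segregation contributes 1/2 per allele and\n"
    "independent assortment multiplies across genes, so the double-dominant\n"
    "class collects 9 of the 16 equally likely assortments."
)
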