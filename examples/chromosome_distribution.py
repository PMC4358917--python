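"""Test whether gene placement is random with respect to chromosome size.

Compares a clustered configuration against the length-proportional null via
the Monte-Carlo chi-square test, and prints a k-value subfamily profile.
"""

from abc_evolve.classify import SubfamilyAssignment
from abc_evolve.genomics import chrom_distribution_test, k_profile
from abc_evolve.io_formats import GeneLocus

lengths = {"c1": 50_000_000, "c2": 30_000_000, "c3": 20_000_000}

# 20 genes, 15 crowded onto the shortest chromosome
loci = [GeneLocus(f"g{i}", "c3" if i <= 15 else "c1", i * 10_000, i * 10_000 + 500)
        for i in range(1, 21)]
res = chrom_distribution_test(loci, lengths, n_mc=10_000, seed=0)
print("observed counts :", dict(zip(res.chroms, res.observed)))
print("expected counts :", {c: round(e, 1) for c, e in zip(res.chroms, res.expected)})
print(f"chi-square statistic = {res.statistic:.2f},  Monte-Carlo p = {res.p_value:.4f}")
print("(small p: the distribution is non-random with respect to chromosome size)\n")

assigns = [SubfamilyAssignment(f"p{i}", "G_PDR", "x") for i in range(10)]
assigns += [SubfamilyAssignment(f"q{i}", "B", "x") for i in range(4)]
profile = k_profile(assigns, proteome_size=20_000)
print(profile[profile["count"] > 0].to_string(index=False))
print("(k = subfamily count / proteome size: comparable across species)")
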