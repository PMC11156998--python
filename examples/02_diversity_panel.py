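"""Per-population diversity panel: Pn, Ho, He, windowed pi and IBS distance.

On a neutral Balding-Nichols cohort with a uniform ancestral frequency law
the expected heterozygosity is close to 1/3, and the drift F = 0.05 keeps
the three populations mildly differentiated.
"""

from popsig import SimConfig, diversity_summary, simulate

g, pops, _ = simulate(SimConfig(seed=2))
table = diversity_summary(g, pops)
print(table.round(4).to_string())
# pn:       fraction of SNPs with MAF > 0.01 in the population
# ho/he:    observed vs expected heterozygosity (He > Ho under drift)
# pi:       average per-bp nucleotide diversity in 100 kb windows
# d:        mean IBS distance between individuals within the population
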