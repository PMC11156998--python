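"""Simulate a three-population cohort and write it as VCF + population map.

The generator draws ancestral allele frequencies from Beta(1,1), drifts
each population with a Balding-Nichols parameter F = 0.05, and emits
diploid genotypes for 10 samples per population on two 10 Mb chromosomes.
"""

from popsig import SimConfig, Sweep, Tract, simulate, write_population_map, write_vcf

cfg = SimConfig(
    sweeps=(Sweep("pop1", "1", 3_000_001, 3_100_000, max_maf=0.02),),
    roh_tracts=(Tract("pop1_01", "2", 5_000_000, 5_400_000),),
    seed=1,
)
g, pops, truth = simulate(cfg)
write_vcf(g, "cohort.vcf")
write_population_map(pops, "cohort.popmap.tsv")

print(f"samples:  {g.n_samples}  ({', '.join(pops.populations)})")
print(f"variants: {g.n_variants} SNPs on chromosomes {g.chroms}")
print(f"planted sweep SNPs:  {truth.sweep_registry['n_snps'].iloc[0]}")
print(f"planted tract SNPs:  {truth.tract_registry['n_snps'].iloc[0]}")
# The sweep depletes minor alleles of pop1 in a 100 kb window; the tract
# forces one sample homozygous across 400 kb — both are recoverable truth
# for the scan and ROH examples.
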