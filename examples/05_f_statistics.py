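"""f3 admixture and f4 topology tests with block-jackknife Z-scores.

pop_mix is constructed as a 50/50 frequency mixture of pop_b and pop_c;
f3(pop_mix; pop_b, pop_c) is then negative with a strongly negative Z,
the classical admixture signal.  Unadmixed targets give positive f3.
"""

import numpy as np

from popsig import PopulationMap, f3, f4
from popsig.io import GenotypeMatrix
import pandas as pd

rng = np.random.default_rng(5)
n_sites = 25_000
p_anc = rng.uniform(0.05, 0.95, n_sites)
lam = (1 - 0.2) / 0.2
freqs = {
    "pop_b": rng.beta(p_anc * lam, (1 - p_anc) * lam),
    "pop_c": rng.beta(p_anc * lam, (1 - p_anc) * lam),
    "pop_d": rng.beta(p_anc * lam, (1 - p_anc) * lam),
}
freqs["pop_mix"] = (freqs["pop_b"] + freqs["pop_c"]) / 2

samples, rows = [], []
for pop, p in freqs.items():
    for i in range(8):
        samples.append(f"{pop}_{i}")
        rows.append(rng.binomial(2, p))
g = GenotypeMatrix(
    samples,
    pd.DataFrame({"chrom": "1", "pos": np.arange(n_sites) * 100 + 1,
                  "ref": "A", "alt": "G"}),
    np.array(rows, dtype=np.int8),
)
pops = PopulationMap({s: s.rsplit("_", 1)[0] for s in samples})

r = f3(g, pops, "pop_mix", "pop_b", "pop_c", correct_target_het=True)
print(f"f3(pop_mix; pop_b, pop_c) = {r.value:.5f}  SE {r.se:.5f}  Z {r.z:.1f}")
r = f3(g, pops, "pop_d", "pop_b", "pop_c", correct_target_het=True)
print(f"f3(pop_d;   pop_b, pop_c) = {r.value:.5f}  SE {r.se:.5f}  Z {r.z:.1f}")
r = f4(g, pops, "pop_mix", "pop_d", "pop_b", "pop_c")
print(f"f4(pop_mix, pop_d; pop_b, pop_c) = {r.value:.6f}  Z {r.z:.1f}")
# A significantly negative f3 Z marks the target as admixed; the f4 sign
# indicates which cross-pairs of the quartet share gene flow.
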