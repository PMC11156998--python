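"""Balding-Nichols cohort simulator with planted sweeps and autozygous tracts.

The generator emulates the statistical structure a multi-population
resequencing cohort presents to the analysis stages, without a linkage or
read-level model (every implemented statistic is frequency- or
genotype-run-based):

* ancestral alt-allele frequencies p ~ Beta(alpha, beta) per SNP;
* per-population frequencies p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F) — the
  Balding-Nichols drift law, whose closed-form moments
  (E[p_k] = p, Var[p_k] = F p(1-p)) make FST expectations analytic;
* genotypes ~ Binomial(2, p_k) per diploid sample, i.i.d. across samples;
* *sweeps*: inside a registered window the target population's frequencies
  are redrawn so the minor allele frequency is at most a residual ceiling
  (depleted diversity, elevated differentiation);
* *autozygous tracts*: a named sample's genotypes inside a registered span
  are forced homozygous for the population-major allele; the two SNPs
  immediately flanking each end are forced heterozygous so the planted
  extent is identifiable against the homozygosity of the background (the
  run would otherwise extend stochastically past the tract);
* missing calls dropped i.i.d. at ``missing_rate``; planted tract calls
  (and their flanks) are exempt, so the planted extent survives masking.

Everything is reproducible from the config seed; the same config yields a
byte-identical VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class Sweep:
    """A planted sweep: depleted minor-allele frequency in one population."""

    pop: str
    chrom: str
    start: int
    end: int  # inclusive bp span
    max_maf: float = 0.02


@dataclass
class Tract:
    """A planted autozygous tract in one sample."""

    sample: str
    chrom: str
    start: int
    end: int


@dataclass
class SimConfig:
    """Full parameterization of a synthetic cohort.

    Defaults give 3 populations x 10 diploid samples on 2 chromosomes of
    10 Mb with 40,000 SNPs total — enough density (2 SNPs/kb) for every
    window- and run-based statistic, and small enough to run the whole
    pipeline in seconds.  The uniform ancestral frequency law
    (Beta(1, 1)) yields an expected heterozygosity of 1/3, in the range
    seen in outbred livestock cohorts.
    """

    pop_names: tuple[str, ...] = ("pop1", "pop2", "pop3")
    samples_per_pop: int = 10
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 10_000_000, "2": 10_000_000}
    )
    n_snps: int = 40_000
    beta_params: tuple[float, float] = (1.0, 1.0)
    drift: float | dict[str, float] = 0.05
    sweeps: tuple[Sweep, ...] = ()
    roh_tracts: tuple[Tract, ...] = ()
    missing_rate: float = 0.01
    seed: int = 0

    def drift_of(self, pop: str) -> float:
        f = self.drift[pop] if isinstance(self.drift, dict) else self.drift
        if not 0 < f < 1:
            raise ValueError(f"drift F for {pop!r} must be in (0,1), got {f}")
        return f

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{pop}_{i:02d}"
            for pop in self.pop_names
            for i in range(1, self.samples_per_pop + 1)
        ]

    def validate(self) -> None:
        if self.samples_per_pop < 1:
            raise ValueError("samples_per_pop must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        names = set(self.sample_names)
        seen: set[tuple[str, str]] = set()
        for sw in self.sweeps:
            if sw.pop not in self.pop_names:
                raise ValueError(f"sweep names unknown population {sw.pop!r}")
            self._check_span(sw.chrom, sw.start, sw.end)
            for other in self.sweeps:
                if other is not sw and other.pop == sw.pop and other.chrom == sw.chrom:
                    if not (sw.end < other.start or other.end < sw.start):
                        raise ValueError(
                            f"overlapping sweeps on {sw.pop}/{sw.chrom}"
                        )
            seen.add((sw.pop, sw.chrom))
        for t in self.roh_tracts:
            if t.sample not in names:
                raise ValueError(f"tract names unknown sample {t.sample!r}")
            self._check_span(t.chrom, t.start, t.end)

    def _check_span(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 1 <= start <= end <= self.chrom_lengths[chrom]:
            raise ValueError(f"span {start}-{end} outside chromosome {chrom}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the genotypes.

    ``freqs`` holds the realized per-population per-site frequencies;
    ``sweep_registry``/``tract_registry`` carry the planted features with
    coordinates snapped to the first/last SNP actually inside each span,
    so they match the emitted VCF exactly.
    """

    freqs: dict[str, np.ndarray]
    ancestral: np.ndarray
    sweep_registry: pd.DataFrame  # pop, chrom, start, end, snp_start, snp_end, n_snps
    tract_registry: pd.DataFrame  # sample, chrom, start, end, snp_start, snp_end, n_snps


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Draw a cohort under the Balding-Nichols model (see module docstring)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    alpha, beta = cfg.beta_params

    # SNP positions: uniform without replacement per chromosome, sorted
    chrom_col, pos_col = [], []
    total_len = sum(cfg.chrom_lengths.values())
    remaining = cfg.n_snps
    items = list(cfg.chrom_lengths.items())
    for i, (chrom, length) in enumerate(items):
        k = remaining if i == len(items) - 1 else round(cfg.n_snps * length / total_len)
        k = min(k, length)
        remaining -= k
        pos = np.sort(rng.choice(length, size=k, replace=False)) + 1
        chrom_col.extend([chrom] * k)
        pos_col.append(pos)
    pos_all = np.concatenate(pos_col)
    variants = pd.DataFrame(
        {"chrom": chrom_col, "pos": pos_all, "ref": "A", "alt": "G"}
    )
    n_sites = len(variants)
    chrom_arr = variants["chrom"].to_numpy()

    p_anc = rng.beta(alpha, beta, size=n_sites)
    p_anc = np.clip(p_anc, 1e-6, 1 - 1e-6)

    pop_freqs: dict[str, np.ndarray] = {}
    for pop in cfg.pop_names:
        F = cfg.drift_of(pop)
        lam = (1.0 - F) / F
        pk = rng.beta(p_anc * lam, (1.0 - p_anc) * lam)
        pop_freqs[pop] = np.clip(pk, 0.0, 1.0)

    # plant sweeps: redraw target-pop frequencies with MAF <= ceiling
    sweep_rows = []
    for sw in cfg.sweeps:
        mask = (
            (chrom_arr == sw.chrom)
            & (pos_all >= sw.start)
            & (pos_all <= sw.end)
        )
        k = int(mask.sum())
        u = rng.uniform(0.0, sw.max_maf, size=k)
        major_is_alt = p_anc[mask] >= 0.5
        pop_freqs[sw.pop][mask] = np.where(major_is_alt, 1.0 - u, u)
        snp_pos = pos_all[mask]
        sweep_rows.append(
            dict(pop=sw.pop, chrom=sw.chrom, start=sw.start, end=sw.end,
                 snp_start=int(snp_pos[0]) if k else -1,
                 snp_end=int(snp_pos[-1]) if k else -1, n_snps=k)
        )

    samples = cfg.sample_names
    assignments = {s: s.rsplit("_", 1)[0] for s in samples}
    calls = np.empty((len(samples), n_sites), dtype=np.int8)
    for i, s in enumerate(samples):
        pk = pop_freqs[assignments[s]]
        calls[i] = rng.binomial(2, pk).astype(np.int8)

    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls[miss] = MISSING

    # plant autozygous tracts with identifiable het flanks; planting happens
    # after missingness so the forced calls are exempt and the planted
    # extent stays identifiable
    tract_rows = []
    for t in cfg.roh_tracts:
        i = samples.index(t.sample)
        pk = pop_freqs[assignments[t.sample]]
        on_chrom = np.flatnonzero(chrom_arr == t.chrom)
        inside = on_chrom[
            (pos_all[on_chrom] >= t.start) & (pos_all[on_chrom] <= t.end)
        ]
        if inside.size == 0:
            raise ValueError(f"tract {t} contains no SNP")
        calls[i, inside] = np.where(pk[inside] >= 0.5, 2, 0).astype(np.int8)
        lo, hi = inside[0], inside[-1]
        for flank in (lo - 1, lo - 2, hi + 1, hi + 2):
            if 0 <= flank < n_sites and chrom_arr[flank] == t.chrom:
                calls[i, flank] = 1
        tract_rows.append(
            dict(sample=t.sample, chrom=t.chrom, start=t.start, end=t.end,
                 snp_start=int(pos_all[lo]), snp_end=int(pos_all[hi]),
                 n_snps=int(inside.size))
        )

    g = GenotypeMatrix(samples, variants, calls)
    pops = PopulationMap(assignments)
    truth = SimTruth(
        freqs=pop_freqs,
        ancestral=p_anc,
        sweep_registry=pd.DataFrame(
            sweep_rows,
            columns=["pop", "chrom", "start", "end", "snp_start", "snp_end", "n_snps"],
        ),
        tract_registry=pd.DataFrame(
            tract_rows,
            columns=["sample", "chrom", "start", "end", "snp_start", "snp_end", "n_snps"],
        ),
    )
    return g, pops, truth


def sweep_grid_config(
    n_sweeps: int = 12,
    seed: int = 0,
    window: int = 100_000,
    chrom_length: int = 45_000_000,
    n_chroms: int = 3,
    snps_per_mb: int = 500,
    drift: float = 0.05,
    max_maf: float = 0.02,
    target_pop: str = "pop1",
) -> SimConfig:
    """A larger cohort for sweep-recovery benchmarking: ``n_sweeps``
    window-aligned 100 kb sweeps in the target population spread over a
    multi-chromosome genome with thousands of neutral windows."""
    chroms = {str(c + 1): chrom_length for c in range(n_chroms)}
    sweeps = []
    # evenly spaced, window-aligned, away from chromosome ends
    per_chrom = -(-n_sweeps // n_chroms)
    k = 0
    for chrom in chroms:
        for j in range(per_chrom):
            if k >= n_sweeps:
                break
            start = (2_000_000 + j * ((chrom_length - 4_000_000) // per_chrom))
            start = (start // window) * window + 1  # align to the window grid
            sweeps.append(
                Sweep(pop=target_pop, chrom=chrom, start=start,
                      end=start + window - 1, max_maf=max_maf)
            )
            k += 1
    return SimConfig(
        chrom_lengths=chroms,
        n_snps=int(snps_per_mb * n_chroms * chrom_length / 1_000_000),
        drift=drift,
        sweeps=tuple(sweeps),
        seed=seed,
    )
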