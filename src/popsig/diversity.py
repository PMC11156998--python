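"""Per-population genome diversity metrics.

Covers the classical panel reported for resequencing cohorts: the
proportion of polymorphic SNPs (Pn, MAF > 0.01), observed and expected
heterozygosity (Ho, He), windowed nucleotide diversity pi (100 kb windows,
50 kb step), and the identity-by-state pairwise distance D = 1 - DST with
DST = (IBS2 + 0.5*IBS1)/N.

Conventions: all mean +/- SD summaries use the sample SD (n-1 denominator);
pi follows the VCFtools "windowed-pi" dialect — unbiased per-site estimator
2*p*(1-p)*m/(m-1) with m the number of called alleles, summed and divided
by the nominal window length in bp (monomorphic positions included in the
denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, AlleleFrequency, GenotypeMatrix, PopulationMap, allele_frequencies
from .windows import window_grid, window_sums


def prop_polymorphic(freqs: AlleleFrequency, maf_threshold: float = 0.01) -> float:
    """Fraction of defined sites with minor allele frequency strictly > threshold."""
    defined = freqs.defined
    n_def = int(defined.sum())
    if n_def == 0:
        raise ValueError("no sites with defined allele frequency")
    maf = freqs.maf[defined]
    return float((maf > maf_threshold).sum() / n_def)


def observed_heterozygosity(
    g: GenotypeMatrix, pops: PopulationMap | None = None
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-sample Ho = het calls / non-missing calls, and per-population mean +/- SD.

    Samples with no non-missing call get NaN and are excluded from the
    population mean.  Returns ``(per_sample, per_population)``; the second
    element is None when no population map is given.
    """
    het = (g.calls == 1).sum(axis=1)
    called = (g.calls != MISSING).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ho = np.where(called > 0, het / called, np.nan)
    per_sample = pd.Series(ho, index=g.samples, name="ho")
    if pops is None:
        return per_sample, None
    rows = []
    for pop in pops.populations:
        vals = per_sample.reindex(pops.samples_of(pop)).dropna()
        rows.append(
            {
                "population": pop,
                "n": len(vals),
                "ho_mean": vals.mean(),
                "ho_sd": vals.std(ddof=1),
            }
        )
    return per_sample, pd.DataFrame(rows).set_index("population")


def expected_heterozygosity(freqs: AlleleFrequency) -> tuple[float, float]:
    """He = mean over polymorphic sites of 2p(1-p); returns (mean, SD over sites)."""
    p = freqs.p[freqs.defined]
    p = p[(p > 0) & (p < 1)]
    if p.size == 0:
        raise ValueError("no variable sites; expected heterozygosity undefined")
    he = 2.0 * p * (1.0 - p)
    sd = float(np.std(he, ddof=1)) if he.size > 1 else 0.0
    return float(he.mean()), sd


def nucleotide_diversity_windows(
    g: GenotypeMatrix,
    pops: PopulationMap,
    pop: str,
    window: int = 100_000,
    step: int = 50_000,
) -> pd.DataFrame:
    """Windowed nucleotide diversity for one population.

    Per-site pi is the mean pairwise difference among the ``m`` called
    alleles, ``2*p*(1-p)*m/(m-1)``; window pi is the site sum divided by the
    nominal window length in bp.  Empty windows are emitted with pi = 0.
    """
    af = allele_frequencies(g, pops)[pop]
    p = af.p
    m = 2.0 * af.n_called
    with np.errstate(divide="ignore", invalid="ignore"):
        site_pi = np.where(m > 1, 2.0 * p * (1.0 - p) * m / (m - 1.0), 0.0)
    site_pi = np.nan_to_num(site_pi)
    out = []
    for chrom in g.chroms:
        sl = g.chrom_slice(chrom)
        pos = g.variants["pos"].to_numpy()[sl]
        starts = window_grid(int(pos[0]), int(pos[-1]), window, step)
        sums, counts = window_sums(pos, starts, window, site_pi[sl])
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window,
                    "n_snps": counts,
                    "pi": sums / window,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


@dataclass
class PairwiseDistance:
    """IBS sharing and distance for every unordered sample pair."""

    samples: list[str]
    table: pd.DataFrame  # sample_a, sample_b, ibs0, ibs1, ibs2, n, dst, d

    def matrix(self, column: str = "d") -> pd.DataFrame:
        """Square symmetric matrix of ``column`` (diagonal 0 for d, 1 for dst)."""
        n = len(self.samples)
        m = np.zeros((n, n))
        if column == "dst":
            np.fill_diagonal(m, 1.0)
        idx = {s: i for i, s in enumerate(self.samples)}
        for row in self.table.itertuples():
            i, j = idx[row.sample_a], idx[row.sample_b]
            v = getattr(row, column)
            m[i, j] = m[j, i] = v
        return pd.DataFrame(m, index=self.samples, columns=self.samples)


def pairwise_ibs_distance(g: GenotypeMatrix) -> PairwiseDistance:
    """IBS-based distance for all sample pairs at mutually called sites.

    IBS2 counts identical genotype classes, IBS0 opposite homozygotes,
    IBS1 the remainder; DST = (IBS2 + 0.5*IBS1)/N and D = 1 - DST.  Pairs
    with no co-called site get NaN distances.
    """
    if g.n_samples < 2:
        raise ValueError("need >=2 samples for pairwise distances")
    rows = []
    calls = g.calls
    for i in range(g.n_samples):
        gi = calls[i]
        for j in range(i + 1, g.n_samples):
            gj = calls[j]
            both = (gi != MISSING) & (gj != MISSING)
            n = int(both.sum())
            if n == 0:
                rows.append(
                    dict(sample_a=g.samples[i], sample_b=g.samples[j],
                         ibs0=0, ibs1=0, ibs2=0, n=0, dst=np.nan, d=np.nan)
                )
                continue
            a, b = gi[both], gj[both]
            ibs2 = int((a == b).sum())
            ibs0 = int((np.abs(a.astype(np.int16) - b) == 2).sum())
            ibs1 = n - ibs2 - ibs0
            dst = (ibs2 + 0.5 * ibs1) / n
            rows.append(
                dict(sample_a=g.samples[i], sample_b=g.samples[j],
                     ibs0=ibs0, ibs1=ibs1, ibs2=ibs2, n=n, dst=dst, d=1.0 - dst)
            )
    return PairwiseDistance(list(g.samples), pd.DataFrame(rows))


def diversity_summary(
    g: GenotypeMatrix,
    pops: PopulationMap,
    froh_by_sample: pd.Series | None = None,
    pi_window: int = 100_000,
    pi_step: int = 50_000,
) -> pd.DataFrame:
    """Population summary table: Pn, Ho, He, (F_ROH,) pi, D — mean +/- SD.

    Mirrors the layout of a per-population diversity table in a
    resequencing study.  ``froh_by_sample`` (if given) is averaged within
    populations.
    """
    freqs = allele_frequencies(g, pops)
    ho_sample, ho_pop = observed_heterozygosity(g, pops)
    dist = pairwise_ibs_distance(g)
    rows = []
    for pop in pops.populations:
        members = set(pops.samples_of(pop))
        he_mean, he_sd = expected_heterozygosity(freqs[pop])
        piw = nucleotide_diversity_windows(g, pops, pop, pi_window, pi_step)
        within = dist.table[
            dist.table["sample_a"].isin(members) & dist.table["sample_b"].isin(members)
        ]["d"].dropna()
        row = {
            "population": pop,
            "n": len(members),
            "pn": prop_polymorphic(freqs[pop]),
            "ho_mean": ho_pop.loc[pop, "ho_mean"],
            "ho_sd": ho_pop.loc[pop, "ho_sd"],
            "he_mean": he_mean,
            "he_sd": he_sd,
            "pi_mean": piw["pi"].mean(),
            "pi_sd": piw["pi"].std(ddof=1),
            "d_mean": within.mean(),
            "d_sd": within.std(ddof=1),
        }
        if froh_by_sample is not None:
            fr = froh_by_sample.reindex(sorted(members)).dropna()
            row["froh_mean"] = fr.mean()
            row["froh_sd"] = fr.std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("population")
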