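"""VCF and population-map ingestion into an in-memory genotype matrix.

Genotypes are stored as a dense ``int8`` array of unordered genotype classes
(0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing); phasing is deliberately
discarded because every statistic in this package depends only on the
genotype class.  Variants must be biallelic SNPs; multiallelic and indel
records are skipped (with a logged count) or rejected, mirroring the usual
"biallelic autosomal SNPs" contract of resequencing studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING: int = -1

#: cyvcf2 gt_types codes -> our genotype classes
_CYVCF2_MAP = {0: 0, 1: 1, 2: MISSING, 3: 2}


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for ``samples`` x ``variants``.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    variants
        DataFrame with columns ``chrom``, ``pos`` (1-based, as in VCF),
        ``ref``, ``alt``; positions strictly increasing within a chromosome.
    calls
        ``(n_samples, n_variants)`` int8 array over {0, 1, 2, -1}.
    """

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.samples) < 1 or len(self.variants) < 1:
            raise ValueError("GenotypeMatrix needs >=1 sample and >=1 variant")
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain symbols outside {0,1,2,missing}")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chroms(self) -> list[str]:
        return list(self.variants["chrom"].unique())

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def chrom_slice(self, chrom: str) -> slice:
        """Column slice of a chromosome (variants are chrom-grouped)."""
        idx = np.flatnonzero((self.variants["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no variants on chromosome {chrom!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class PopulationMap:
    """Assignment of samples to population labels."""

    assignments: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def samples_of(self, pop: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == pop]
        if not out:
            raise KeyError(f"unknown population {pop!r}")
        return out

    def validate_against(self, g: GenotypeMatrix, min_per_pop: int = 2) -> None:
        """Check every assigned sample exists and populations are usable.

        Frequency-based statistics need at least ``min_per_pop`` samples per
        population.
        """
        missing = [s for s in self.assignments if s not in g.samples]
        if missing:
            raise ValueError(f"samples not in genotype matrix: {missing}")
        for pop in self.populations:
            n = len(self.samples_of(pop))
            if n < min_per_pop:
                raise ValueError(
                    f"population {pop!r} has {n} sample(s); >= {min_per_pop} required"
                )


@dataclass
class AlleleFrequency:
    """Per-variant alt-allele frequency for one population.

    ``p`` is NaN where no sample in the population has a call; ``n_called``
    counts diploid samples with a non-missing genotype.
    """

    p: np.ndarray
    n_called: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.n_called > 0

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p, 1.0 - self.p)


@dataclass
class VcfReadReport:
    """Accounting of records excluded while reading a VCF."""

    n_kept: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0
    skipped: list[tuple[str, int, str]] = field(default_factory=list)


def read_vcf(
    path: str,
    region_filter: set[str] | None = None,
    skip_non_biallelic: bool = True,
    with_report: bool = False,
):
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped with a logged count when
    ``skip_non_biallelic`` is true, otherwise they raise.  Phased and
    unphased genotypes are treated identically.  Variants are sorted by
    (chromosome in header order, position); duplicate (chrom, pos) raises.

    Returns the matrix, or ``(matrix, VcfReadReport)`` if ``with_report``.
    """
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # htslib reports the offending header/line
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    report = VcfReadReport()
    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if region_filter is not None and rec.CHROM not in region_filter:
            continue
        if len(rec.ALT) != 1:
            if not skip_non_biallelic:
                raise ValueError(
                    f"multiallelic record at {rec.CHROM}:{rec.POS}"
                )
            report.n_multiallelic += 1
            report.skipped.append((rec.CHROM, rec.POS, "multiallelic"))
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            if not skip_non_biallelic:
                raise ValueError(f"non-SNP record at {rec.CHROM}:{rec.POS}")
            report.n_non_snp += 1
            report.skipped.append((rec.CHROM, rec.POS, "non-snp"))
            continue
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        # with gts012=True: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        report.n_kept += 1
    if report.n_multiallelic or report.n_non_snp:
        logger.info(
            "read_vcf(%s): skipped %d multiallelic and %d non-SNP record(s)",
            path,
            report.n_multiallelic,
            report.n_non_snp,
        )
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path!r}")
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": ref, "alt": alt}
    )
    dup = variants.duplicated(subset=["chrom", "pos"])
    if dup.any():
        first = variants[dup].iloc[0]
        raise ValueError(
            f"duplicate record at {first['chrom']}:{first['pos']}"
        )
    calls = np.stack(rows, axis=1)
    # sort by (chrom in order of first appearance, pos)
    order_map = {c: i for i, c in enumerate(dict.fromkeys(chroms))}
    order = np.lexsort(
        (variants["pos"].to_numpy(), variants["chrom"].map(order_map).to_numpy())
    )
    variants = variants.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    g = GenotypeMatrix(samples, variants, calls)
    return (g, report) if with_report else g


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a GT-only VCF 4.2 file that round-trips through :func:`read_vcf`."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popsig\n")
        for chrom in g.chroms:
            sl = g.chrom_slice(chrom)
            length = int(g.variants["pos"].iloc[sl.stop - 1])
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        var = g.variants
        for j in range(g.n_variants):
            fields = [
                str(var["chrom"].iloc[j]),
                str(int(var["pos"].iloc[j])),
                ".",
                str(var["ref"].iloc[j]),
                str(var["alt"].iloc[j]),
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt_str[int(c)] for c in g.calls[:, j]]
            fh.write("\t".join(fields) + "\n")


def read_population_map(path: str) -> PopulationMap:
    """Read a 2-column TSV (sample, population)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return PopulationMap(dict(zip(df["sample"], df["population"])))


def write_population_map(pops: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for s, p in pops.assignments.items():
            fh.write(f"{s}\t{p}\n")


def allele_frequencies(
    g: GenotypeMatrix, pops: PopulationMap
) -> dict[str, AlleleFrequency]:
    """Per-population alt-allele frequencies with site-wise missing exclusion.

    ``p = (het + 2*hom_alt) / (2*n_called)``; NaN where a population has no
    call at a site.  Raises on samples assigned to the map but absent from
    the matrix.
    """
    unknown = [s for s in pops.assignments if s not in g.samples]
    if unknown:
        raise KeyError(f"population map names unknown samples: {unknown}")
    out: dict[str, AlleleFrequency] = {}
    for pop in pops.populations:
        idx = [g.sample_index(s) for s in pops.samples_of(pop)]
        sub = g.calls[idx, :]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        out[pop] = AlleleFrequency(p=p, n_called=n_called)
    return out


def allele_counts(
    g: GenotypeMatrix, pops: PopulationMap
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-population (alt allele count, total called alleles) per site."""
    out = {}
    for pop, af in allele_frequencies(g, pops).items():
        total = 2 * af.n_called
        alt = np.round(np.nan_to_num(af.p) * total).astype(np.int64)
        out[pop] = (alt, total)
    return out
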