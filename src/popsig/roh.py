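"""Runs of homozygosity: PLINK-style scanning-window detection, length-class
binning, and the genomic inbreeding coefficient F_ROH.

Detection follows the two-phase scheme of PLINK ``--homozyg``:

1. slide a window of ``scan_window_snps`` consecutive SNPs along each
   chromosome; a window *hits* when it contains at most
   ``max_het_per_window`` heterozygous and ``max_missing_per_window``
   missing calls;
2. a SNP is *in* a run when the fraction of windows covering it that hit is
   at least ``window_hit_threshold``;
3. maximal consecutive *in* stretches are split at inter-SNP gaps larger
   than ``max_gap_bp``, trimmed so both endpoints are homozygous
   non-missing calls, and filtered by ``min_snps``, ``min_length_bp`` and
   the segment-average density requirement (at least one SNP per
   ``max_bp_per_snp`` bp).

Segment coordinates are the first/last SNP positions of the run (inclusive)
and length = end - start + 1, so F_ROH = sum(length)/L_auto is exact for a
fully homozygous genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

#: autosomal genome length used for F_ROH on real goat data (~2400 Mb)
DEFAULT_AUTOSOME_BP: float = 2.4e9

#: length-class boundaries in bp: [100-150], (150-250], (250-400], (400, inf) kb
ROH_CLASS_EDGES = (100_000, 150_000, 250_000, 400_000)
ROH_CLASS_LABELS = ("roh_100_150kb", "roh_150_250kb", "roh_250_400kb", "roh_gt400kb")


@dataclass
class ROHParams:
    """Thresholds defining an ROH (defaults follow the PLINK settings used
    for ~35M-SNP goat resequencing data; scale them down for sparse
    synthetic genomes)."""

    scan_window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 1
    window_hit_threshold: float = 0.05
    min_snps: int = 50
    min_length_bp: int = 100_000
    max_bp_per_snp: int = 100_000  # density >= 1 SNP / 100 kb
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.scan_window_snps, self.min_snps, self.min_length_bp,
               self.max_bp_per_snp, self.max_gap_bp) <= 0:
            raise ValueError("ROH thresholds must be positive")
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must be in (0, 1]")


_SEG_COLUMNS = ["sample", "chrom", "start", "end", "length", "n_snps"]


def _empty_segments() -> pd.DataFrame:
    return pd.DataFrame(columns=_SEG_COLUMNS).astype(
        {"start": np.int64, "end": np.int64, "length": np.int64, "n_snps": np.int64}
    )


def detect_roh(
    g: GenotypeMatrix, sample: str, params: ROHParams | None = None
) -> pd.DataFrame:
    """Detect ROH segments for one sample; returns a BED-like DataFrame
    (sample, chrom, start, end, length, n_snps), sorted and non-overlapping.

    Chromosomes with fewer SNPs than the scanning window yield no calls
    (logged), not an error.
    """
    params = params or ROHParams()
    gi = g.sample_index(sample)
    rows: list[dict] = []
    for chrom in g.chroms:
        sl = g.chrom_slice(chrom)
        calls = g.calls[gi, sl]
        pos = g.variants["pos"].to_numpy()[sl]
        L = calls.size
        W = params.scan_window_snps
        if L < W:
            logger.info(
                "detect_roh(%s): chromosome %s has %d < %d SNPs; no calls",
                sample, chrom, L, W,
            )
            continue
        het = (calls == 1).astype(np.int64)
        mis = (calls == MISSING).astype(np.int64)
        hcs = np.concatenate([[0], np.cumsum(het)])
        mcs = np.concatenate([[0], np.cumsum(mis)])
        idx = np.arange(L - W + 1)
        hit = (
            (hcs[idx + W] - hcs[idx] <= params.max_het_per_window)
            & (mcs[idx + W] - mcs[idx] <= params.max_missing_per_window)
        ).astype(np.int64)
        hitcs = np.concatenate([[0], np.cumsum(hit)])
        j = np.arange(L)
        w_lo = np.maximum(0, j - W + 1)
        w_hi = np.minimum(j, L - W)
        n_cover = w_hi - w_lo + 1
        n_hits = hitcs[w_hi + 1] - hitcs[w_lo]
        in_run = n_hits >= params.window_hit_threshold * n_cover - 1e-9
        rows.extend(
            _segments_from_in_status(sample, chrom, pos, calls, in_run, params)
        )
    if not rows:
        return _empty_segments()
    df = pd.DataFrame(rows, columns=_SEG_COLUMNS)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _segments_from_in_status(sample, chrom, pos, calls, in_run, params):
    """Phase-3 of detection: split, trim, and filter runs of *in* SNPs."""
    hom = (calls == 0) | (calls == 2)
    rows = []
    # maximal stretches of in_run == True
    edges = np.flatnonzero(np.diff(np.concatenate([[0], in_run.view(np.int8), [0]])))
    for a, b in zip(edges[::2], edges[1::2]):  # [a, b) index stretch
        # split at gaps > max_gap
        gaps = np.flatnonzero(np.diff(pos[a:b]) > params.max_gap_bp) + a + 1
        for lo, hi in zip(np.concatenate([[a], gaps]), np.concatenate([gaps, [b]])):
            # trim endpoints to homozygous non-missing calls
            sub = np.flatnonzero(hom[lo:hi])
            if sub.size == 0:
                continue
            lo2, hi2 = lo + sub[0], lo + sub[-1] + 1
            n_snps = hi2 - lo2
            start, end = int(pos[lo2]), int(pos[hi2 - 1])
            length = end - start + 1
            if n_snps < params.min_snps or length < params.min_length_bp:
                continue
            if n_snps * params.max_bp_per_snp < length:
                continue
            rows.append(
                dict(sample=sample, chrom=chrom, start=start, end=end,
                     length=length, n_snps=n_snps)
            )
    return rows


def detect_roh_all(
    g: GenotypeMatrix, params: ROHParams | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """ROH segments for all (or the given) samples, concatenated."""
    frames = [detect_roh(g, s, params) for s in (samples or g.samples)]
    frames = [f for f in frames if len(f)] or [_empty_segments()]
    return pd.concat(frames, ignore_index=True)


def froh(segments: pd.DataFrame, autosome_length: float = DEFAULT_AUTOSOME_BP) -> float:
    """Genomic inbreeding coefficient: total ROH length / autosomal length."""
    if autosome_length <= 0:
        raise ValueError("autosome_length must be positive")
    if len(segments) == 0:
        return 0.0
    lengths = segments["length"].to_numpy()
    if (lengths <= 0).any():
        raise ValueError("segment lengths must be positive")
    return float(lengths.sum() / autosome_length)


def froh_by_sample(
    segments: pd.DataFrame,
    samples: list[str],
    autosome_length: float = DEFAULT_AUTOSOME_BP,
) -> pd.Series:
    """F_ROH per sample (0 for samples without segments)."""
    out = pd.Series(0.0, index=list(samples), name="froh")
    if len(segments):
        tot = segments.groupby("sample")["length"].sum()
        out.loc[tot.index] = tot / autosome_length
    return out


def categorize_roh(
    segments: pd.DataFrame, pops: PopulationMap | None = None
) -> pd.DataFrame:
    """Count segments per population in the four length classes.

    Classes partition (100 kb, inf) at 150/250/400 kb, the boundary going
    to the lower class.  Segments shorter than 100 kb violate the caller
    contract and raise.
    """
    if len(segments) and (segments["length"] < ROH_CLASS_EDGES[0]).any():
        raise ValueError("segments shorter than 100 kb violate the length contract")
    seg = segments.copy()
    if pops is not None:
        seg["population"] = seg["sample"].map(pops.assignments)
    else:
        seg["population"] = "all"
    bins = list(ROH_CLASS_EDGES) + [np.inf]
    # right-closed: (100k-eps, 150k], (150k, 250k], ...
    seg["length_class"] = pd.cut(
        seg["length"], bins=[ROH_CLASS_EDGES[0] - 1] + bins[1:],
        labels=ROH_CLASS_LABELS, right=True,
    )
    counts = (
        seg.groupby(["population", "length_class"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(ROH_CLASS_LABELS), fill_value=0)
    )
    counts.insert(0, "total", counts.sum(axis=1))
    counts.columns.name = None
    return counts


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Append an overall row and percentage shares to a per-population ROH
    count table with columns (total, four length classes)."""
    out = counts.copy()
    out.loc["overall"] = out.sum(axis=0)
    for col in ROH_CLASS_LABELS:
        out[col + "_pct"] = 100.0 * out[col] / out["total"]
    return out
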