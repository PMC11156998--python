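"""Sliding-window selection-signature scanning.

Two complementary scans over 100 kb windows with a 25 kb step:

* between-population differentiation FST — per-site
  ``1 - (p1*q1 + p2*q2) / (2*pbar*qbar)`` averaged within windows (the
  two-deme Nei/Hudson-style dialect), with Weir-Cockerham and Hudson
  ratio-of-sums dialects available for estimation of the drift parameter;
* within-population pooled heterozygosity
  ``Hp = 2*sum(nMaj)*sum(nMin) / (sum(nMaj)+sum(nMin))^2`` over per-SNP
  major/minor allele counts, depressed in swept windows.

Both scans are Z-standardized genome-wide; windows simultaneously in the
top 1% of Z(FST) and the bottom 1% of Z(Hp) are merged into candidate
selection regions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationMap, allele_frequencies
from .windows import window_grid, window_sums

FST_DIALECTS = ("mean", "wc", "hudson")


def site_fst(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-site two-population FST, ``1 - (p1q1 + p2q2)/(2*pbar*qbar)``.

    Algebraically equal to ``(p1-p2)^2 / (4*pbar*qbar)``, hence always in
    [0, 1].  NaN where the pooled frequency is fixed (pbar*qbar = 0).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = 0.5 * (p1 + p2)
    denom = 2.0 * pbar * (1.0 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - (p1 * (1 - p1) + p2 * (1 - p2)) / denom
    out = np.where(denom > 0, out, np.nan)
    return out


def _pop_site_stats(g: GenotypeMatrix, pops: PopulationMap, pop: str):
    """(n called diploids, alt freq, observed het proportion) per site."""
    idx = [g.sample_index(s) for s in pops.samples_of(pop)]
    sub = g.calls[idx, :]
    called = sub != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    het = ((sub == 1) & called).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) per-site variance components (a, b, c) for
    two populations; window FST is sum(a)/sum(a+b+c)."""
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    ok = (n1 > 1) & (n2 > 1) & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return np.where(ok, a, np.nan), np.where(ok, b, np.nan), np.where(ok, c, np.nan)


def _hudson_components(n1, p1, n2, p2):
    """Bhatia-style sample-size-corrected Hudson FST components; window FST
    is sum(num)/sum(den)."""
    m1, m2 = 2.0 * n1, 2.0 * n2  # allele counts
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (m1 - 1.0)
            - p2 * (1 - p2) / (m2 - 1.0)
        )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = (m1 > 1) & (m2 > 1)
    return np.where(ok, num, np.nan), np.where(ok, den, np.nan)


def fst_windows(
    g: GenotypeMatrix,
    pops: PopulationMap,
    pop_a: str,
    pop_b: str,
    window: int = 100_000,
    step: int = 25_000,
    min_snps: int = 30,
    dialect: str = "mean",
) -> pd.DataFrame:
    """Windowed FST between two populations.

    ``dialect`` selects the estimator: ``"mean"`` (default) is the
    unweighted mean of the per-site closed-form FST; ``"wc"`` the
    Weir-Cockerham ratio-of-sums (the VCFtools weighted estimator, nearly
    unbiased for the drift parameter); ``"hudson"`` the sample-size
    corrected Hudson ratio-of-sums.  Windows with fewer than ``min_snps``
    informative SNPs are dropped.
    """
    if pop_a == pop_b:
        raise ValueError("FST requires two distinct populations")
    if dialect not in FST_DIALECTS:
        raise ValueError(f"unknown FST dialect {dialect!r}; use one of {FST_DIALECTS}")
    n1, p1, h1 = _pop_site_stats(g, pops, pop_a)
    n2, p2, h2 = _pop_site_stats(g, pops, pop_b)
    if dialect == "mean":
        vals = site_fst(p1, p2)
        num, den = vals, None
    elif dialect == "wc":
        a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
        num, den = a, a + b + c
    else:
        num, den = _hudson_components(n1, p1, n2, p2)
    out = []
    for chrom in g.chroms:
        sl = g.chrom_slice(chrom)
        pos = g.variants["pos"].to_numpy()[sl]
        starts = window_grid(int(pos[0]), int(pos[-1]), window, step)
        if den is None:
            informative = np.isfinite(num[sl]).astype(float)
            s_num, _ = window_sums(pos, starts, window, num[sl])
            s_n, _ = window_sums(pos, starts, window, informative)
            with np.errstate(divide="ignore", invalid="ignore"):
                fst = np.where(s_n > 0, s_num / s_n, np.nan)
            n_inf = s_n.astype(np.int64)
        else:
            informative = (np.isfinite(num[sl]) & np.isfinite(den[sl])).astype(float)
            s_num, _ = window_sums(pos, starts, window, num[sl])
            s_den, _ = window_sums(pos, starts, window, den[sl])
            s_n, _ = window_sums(pos, starts, window, informative)
            with np.errstate(divide="ignore", invalid="ignore"):
                fst = np.where(s_den > 0, s_num / s_den, np.nan)
            n_inf = s_n.astype(np.int64)
        out.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + window,
                 "n_snps": n_inf, "fst": fst}
            )
        )
    df = pd.concat(out, ignore_index=True)
    df = df[(df["n_snps"] >= min_snps) & np.isfinite(df["fst"])]
    return df.reset_index(drop=True)


def hp_windows(
    g: GenotypeMatrix,
    pops: PopulationMap,
    pop: str,
    window: int = 100_000,
    step: int = 25_000,
    min_snps: int = 1,
) -> pd.DataFrame:
    """Windowed pooled heterozygosity Hp for one population.

    Per SNP the major/minor *allele counts* among called genotypes are
    summed over the window; Hp = 2*SM*Sm/(SM+Sm)^2 is in [0, 0.5], equal
    to 0.5 iff the two sums are equal.  Windows without SNPs are dropped.
    """
    n, p, _ = _pop_site_stats(g, pops, pop)
    total = 2.0 * n
    alt = np.round(np.nan_to_num(p) * total)
    n_min = np.minimum(alt, total - alt)
    n_maj = total - n_min
    out = []
    for chrom in g.chroms:
        sl = g.chrom_slice(chrom)
        pos = g.variants["pos"].to_numpy()[sl]
        starts = window_grid(int(pos[0]), int(pos[-1]), window, step)
        called = (total[sl] > 0).astype(float)
        s_maj, _ = window_sums(pos, starts, window, n_maj[sl])
        s_min, _ = window_sums(pos, starts, window, n_min[sl])
        s_n, _ = window_sums(pos, starts, window, called)
        tot = s_maj + s_min
        with np.errstate(divide="ignore", invalid="ignore"):
            hp = np.where(tot > 0, 2.0 * s_maj * s_min / tot**2, np.nan)
        out.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + window,
                 "n_snps": s_n.astype(np.int64), "hp": hp}
            )
        )
    df = pd.concat(out, ignore_index=True)
    df = df[(df["n_snps"] >= min_snps) & np.isfinite(df["hp"])]
    return df.reset_index(drop=True)


def zscore(values: np.ndarray) -> np.ndarray:
    """Genome-wide Z-standardization, ``(x - mean)/SD`` with sample SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >=2 windows to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("scan is degenerate: all window values identical (SD = 0)")
    return (x - x.mean()) / sd


def add_z(df: pd.DataFrame, column: str) -> pd.DataFrame:
    """Return a copy of a scan table with a ``z`` column for ``column``."""
    out = df.copy()
    out["z"] = zscore(out[column].to_numpy())
    return out


def n_tail(n_windows: int, tail: float = 0.01) -> int:
    """Number of windows selected from a tail: ceil(tail * N)."""
    if not 0 < tail < 1:
        raise ValueError("tail must be in (0, 1)")
    return math.ceil(tail * n_windows)


def select_tail(df: pd.DataFrame, column: str, tail: float, side: str) -> pd.DataFrame:
    """The ceil(tail*N) most extreme windows of a scan.

    Ties at the threshold are resolved by deterministic (chrom, start)
    order so the selection is reproducible.
    """
    k = n_tail(len(df), tail)
    asc = side == "lower"
    if side not in ("lower", "upper"):
        raise ValueError("side must be 'lower' or 'upper'")
    ordered = df.sort_values(
        [column, "chrom", "start"], ascending=[asc, True, True]
    )
    return ordered.head(k)


def manhattan_table(scan: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (chrom, mid, z) table from a Z-scored scan."""
    return pd.DataFrame(
        {"chrom": scan["chrom"],
         "mid": ((scan["start"] + scan["end"]) // 2).astype(np.int64),
         "z": scan["z"]}
    )


def call_outliers(
    zfst: pd.DataFrame,
    zhp: pd.DataFrame,
    tail: float = 0.01,
    strict_grid: bool = True,
) -> pd.DataFrame:
    """Intersect the upper Z(FST) tail with the lower Z(Hp) tail and merge
    the shared outlier windows into candidate selection regions.

    Both inputs need (chrom, start, end, z).  With ``strict_grid`` the two
    scans must cover identical windows; otherwise the intersection is taken
    over the shared windows only (the two scans can emit slightly different
    grids on real data).  Overlapping or abutting selected windows are
    union-merged; each region reports its member count, peak Z(FST) and
    trough Z(Hp).
    """
    key = ["chrom", "start", "end"]
    a = set(map(tuple, zfst[key].itertuples(index=False)))
    b = set(map(tuple, zhp[key].itertuples(index=False)))
    if strict_grid and a != b:
        raise ValueError(
            f"window grids differ ({len(a - b)} FST-only, {len(b - a)} Hp-only "
            "windows); rerun the scans on a common grid or pass strict_grid=False"
        )
    top = select_tail(zfst, "z", tail, "upper")
    bottom = select_tail(zhp, "z", tail, "lower")
    top_keys = set(map(tuple, top[key].itertuples(index=False)))
    bot = bottom[bottom[key].apply(tuple, axis=1).isin(top_keys)]
    if len(bot) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_windows", "peak_zfst", "trough_zhp"]
        )
    members = bot[key].merge(top.rename(columns={"z": "zfst"})[key + ["zfst"]], on=key)
    members = members.merge(bot.rename(columns={"z": "zhp"})[key + ["zhp"]], on=key)
    members = members.sort_values(["chrom", "start"]).reset_index(drop=True)
    regions = []
    cur = None
    for row in members.itertuples():
        if cur is not None and row.chrom == cur["chrom"] and row.start <= cur["end"]:
            cur["end"] = max(cur["end"], row.end)
            cur["n_windows"] += 1
            cur["peak_zfst"] = max(cur["peak_zfst"], row.zfst)
            cur["trough_zhp"] = min(cur["trough_zhp"], row.zhp)
        else:
            if cur is not None:
                regions.append(cur)
            cur = dict(chrom=row.chrom, start=row.start, end=row.end,
                       n_windows=1, peak_zfst=row.zfst, trough_zhp=row.zhp)
    regions.append(cur)
    return pd.DataFrame(regions)
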