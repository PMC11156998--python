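"""f3 and f4 statistics with block-jackknife standard errors.

f3(A; B, C) = mean over sites of (a-b)(a-c) tests whether target A is
admixed between sources related to B and C (significantly negative Z);
f4(A, B; C, D) = mean of (a-b)(c-d) tests the four-population tree
topology, the sign indicating which cross pairs share gene flow.  Standard
errors come from a delete-one jackknife over consecutive blocks of 500
retained SNPs (trailing partial block merged into the last full one),
which accommodates linkage between nearby sites.

No finite-sample bias correction is applied by default; the statistics are
validated for the sign/Z contract.  ``correct_target_het`` subtracts the
unbiased within-target sampling-variance term from f3, which removes the
positive bias of order het/(2n) when sample sizes are small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix, PopulationMap, allele_frequencies


@dataclass
class FStatResult:
    value: float
    se: float
    z: float
    n_blocks: int
    block_size_snps: int
    n_sites: int


def _block_slices(n_sites: int, block_size: int) -> list[slice]:
    """Consecutive blocks of block_size sites; a trailing partial block is
    merged into the final full block."""
    n_full = n_sites // block_size
    if n_full == 0:
        return [slice(0, n_sites)]
    bounds = [i * block_size for i in range(n_full)] + [n_sites]
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def _jackknife(site_values: np.ndarray, block_size: int) -> FStatResult:
    """Weighted delete-one block jackknife for a mean over sites."""
    n = site_values.size
    slices = _block_slices(n, block_size)
    B = len(slices)
    if B < 2:
        raise ValueError(
            f"only {B} jackknife block(s) from {n} sites at block size "
            f"{block_size}; need >=2"
        )
    total = site_values.sum()
    theta = total / n
    m = np.array([s.stop - s.start for s in slices], dtype=float)
    block_sums = np.array([site_values[s].sum() for s in slices])
    theta_del = (total - block_sums) / (n - m)
    # Busing-style weighted jackknife (reduces to the standard formula for
    # equal blocks)
    h = n / m
    theta_j = B * theta - np.sum((1.0 - m / n) * theta_del)
    tau = h * theta - (h - 1.0) * theta_del
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / B
    se = float(np.sqrt(var))
    z = theta / se if se > 0 else np.inf * np.sign(theta)
    return FStatResult(float(theta), se, float(z), B, block_size, n)


def _retained_freqs(g, pops, labels):
    freqs = allele_frequencies(g, pops)
    fs = [freqs[l] for l in labels]
    keep = np.logical_and.reduce([f.defined for f in fs])
    if not keep.any():
        raise ValueError("no site with defined frequency in every population")
    return [f.p[keep] for f in fs], [f.n_called[keep] for f in fs]


def f3_from_freqs(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    block_size: int = 500,
    het_correction: np.ndarray | None = None,
) -> FStatResult:
    """f3 from per-site population frequencies (sites already filtered)."""
    d = (np.asarray(a) - np.asarray(b)) * (np.asarray(a) - np.asarray(c))
    if het_correction is not None:
        d = d - het_correction
    return _jackknife(np.asarray(d, dtype=float), block_size)


def f4_from_freqs(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
    block_size: int = 500,
) -> FStatResult:
    """f4 from per-site population frequencies."""
    v = (np.asarray(a) - np.asarray(b)) * (np.asarray(c) - np.asarray(d))
    return _jackknife(np.asarray(v, dtype=float), block_size)


def f3(
    g: GenotypeMatrix,
    pops: PopulationMap,
    target: str,
    source_b: str,
    source_c: str,
    block_size: int = 500,
    correct_target_het: bool = False,
) -> FStatResult:
    """f3(target; source_b, source_c) with block-jackknife SE and Z.

    Sites where any of the three populations is entirely missing are
    excluded listwise; blocks are drawn on the retained-site sequence.
    """
    if len({target, source_b, source_c}) != 3:
        raise ValueError("f3 requires three distinct populations")
    (a, b, c), (na, _, _) = _retained_freqs(g, pops, [target, source_b, source_c])
    corr = None
    if correct_target_het:
        ma = 2.0 * na
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(ma > 1, a * (1 - a) / (ma - 1.0), 0.0)
    return f3_from_freqs(a, b, c, block_size, het_correction=corr)


def f4(
    g: GenotypeMatrix,
    pops: PopulationMap,
    a_pop: str,
    b_pop: str,
    c_pop: str,
    d_pop: str,
    block_size: int = 500,
) -> FStatResult:
    """f4(a_pop, b_pop; c_pop, d_pop) with block-jackknife SE and Z."""
    if len({a_pop, b_pop, c_pop, d_pop}) != 4:
        raise ValueError("f4 requires four distinct populations")
    (a, b, c, d), _ = _retained_freqs(g, pops, [a_pop, b_pop, c_pop, d_pop])
    return f4_from_freqs(a, b, c, d, block_size)
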