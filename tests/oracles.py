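"""Independent brute-force reference implementations used only by tests.

These are deliberately naive (explicit Python loops, no shared code with
the package) so they can serve as oracles for the vectorized
implementations.
"""

from __future__ import annotations


def roh_oracle(pos, calls, params):
    """Exhaustive ROH finder applying the documented scanning-window rules.

    Returns a list of (start, end, length, n_snps) tuples for one sample on
    one chromosome.
    """
    L = len(pos)
    W = params.scan_window_snps
    if L < W:
        return []
    hits = []
    for i in range(L - W + 1):
        w = calls[i : i + W]
        het = sum(1 for c in w if c == 1)
        mis = sum(1 for c in w if c == -1)
        hits.append(
            het <= params.max_het_per_window and mis <= params.max_missing_per_window
        )
    in_run = []
    for j in range(L):
        lo = max(0, j - W + 1)
        hi = min(j, L - W)
        cov = hits[lo : hi + 1]
        in_run.append(
            sum(cov) / len(cov) >= params.window_hit_threshold - 1e-12
        )
    segs = []
    j = 0
    while j < L:
        if not in_run[j]:
            j += 1
            continue
        k = j
        while k + 1 < L and in_run[k + 1]:
            k += 1
        parts = []
        s = j
        for t in range(j, k):
            if pos[t + 1] - pos[t] > params.max_gap_bp:
                parts.append((s, t))
                s = t + 1
        parts.append((s, k))
        for a, b in parts:
            while a <= b and calls[a] not in (0, 2):
                a += 1
            while b >= a and calls[b] not in (0, 2):
                b -= 1
            if a > b:
                continue
            n = b - a + 1
            length = pos[b] - pos[a] + 1
            if (
                n >= params.min_snps
                and length >= params.min_length_bp
                and n * params.max_bp_per_snp >= length
            ):
                segs.append((int(pos[a]), int(pos[b]), int(length), int(n)))
        j = k + 1
    return segs


def ibs_oracle(a, b):
    """Per-pair IBS counts by explicit per-site comparison of genotype
    classes (0/1/2, -1 missing)."""
    ibs0 = ibs1 = ibs2 = 0
    for x, y in zip(a, b):
        if x == -1 or y == -1:
            continue
        if x == y:
            ibs2 += 1
        elif {x, y} == {0, 2}:
            ibs0 += 1
        else:
            ibs1 += 1
    return ibs0, ibs1, ibs2


def merge_intervals_oracle(intervals):
    """Union-merge of half-open intervals (chrom, start, end)."""
    out = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out
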