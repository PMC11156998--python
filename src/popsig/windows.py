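"""Sliding-window bookkeeping shared by the scan modules.

Windows are half-open ``[start, start + window)`` in bp with 1-based starts
at multiples of the step (start = k*step + 1).  For a chromosome, windows
run from the earliest step-aligned window containing the first SNP to the
last window starting at or before the last SNP.
"""

from __future__ import annotations

import numpy as np


def window_grid(first_pos: int, last_pos: int, window: int, step: int) -> np.ndarray:
    """Step-aligned window starts covering [first_pos, last_pos]."""
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    k0 = max(0, -(-(first_pos - window) // step))  # ceil((first-window)/step)
    k1 = (last_pos - 1) // step
    if k1 < k0:
        k1 = k0
    return np.arange(k0, k1 + 1, dtype=np.int64) * step + 1


def window_sums(
    pos: np.ndarray, starts: np.ndarray, window: int, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (sum of values over member SNPs, member count).

    ``pos`` must be sorted; ``values`` may be 1-D or 2-D with sites on the
    last axis (each row summed on the same grid).  NaN values are treated
    as absent for the sum but SNPs still count as members.
    """
    pos = np.asarray(pos)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window, side="left")
    vals = np.atleast_2d(np.asarray(values, dtype=float))
    cs = np.concatenate(
        [np.zeros((vals.shape[0], 1)), np.cumsum(np.nan_to_num(vals), axis=1)], axis=1
    )
    sums = cs[:, hi] - cs[:, lo]
    counts = (hi - lo).astype(np.int64)
    if np.ndim(values) == 1:
        return sums[0], counts
    return sums, counts
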