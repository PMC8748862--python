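"""Independent brute-force oracles, deliberately written apart from the
package implementation paths they check."""

from __future__ import annotations

import numpy as np


def tally_oracle(residues: str) -> dict[str, int]:
    """Single-pass character tally over a sequence string."""
    counts = {"A": 0, "C": 0, "G": 0, "U": 0, "ambiguous": 0}
    for ch in residues:
        if ch in counts:
            counts[ch] += 1
        else:
            counts["ambiguous"] += 1
    return counts


def ols_oracle(x, y) -> tuple[float, float]:
    """Closed-form least-squares slope and intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
    return slope, ybar - slope * xbar


def bh_oracle(pvalues) -> np.ndarray:
    """Naive two-pass Benjamini-Hochberg step-up with right-to-left minimum."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end  # 1-based ascending rank
        running_min = min(running_min, p[idx] * n / rank)
        adjusted[idx] = running_min
    return adjusted


def cpm_keep_oracle(counts_row, library_sizes, min_cpm=1.0) -> bool:
    """Per-gene application of the CPM filter definition (all samples)."""
    return all(
        c / lib * 1e6 >= min_cpm for c, lib in zip(counts_row, library_sizes)
    )
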