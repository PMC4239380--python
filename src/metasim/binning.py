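"""Logarithmic size bins for metastasis histograms.

The first bin {1} holds disseminated tumour cells (DTCs); the remaining bins
are half-open decades (1,10], (10,100], ... up to (1e9,1e10]. Sizes are
floored to whole cells before binning, and anything above the last edge is
counted in the top bin.
"""

from __future__ import annotations

import numpy as np

# edges[i] is the inclusive upper edge of bin i: {1}, (1,10], (10,100], ...
BIN_EDGES: np.ndarray = np.array([1.0] + [10.0**k for k in range(1, 11)])
N_BINS: int = len(BIN_EDGES)

BIN_LABELS: tuple[str, ...] = ("DTC",) + tuple(
    f"({lo:g},{hi:g}]" for lo, hi in zip(BIN_EDGES[:-1], BIN_EDGES[1:])
)

DTC_BIN: str = BIN_LABELS[0]


def bin_index(sizes) -> np.ndarray:
    """Bin index (0 = DTC) for each size; sizes are floored to integers."""
    s = np.floor(np.asarray(sizes, dtype=float))
    if s.size and np.any(s < 1):
        raise ValueError("deposit sizes must be >= 1 cell")
    idx = np.searchsorted(BIN_EDGES, s, side="left")
    return np.minimum(idx, N_BINS - 1)


def histogram_counts(sizes) -> np.ndarray:
    """Counts per bin (length N_BINS) for a collection of deposit sizes."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        return np.zeros(N_BINS, dtype=int)
    return np.bincount(bin_index(sizes), minlength=N_BINS)


def classify_deposit(size: float) -> str:
    """Label a single deposit: 'DTC' for a single cell (size < 2 before
    flooring still counts as one cell), else its enclosing decade bin."""
    if size < 1:
        raise ValueError("deposit size must be >= 1 cell")
    return BIN_LABELS[int(bin_index([size])[0])]
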