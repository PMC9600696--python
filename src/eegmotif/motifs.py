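"""Ternary motif pattern (TMP) features.

A local ordinal descriptor for 1-D signals.  A stride-1 window of five
samples is slid along the signal; within each window the 10 ordered pairs
(i, j), i < j, are compared with a ternary function (0: less, 1: equal,
2: greater).  The first five ternary digits and the last five are each
encoded as a base-3 integer in [0, 242], producing two "map signals".
The 243-bin histograms of the two map signals, concatenated, form the
486-dimensional feature vector.

Because only order relations are used, the features are exactly invariant
under any strictly increasing transform of the signal, and negating the
signal reverses each histogram (digit 0 swaps with 2, so a code ``m``
becomes ``242 - m``).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "BLOCK_LEN",
    "N_PAIRS",
    "N_BINS",
    "TMP_LEN",
    "ternary_compare",
    "block_motif",
    "map_signals",
    "tmp_histogram",
]

BLOCK_LEN = 5
N_PAIRS = 10
#: size of the code alphabet of one map signal: 3**5
N_BINS = 3**BLOCK_LEN
#: length of the full TMP feature vector: two concatenated histograms
TMP_LEN = 2 * N_BINS

# ordered pairs (i, j), i < j, over block positions 0..4; pairs 0..4 feed the
# first map signal, pairs 5..9 the second
_PAIRS = [(i, j) for i in range(4) for j in range(i + 1, 5)]
_PI = np.array([p[0] for p in _PAIRS])
_PJ = np.array([p[1] for p in _PAIRS])
#: base-3 place values 3**0 .. 3**4
_W3 = 3 ** np.arange(BLOCK_LEN)


def ternary_compare(a: float, b: float, tau: float = 0.0) -> int:
    """Ternary order comparison: 0 if a < b, 1 if equal, 2 if a > b.

    ``tau >= 0`` widens the equality band to ``|a - b| <= tau`` (by default
    equality is exact).
    """
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("ternary_compare requires finite inputs")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    d = a - b
    if d < -tau:
        return 0
    if d > tau:
        return 2
    return 1


def _digits(blocks: np.ndarray, tau: float) -> np.ndarray:
    """Ternary digits for every block row; shape (n_blocks, 10)."""
    a = blocks[:, _PI]
    b = blocks[:, _PJ]
    d = a - b
    out = np.ones(d.shape, dtype=np.int64)  # 1 = equal
    out[d < -tau] = 0
    out[d > tau] = 2
    return out


def block_motif(block: np.ndarray, tau: float = 0.0) -> tuple[int, int]:
    """Encode one 5-sample block into its two base-3 map values.

    The ten pairwise ternary digits are taken in nested order (i ascending,
    j ascending); digits 1..5 weighted by 3**0..3**4 give the first map
    value, digits 6..10 the second.  Both lie in [0, 242].
    """
    block = np.asarray(block, dtype=float)
    if block.shape != (BLOCK_LEN,):
        raise ValueError(f"block must have exactly {BLOCK_LEN} samples")
    if not np.all(np.isfinite(block)):
        raise ValueError("block contains non-finite values")
    dg = _digits(block[None, :], tau)[0]
    return int(dg[:5] @ _W3), int(dg[5:] @ _W3)


def map_signals(signal: np.ndarray, tau: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Both map signals of a 1-D signal; each has length ``len - 4``."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < BLOCK_LEN:
        raise ValueError(f"need at least {BLOCK_LEN} samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    blocks = sliding_window_view(x, BLOCK_LEN)
    dg = _digits(blocks, tau)
    return dg[:, :5] @ _W3, dg[:, 5:] @ _W3


def tmp_histogram(signal: np.ndarray, tau: float = 0.0) -> np.ndarray:
    """TMP feature vector: concatenated 243-bin histograms of both maps.

    Returns a float vector of length 486 whose first and second halves each
    sum to ``len(signal) - 4``.
    """
    m1, m2 = map_signals(signal, tau)
    h1 = np.bincount(m1, minlength=N_BINS)
    h2 = np.bincount(m2, minlength=N_BINS)
    return np.concatenate([h1, h2]).astype(float)
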