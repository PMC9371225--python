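"""Bit error rate and normalized correlation between binary watermarks."""

from __future__ import annotations

import numpy as np

__all__ = ["ber", "nc"]


def _binary_pair(w: np.ndarray, w_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(w)
    b = np.asarray(w_star)
    if a.shape != b.shape:
        raise ValueError(f"watermark shapes differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("watermarks must be non-empty")
    for arr in (a, b):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("watermarks must be binary (entries in {0, 1})")
    return a.astype(np.int64), b.astype(np.int64)


def ber(w: np.ndarray, w_star: np.ndarray) -> float:
    """Bit error rate: fraction of differing bits; 0 is a perfect extraction."""
    a, b = _binary_pair(w, w_star)
    return float(np.mean((a - b) ** 2))


def nc(w: np.ndarray, w_star: np.ndarray) -> float:
    """Normalized correlation sum(w * w*) / sum(w**2); 1 is perfect.

    Asymmetric by definition — the denominator uses the reference watermark
    ``w`` only, which therefore must not be all-zero.
    """
    a, b = _binary_pair(w, w_star)
    denom = int(np.sum(a * a))
    if denom == 0:
        raise ValueError("NC is undefined for an all-zero reference watermark")
    return float(np.sum(a * b) / denom)
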