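"""Chebyshev chaotic map keystream and XOR watermark scrambling.

The 1D Chebyshev map x_{n+1} = cos(r arccos x_n) on [-1, 1] is chaotic for
control parameter r >= 2 and serves as a keyed pseudo-random bit source: the
iterates are thresholded at 0 and XORed with the flattened binary watermark.
Because XOR with a fixed keystream is an involution, the same operation both
scrambles and descrambles.

Iteration is pinned to IEEE double precision; a key is reproducible within
one implementation but chaotic divergence makes keystreams non-portable
across differing math libraries.  Generation and verification always run in
the same implementation, so this is acceptable key material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChebyshevKey",
    "chebyshev_step",
    "chebyshev_sequence",
    "binarize_chaotic",
    "chaotic_bits",
    "scramble",
    "descramble",
]

DEFAULT_BURN_IN = 100


@dataclass(frozen=True)
class ChebyshevKey:
    """Secret parameters of the chaotic scrambler.

    r must be >= 2 (the chaotic regime of the map); x0 is the initial value
    in [-1, 1]; burn_in iterates are discarded to decorrelate the keystream
    from x0 and is part of the key material.
    """

    r: float
    x0: float
    burn_in: int = DEFAULT_BURN_IN

    def __post_init__(self) -> None:
        if not self.r >= 2:
            raise ValueError(f"control parameter r must be >= 2, got {self.r}")
        if not -1.0 <= self.x0 <= 1.0:
            raise ValueError(f"x0 must lie in [-1, 1], got {self.x0}")
        if self.burn_in < 0:
            raise ValueError(f"burn_in must be >= 0, got {self.burn_in}")

    def to_dict(self) -> dict:
        return {"r": self.r, "x0": self.x0, "burn_in": self.burn_in}

    @classmethod
    def from_dict(cls, d: dict) -> "ChebyshevKey":
        return cls(
            r=float(d["r"]),
            x0=float(d["x0"]),
            burn_in=int(d.get("burn_in", DEFAULT_BURN_IN)),
        )


def chebyshev_step(x: float, r: float) -> float:
    """One iterate cos(r arccos x); x must already be in [-1, 1]."""
    if not -1.0 <= x <= 1.0:
        raise ValueError(f"map state must lie in [-1, 1], got {x}")
    if not r >= 2:
        raise ValueError(f"control parameter r must be >= 2, got {r}")
    # cos of a real argument can exceed 1 only by rounding; keep the state
    # admissible without masking genuine domain errors above.
    return float(min(1.0, max(-1.0, np.cos(r * np.arccos(x)))))


def chebyshev_sequence(key: ChebyshevKey, n: int) -> np.ndarray:
    """The n keystream iterates after the burn-in, fully determined by the key."""
    if n < 0:
        raise ValueError(f"sequence length must be >= 0, got {n}")
    out = np.empty(n)
    x = key.x0
    for _ in range(key.burn_in):
        x = chebyshev_step(x, key.r)
    for i in range(n):
        x = chebyshev_step(x, key.r)
        out[i] = x
    return out


def binarize_chaotic(seq: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Threshold a chaotic sequence into bits: 1 where value >= threshold.

    The default threshold 0 is the midpoint of the map's range and yields
    near-balanced bits.
    """
    return (np.asarray(seq, dtype=float) >= threshold).astype(np.uint8)


def chaotic_bits(key: ChebyshevKey, n: int, threshold: float = 0.0) -> np.ndarray:
    """Keyed binary keystream of length n."""
    return binarize_chaotic(chebyshev_sequence(key, n), threshold)


def _check_binary(w: np.ndarray) -> np.ndarray:
    arr = np.asarray(w)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("watermark must be binary (entries in {0, 1})")
    return arr.astype(np.uint8)


def scramble(w: np.ndarray, key: ChebyshevKey, threshold: float = 0.0) -> np.ndarray:
    """XOR a P x Q binary matrix with the keyed keystream (row-major order).

    Involutory: ``scramble(scramble(w, key), key) == w``.
    """
    arr = _check_binary(w)
    bits = chaotic_bits(key, arr.size, threshold).reshape(arr.shape)
    return arr ^ bits


# XOR scrambling is its own inverse.
descramble = scramble
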