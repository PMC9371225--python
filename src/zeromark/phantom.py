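"""Synthetic carriers and watermarks for a download-free test bed.

Real brain MRI slices cannot ship with the package, so the carrier images
are seeded phantoms that emulate their gross structure: dark background, a
bright elliptical "skull" annulus, a handful of interior elliptical
structures of varying intensity, and mild texture noise, pseudo-colored to
RGB.  Watermarks are small binary patterns (checkerboard, letter glyphs, or
seeded random bits) standing in for binary logo images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhantomSpec", "make_phantom", "make_watermark"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic brain-slice-like carrier."""

    side: int = 256
    n_blobs: int = 6
    seed: int = 0
    noise_sd: float = 0.02
    colormap: str = "mri"

    def __post_init__(self) -> None:
        if self.side < 16:
            raise ValueError(f"side must be >= 16, got {self.side}")
        if self.n_blobs < 1:
            raise ValueError(f"n_blobs must be >= 1, got {self.n_blobs}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.colormap not in ("mri", "gray"):
            raise ValueError(f"colormap must be 'mri' or 'gray', got {self.colormap!r}")


def _ellipse_mask(yy, xx, cy, cx, ry, rx, angle=0.0):
    ct, st = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / rx) ** 2 + (v / ry) ** 2


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic (seeded) color phantom, shape (side, side, 3), uint8."""
    n = spec.side
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n), indexing="ij")

    s = np.zeros((n, n))
    # skull annulus, centered so rotations move little mass out of frame
    outer = _ellipse_mask(yy, xx, 0.0, 0.0, 0.82, 0.72)
    inner = _ellipse_mask(yy, xx, 0.0, 0.0, 0.72, 0.62)
    s[outer <= 1.0] = 1.0
    s[inner <= 1.0] = 0.25  # interior "tissue" base level

    for _ in range(spec.n_blobs):
        cy, cx = rng.uniform(-0.4, 0.4, size=2)
        ry, rx = rng.uniform(0.08, 0.3, size=2)
        angle = rng.uniform(0, np.pi)
        level = rng.uniform(0.35, 0.95)
        d = _ellipse_mask(yy, xx, cy, cx, ry, rx, angle)
        blob = d <= 1.0
        # soft-edged blobs blended over the tissue
        s[blob] = 0.5 * s[blob] + 0.5 * level * (1.0 - 0.3 * d[blob])

    if spec.noise_sd > 0:
        s = s + rng.normal(0.0, spec.noise_sd, size=s.shape)
    s = np.clip(s, 0.0, 1.0)

    if spec.colormap == "gray":
        rgb = np.stack([s, s, s], axis=-1)
    else:
        # warm MRI-like pseudo-color: full range in R, compressed G/B
        rgb = np.stack([s**0.8, s**1.4, 0.9 * s**2.0 + 0.08 * s], axis=-1)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


# 5x7 glyphs used by the "letters" watermark kind
_GLYPHS = {
    "Z": ["11111", "00001", "00010", "00100", "01000", "10000", "11111"],
    "W": ["10001", "10001", "10001", "10101", "10101", "11011", "10001"],
}


def make_watermark(kind: str, p: int = 32, q: int = 32, seed: int = 0) -> np.ndarray:
    """Binary P x Q watermark pattern of the requested kind.

    ``checkerboard`` and ``letters`` are deterministic; ``random`` is seeded
    Bernoulli(1/2).
    """
    if p < 2 or q < 2:
        raise ValueError("watermark must be at least 2 x 2")
    if kind == "checkerboard":
        yy, xx = np.meshgrid(np.arange(p), np.arange(q), indexing="ij")
        return ((yy + xx + 1) % 2).astype(np.uint8)
    if kind == "random":
        rng = np.random.default_rng(seed)
        return rng.integers(0, 2, size=(p, q)).astype(np.uint8)
    if kind == "letters":
        canvas = np.zeros((p, q), dtype=np.uint8)
        glyphs = [np.array([[int(ch) for ch in row] for row in _GLYPHS[g]]) for g in "ZW"]
        total_w = sum(g.shape[1] for g in glyphs) + 1
        scale = max(1, min((p - 2) // 7, (q - 2) // total_w))
        x = max(0, (q - total_w * scale) // 2)
        y = max(0, (p - 7 * scale) // 2)
        for g in glyphs:
            block = np.kron(g, np.ones((scale, scale), dtype=np.uint8))
            canvas[y : y + block.shape[0], x : x + block.shape[1]] = block
            x += (g.shape[1] + 1) * scale
        return canvas
    raise ValueError(f"unknown watermark kind {kind!r}")
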