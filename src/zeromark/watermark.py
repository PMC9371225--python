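"""Zero-watermark generation and verification.

Zero-watermarking protects an image without touching a single pixel: a keyed
selection of moment amplitudes of the carrier is binarized into a feature
image LF, the payload watermark is scrambled with a chaotic keystream, and
the registered zero-watermark is the XOR of the two.  Verification recomputes
the feature image from the presented (possibly attacked) image and XORs it
with the registered bits; descrambling recovers the watermark wherever the
features survived the attack.

Feature eligibility follows the amplitude-selection rule |MFG_pq| with q not
a multiple of 4 (q=0 counts as 4*0 and is excluded), pooled over the three
colour channels.  The keyed sampler is numpy's PCG64 generator drawing
without replacement; generator name and draw method are recorded in the
zero-watermark metadata so registered watermarks remain verifiable across
releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import metrics
from .basis import BasisSpec, MomentSet, as_color_image, compute_moments, kernel_integrals
from .chaotic import ChebyshevKey, descramble, scramble

__all__ = [
    "SelectionKey",
    "ZeroWatermark",
    "VerificationResult",
    "SELECTION_RNG_VERSION",
    "eligible_indices",
    "select_features",
    "binarize_features",
    "generate",
    "verify",
]

#: Identifier of the keyed-sampling procedure baked into the sidecar format.
SELECTION_RNG_VERSION = "numpy-pcg64/choice-v1"


@dataclass(frozen=True)
class SelectionKey:
    """Seed of the deterministic pseudo-random coefficient selection."""

    seed: int

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("selection seed must be non-negative")


@dataclass
class ZeroWatermark:
    """Registered verification bitmap plus the metadata needed to reuse it."""

    bits: np.ndarray
    spec_hash: str
    shape: tuple[int, int] = field(init=False)
    rng_version: str = SELECTION_RNG_VERSION

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("zero-watermark bits must be binary")
        self.shape = self.bits.shape


@dataclass
class VerificationResult:
    """Extracted watermark and, when a reference is supplied, its BER / NC."""

    extracted: np.ndarray
    ber: float | None = None
    nc: float | None = None


def eligible_indices(spec: BasisSpec) -> np.ndarray:
    """All (channel, p, q) triples with q not a multiple of 4, in fixed order.

    Order is channel-major (R, G, B), then p ascending, then q ascending —
    part of the zero-watermark format.
    """
    qs = np.array([q for q in range(spec.nmax + 1) if q % 4 != 0], dtype=np.int64)
    ps = np.arange(spec.nmax + 1, dtype=np.int64)
    chan, p, q = np.meshgrid(np.arange(3), ps, qs, indexing="ij")
    return np.stack([chan.ravel(), p.ravel(), q.ravel()], axis=1)


def _selected_indices(spec: BasisSpec, key: SelectionKey, count: int) -> np.ndarray:
    pool = eligible_indices(spec)
    if count > len(pool):
        raise ValueError(
            f"requested {count} features but only {len(pool)} moment indices are "
            f"eligible at nmax={spec.nmax}; increase nmax"
        )
    rng = np.random.default_rng(key.seed)
    pick = rng.choice(len(pool), size=count, replace=False)
    return pool[pick]


def select_features(moments: MomentSet, key: SelectionKey, count: int) -> np.ndarray:
    """Keyed sample of ``count`` distinct moment amplitudes |MFG_pq|.

    The selected index set is reproducible from the key alone, so generation
    and verification agree on it without sharing the carrier.
    """
    idx = _selected_indices(moments.spec, key, count)
    return np.abs(moments.mfg[idx[:, 0], idx[:, 1], idx[:, 2]])


def binarize_features(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Threshold amplitudes at their mean into the P x Q binary feature image.

    Bit i is 1 iff A_i >= mean(A) (ties go to 1); reshaped row-major.
    """
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("amplitude vector is empty")
    if a.size != shape[0] * shape[1]:
        raise ValueError(f"{a.size} amplitudes cannot fill a {shape} feature image")
    t = a.mean()
    return (a >= t).astype(np.uint8).reshape(shape)


def _feature_image(
    image: np.ndarray,
    sel_key: SelectionKey,
    spec: BasisSpec,
    shape: tuple[int, int],
) -> np.ndarray:
    kernels = kernel_integrals(spec)
    moments = compute_moments(image, kernels)
    amps = select_features(moments, sel_key, shape[0] * shape[1])
    return binarize_features(amps, shape)


def generate(
    carrier: np.ndarray,
    w: np.ndarray,
    sel_key: SelectionKey,
    scr_key: ChebyshevKey,
    spec: BasisSpec,
) -> ZeroWatermark:
    """Build the zero-watermark LF xor scramble(w) for a carrier image.

    The carrier is read, never written — the lossless contract of
    zero-embedding.
    """
    carrier = as_color_image(carrier)
    if carrier.shape[0] != spec.grid_n:
        raise ValueError(f"carrier side {carrier.shape[0]} != spec grid {spec.grid_n}")
    w = np.asarray(w)
    if w.ndim != 2 or not np.isin(w, (0, 1)).all():
        raise ValueError("watermark must be a 2-D binary matrix")
    lf = _feature_image(carrier, sel_key, spec, w.shape)
    w_scrambled = scramble(w, scr_key)
    return ZeroWatermark(bits=lf ^ w_scrambled, spec_hash=spec.spec_hash())


def verify(
    image: np.ndarray,
    zw: ZeroWatermark,
    sel_key: SelectionKey,
    scr_key: ChebyshevKey,
    spec: BasisSpec,
    reference: np.ndarray | None = None,
) -> VerificationResult:
    """Extract the watermark carried by a (possibly attacked) image.

    A presented image whose frame no longer matches the basis grid is
    resampled back to grid_n x grid_n (bilinear) before moment computation.
    """
    image = as_color_image(image)
    if image.shape[0] != spec.grid_n:
        image = np.clip(
            resize(
                image.astype(float),
                (spec.grid_n, spec.grid_n, 3),
                order=1,
                anti_aliasing=False,
            ),
            0,
            255,
        )
    lf_star = _feature_image(image, sel_key, spec, zw.shape)
    extracted = descramble(lf_star ^ zw.bits, scr_key)
    result = VerificationResult(extracted=extracted)
    if reference is not None:
        result.ber = metrics.ber(reference, extracted)
        result.nc = metrics.nc(reference, extracted)
    return result
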