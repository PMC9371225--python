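"""Attack simulator and PSNR for robustness evaluation.

Implements the standard watermarking attack battery: JPEG re-compression,
Gaussian and salt-and-pepper noise, 3x3 median / Gaussian / average
filtering, rotation, uniform and anisotropic (length-width ratio) rescaling,
flips, and upper-left-corner cropping.  Every attack returns an image of the
same frame size and channel count as its input, which is what the fixed-grid
verification pipeline requires.

Conventions: JPEG goes through a real baseline codec (Pillow, 4:2:0 chroma
subsampling) at the given quality factor; noise variance / density are on
intensities normalized to [0, 1]; rotation keeps the original frame and
zero-fills the exposed corners; scaling attacks resize away and back with
bilinear interpolation.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize, rotate
from skimage.util import random_noise

from .basis import as_color_image

__all__ = ["AttackSpec", "ATTACK_NAMES", "DEFAULT_BATTERY", "apply_attack", "psnr"]

ATTACK_NAMES = (
    "jpeg",
    "gaussian_noise",
    "salt_pepper",
    "median_filter",
    "gaussian_filter",
    "average_filter",
    "rotate",
    "scale",
    "lwr",
    "flip",
    "crop_ul",
)


@dataclass(frozen=True)
class AttackSpec:
    """One named attack with its parameter map.

    Noise attacks take a ``seed`` parameter; with a fixed seed the attack is
    reproducible.
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ATTACK_NAMES:
            raise ValueError(f"unknown attack {self.name!r}; choose from {ATTACK_NAMES}")

    def label(self) -> str:
        if not self.params:
            return self.name
        inner = ",".join(f"{k}={v}" for k, v in sorted(self.params.items()) if k != "seed")
        return f"{self.name}({inner})"


def _to_unit(image: np.ndarray) -> np.ndarray:
    return image.astype(float) / 255.0


def _to_uint8(unit: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(unit * 255.0), 0, 255).astype(np.uint8)


def _jpeg(image: np.ndarray, quality: int) -> np.ndarray:
    if not 1 <= quality <= 100:
        raise ValueError(f"JPEG quality must be in 1..100, got {quality}")
    buf = _io.BytesIO()
    Image.fromarray(image.astype(np.uint8)).save(
        buf, format="JPEG", quality=int(quality), subsampling=2
    )
    buf.seek(0)
    return np.asarray(Image.open(buf).convert("RGB"))


def _resize_rgb(unit: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return resize(unit, (*shape, 3), order=1, anti_aliasing=False, mode="reflect")


def apply_attack(image: np.ndarray, spec: AttackSpec) -> np.ndarray:
    """Apply one attack; output has the same dimensions and dtype uint8."""
    image = as_color_image(image).astype(np.uint8)
    n = image.shape[0]
    p = spec.params
    name = spec.name

    if name == "jpeg":
        return _jpeg(image, p.get("quality", 70))

    if name in ("gaussian_noise", "salt_pepper"):
        rng = np.random.default_rng(p.get("seed", 0))
        unit = _to_unit(image)
        if name == "gaussian_noise":
            noisy = random_noise(
                unit, mode="gaussian", var=p.get("var", 0.005), rng=rng, clip=True
            )
        else:
            noisy = random_noise(
                unit, mode="s&p", amount=p.get("density", 0.005), rng=rng
            )
        return _to_uint8(noisy)

    if name == "median_filter":
        size = p.get("size", 3)
        out = np.empty_like(image)
        for c in range(3):
            out[:, :, c] = ndimage.median_filter(image[:, :, c], size=size, mode="reflect")
        return out

    if name == "gaussian_filter":
        # sigma 0.5 with radius 1 reproduces the common 3x3 Gaussian window
        sigma = p.get("sigma", 0.5)
        radius = (p.get("size", 3) - 1) // 2
        out = np.empty_like(image)
        for c in range(3):
            out[:, :, c] = _to_uint8(
                ndimage.gaussian_filter(
                    _to_unit(image[:, :, c]), sigma=sigma, radius=radius, mode="reflect"
                )
            )
        return out

    if name == "average_filter":
        size = p.get("size", 3)
        out = np.empty_like(image)
        for c in range(3):
            out[:, :, c] = _to_uint8(
                ndimage.uniform_filter(_to_unit(image[:, :, c]), size=size, mode="reflect")
            )
        return out

    if name == "rotate":
        angle = p.get("angle", 5.0)
        rot = rotate(
            _to_unit(image), angle, resize=False, order=1, mode="constant", cval=0.0
        )
        return _to_uint8(rot)

    if name == "scale":
        s = p.get("factor", 0.75)
        if s <= 0:
            raise ValueError("scaling factor must be positive")
        side = max(1, round(n * s))
        small = _resize_rgb(_to_unit(image), (side, side))
        return _to_uint8(_resize_rgb(small, (n, n)))

    if name == "lwr":
        fy = p.get("fy", 1.0)
        fx = p.get("fx", 0.75)
        if fx <= 0 or fy <= 0:
            raise ValueError("length-width ratio factors must be positive")
        shape = (max(1, round(n * fy)), max(1, round(n * fx)))
        warped = _resize_rgb(_to_unit(image), shape)
        return _to_uint8(_resize_rgb(warped, (n, n)))

    if name == "flip":
        direction = p.get("direction", "horizontal")
        if direction == "horizontal":  # mirror left-right
            return image[:, ::-1].copy()
        if direction == "vertical":  # mirror top-bottom
            return image[::-1].copy()
        raise ValueError(f"flip direction must be horizontal or vertical, got {direction!r}")

    if name == "crop_ul":
        frac = p.get("fraction", 1 / 16)
        if not 0 < frac <= 1:
            raise ValueError("crop fraction must be in (0, 1]")
        side = round(n * np.sqrt(frac))
        out = image.copy()
        out[:side, :side] = 0
        return out

    raise AssertionError(f"unhandled attack {name!r}")  # pragma: no cover


def psnr(original: np.ndarray, attacked: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, MSE averaged over pixels and channels.

    Identical images have zero MSE; the infinite-PSNR condition is reported
    as ``float('inf')``.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(attacked, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(255.0**2 / mse)


#: The attack battery mirrored from the standard robustness protocol:
#: JPEG qualities, two noise levels each, the three 3x3 filters, rotations,
#: scalings, length-width-ratio changes, flips, and corner crops.
DEFAULT_BATTERY: tuple[AttackSpec, ...] = (
    *(AttackSpec("jpeg", {"quality": q}) for q in (10, 30, 50, 70, 90)),
    *(AttackSpec("gaussian_noise", {"var": v, "seed": 0}) for v in (0.005, 0.02)),
    *(AttackSpec("salt_pepper", {"density": d, "seed": 0}) for d in (0.005, 0.02)),
    AttackSpec("median_filter", {"size": 3}),
    AttackSpec("gaussian_filter", {"size": 3, "sigma": 0.5}),
    AttackSpec("average_filter", {"size": 3}),
    *(AttackSpec("rotate", {"angle": a}) for a in (5, 15, 25, 45)),
    *(AttackSpec("scale", {"factor": s}) for s in (0.5, 0.75, 1.5, 2.0)),
    AttackSpec("lwr", {"fy": 1.0, "fx": 0.75}),
    AttackSpec("lwr", {"fy": 0.5, "fx": 1.0}),
    AttackSpec("flip", {"direction": "horizontal"}),
    AttackSpec("flip", {"direction": "vertical"}),
    AttackSpec("crop_ul", {"fraction": 1 / 16}),
    AttackSpec("crop_ul", {"fraction": 1 / 8}),
)
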