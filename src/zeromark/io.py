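"""Image and key/value serialization: PNG carriers, 1-bit watermark PNGs with
JSON sidecars, and the YAML run configuration shared by all CLI phases."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .attacks import AttackSpec
from .basis import BasisSpec, as_color_image
from .chaotic import ChebyshevKey
from .watermark import SELECTION_RNG_VERSION, SelectionKey, ZeroWatermark

__all__ = [
    "load_color_image",
    "save_color_image",
    "load_watermark",
    "save_watermark",
    "load_zero_watermark",
    "save_zero_watermark",
    "RunConfig",
]


def load_color_image(path: str | Path) -> np.ndarray:
    """Read a square RGB carrier (PNG/BMP/TIFF); intensities used as-is."""
    img = Image.open(path)
    if img.mode != "RGB":
        raise ValueError(f"{path}: expected an RGB image, got mode {img.mode!r}")
    arr = np.asarray(img)
    return as_color_image(arr)


def save_color_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(as_color_image(image).astype(np.uint8)).save(path)


def load_watermark(path: str | Path) -> np.ndarray:
    """Read a binary watermark PNG (any mode; nonzero pixels become 1)."""
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def save_watermark(path: str | Path, bits: np.ndarray) -> None:
    bits = np.asarray(bits, dtype=np.uint8)
    Image.fromarray((bits * 255).astype(np.uint8)).convert("1").save(path)


def save_zero_watermark(path: str | Path, zw: ZeroWatermark) -> None:
    """Write the registered bitmap as a 1-bit PNG plus a JSON sidecar."""
    path = Path(path)
    save_watermark(path, zw.bits)
    sidecar = {
        "P": int(zw.shape[0]),
        "Q": int(zw.shape[1]),
        "basis_spec_hash": zw.spec_hash,
        "selection_order_version": zw.rng_version,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_zero_watermark(path: str | Path) -> ZeroWatermark:
    path = Path(path)
    bits = load_watermark(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if bits.shape != (meta["P"], meta["Q"]):
        raise ValueError(f"{path}: bitmap shape {bits.shape} disagrees with sidecar")
    zw = ZeroWatermark(bits=bits, spec_hash=meta["basis_spec_hash"])
    if meta.get("selection_order_version", SELECTION_RNG_VERSION) != zw.rng_version:
        raise ValueError(
            f"{path}: zero-watermark was built with selection order "
            f"{meta['selection_order_version']!r}; this release uses {zw.rng_version!r}"
        )
    return zw


@dataclass
class RunConfig:
    """One structured config drives generation, verification, and evaluation,
    so the two phases cannot silently diverge in basis parameters."""

    basis: BasisSpec
    selection_key: SelectionKey
    scramble_key: ChebyshevKey
    battery: list[AttackSpec] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        keys = data.get("keys", {})
        battery = [
            AttackSpec(name=a["name"], params=a.get("params", {}))
            for a in data.get("attacks", [])
        ]
        return cls(
            basis=BasisSpec.from_dict(data["basis"]),
            selection_key=SelectionKey(int(keys.get("selection_seed", 0))),
            scramble_key=ChebyshevKey.from_dict(keys.get("chebyshev", {"r": 4.0, "x0": 0.631})),
            battery=battery,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "basis": self.basis.to_dict(),
            "keys": {
                "selection_seed": self.selection_key.seed,
                "chebyshev": self.scramble_key.to_dict(),
            },
            "attacks": [{"name": a.name, "params": dict(a.params)} for a in self.battery],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
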