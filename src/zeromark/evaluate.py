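"""Robustness evaluation harness: image x attack grid of PSNR / BER / NC."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import watermark as wm
from .attacks import AttackSpec, apply_attack, psnr
from .basis import BasisSpec
from .chaotic import ChebyshevKey

__all__ = ["run_battery", "summarize"]


def run_battery(
    carriers: Sequence[tuple[str, np.ndarray]],
    w: np.ndarray,
    sel_key: wm.SelectionKey,
    scr_key: ChebyshevKey,
    spec: BasisSpec,
    battery: Iterable[AttackSpec],
    include_clean: bool = True,
) -> pd.DataFrame:
    """Generate a zero-watermark per carrier, attack, verify, and tabulate.

    Returns one row per (carrier, attack) — plus a no-attack row per carrier
    when ``include_clean`` — with columns image, attack, params, psnr, ber,
    nc.  Individual attack failures are recorded as NaN rows rather than
    aborting the run.
    """
    battery = list(battery)
    rows = []
    for name, carrier in carriers:
        zw = wm.generate(carrier, w, sel_key, scr_key, spec)
        cells: list[tuple[AttackSpec | None, np.ndarray | None]] = []
        if include_clean:
            cells.append((None, carrier))
        for atk in battery:
            try:
                cells.append((atk, apply_attack(carrier, atk)))
            except Exception as exc:  # keep the sweep alive; surface in the table
                rows.append(
                    dict(image=name, attack=atk.label(), params=str(atk.params),
                         psnr=np.nan, ber=np.nan, nc=np.nan, error=str(exc))
                )
                continue
        for atk, attacked in cells:
            res = wm.verify(attacked, zw, sel_key, scr_key, spec, reference=w)
            rows.append(
                dict(
                    image=name,
                    attack="none" if atk is None else atk.label(),
                    params="" if atk is None else str(atk.params),
                    psnr=psnr(carrier, attacked),
                    ber=res.ber,
                    nc=res.nc,
                    error="",
                )
            )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-attack mean BER / NC over all evaluated images."""
    return (
        results.dropna(subset=["ber"])
        .groupby("attack", sort=False)[["ber", "nc"]]
        .mean()
        .reset_index()
    )
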