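"""Persistence: phantoms and dose grids as flat binary arrays with JSON
sidecars, plans as JSON, metric tables as CSV."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .grids import DoseGrid
from .phantom import Phantom


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_dose(dose: DoseGrid, path) -> None:
    path = Path(path)
    dose.values.astype("<f4").tofile(path)
    meta = {
        "dims": list(dose.shape),
        "spacing_mm": dose.spacing.tolist(),
        "origin_mm": dose.origin.tolist(),
        "axis_order": "RL,AP,SI",
        "dtype": "<f4",
    }
    _sidecar(path).write_text(json.dumps(meta))


def load_dose(path) -> DoseGrid:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    vals = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["dims"])
    return DoseGrid(vals.astype(np.float64), meta["spacing_mm"], meta["origin_mm"])


def save_phantom(phantom: Phantom, path) -> None:
    """Structure masks packed as a uint8 label-bit volume + JSON sidecar."""
    path = Path(path)
    names = ["body"] + sorted(phantom.structures)
    if len(names) > 16:
        raise ValueError("too many structures for the 16-bit label volume")
    labels = np.zeros(phantom.grid_shape, dtype="<u2")
    labels |= phantom.body_mask.astype("<u2")
    for bit, name in enumerate(names[1:], start=1):
        labels |= phantom.structures[name].astype("<u2") << bit
    labels.tofile(path)
    meta = {
        "dims": list(phantom.grid_shape),
        "spacing_mm": phantom.spacing.tolist(),
        "origin_mm": phantom.origin.tolist(),
        "axis_order": "RL,AP,SI",
        "dtype": "<u2",
        "structure_bits": {name: bit for bit, name in enumerate(names)},
    }
    _sidecar(path).write_text(json.dumps(meta))


def load_phantom(path) -> Phantom:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    labels = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["dims"])
    bits = meta["structure_bits"]
    masks = {n: (labels >> b) & 1 for n, b in bits.items()}
    body = masks.pop("body").astype(bool)
    return Phantom(
        grid_shape=tuple(meta["dims"]),
        spacing=np.asarray(meta["spacing_mm"]),
        origin=np.asarray(meta["origin_mm"]),
        structures={n: m.astype(bool) for n, m in masks.items()},
        body_mask=body,
    )


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
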