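"""Snapshot and metadata input/output.

Snapshots are strain-labelled rasters stored either as two tab-separated
integer matrices (portable, diff-friendly) or as an RGB image with strain 1
mapped to green, strain 2 to red, mixtures blended and empty space black.
Run metadata goes to a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import __version__
from .lattice import LatticeState

__all__ = [
    "write_snapshot_tsv",
    "read_snapshot_tsv",
    "write_snapshot_png",
    "write_metadata",
]


def write_snapshot_tsv(path, state: LatticeState) -> Path:
    """Write the two occupancy matrices to one TSV file.

    Layout: a comment header, the strain-1 matrix, a blank line, the
    strain-2 matrix (row 0 = bottom of the lattice)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# chiralgrowth snapshot t={state.t} geometry={state.geometry} "
                 f"shape={state.n1.shape[0]}x{state.n1.shape[1]}\n")
        np.savetxt(fh, state.n1, fmt="%d", delimiter="\t")
        fh.write("\n")
        np.savetxt(fh, state.n2, fmt="%d", delimiter="\t")
    return path


def read_snapshot_tsv(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a snapshot written by :func:`write_snapshot_tsv`.

    Returns (n1, n2, t)."""
    path = Path(path)
    t = 0.0
    blocks: list[list[list[int]]] = [[]]
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tok in line.split():
                    if tok.startswith("t="):
                        t = float(tok[2:])
                continue
            if not line.strip():
                if blocks[-1]:
                    blocks.append([])
                continue
            blocks[-1].append([int(v) for v in line.split("\t")])
    blocks = [b for b in blocks if b]
    if len(blocks) != 2:
        raise ValueError(f"expected 2 matrices in {path}, found {len(blocks)}")
    return np.asarray(blocks[0]), np.asarray(blocks[1]), t


def write_snapshot_png(path, state: LatticeState, N: int) -> Path:
    """Render the snapshot as an RGB PNG (strain 1 green, strain 2 red)."""
    from PIL import Image

    r = (state.n2 * (255.0 / N)).astype(np.uint8)
    g = (state.n1 * (255.0 / N)).astype(np.uint8)
    b = np.zeros_like(r)
    rgb = np.stack([r, g, b], axis=-1)[::-1]  # row 0 at the image bottom
    img = Image.fromarray(rgb, mode="RGB")
    path = Path(path)
    img.save(path)
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_metadata(path, **fields) -> Path:
    """Write run metadata (parameters, seed, stop reason, ...) as JSON."""
    path = Path(path)
    payload = {"code_version": __version__}
    payload.update({k: _jsonable(v) for k, v in fields.items()})
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
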