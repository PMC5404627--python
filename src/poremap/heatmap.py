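"""Compress the banded pairwise dependence matrix to per-residue heat values.

The column average runs over *computed* partners only: with significant-
interaction culling active, averaging in structural zeros for never-near pairs
would systematically deflate residues in sparse neighbourhoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dependence import DependenceMatrix
from .errors import BoundsError, DimensionError

__all__ = ["HeatMap", "compress", "rank_residues", "export_heatmap", "read_heatmap"]


@dataclass
class HeatMap:
    """Per-residue heat values aligned with the trajectory site order."""

    values: np.ndarray  # >= 0, one per residue
    residue_ids: np.ndarray  # aligned with site order
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.values.shape != self.residue_ids.shape or self.values.ndim != 1:
            raise DimensionError("values and residue_ids must be 1-D and equal length")
        if np.any(self.values < 0):
            raise DimensionError("heat values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def compress(R: DependenceMatrix, residue_ids=None, provenance: dict | None = None) -> HeatMap:
    """Masked column mean: values[i] = mean of R(i, j) over computed partners j.

    Residues with no computed partner get heat 0.
    """
    # row-wise gather-then-mean so the result is bitwise identical to a naive
    # masked row-mean over the selected entries
    values = np.zeros(R.n)
    for i in range(R.n):
        sel = R.R[i][R.computed_mask[i]]
        if sel.size:
            values[i] = sel.mean()
    if residue_ids is None:
        residue_ids = np.arange(R.n)
    prov = dict(provenance or {})
    prov.setdefault("method", R.method)
    return HeatMap(values=values, residue_ids=residue_ids, provenance=prov)


def rank_residues(heat: HeatMap, top_k: int) -> list[int]:
    """Residue ids sorted by descending heat; ties broken by ascending residue id."""
    n = len(heat)
    if not (1 <= top_k <= n):
        raise BoundsError(f"top_k={top_k} out of range for {n} residues")
    order = np.lexsort((heat.residue_ids, -heat.values))
    return [int(r) for r in heat.residue_ids[order][:top_k]]


def export_heatmap(heat: HeatMap, path: str | Path) -> None:
    """Two-column TSV (residue id, heat) with a provenance header; lossless re-read."""
    with open(path, "w") as fh:
        for key, val in sorted(heat.provenance.items()):
            fh.write(f"# {key}={val}\n")
        fh.write("# residue_id\theat\n")
        for rid, val in zip(heat.residue_ids, heat.values):
            fh.write(f"{rid}\t{val:.17g}\n")


def read_heatmap(path: str | Path) -> HeatMap:
    """Read a heat map written by :func:`export_heatmap`."""
    prov: dict = {}
    ids: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    prov[key.strip()] = val.strip()
                continue
            if not line.strip():
                continue
            rid, val = line.split("\t")
            ids.append(int(rid))
            vals.append(float(val))
    return HeatMap(
        values=np.array(vals, dtype=float),
        residue_ids=np.array(ids, dtype=int),
        provenance=prov,
    )
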