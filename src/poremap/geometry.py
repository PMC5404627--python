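"""Periodic-boundary distance geometry for orthorhombic cells.

Minimum-image distances, culling of site pairs to those that ever come within a
significant-interaction cutoff, per-pair distance time series, and non-negative
rate series (absolute finite differences on a midpoint grid).

Exact half-box displacements wrap with round-half-to-even (numpy rounding); the
result at this measure-zero tie is convention-dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import BoundsError, DegenerateInputError, DomainError
from .trajio import FrameSeries

__all__ = [
    "PairSet",
    "DistancePairSeries",
    "RateSeries",
    "min_image_displacement",
    "min_image_distance",
    "cull_pairs",
    "pair_distance_series",
    "rate_series",
    "export_pair_series_tsv",
]


@dataclass
class PairSet:
    """Ordered set of (i, j) site-index pairs with i < j.

    ``cull_cutoff`` records the significant-interaction cutoff used to build the
    set (None means all pairs were kept).
    """

    pairs: np.ndarray  # (m, 2) int, i < j, ascending lexicographic order
    cull_cutoff: float | None = None

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if self.pairs.size:
            if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
                raise DomainError("pairs must satisfy i < j")
            uniq = {tuple(p) for p in self.pairs}
            if len(uniq) != len(self.pairs):
                raise DomainError("duplicate pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return (tuple(p) for p in self.pairs)


@dataclass
class DistancePairSeries:
    """Minimum-image distance trace of one site pair over the analysed frames."""

    pair: tuple[int, int]
    d: np.ndarray  # Angstrom, >= 0
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.times is None:
            self.times = np.arange(len(self.d), dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != self.d.shape:
            raise DomainError("times and d must have equal length")


@dataclass
class RateSeries:
    """Non-negative rate of change |Δd|/Δt of a pair distance, on the midpoint grid."""

    pair: tuple[int, int]
    r: np.ndarray  # Angstrom/ps, >= 0, length frames-1
    times: np.ndarray  # midpoints t_k + dt/2


def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if not np.all(box > 0):
        raise DomainError("box components must be strictly positive")
    return box


def min_image_displacement(delta, box) -> np.ndarray:
    """Wrap a displacement vector into the minimum-image convention (orthorhombic)."""
    box = _check_box(box)
    delta = np.asarray(delta, dtype=float)
    return delta - box * np.round(delta / box)


def min_image_distance(p, q, box) -> float | np.ndarray:
    """Minimum-image distance between points p and q in an orthorhombic box.

    Equals min over all integer image translations n of |p - q + box*n|;
    broadcasts over leading axes.
    """
    disp = min_image_displacement(np.asarray(p, float) - np.asarray(q, float), box)
    return np.linalg.norm(disp, axis=-1)


def _frame_distance_matrix(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(s, s) minimum-image distance matrix for one frame."""
    delta = coords[:, None, :] - coords[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))


def cull_pairs(traj: FrameSeries, cutoff: float | None = None) -> PairSet:
    """Select site pairs with a significant interaction in the analysed window.

    cutoff=None keeps all C(n, 2) pairs; otherwise exactly the pairs whose
    minimum-image distance is <= cutoff in at least one frame are kept. The
    output order is ascending (i, j).
    """
    s = traj.n_sites
    if s < 2:
        warnings.warn("fewer than 2 sites: empty pair set", stacklevel=2)
        return PairSet(np.empty((0, 2), dtype=int), cull_cutoff=cutoff)
    iu, ju = np.triu_indices(s, k=1)
    if cutoff is None or np.isinf(cutoff):
        return PairSet(np.column_stack([iu, ju]), cull_cutoff=None)
    ever = np.zeros(len(iu), dtype=bool)
    for k in range(traj.n_frames):
        if ever.all():
            break
        dmat = _frame_distance_matrix(traj.coords[k], traj.box[k])
        ever |= dmat[iu, ju] <= cutoff
    return PairSet(np.column_stack([iu[ever], ju[ever]]), cull_cutoff=float(cutoff))


def pair_distance_series(traj: FrameSeries, pairs: PairSet) -> list[DistancePairSeries]:
    """Minimum-image distance time series for every pair, using each frame's own box.

    The per-frame box matters because the cell may deform during the window.
    """
    if len(pairs) == 0:
        return []
    idx = pairs.pairs
    if idx.min() < 0 or idx.max() >= traj.n_sites:
        raise BoundsError("pair index out of range")
    delta = traj.coords[:, idx[:, 0], :] - traj.coords[:, idx[:, 1], :]  # (f, m, 3)
    box = traj.box[:, None, :]
    delta -= box * np.round(delta / box)
    d = np.sqrt(np.einsum("fmk,fmk->fm", delta, delta))
    return [
        DistancePairSeries(pair=(int(i), int(j)), d=d[:, m], times=traj.times)
        for m, (i, j) in enumerate(idx)
    ]


def rate_series(series: DistancePairSeries, dt: float | None = None) -> RateSeries:
    """Absolute forward difference |d_{k+1} - d_k| / dt on the midpoint time grid."""
    d = series.d
    if len(d) < 2:
        raise DegenerateInputError("rate series needs at least 2 frames")
    if dt is None:
        dt = float(series.times[1] - series.times[0])
    if dt <= 0:
        raise DomainError("dt must be positive")
    r = np.abs(np.diff(d)) / dt
    mid = series.times[:-1] + dt / 2.0
    return RateSeries(pair=series.pair, r=r, times=mid)


def export_pair_series_tsv(series_list: list[DistancePairSeries], path: str | Path) -> None:
    """Write pair series as TSV: columns i, j, then one distance per frame."""
    with open(path, "w") as fh:
        fh.write("# i\tj\td_per_frame...\n")
        for s in series_list:
            vals = "\t".join(f"{v:.6f}" for v in s.d)
            fh.write(f"{s.pair[0]}\t{s.pair[1]}\t{vals}\n")
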