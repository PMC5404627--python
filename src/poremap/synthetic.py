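"""Seeded generators of toy pore-formation trajectories and estimator fixtures.

The trajectory generator is a geometric fixture, not an MD engine: two jittered
square lattices of representative sites (one per leaflet) fluctuate in-plane in
a periodic box; from a chosen onset frame, the sites nearest a pore centre are
pushed radially outward (breaking their mutual contacts) while the box shrinks
along z and widens in x/y at constant volume. Ground truth (pore-lining ids,
onset time) is recorded so every downstream stage can be validated end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .trajio import FrameSeries, SiteMeta

__all__ = [
    "PoreSimParams",
    "GroundTruth",
    "make_pore_trajectory",
    "make_gaussian_pair",
    "make_zero_inflated_activity",
]

#: pushed sites stop once this many pore radii from the centre (the pore rim)
_RIM_FACTOR = 3.0


@dataclass(frozen=True)
class PoreSimParams:
    """Parameters of the toy poration trajectory (lengths Angstrom, times ps)."""

    n_per_leaflet: int = 64
    box0: tuple[float, float, float] = (70.0, 70.0, 120.0)
    leaflet_offset: float = 20.0  # +- offset of each leaflet from the box z centre
    jitter_sigma: float = 0.3  # per-frame in-plane Gaussian jitter
    n_frames: int = 500
    dt: float = 10.0
    pore_onset_frame: int = 300
    pore_center: tuple[float, float] | None = None  # default: box centre
    pore_radius: float = 12.0
    pore_push: float = 0.5  # radial displacement per frame during opening
    box_shrink_rate: float = 0.08  # z shrink per frame after onset (x, y grow)
    seed: int = 0
    distractor: bool = False  # displace one far-from-pore site pre-onset

    def __post_init__(self) -> None:
        if self.n_per_leaflet < 1 or self.n_frames < 1:
            raise ParameterError("n_per_leaflet and n_frames must be positive")
        if not (0 <= self.pore_onset_frame < self.n_frames):
            raise ParameterError(
                f"pore_onset_frame {self.pore_onset_frame} must be < n_frames {self.n_frames}"
            )
        if any(b <= 0 for b in self.box0):
            raise ParameterError("box dimensions must be positive")
        if self.pore_radius >= min(self.box0[0], self.box0[1]) / 2:
            raise ParameterError("pore_radius must be < half the in-plane box size")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        zmin = self.box0[2] - self.box_shrink_rate * (self.n_frames - 1 - self.pore_onset_frame)
        if zmin <= 0:
            raise ParameterError("box z would shrink to zero before the last frame")


@dataclass(frozen=True)
class GroundTruth:
    """What the pipeline should recover from the generated trajectory."""

    pore_lining_ids: tuple[int, ...]  # residue ids (1-based, matching the PDB)
    onset_time: float  # ps
    seed: int

    def to_json(self, path: str | Path, params: PoreSimParams | None = None) -> None:
        payload = {
            "pore_lining_ids": list(self.pore_lining_ids),
            "onset_time": self.onset_time,
            "seed": self.seed,
        }
        if params is not None:
            payload["params"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in params.__dict__.items()
            }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _box_edges(params: PoreSimParams, z: float) -> tuple[float, float, float]:
    """Box edges for a given z, with x and y grown to conserve the cell volume."""
    x0, y0, z0 = params.box0
    s = math.sqrt(z0 / z)
    return (x0 * s, y0 * s, z)


def make_pore_trajectory(params: PoreSimParams) -> tuple[FrameSeries, GroundTruth]:
    """Generate the toy poration trajectory; same params+seed give identical output."""
    rng = np.random.default_rng(params.seed)
    n_leaf = params.n_per_leaflet
    n = 2 * n_leaf
    x0, y0, z0 = params.box0
    m = math.ceil(math.sqrt(n_leaf))
    sx, sy = x0 / m, y0 / m
    # staggered rows (triangular-like packing): keeps every lattice pair
    # distance well away from the contact-detection buffer, so the quiescent
    # pre-onset window produces essentially no spurious events
    grid = np.array(
        [
            (((c + 0.25 + 0.5 * (r % 2)) * sx) % x0, (r + 0.5) * sy)
            for r in range(m)
            for c in range(m)
        ][:n_leaf]
    )
    base_xy = np.vstack([grid, grid]) + rng.normal(0.0, params.jitter_sigma, (n, 2))
    zs = np.concatenate(
        [
            np.full(n_leaf, z0 / 2 - params.leaflet_offset),
            np.full(n_leaf, z0 / 2 + params.leaflet_offset),
        ]
    )
    center = np.array(params.pore_center if params.pore_center is not None else (x0 / 2, y0 / 2))

    # The distractor draws from its own RNG so the jitter stream (and hence
    # the rest of the trajectory) is identical with and without the flag.
    distractor_site = -1
    distractor_dir = np.zeros(2)
    if params.distractor:
        drng = np.random.default_rng((params.seed, 0xD157))
        base_d = np.linalg.norm(
            (base_xy - center) - params.box0[:2] * np.round((base_xy - center) / params.box0[:2]),
            axis=1,
        )
        far = np.flatnonzero(base_d > 2 * params.pore_radius)
        distractor_site = int(drng.choice(far)) if far.size else int(np.argmax(base_d))
        theta = drng.uniform(0, 2 * np.pi)
        distractor_dir = np.array([np.cos(theta), np.sin(theta)])

    boxes = np.tile(np.array(params.box0), (params.n_frames, 1))
    push = np.zeros((n, 2))
    coords = np.empty((params.n_frames, n, 3))
    lining: np.ndarray | None = None
    rim = _RIM_FACTOR * params.pore_radius
    # The cell deforms while the pore opens (the deformation is concomitant
    # with poration): z shrinks linearly as long as lining sites are still
    # moving toward the rim, then holds.
    z_now = z0
    opening = False

    box0_xy = np.array(params.box0[:2])
    for k in range(params.n_frames):
        jit = rng.normal(0.0, params.jitter_sigma, (n, 2)) if params.jitter_sigma > 0 else 0.0
        if params.distractor and k == params.pore_onset_frame // 2:
            push[distractor_site] += distractor_dir * 1.5 * params.pore_radius
        if opening:
            z_now = z_now - params.box_shrink_rate
        if lining is not None:
            boxes[k] = _box_edges(params, z_now)
        box_xy = boxes[k, :2]
        # in-plane coordinates scale affinely with the box, as under a
        # semi-isotropic barostat; jitter is applied in absolute Angstrom
        xy = np.mod((base_xy + push) * (box_xy / box0_xy) + jit, box_xy)
        coords[k, :, :2] = xy
        coords[k, :, 2] = zs
        if k == params.pore_onset_frame:
            delta = xy - center
            delta -= box_xy * np.round(delta / box_xy)
            lining = np.flatnonzero(np.linalg.norm(delta, axis=1) <= params.pore_radius)
        if lining is not None:
            # push pore-lining sites radially outward (reference coordinates)
            # until they reach the rim
            pos = base_xy[lining] + push[lining]
            delta = pos - center
            delta -= box0_xy * np.round(delta / box0_xy)
            r = np.linalg.norm(delta, axis=1)
            moving = r < rim
            safe_r = np.where(r > 1e-9, r, 1.0)
            step = (delta / safe_r[:, None]) * params.pore_push
            step[r <= 1e-9] = (params.pore_push, 0.0)
            push[lining[moving]] += step[moving]
            opening = bool(moving.any()) and params.pore_push > 0

    sites = [SiteMeta(resid=i + 1, resname="LIP", atom="P") for i in range(n)]
    times = params.dt * np.arange(params.n_frames)
    traj = FrameSeries(times=times, coords=coords, box=boxes, sites=sites)
    truth = GroundTruth(
        pore_lining_ids=tuple(int(i) + 1 for i in lining),  # type: ignore[union-attr]
        onset_time=float(times[params.pore_onset_frame]),
        seed=params.seed,
    )
    return traj, truth


def make_gaussian_pair(n: int, rho: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """n samples from a standard bivariate Gaussian with correlation rho."""
    if n < 2:
        raise ParameterError("n must be >= 2")
    if not -1.0 < rho < 1.0:
        raise ParameterError(f"|rho| must be < 1, got {rho}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rho * x + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return x, y


def make_zero_inflated_activity(n: int, zero_fraction: float, seed: int) -> np.ndarray:
    """Quiescent-then-active fixture: a leading block of exact zeros, then
    positive half-Gaussian samples."""
    if not 0.0 <= zero_fraction < 1.0:
        raise ParameterError(f"zero_fraction must be in [0, 1), got {zero_fraction}")
    if n < 1:
        raise ParameterError("n must be positive")
    rng = np.random.default_rng(seed)
    n_zero = int(math.floor(zero_fraction * n))
    tail = np.abs(rng.standard_normal(n - n_zero))
    tail[tail == 0] = np.finfo(float).tiny  # keep strictly positive support
    return np.concatenate([np.zeros(n_zero), tail])
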