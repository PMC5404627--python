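"""Trajectory I/O: multi-model PDB and multi-frame GRO readers, representative-site
selection, window trimming, and B-factor annotated structure output.

Internal units are Angstrom and picosecond throughout; GRO nanometre values are
converted on read. Only orthorhombic unit cells are supported — a triclinic cell
is a hard error, never a silent approximation.

Neither PDB nor (reliably) GRO stores a time axis, so ``read_trajectory`` builds
a uniform grid from ``dt``/``t0``; GRO titles containing ``t=`` override it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fnmatch import fnmatchcase
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import (
    BoundsError,
    DimensionError,
    FormatError,
    SelectionError,
    UnsupportedGeometryError,
)

__all__ = [
    "SiteMeta",
    "FrameSeries",
    "SelectionSpec",
    "read_trajectory",
    "register_reader",
    "select_representatives",
    "trim",
    "write_heat_structure",
    "write_trajectory_pdb",
    "write_trajectory_gro",
]

#: relative tolerance for the uniform-time-grid invariant
_UNIFORM_RTOL = 1e-6


@dataclass(frozen=True)
class SiteMeta:
    """Identity of one representative site (one atom standing in for a residue)."""

    resid: int
    resname: str
    atom: str
    chain: str = ""

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """Residue identity tuple that survives resid wrap-around in large solvent sets."""
        return (self.resname, self.resid, self.chain)


@dataclass
class FrameSeries:
    """Per-frame coordinates of representative sites on a uniform time grid.

    Attributes
    ----------
    times : (n_frames,) float array, ps, strictly increasing, uniform spacing.
    coords : (n_frames, n_sites, 3) float array, Angstrom.
    box : (n_frames, 3) float array, Angstrom; orthorhombic edge lengths.
    sites : per-site metadata, constant across frames.
    """

    times: np.ndarray
    coords: np.ndarray
    box: np.ndarray
    sites: list[SiteMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise DimensionError(f"coords must be (frames, sites, 3), got {self.coords.shape}")
        n = self.n_frames
        if n < 1:
            raise DimensionError("FrameSeries requires at least one frame")
        if self.times.shape != (n,):
            raise DimensionError("times length must equal the frame count")
        if self.box.shape != (n, 3):
            raise DimensionError("box must be (frames, 3)")
        if len(self.sites) != self.n_sites:
            raise DimensionError("site metadata length must equal the site count")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")
        if not np.all(self.box > 0):
            raise FormatError("box components must be strictly positive in every frame")
        if n >= 2:
            dts = np.diff(self.times)
            dt0 = dts[0]
            if dt0 <= 0:
                raise FormatError("times must be strictly increasing")
            if np.max(np.abs(dts - dt0)) >= _UNIFORM_RTOL * dt0:
                raise FormatError("time grid is not uniform")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ps (0.0 for a single-frame series)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def residue_ids(self) -> np.ndarray:
        return np.array([s.resid for s in self.sites], dtype=int)


@dataclass(frozen=True)
class SelectionSpec:
    """Name-based selection: (residue-name pattern, representative atom name) pairs."""

    rules: tuple[tuple[str, str], ...]

    def __init__(self, rules: Sequence[tuple[str, str]]):
        object.__setattr__(self, "rules", tuple((str(p), str(a)) for p, a in rules))

    def match(self, resname: str) -> str | None:
        """Return the representative atom name for *resname*, or None.

        Raises SelectionError if more than one rule matches the residue name.
        """
        hits = [atom for pat, atom in self.rules if fnmatchcase(resname, pat)]
        if len(hits) > 1:
            raise SelectionError(f"residue name {resname!r} matched by {len(hits)} rules")
        return hits[0] if hits else None


# ---------------------------------------------------------------------------
# readers

_READER_REGISTRY: dict[str, Callable] = {}


def register_reader(name: str, reader: Callable) -> None:
    """Register a plug-in reader for ``read_trajectory(format=name)``.

    The plug-in contract: ``reader(path)`` returns a tuple
    ``(times_ps, coords_angstrom, box_angstrom, sites)`` with shapes as in
    :class:`FrameSeries`.
    """
    _READER_REGISTRY[name] = reader


def _parse_cryst1(line: str) -> np.ndarray:
    try:
        a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
        alpha, beta, gamma = float(line[33:40]), float(line[40:47]), float(line[47:54])
    except ValueError as exc:
        raise FormatError(f"unparseable CRYST1 record: {line.rstrip()!r}") from exc
    if any(abs(ang - 90.0) > 1e-3 for ang in (alpha, beta, gamma)):
        raise UnsupportedGeometryError(
            f"triclinic cell (angles {alpha} {beta} {gamma}) is not supported"
        )
    return np.array([a, b, c], dtype=float)


def _read_pdb(path: Path) -> tuple[np.ndarray | None, np.ndarray, np.ndarray, list[SiteMeta]]:
    frames: list[list[tuple[float, float, float]]] = []
    frame_meta: list[list[SiteMeta]] = []
    frame_boxes: list[np.ndarray | None] = []
    current_box: np.ndarray | None = None
    cur_xyz: list[tuple[float, float, float]] | None = None
    cur_meta: list[SiteMeta] | None = None
    in_model = False

    def _flush() -> None:
        nonlocal cur_xyz, cur_meta
        if cur_xyz:
            frames.append(cur_xyz)
            frame_meta.append(cur_meta)  # type: ignore[arg-type]
            frame_boxes.append(current_box)
        cur_xyz, cur_meta = None, None

    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "CRYST1":
                current_box = _parse_cryst1(line)
            elif rec == "MODEL ":
                _flush()
                in_model = True
                cur_xyz, cur_meta = [], []
            elif rec == "ENDMDL":
                _flush()
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                if cur_xyz is None:
                    cur_xyz, cur_meta = [], []
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    resid = int(line[22:26])
                except ValueError as exc:
                    raise FormatError(f"unparseable ATOM record: {line.rstrip()!r}") from exc
                cur_xyz.append((x, y, z))
                cur_meta.append(  # type: ignore[union-attr]
                    SiteMeta(
                        resid=resid,
                        resname=line[17:21].strip(),
                        atom=line[12:16].strip(),
                        chain=line[21].strip(),
                    )
                )
    _flush()

    if not frames:
        raise FormatError(f"no coordinates found in {path}")
    counts = {len(f) for f in frames}
    if len(counts) != 1:
        raise FormatError(f"inconsistent atom count across models: {sorted(counts)}")
    for k, meta in enumerate(frame_meta[1:], start=2):
        if meta != frame_meta[0]:
            raise FormatError(f"site order in model {k} differs from model 1")
    boxes = []
    for k, b in enumerate(frame_boxes):
        if b is None:
            raise FormatError(f"frame {k}: missing CRYST1 box record")
        boxes.append(b)
    coords = np.array(frames, dtype=float)
    return None, coords, np.array(boxes), frame_meta[0]


_GRO_TIME_RE = re.compile(r"\bt\s*=\s*([0-9.eE+\-]+)")


def _read_gro(path: Path) -> tuple[np.ndarray | None, np.ndarray, np.ndarray, list[SiteMeta]]:
    frames: list[np.ndarray] = []
    frame_meta: list[list[SiteMeta]] = []
    boxes: list[np.ndarray] = []
    times: list[float] = []
    have_time = True
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    nlines = len(lines)
    while pos < nlines:
        title = lines[pos]
        if not title.strip() and pos == nlines - 1:
            break
        m = _GRO_TIME_RE.search(title)
        if m:
            times.append(float(m.group(1)))
        else:
            have_time = False
        try:
            natoms = int(lines[pos + 1].strip())
        except (IndexError, ValueError) as exc:
            raise FormatError(f"bad atom-count line at line {pos + 2}") from exc
        atom_lines = lines[pos + 2 : pos + 2 + natoms]
        if len(atom_lines) < natoms:
            raise FormatError("truncated GRO frame")
        xyz = np.empty((natoms, 3))
        meta: list[SiteMeta] = []
        for i, line in enumerate(atom_lines):
            try:
                xyz[i] = (float(line[20:28]), float(line[28:36]), float(line[36:44]))
                resid = int(line[0:5])
            except ValueError as exc:
                raise FormatError(f"unparseable GRO atom line: {line!r}") from exc
            meta.append(
                SiteMeta(resid=resid, resname=line[5:10].strip(), atom=line[10:15].strip())
            )
        box_idx = pos + 2 + natoms
        if box_idx >= nlines:
            raise FormatError("missing GRO box line")
        box_fields = lines[box_idx].split()
        if len(box_fields) not in (3, 9):
            raise FormatError(f"malformed GRO box line: {lines[box_idx]!r}")
        vals = [float(v) for v in box_fields]
        if len(vals) == 9 and any(abs(v) > 1e-9 for v in vals[3:]):
            raise UnsupportedGeometryError("triclinic GRO box is not supported")
        frames.append(xyz * 10.0)  # nm -> Angstrom
        boxes.append(np.array(vals[:3]) * 10.0)
        frame_meta.append(meta)
        pos = box_idx + 1

    if not frames:
        raise FormatError(f"no frames found in {path}")
    counts = {f.shape[0] for f in frames}
    if len(counts) != 1:
        raise FormatError(f"inconsistent atom count across frames: {sorted(counts)}")
    for k, meta in enumerate(frame_meta[1:], start=2):
        if meta != frame_meta[0]:
            raise FormatError(f"site order in frame {k} differs from frame 1")
    t = np.array(times) if have_time and len(times) == len(frames) else None
    return t, np.array(frames), np.array(boxes), frame_meta[0]


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix == ".gro":
        return "gro"
    with open(path) as fh:
        head = fh.readline()
    if head[:6] in ("CRYST1", "MODEL ", "ATOM  ", "HETATM", "REMARK", "HEADER"):
        return "pdb"
    return "gro"


def read_trajectory(
    path: str | Path,
    format: str = "auto",
    dt: float = 1.0,
    t0: float = 0.0,
) -> FrameSeries:
    """Read a multi-frame trajectory into a :class:`FrameSeries`.

    Parameters
    ----------
    path : trajectory file (multi-model PDB or multi-frame GRO).
    format : "pdb", "gro", "auto" (extension/content sniffing), or the name of a
        reader registered with :func:`register_reader`.
    dt, t0 : time grid (ps) used when the file itself carries no times. GRO
        title lines containing ``t=`` take precedence.

    Raises
    ------
    FileNotFoundError, FormatError, UnsupportedGeometryError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")
    if format in _READER_REGISTRY:
        times, coords, box, sites = _READER_REGISTRY[format](path)
        return FrameSeries(np.asarray(times, float), coords, box, list(sites))
    if format == "auto":
        format = _sniff_format(path)
    if format == "pdb":
        times, coords, box, sites = _read_pdb(path)
    elif format == "gro":
        times, coords, box, sites = _read_gro(path)
    else:
        raise FormatError(f"unknown trajectory format {format!r}")
    if times is None:
        times = t0 + dt * np.arange(coords.shape[0])
    return FrameSeries(times, coords, box, sites)


# ---------------------------------------------------------------------------
# selection and trimming


def select_representatives(traj: FrameSeries, spec: SelectionSpec) -> FrameSeries:
    """Reduce to one representative site per matched residue.

    Residues not matched by any rule are dropped; output sites are ordered by
    (chain, resid, resname). Time grid and boxes are unchanged.
    """
    by_residue: dict[tuple, list[int]] = {}
    for idx, site in enumerate(traj.sites):
        by_residue.setdefault(site.residue_key, []).append(idx)

    chosen: list[tuple[tuple, int]] = []
    for key, indices in by_residue.items():
        resname = key[0]
        atom = spec.match(resname)
        if atom is None:
            continue
        hits = [i for i in indices if traj.sites[i].atom == atom]
        if len(hits) == 0:
            raise SelectionError(
                f"residue {resname} {key[1]} {key[2] or ''}".strip()
                + f" has no atom named {atom!r}"
            )
        if len(hits) > 1:
            raise SelectionError(
                f"residue {resname} {key[1]} has {len(hits)} atoms named {atom!r}"
            )
        chosen.append((key, hits[0]))

    chosen.sort(key=lambda item: (item[0][2], item[0][1], item[0][0]))  # chain, resid, resname
    idx = [i for _, i in chosen]
    return FrameSeries(
        times=traj.times.copy(),
        coords=traj.coords[:, idx, :].copy(),
        box=traj.box.copy(),
        sites=[traj.sites[i] for i in idx],
    )


def trim(traj: FrameSeries, first_frame: int, last_frame: int, stride: int = 1) -> FrameSeries:
    """Keep frames ``first, first+stride, ... <= last`` (0-based, inclusive).

    Times are preserved from the input (not re-zeroed).
    """
    n = traj.n_frames
    if stride < 1:
        raise BoundsError(f"stride must be >= 1, got {stride}")
    if not (0 <= first_frame <= last_frame < n):
        raise BoundsError(
            f"window [{first_frame}, {last_frame}] out of range for {n} frames"
        )
    sel = np.arange(first_frame, last_frame + 1, stride)
    return FrameSeries(
        times=traj.times[sel].copy(),
        coords=traj.coords[sel].copy(),
        box=traj.box[sel].copy(),
        sites=list(traj.sites),
    )


# ---------------------------------------------------------------------------
# writers

_PDB_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{alt:1s}{resname:<4s}{chain:1s}{resid:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}          {elem:>2s}\n"
)


def _pdb_atom_name(name: str) -> str:
    # Standard PDB convention: names shorter than 4 chars start in column 14.
    return name if len(name) >= 4 else f" {name:<3s}"


def _write_pdb_frame(fh, traj: FrameSeries, frame: int, bfactors: np.ndarray) -> None:
    box = traj.box[frame]
    fh.write(
        f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
    )
    for i, site in enumerate(traj.sites):
        x, y, z = traj.coords[frame, i]
        elem = (site.atom[:1] or "X").upper()
        fh.write(
            _PDB_ATOM_FMT.format(
                serial=(i + 1) % 100000,
                name=_pdb_atom_name(site.atom),
                alt=" ",
                resname=site.resname,
                chain=site.chain or " ",
                resid=site.resid % 10000,
                x=x,
                y=y,
                z=z,
                occ=1.0,
                bf=min(max(bfactors[i], 0.0), 999.99),
                elem=elem,
            )
        )


def write_trajectory_pdb(traj: FrameSeries, path: str | Path, bfactors=None) -> None:
    """Write all frames as a multi-model PDB with per-model CRYST1 records."""
    bf = np.zeros(traj.n_sites) if bfactors is None else np.asarray(bfactors, float)
    if bf.shape != (traj.n_sites,):
        raise DimensionError("bfactors length must equal the site count")
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"MODEL     {k + 1:>4d}\n")
            _write_pdb_frame(fh, traj, k, bf)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_trajectory_gro(traj: FrameSeries, path: str | Path) -> None:
    """Write all frames as a concatenated GRO file (nm units, ``t=`` in titles)."""
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"poremap frame {k} t= {traj.times[k]:.4f}\n")
            fh.write(f"{traj.n_sites:>5d}\n")
            for i, site in enumerate(traj.sites):
                x, y, z = traj.coords[k, i] / 10.0
                fh.write(
                    f"{site.resid % 100000:>5d}{site.resname:<5s}{site.atom:>5s}"
                    f"{(i + 1) % 100000:>5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = traj.box[k] / 10.0
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def write_heat_structure(traj: FrameSeries, frame: int, heat, path: str | Path) -> None:
    """Write one frame as a PDB whose B-factor column carries per-site heat.

    Heat values are rescaled linearly so the maximum maps to 99.99; an all-zero
    heat map yields all-zero B-factors. Rescaling is per call (per map).
    """
    values = np.asarray(getattr(heat, "values", heat), dtype=float)
    if values.shape != (traj.n_sites,):
        raise DimensionError(
            f"heat length {values.shape} does not match site count {traj.n_sites}"
        )
    if not (0 <= frame < traj.n_frames):
        raise BoundsError(f"frame {frame} out of range for {traj.n_frames} frames")
    vmax = values.max() if values.size else 0.0
    bf = values / vmax * 99.99 if vmax > 0 else np.zeros_like(values)
    with open(path, "w") as fh:
        _write_pdb_frame(fh, traj, frame, bf)
        fh.write("END\n")
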