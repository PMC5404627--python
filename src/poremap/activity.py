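"""Slow, non-negative activity functions a(t).

Contact events come from a two-cutoff hysteresis ("buffer") detector on each
pair-distance series: an edge forms when the distance drops below the low
cutoff and breaks when it rises above the high cutoff; excursions inside the
buffer zone never change state, which suppresses recrossing noise. Event times
are turned into a smooth rate (events/ps) with a truncated Gaussian kernel.
A per-frame unit-cell edge length serves as the alternative, geometric activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import erf

from .errors import DomainError, ParameterError
from .geometry import DistancePairSeries
from .trajio import FrameSeries

__all__ = [
    "FORMING",
    "BREAKING",
    "GraphParams",
    "Event",
    "ActivityTrace",
    "detect_edge_events",
    "detect_events",
    "smooth_event_activity",
    "box_dimension_activity",
    "auto_sigma",
    "write_activity_tsv",
    "read_activity_tsv",
]

FORMING = "forming"
BREAKING = "breaking"

#: Gaussian kernels are truncated at +-4 sigma and renormalised to unit mass.
_TRUNC = 4.0
_TRUNC_MASS = float(erf(_TRUNC / np.sqrt(2.0)))


@dataclass(frozen=True)
class GraphParams:
    """Cutoff-graph parameters: hysteresis cutoffs (Angstrom) and smoothing (ps).

    Defaults follow the nearest-neighbour rule of thumb for lipid phosphorus
    coarse-graining: low 11, high 13 (a 2 Angstrom buffer).
    """

    low_cutoff: float = 11.0
    high_cutoff: float = 13.0
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.low_cutoff < self.high_cutoff):
            raise ParameterError(
                f"need 0 < low < high, got {self.low_cutoff}, {self.high_cutoff}"
            )
        if self.smoothing_sigma <= 0:
            raise ParameterError("smoothing_sigma must be positive")


@dataclass(frozen=True)
class Event:
    """One contact-forming or contact-breaking event on the frame grid."""

    pair: tuple[int, int]
    time: float
    kind: str  # FORMING or BREAKING


@dataclass
class ActivityTrace:
    """Non-negative scalar activity on a time grid.

    kind is one of {forming, breaking, box_x, box_y, box_z}; units are
    events/ps for graph activities and Angstrom for box activities.
    """

    times: np.ndarray
    a: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.times.shape != self.a.shape:
            raise DomainError("times and a must have equal length")
        if np.any(self.a < 0):
            raise DomainError("activity must be non-negative")


def detect_edge_events(series: DistancePairSeries, params: GraphParams) -> list[Event]:
    """Run the two-state hysteresis machine on one pair-distance series.

    Initial state at frame 0 is PRESENT iff d0 < low_cutoff; a start inside the
    buffer zone counts as ABSENT (avoids phantom breaking events from borderline
    starting contacts). ABSENT -> PRESENT when d < low emits a forming event;
    PRESENT -> ABSENT when d > high emits a breaking event.
    """
    d = series.d
    t = series.times
    low, high = params.low_cutoff, params.high_cutoff
    events: list[Event] = []
    present = bool(d[0] < low)
    for k in range(1, len(d)):
        if present:
            if d[k] > high:
                present = False
                events.append(Event(series.pair, float(t[k]), BREAKING))
        elif d[k] < low:
            present = True
            events.append(Event(series.pair, float(t[k]), FORMING))
    return events


def detect_events(series_list: list[DistancePairSeries], params: GraphParams) -> list[Event]:
    """Detect events for every pair; result sorted by time, then pair."""
    events: list[Event] = []
    for s in series_list:
        events.extend(detect_edge_events(s, params))
    events.sort(key=lambda e: (e.time, e.pair))
    return events


def smooth_event_activity(
    events: list[Event], kind: str, sigma: float, grid: np.ndarray
) -> ActivityTrace:
    """Kernel event-rate estimate: sum of unit-mass truncated Gaussians (events/ps).

    The trapezoidal integral of the trace over the event support approximates
    the number of events of the requested kind. An empty event list yields the
    all-zero trace (the zero-valued-activity case downstream estimators must
    tolerate).
    """
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    if kind not in (FORMING, BREAKING):
        raise ParameterError(f"kind must be forming/breaking, got {kind!r}")
    grid = np.asarray(grid, dtype=float)
    a = np.zeros_like(grid)
    peak = 1.0 / (sigma * np.sqrt(2.0 * np.pi) * _TRUNC_MASS)
    width = _TRUNC * sigma
    for e in events:
        if e.kind != kind:
            continue
        lo = np.searchsorted(grid, e.time - width, side="left")
        hi = np.searchsorted(grid, e.time + width, side="right")
        u = (grid[lo:hi] - e.time) / sigma
        a[lo:hi] += peak * np.exp(-0.5 * u * u)
    return ActivityTrace(grid, a, kind, meta={"sigma": float(sigma)})


def box_dimension_activity(traj: FrameSeries, axis: str) -> ActivityTrace:
    """Per-frame unit-cell edge length (Angstrom) as a geometric activity marker."""
    try:
        idx = {"x": 0, "y": 1, "z": 2}[axis]
    except KeyError:
        raise ParameterError(f"axis must be x, y or z, got {axis!r}") from None
    return ActivityTrace(traj.times.copy(), traj.box[:, idx].copy(), f"box_{axis}")


def auto_sigma(times: np.ndarray, fraction: float = 0.05) -> float:
    """Smoothing rule of thumb: 5% of the window length, rounded to the frame grid."""
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise DomainError("need at least 2 frames to derive a smoothing scale")
    dt = float(times[1] - times[0])
    span = float(times[-1] - times[0])
    return max(dt, round(fraction * span / dt) * dt)


def write_activity_tsv(trace: ActivityTrace, path: str | Path) -> None:
    """Two-column TSV (time ps, activity) with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# kind={trace.kind}\n")
        for key, val in sorted(trace.meta.items()):
            fh.write(f"# {key}={val}\n")
        fh.write("# time_ps\tactivity\n")
        for t, v in zip(trace.times, trace.a):
            fh.write(f"{t:.17g}\t{v:.17g}\n")


def read_activity_tsv(path: str | Path) -> ActivityTrace:
    """Read a trace written by :func:`write_activity_tsv`."""
    kind = "unknown"
    meta: dict = {}
    times: list[float] = []
    vals: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key == "kind":
                        kind = val.strip()
                    else:
                        meta[key] = val.strip()
                continue
            if not line.strip():
                continue
            t, v = line.split("\t")
            times.append(float(t))
            vals.append(float(v))
    return ActivityTrace(np.array(times), np.array(vals), kind, meta)
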