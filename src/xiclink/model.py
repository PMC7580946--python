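"""Core domain types: points, scans, runs, XICs and annotated XIC sets."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence


class XiclinkError(Exception):
    """Base class for package errors."""


class EmptyRunError(XiclinkError):
    """Raised when an operation requires a non-empty run."""


class CalibrationError(XiclinkError):
    """Raised when a self-calibration quantity cannot be estimated."""


class SchemaError(XiclinkError):
    """Raised when a table is missing required columns or is malformed."""


class InvariantError(XiclinkError):
    """Raised when input data violates a structural invariant."""


class FormatError(XiclinkError):
    """Raised when a source file cannot be parsed."""


@dataclass(frozen=True, slots=True)
class Point:
    """One raw MS1 data point.

    Attributes
    ----------
    point_id : int
        Stable identifier, unique within a run.  Ids also serve as the
        final deterministic tie-break wherever points must be ordered.
    mz : float
        Mass-to-charge ratio (Thomson).
    rt : float
        Retention time (seconds).
    intensity : float
        Ion count (arbitrary units), non-negative and finite.
    scan_index : int
        0-based index of the containing scan.
    """

    point_id: int
    mz: float
    rt: float
    intensity: float
    scan_index: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.intensity) and self.intensity >= 0):
            raise InvariantError(
                f"point {self.point_id}: intensity must be finite and >= 0, "
                f"got {self.intensity!r}"
            )
        if not (math.isfinite(self.mz) and self.mz > 0):
            raise InvariantError(
                f"point {self.point_id}: mz must be finite and > 0, got {self.mz!r}"
            )
        if not (math.isfinite(self.rt) and self.rt >= 0):
            raise InvariantError(
                f"point {self.point_id}: rt must be finite and >= 0, got {self.rt!r}"
            )


def intensity_order_key(p: Point) -> tuple:
    """Sort key for decreasing-intensity processing order.

    Ties in intensity are broken by ascending RT, then ascending m/z, then
    ascending point id, so the processing order is a deterministic total
    order.
    """
    return (-p.intensity, p.rt, p.mz, p.point_id)


@dataclass(frozen=True, slots=True)
class Scan:
    """One mass spectrum: the points acquired at a single retention time."""

    scan_index: int
    rt: float
    points: tuple[Point, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.points, self.points[1:]):
            if b.mz < a.mz:
                raise InvariantError(
                    f"scan {self.scan_index}: points not sorted by ascending mz"
                )
        for p in self.points:
            if p.rt != self.rt:
                raise InvariantError(
                    f"scan {self.scan_index}: point {p.point_id} has rt {p.rt}, "
                    f"scan rt is {self.rt}"
                )


@dataclass(frozen=True, slots=True)
class Run:
    """An ordered collection of MS1 scans plus acquisition metadata.

    ``mode`` is one of ``"centroid"``, ``"profile"`` or ``"unknown"``.
    """

    scans: tuple[Scan, ...]
    mode: str = "unknown"
    source: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("centroid", "profile", "unknown"):
            raise InvariantError(f"unknown acquisition mode {self.mode!r}")
        for a, b in zip(self.scans, self.scans[1:]):
            if b.rt <= a.rt:
                raise InvariantError(
                    f"scan RTs not strictly increasing at scans "
                    f"{a.scan_index}/{b.scan_index} ({a.rt} -> {b.rt})"
                )
        seen: set[int] = set()
        for s in self.scans:
            for p in s.points:
                if p.point_id in seen:
                    raise InvariantError(f"duplicate point_id {p.point_id} in run")
                seen.add(p.point_id)

    def iter_points(self) -> Iterator[Point]:
        for s in self.scans:
            yield from s.points

    @property
    def n_points(self) -> int:
        return sum(len(s.points) for s in self.scans)

    @property
    def n_scans(self) -> int:
        return len(self.scans)


@dataclass(frozen=True, slots=True)
class Xic:
    """One extracted ion chromatogram: a rooted set of points.

    The root is the point that seeded the cluster; because links only run
    from higher to lower intensity, the root is also the intensity apex.
    Bounds and the total intensity are computed from the members.
    """

    xic_id: str
    root: Point
    points: tuple[Point, ...]

    @property
    def apex(self) -> Point:
        return min(self.points, key=intensity_order_key)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def mz_min(self) -> float:
        return min(p.mz for p in self.points)

    @property
    def mz_max(self) -> float:
        return max(p.mz for p in self.points)

    @property
    def rt_min(self) -> float:
        return min(p.rt for p in self.points)

    @property
    def rt_max(self) -> float:
        return max(p.rt for p in self.points)

    @property
    def total_intensity(self) -> float:
        return float(sum(p.intensity for p in self.points))

    def point_ids(self) -> frozenset[int]:
        return frozenset(p.point_id for p in self.points)


@dataclass(frozen=True, slots=True)
class AnnotationPoint:
    """A point reference inside an annotated XIC.

    Either carries an explicit ``point_id`` (resolved against a run), or
    (mz, rt, intensity) coordinates to be matched within the documented
    tolerances, or both.
    """

    point_id: Optional[int] = None
    mz: Optional[float] = None
    rt: Optional[float] = None
    intensity: Optional[float] = None

    def has_coords(self) -> bool:
        return self.mz is not None and self.rt is not None


@dataclass(frozen=True)
class AnnotatedXicSet:
    """A labeled partition of points into XICs, e.g. a hand annotation.

    ``xics`` maps each XIC id to the points it contains.  No point may
    belong to two XICs of the same set.
    """

    xics: Mapping[str, tuple[AnnotationPoint, ...]]
    label: str = ""

    def __post_init__(self) -> None:
        seen_ids: dict[int, str] = {}
        seen_coords: dict[tuple[float, float], str] = {}
        offenders = []
        for xid, pts in self.xics.items():
            for ap in pts:
                if ap.point_id is not None:
                    prev = seen_ids.get(ap.point_id)
                    if prev is not None and prev != xid:
                        offenders.append((ap.point_id, prev, xid))
                    seen_ids[ap.point_id] = xid
                elif ap.has_coords():
                    key = (ap.mz, ap.rt)
                    prev = seen_coords.get(key)
                    if prev is not None and prev != xid:
                        offenders.append((key, prev, xid))
                    seen_coords[key] = xid
        if offenders:
            raise InvariantError(
                "point(s) assigned to two XICs of the same set: "
                + "; ".join(f"{p} in {a!r} and {b!r}" for p, a, b in offenders)
            )

    def __len__(self) -> int:
        return len(self.xics)

    def ids(self) -> list[str]:
        return list(self.xics.keys())


def run_from_points(
    points: Sequence[tuple[float, float, float]],
    mode: str = "centroid",
    source: str = "",
) -> Run:
    """Build a Run from raw (mz, rt, intensity) triples.

    Points are grouped into scans by exact RT, scans ordered by RT, points
    within a scan ordered by m/z.  Point ids are assigned sequentially in
    that canonical order.  Zero-intensity points are dropped (profile
    padding carries no information and would inflate the baseline
    denominator).
    """
    by_rt: dict[float, list[tuple[float, float]]] = {}
    for mz, rt, inten in points:
        if inten == 0:
            continue
        by_rt.setdefault(rt, []).append((mz, inten))
    scans = []
    pid = 0
    for si, rt in enumerate(sorted(by_rt)):
        members = []
        for mz, inten in sorted(by_rt[rt]):
            members.append(Point(pid, mz, rt, inten, si))
            pid += 1
        scans.append(Scan(si, rt, tuple(members)))
    return Run(scans=tuple(scans), mode=mode, source=source)
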