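"""Intensity-ordered budget linking and confidence-based XIC extraction.

The clustering pass works as follows.  All points at or above the noise
baseline are sorted by decreasing intensity.  Each point whose intensity is
at least twice the baseline is visited in that order and linked to the
lower-intensity points inside a small window around it (half-width twice
the self-calibrated m/z resolution on the m/z axis and twice the RT
sampling interval on the RT axis).  Window candidates are traversed in
decreasing scaled distance; each link consumes part of the center point's
intensity *budget*:

    budget_{k+1} = budget_k - |budget_k - I(w_k)| * d(center, w_k)

and carries a confidence ``1 - cost / budget_k`` in [0, 1] -- high when the
neighbor is near in space and similar in intensity.  Linking from a center
stops when its budget is exhausted.

Extraction keeps, for every point, only its maximum-confidence incoming
link; the kept links form a forest, and every tree whose root reaches the
seed threshold and whose size passes the mode-dependent minimum (more than
5 points for centroid data, more than 15 for profile) becomes an XIC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from xiclink import constants
from xiclink.calibration import Calibration, calibrate
from xiclink.model import EmptyRunError, Point, Run, Xic, intensity_order_key

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class Link:
    """A directed parent -> child link with its cost and confidence.

    ``cost`` is the budget actually consumed (clamped to the remaining
    budget); ``distance`` is the scaled distance between the endpoints,
    retained for deterministic tie-breaking at extraction.
    """

    parent: Point
    child: Point
    cost: float
    confidence: float
    distance: float


@dataclass(frozen=True, slots=True)
class CandidateWindow:
    """The lower-intensity points eligible to link to a given center point.

    Members lie within the closed window around the center and are ordered
    by decreasing scaled distance (ties: ascending point id).
    """

    center: Point
    half_width_mz: float
    half_width_rt: float
    members: tuple[Point, ...]


class LinkGraph:
    """All candidate links of one run, indexed by child point."""

    def __init__(self, links: Iterable[Link] = ()):
        self.links: list[Link] = []
        self.by_child: dict[int, list[Link]] = {}
        self._pairs: set[tuple[int, int]] = set()
        for link in links:
            self.add(link)

    def add(self, link: Link) -> None:
        pair = (link.parent.point_id, link.child.point_id)
        if link.parent.point_id == link.child.point_id:
            raise ValueError(f"self-link on point {link.parent.point_id}")
        if pair in self._pairs:
            raise ValueError(f"duplicate link {pair}")
        self._pairs.add(pair)
        self.links.append(link)
        self.by_child.setdefault(link.child.point_id, []).append(link)

    def __len__(self) -> int:
        return len(self.links)

    def incoming(self, point_id: int) -> list[Link]:
        return self.by_child.get(point_id, [])


def filter_points(run: Run, calib: Calibration) -> list[Point]:
    """All points at or above the baseline, in decreasing-intensity order.

    Intensity ties are broken by ascending RT, then m/z, then point id, so
    the processing order is a deterministic total order.
    """
    kept = [p for p in run.iter_points() if p.intensity >= calib.baseline]
    kept.sort(key=intensity_order_key)
    return kept


def scaled_distance(a: Point, b: Point, calib: Calibration) -> float:
    """Euclidean distance after normalizing each axis by its calibration unit.

    m/z deltas are measured in units of the resolution estimate and RT
    deltas in units of the sampling interval, making the distance (and
    hence the link cost) dimensionless and instrument-independent.
    """
    dmz = (a.mz - b.mz) / calib.resolution_mz
    drt = (a.rt - b.rt) / calib.sampling_rate_rt
    return math.hypot(dmz, drt)


def _admissible(center: Point, w: Point) -> bool:
    # Strictly lower intensity; an exact tie is admitted only when the
    # candidate's id orders after the center's, which keeps the link
    # relation acyclic.
    if w.intensity < center.intensity:
        return True
    return w.intensity == center.intensity and w.point_id > center.point_id


class _GridIndex:
    """Uniform grid hash over (m/z, RT) for window queries.

    Cell sizes equal the window half-widths, so a query only has to visit
    the 3x3 block of cells around the center.  Results are checked against
    the exact closed-interval predicate, so the index is an accelerator
    only: outputs are identical to a full scan.
    """

    def __init__(self, points: Sequence[Point], cell_mz: float, cell_rt: float):
        self.cell_mz = cell_mz
        self.cell_rt = cell_rt
        self.cells: dict[tuple[int, int], list[Point]] = {}
        for p in points:
            key = (int(math.floor(p.mz / cell_mz)), int(math.floor(p.rt / cell_rt)))
            self.cells.setdefault(key, []).append(p)

    def query(self, center: Point, half_mz: float, half_rt: float) -> list[Point]:
        ci = int(math.floor(center.mz / self.cell_mz))
        cj = int(math.floor(center.rt / self.cell_rt))
        out: list[Point] = []
        for i in range(ci - 1, ci + 2):
            for j in range(cj - 1, cj + 2):
                for p in self.cells.get((i, j), ()):
                    if (
                        abs(p.mz - center.mz) <= half_mz
                        and abs(p.rt - center.rt) <= half_rt
                    ):
                        out.append(p)
        return out


def _window_members(
    center: Point,
    pool: Iterable[Point],
    calib: Calibration,
    exclude: frozenset[int],
) -> tuple[Point, ...]:
    half_mz = constants.WINDOW_HALFWIDTH_MULTIPLE * calib.resolution_mz
    half_rt = constants.WINDOW_HALFWIDTH_MULTIPLE * calib.sampling_rate_rt
    members = [
        w
        for w in pool
        if w.point_id != center.point_id
        and w.point_id not in exclude
        and abs(w.mz - center.mz) <= half_mz
        and abs(w.rt - center.rt) <= half_rt
        and _admissible(center, w)
    ]
    members.sort(key=lambda w: (-scaled_distance(center, w, calib), w.point_id))
    return tuple(members)


def candidate_window(
    center: Point,
    run: Run,
    calib: Calibration,
    already_assigned: frozenset[int] = frozenset(),
) -> CandidateWindow:
    """Build the candidate window around a center point by scanning the run.

    Members are baseline-surviving points within the closed window (boundary
    points included), with intensity strictly below the center's (ties per
    the id rule), minus any ids in ``already_assigned``; ordered by
    decreasing scaled distance, ties by ascending point id.
    """
    pool = (p for p in run.iter_points() if p.intensity >= calib.baseline)
    members = _window_members(center, pool, calib, already_assigned)
    return CandidateWindow(
        center=center,
        half_width_mz=constants.WINDOW_HALFWIDTH_MULTIPLE * calib.resolution_mz,
        half_width_rt=constants.WINDOW_HALFWIDTH_MULTIPLE * calib.sampling_rate_rt,
        members=members,
    )


def link_from(
    center: Point, window: CandidateWindow, calib: Calibration
) -> list[Link]:
    """Run the budget recurrence over a window and emit the links.

    The budget starts at the center's intensity.  For each member (in the
    window's decreasing-distance order) the cost is
    ``|budget - I(w)| * d(center, w)``; the link is emitted with the cost
    clamped to the remaining budget and confidence ``1 - cost/budget``
    clamped to [0, 1]; then the budget is reduced.  Linking stops once the
    budget reaches zero.  Budgets are per-center bookkeeping: stored point
    intensities are never modified.
    """
    links: list[Link] = []
    budget = center.intensity
    for w in window.members:
        if budget <= 0:
            break
        d = scaled_distance(center, w, calib)
        cost = abs(budget - w.intensity) * d
        confidence = min(max(1.0 - cost / budget, 0.0), 1.0)
        links.append(
            Link(
                parent=center,
                child=w,
                cost=min(cost, budget),
                confidence=confidence,
                distance=d,
            )
        )
        budget = max(budget - cost, 0.0)
    return links


def run_linking(run: Run, calib: Calibration) -> LinkGraph:
    """Link every seed-eligible point to its window, in intensity order.

    Points are visited in decreasing-intensity order down to twice the
    baseline; lower points participate only as link targets.  A point may
    receive candidate links from several parents -- conflicts are resolved
    at extraction by the maximum-confidence rule.
    """
    filtered = filter_points(run, calib)
    half_mz = constants.WINDOW_HALFWIDTH_MULTIPLE * calib.resolution_mz
    half_rt = constants.WINDOW_HALFWIDTH_MULTIPLE * calib.sampling_rate_rt
    index = _GridIndex(filtered, half_mz, half_rt)
    graph = LinkGraph()
    n_centers = 0
    for center in filtered:
        if center.intensity < calib.seed_threshold:
            break  # filtered is intensity-sorted
        n_centers += 1
        nearby = index.query(center, half_mz, half_rt)
        members = _window_members(center, nearby, calib, frozenset())
        window = CandidateWindow(center, half_mz, half_rt, members)
        for link in link_from(center, window, calib):
            graph.add(link)
    logger.info(
        "linking: %d points above baseline, %d centers visited, %d links",
        len(filtered),
        n_centers,
        len(graph),
    )
    return graph


def _best_link_key(link: Link) -> tuple:
    # Max confidence; ties: higher parent intensity, smaller scaled
    # distance, ascending parent id.
    return (
        -link.confidence,
        -link.parent.intensity,
        link.distance,
        link.parent.point_id,
    )


def extract_xics(graph: LinkGraph, calib: Calibration) -> list[Xic]:
    """Resolve link conflicts and cut the forest into XICs.

    Every child keeps exactly its best incoming link; surviving links form
    a forest.  Trees rooted at a point below the seed threshold are
    discarded wholesale (seeding is a privilege of high-intensity points),
    as are trees at or below the size minimum for the acquisition mode.
    """
    kept_parent: dict[int, Link] = {}
    for child_id, incoming in graph.by_child.items():
        kept_parent[child_id] = min(incoming, key=_best_link_key)

    children: dict[int, list[Point]] = {}
    nodes: dict[int, Point] = {}
    for link in kept_parent.values():
        nodes[link.parent.point_id] = link.parent
        nodes[link.child.point_id] = link.child
        children.setdefault(link.parent.point_id, []).append(link.child)

    roots = [
        p for pid, p in nodes.items() if pid not in kept_parent
    ]
    roots.sort(key=intensity_order_key)

    min_size = constants.MIN_XIC_POINTS[calib.mode]
    xics: list[Xic] = []
    n_small = n_noise_root = 0
    for root in roots:
        if root.intensity < calib.seed_threshold:
            n_noise_root += 1
            continue
        members: list[Point] = []
        stack = [root]
        while stack:
            p = stack.pop()
            members.append(p)
            stack.extend(children.get(p.point_id, ()))
        if len(members) <= min_size:
            n_small += 1
            continue
        members.sort(key=intensity_order_key)
        xics.append(Xic(xic_id="", root=root, points=tuple(members)))

    xics.sort(key=lambda x: (-x.total_intensity, x.root.point_id))
    width = max(5, len(str(len(xics))))
    out = [
        Xic(xic_id=f"xic_{i:0{width}d}", root=x.root, points=x.points)
        for i, x in enumerate(xics, start=1)
    ]
    logger.info(
        "extraction: %d XICs kept, %d discarded (size <= %d), %d noise-rooted "
        "trees discarded",
        len(out),
        n_small,
        min_size,
        n_noise_root,
    )
    return out


def extract(run: Run, mode_override: Optional[str] = None) -> list[Xic]:
    """Full pipeline: calibrate, filter, link, extract.

    Returns XICs sorted by descending total intensity.  The run is the only
    input -- there are no tuning parameters.
    """
    if run.n_points == 0:
        raise EmptyRunError("cannot extract XICs from an empty run")
    calib = calibrate(run, mode_override=mode_override)
    graph = run_linking(run, calib)
    return extract_xics(graph, calib)
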