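"""Literal O(n^2) reference implementation of the extraction pass.

This module applies the clustering rules exactly as stated -- full scan of
all points for every window, no spatial index, no early exits beyond the
ones the rules themselves prescribe.  It shares no algorithmic code with
``xiclink.linker`` and exists so the production implementation can be
checked for *identical* output on small runs.  It is far too slow for real
data.
"""

from __future__ import annotations

import math
from typing import Optional

from xiclink import constants
from xiclink.calibration import Calibration, calibrate
from xiclink.model import Point, Run, Xic


def extract_naive(run: Run, calib: Optional[Calibration] = None) -> list[Xic]:
    """Extract XICs by literal rule application (quadratic scan)."""
    if calib is None:
        calib = calibrate(run)

    pts = [p for p in run.iter_points() if p.intensity >= calib.baseline]
    pts.sort(key=lambda p: (-p.intensity, p.rt, p.mz, p.point_id))

    half_mz = 2.0 * calib.resolution_mz
    half_rt = 2.0 * calib.sampling_rate_rt

    def dist(a: Point, b: Point) -> float:
        return math.sqrt(
            ((a.mz - b.mz) / calib.resolution_mz) ** 2
            + ((a.rt - b.rt) / calib.sampling_rate_rt) ** 2
        )

    # (parent, child, confidence, distance) for every emitted link
    links: list[tuple[Point, Point, float, float]] = []
    for p in pts:
        if p.intensity < calib.seed_threshold:
            continue
        window = [
            w
            for w in pts
            if w.point_id != p.point_id
            and abs(w.mz - p.mz) <= half_mz
            and abs(w.rt - p.rt) <= half_rt
            and (
                w.intensity < p.intensity
                or (w.intensity == p.intensity and w.point_id > p.point_id)
            )
        ]
        window.sort(key=lambda w: (-dist(p, w), w.point_id))
        budget = p.intensity
        for w in window:
            if budget <= 0:
                break
            d = dist(p, w)
            cost = abs(budget - w.intensity) * d
            conf = min(max(1.0 - cost / budget, 0.0), 1.0)
            links.append((p, w, conf, d))
            budget = max(budget - cost, 0.0)

    # best incoming link per child
    best: dict[int, tuple[Point, Point, float, float]] = {}
    for parent, child, conf, d in links:
        cur = best.get(child.point_id)
        if cur is None:
            best[child.point_id] = (parent, child, conf, d)
            continue
        cand_key = (-conf, -parent.intensity, d, parent.point_id)
        cur_key = (-cur[2], -cur[0].intensity, cur[3], cur[0].point_id)
        if cand_key < cur_key:
            best[child.point_id] = (parent, child, conf, d)

    parent_of: dict[int, Point] = {cid: t[0] for cid, t in best.items()}
    node_by_id: dict[int, Point] = {}
    for parent, child, _, _ in best.values():
        node_by_id[parent.point_id] = parent
        node_by_id[child.point_id] = child

    kids: dict[int, list[Point]] = {}
    for cid, parent in parent_of.items():
        kids.setdefault(parent.point_id, []).append(node_by_id[cid])

    min_size = constants.MIN_XIC_POINTS[calib.mode]
    out: list[Xic] = []
    for pid, node in node_by_id.items():
        if pid in parent_of:
            continue  # not a root
        if node.intensity < calib.seed_threshold:
            continue
        members: list[Point] = []
        stack = [node]
        while stack:
            q = stack.pop()
            members.append(q)
            stack.extend(kids.get(q.point_id, ()))
        if len(members) <= min_size:
            continue
        members.sort(key=lambda p: (-p.intensity, p.rt, p.mz, p.point_id))
        out.append(Xic(xic_id="", root=node, points=tuple(members)))

    out.sort(key=lambda x: (-x.total_intensity, x.root.point_id))
    width = max(5, len(str(len(out))))
    return [
        Xic(xic_id=f"xic_{i:0{width}d}", root=x.root, points=x.points)
        for i, x in enumerate(out, start=1)
    ]
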