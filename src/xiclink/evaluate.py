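"""XIC-set matching: shared-intensity fraction, match rule, directional table.

A candidate XIC ``A`` is matched to a reference XIC ``H`` when the summed
intensity of the points they share exceeds half of ``H``'s total intensity:

    S = sum intensity(A n H) / sum intensity(H),   match iff S > 0.5

The comparison is directional: one XIC in the candidate set may match
several reference XICs (e.g. a concatenated bimodal signal against its two
annotated halves), so comparing two sets in both directions distinguishes
which side failed to separate co-eluting signals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from xiclink import constants
from xiclink.model import (
    AnnotatedXicSet,
    AnnotationPoint,
    InvariantError,
    Point,
    Run,
    Xic,
)

PathLike = Union[str, Path]


@dataclass(frozen=True, slots=True)
class MatchPair:
    """One (candidate, reference) pairing with its shared-intensity fraction."""

    a_id: str
    h_id: str
    s: float


@dataclass(frozen=True)
class MatchReport:
    """Directional matching result of a candidate set against a reference set.

    ``pairs`` holds only the matches (S > 0.5); ``best_pairs`` holds the
    best candidate for every reference XIC regardless of the threshold, for
    reporting.  ``recall`` is the fraction of reference XICs matched.
    """

    pairs: tuple[MatchPair, ...]
    best_pairs: tuple[MatchPair, ...]
    recall: float
    direction: tuple[str, str]
    unmatched_reference_ids: tuple[str, ...]

    @property
    def n_matched(self) -> int:
        return len({p.h_id for p in self.pairs})


def xics_to_annotated_set(xics: Sequence[Xic], label: str = "") -> AnnotatedXicSet:
    """View extractor output as an annotated set, for evaluation."""
    return AnnotatedXicSet(
        xics={
            x.xic_id: tuple(
                AnnotationPoint(
                    point_id=p.point_id, mz=p.mz, rt=p.rt, intensity=p.intensity
                )
                for p in x.points
            )
            for x in xics
        },
        label=label,
    )


def _all_have_ids(*point_groups: Sequence[AnnotationPoint]) -> bool:
    return all(
        ap.point_id is not None for group in point_groups for ap in group
    )


class _CoordIndex:
    """Grid index for matching points by coordinates within tolerances."""

    def __init__(self, points: Sequence[AnnotationPoint]):
        self.cells: dict[tuple[int, int], list[AnnotationPoint]] = {}
        for ap in points:
            if not ap.has_coords():
                raise InvariantError(
                    "coordinate matching requires mz/rt on every point"
                )
            key = (
                int(math.floor(ap.mz / constants.MZ_MATCH_TOL)),
                int(math.floor(ap.rt / constants.RT_MATCH_TOL)),
            )
            self.cells.setdefault(key, []).append(ap)

    def contains(self, ap: AnnotationPoint) -> bool:
        ci = int(math.floor(ap.mz / constants.MZ_MATCH_TOL))
        cj = int(math.floor(ap.rt / constants.RT_MATCH_TOL))
        for i in range(ci - 1, ci + 2):
            for j in range(cj - 1, cj + 2):
                for other in self.cells.get((i, j), ()):
                    if (
                        abs(other.mz - ap.mz) <= constants.MZ_MATCH_TOL
                        and abs(other.rt - ap.rt) <= constants.RT_MATCH_TOL
                    ):
                        return True
        return False


def shared_intensity_fraction(
    a: Sequence[AnnotationPoint], h: Sequence[AnnotationPoint]
) -> float:
    """Fraction of the reference XIC's intensity covered by shared points.

    Point identity uses point ids when both sides carry them, otherwise
    coordinate equality within the documented tolerances.  Intensities are
    taken from the reference side.
    """
    if len(h) == 0:
        raise InvariantError("reference XIC is empty; S is undefined")
    denom = 0.0
    for ap in h:
        if ap.intensity is None:
            raise InvariantError(
                "reference points must carry intensities to compute S"
            )
        denom += ap.intensity
    if denom == 0:
        raise InvariantError("reference XIC has zero total intensity")

    if _all_have_ids(a, h):
        a_ids = {ap.point_id for ap in a}
        num = sum(ap.intensity for ap in h if ap.point_id in a_ids)
    else:
        index = _CoordIndex(a)
        num = sum(ap.intensity for ap in h if index.contains(ap))
    return num / denom


def match_sets(first: AnnotatedXicSet, second: AnnotatedXicSet) -> MatchReport:
    """Match the XICs of ``second`` (reference) against ``first`` (candidate).

    For each reference XIC the best-S candidate is found; it counts as
    matched iff S is strictly greater than 0.5.  A single candidate XIC may
    match several reference XICs (the comparison is directional).
    """
    if len(first) == 0 or len(second) == 0:
        raise InvariantError("match_sets requires two non-empty XIC sets")
    pairs: list[MatchPair] = []
    best_pairs: list[MatchPair] = []
    unmatched: list[str] = []
    for h_id in second.xics:
        h_pts = second.xics[h_id]
        best_s = -1.0
        best_a = ""
        for a_id in sorted(first.xics):
            s = shared_intensity_fraction(first.xics[a_id], h_pts)
            if s > best_s:
                best_s = s
                best_a = a_id
        best_pairs.append(MatchPair(a_id=best_a, h_id=h_id, s=best_s))
        if best_s > constants.MATCH_S_THRESHOLD:
            pairs.append(MatchPair(a_id=best_a, h_id=h_id, s=best_s))
        else:
            unmatched.append(h_id)
    recall = len(pairs) / len(second)
    return MatchReport(
        pairs=tuple(pairs),
        best_pairs=tuple(best_pairs),
        recall=recall,
        direction=(first.label, second.label),
        unmatched_reference_ids=tuple(unmatched),
    )


def directional_table(sets: Sequence[AnnotatedXicSet]) -> pd.DataFrame:
    """All-pairs directional match counts.

    Entry (i, j) is the number of XICs of set j matched by set i (set i as
    candidate, set j as reference); the diagonal is each set's size.  The
    table is generally asymmetric: an algorithm that concatenates bimodal
    signals matches fewer of a well-separated reference than vice versa.
    """
    if len(sets) < 1:
        raise InvariantError("directional_table requires at least one set")
    labels = [s.label or f"set{i}" for i, s in enumerate(sets)]
    n = len(sets)
    counts = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                counts[i][j] = len(sets[j])
            else:
                counts[i][j] = match_sets(sets[i], sets[j]).n_matched
    return pd.DataFrame(counts, index=labels, columns=labels)


def capture_window_points(
    run: Run,
    mz_min: float,
    mz_max: float,
    rt_min: float,
    rt_max: float,
) -> tuple[Point, ...]:
    """All run points inside a closed (m/z, RT) rectangle.

    Helper for converting bounding-box ("window") XIC exports from other
    tools into point sets; one plausible reading of such outputs, not a
    claim about how any particular tool defines them.
    """
    return tuple(
        p
        for p in run.iter_points()
        if mz_min <= p.mz <= mz_max and rt_min <= p.rt <= rt_max
    )


def write_match_report(report: MatchReport, prefix: PathLike) -> tuple[Path, Path]:
    """Write a match report as ``<prefix>_matches.csv`` + ``<prefix>_summary.json``."""
    prefix = Path(prefix)
    csv_path = prefix.parent / (prefix.name + "_matches.csv")
    json_path = prefix.parent / (prefix.name + "_summary.json")
    matched_h = {p.h_id for p in report.pairs}
    rows = [
        {
            "h_id": p.h_id,
            "a_id": p.a_id,
            "S": p.s,
            "matched": int(p.h_id in matched_h),
        }
        for p in report.best_pairs
    ]
    pd.DataFrame(rows, columns=["h_id", "a_id", "S", "matched"]).to_csv(
        csv_path, index=False, float_format="%.10g"
    )
    summary = {
        "direction": list(report.direction),
        "n_reference": len(report.best_pairs),
        "n_matched": report.n_matched,
        "recall": report.recall,
        "unmatched_reference_ids": list(report.unmatched_reference_ids),
    }
    json_path.write_text(json.dumps(summary, indent=1) + "\n")
    return csv_path, json_path
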