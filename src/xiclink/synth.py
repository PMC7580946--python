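"""Synthetic MS1 run generator with ground-truth XIC labels.

Emulates the features of real LC-MS point data that the extractor relies
on: Gaussian elution profiles in RT, narrow m/z dispersion per trace, an
additive low-intensity noise floor with a heavy mass near zero
(exponentially distributed intensities), overlapping bimodal elutions, and
both centroid and profile acquisition.  Every generated signal point is
labeled with its generating trace, so extraction output can be scored
against an exact ground truth.

It does not emulate isotopic envelope structure beyond m/z placement,
intensity-dependent m/z error, chromatographic tailing, or detector
saturation; results on synthetic runs demonstrate the clustering logic, not
instrument-level fidelity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from xiclink.model import AnnotatedXicSet, AnnotationPoint, Point, Run, Scan

# Profile acquisition is emulated as a 5-sample m/z cluster per trace and
# scan with a triangular intensity taper -- the minimal shape that gives
# profile traces a realistic per-scan footprint.
_PROFILE_OFFSETS = (-2, -1, 0, 1, 2)
_PROFILE_TAPER = (1.0 / 3.0, 2.0 / 3.0, 1.0, 2.0 / 3.0, 1.0 / 3.0)


@dataclass(frozen=True, slots=True)
class TraceSpec:
    """Parameters of one Gaussian elution trace.

    ``n_scans_span`` optionally fixes the number of scans the trace covers;
    when 0 (default) the trace spans +-3 rt_sigma around its center.
    """

    mz_center: float
    rt_center: float
    rt_sigma: float
    apex_height: float
    mz_jitter_sd: float = 0.0
    n_scans_span: int = 0

    def __post_init__(self) -> None:
        if self.apex_height <= 0 or self.rt_sigma <= 0 or self.mz_jitter_sd < 0:
            raise ValueError(
                "TraceSpec requires apex_height > 0, rt_sigma > 0, mz_jitter_sd >= 0"
            )

    def intensity_at(self, rt: float) -> float:
        """Closed-form Gaussian elution intensity at a given RT."""
        z = (rt - self.rt_center) / self.rt_sigma
        return self.apex_height * math.exp(-0.5 * z * z)


@dataclass(frozen=True)
class SyntheticRun:
    """A generated run plus its ground truth.

    ``truth`` labels every signal point with its generating trace;
    ``noise_point_ids`` holds the rest, so the two partition the run.
    """

    run: Run
    truth: AnnotatedXicSet
    noise_point_ids: frozenset[int]
    traces: tuple[TraceSpec, ...]


def _snap(mz: float, grid: Optional[float]) -> float:
    if grid is None:
        return mz
    return round(mz / grid) * grid


def _warn_on_collisions(traces: Sequence[TraceSpec], mz_tol: float) -> None:
    for i, a in enumerate(traces):
        for b in traces[i + 1 :]:
            mz_close = abs(a.mz_center - b.mz_center) <= mz_tol
            rt_overlap = (
                a.rt_center - 3 * a.rt_sigma <= b.rt_center + 3 * b.rt_sigma
                and b.rt_center - 3 * b.rt_sigma <= a.rt_center + 3 * a.rt_sigma
            )
            if mz_close and rt_overlap:
                warnings.warn(
                    f"traces at mz {a.mz_center} and {b.mz_center} overlap in "
                    "both m/z and RT; their points may be clustered together",
                    stacklevel=3,
                )


def _build_run(
    scan_rts: Sequence[float],
    per_scan: list[list[tuple[float, float, Optional[str]]]],
    mode: str,
    source: str,
) -> tuple[Run, dict[str, list[AnnotationPoint]], set[int]]:
    """Assemble Run + truth labels from per-scan (mz, intensity, label) rows."""
    scans: list[Scan] = []
    truth: dict[str, list[AnnotationPoint]] = {}
    noise_ids: set[int] = set()
    pid = 0
    for si, rt in enumerate(scan_rts):
        rows = sorted(per_scan[si], key=lambda r: r[0])
        pts = []
        for mz, inten, label in rows:
            if inten <= 0:
                continue
            p = Point(pid, mz, rt, inten, si)
            pts.append(p)
            if label is None:
                noise_ids.add(pid)
            else:
                truth.setdefault(label, []).append(
                    AnnotationPoint(point_id=pid, mz=mz, rt=rt, intensity=inten)
                )
            pid += 1
        scans.append(Scan(si, rt, tuple(pts)))
    run = Run(scans=tuple(scans), mode=mode, source=source)
    return run, truth, noise_ids


def _scan_rts(
    rt_range: tuple[float, float], scan_interval: float
) -> list[float]:
    start = max(rt_range[0], scan_interval)
    rts = []
    rt = start
    while rt <= rt_range[1] + 1e-9:
        rts.append(round(rt, 9))
        rt += scan_interval
    return rts


def generate_run(
    traces: Sequence[TraceSpec],
    scan_interval: float,
    mz_grid: Optional[float] = None,
    noise_density: float = 0.0,
    noise_mean: float = 0.0,
    mode: str = "centroid",
    seed: int = 0,
    rt_range: Optional[tuple[float, float]] = None,
    mz_range: Optional[tuple[float, float]] = None,
) -> SyntheticRun:
    """Generate a run from trace specs plus an exponential noise floor.

    Each trace contributes one point per scan within +-3 rt_sigma of its
    center (profile mode: a 5-point m/z cluster with triangular taper),
    with intensity ``apex_height * exp(-(rt - rt_center)^2 / (2 rt_sigma^2))``.
    Noise points are uniform in m/z over ``mz_range`` with exponentially
    distributed intensities of mean ``noise_mean``; ``noise_density`` of
    them are placed in every scan.  The same seed always yields the same
    run.
    """
    if scan_interval <= 0:
        raise ValueError("scan_interval must be > 0")
    rng = np.random.default_rng(seed)
    traces = tuple(traces)
    if rt_range is None:
        if traces:
            lo = min(t.rt_center - 3 * t.rt_sigma for t in traces) - 2 * scan_interval
            hi = max(t.rt_center + 3 * t.rt_sigma for t in traces) + 2 * scan_interval
        else:
            lo, hi = scan_interval, 100 * scan_interval
        rt_range = (max(lo, scan_interval), hi)
    if mz_range is None:
        if traces:
            mz_range = (
                min(t.mz_center for t in traces) - 5.0,
                max(t.mz_center for t in traces) + 5.0,
            )
        else:
            mz_range = (100.0, 110.0)
    _warn_on_collisions(traces, mz_tol=4 * (mz_grid or 0.01))

    rts = _scan_rts(rt_range, scan_interval)
    per_scan: list[list[tuple[float, float, Optional[str]]]] = [[] for _ in rts]
    n_noise = int(round(noise_density))

    for si, rt in enumerate(rts):
        for ti, t in enumerate(traces):
            if t.n_scans_span > 0:
                half_span = 0.5 * t.n_scans_span * scan_interval
                in_span = abs(rt - t.rt_center) <= half_span
            else:
                in_span = abs(rt - t.rt_center) <= 3 * t.rt_sigma
            if not in_span:
                continue
            h = t.intensity_at(rt)
            label = f"trace_{ti:03d}"
            if mode == "profile":
                grid = mz_grid if mz_grid is not None else 0.01
                for off, taper in zip(_PROFILE_OFFSETS, _PROFILE_TAPER):
                    mz = _snap(t.mz_center, grid) + off * grid
                    per_scan[si].append((mz, h * taper, label))
            else:
                mz = t.mz_center
                if t.mz_jitter_sd > 0:
                    mz += rng.normal(0.0, t.mz_jitter_sd)
                per_scan[si].append((_snap(mz, mz_grid), h, label))
        for _ in range(n_noise):
            mz = _snap(rng.uniform(*mz_range), mz_grid)
            inten = rng.exponential(noise_mean) if noise_mean > 0 else 0.0
            per_scan[si].append((mz, inten, None))

    run, truth, noise_ids = _build_run(
        rts, per_scan, mode, source=f"synthetic(seed={seed})"
    )
    return SyntheticRun(
        run=run,
        truth=AnnotatedXicSet(
            xics={k: tuple(v) for k, v in truth.items()}, label="truth"
        ),
        noise_point_ids=frozenset(noise_ids),
        traces=traces,
    )


def generate_bimodal(
    shared_mz: float,
    rt_centers: tuple[float, float],
    rt_sigmas: tuple[float, float],
    heights: tuple[float, float],
    valley_depth_check: float = 0.5,
    seed: int = 0,
    scan_interval: float = 0.7,
    mz_grid: Optional[float] = 0.01,
    noise_density: float = 8.0,
    noise_mean: Optional[float] = None,
    mz_range: Optional[tuple[float, float]] = None,
) -> SyntheticRun:
    """Two overlapping Gaussian elutions at the same m/z.

    The two modes share one m/z track; where both contribute, point
    intensities are summed and the point is labeled with the mode that
    contributes more.  After generation the summed profile is required to
    exhibit a valley between the two apexes at or below
    ``valley_depth_check`` times the lower apex; otherwise generation fails
    with a request for wider separation.
    """
    if rt_centers[0] == rt_centers[1]:
        raise ValueError("rt_centers must be distinct")
    c1, c2 = sorted(rt_centers)
    order = 0 if rt_centers[0] <= rt_centers[1] else 1
    sig = (rt_sigmas[0], rt_sigmas[1]) if order == 0 else (rt_sigmas[1], rt_sigmas[0])
    h = (heights[0], heights[1]) if order == 0 else (heights[1], heights[0])
    t1 = TraceSpec(shared_mz, c1, sig[0], h[0])
    t2 = TraceSpec(shared_mz, c2, sig[1], h[1])
    if noise_mean is None:
        noise_mean = 0.02 * min(heights)
    if mz_range is None:
        mz_range = (shared_mz - 5.0, shared_mz + 5.0)

    rng = np.random.default_rng(seed)
    lo = c1 - 3 * sig[0] - 2 * scan_interval
    hi = c2 + 3 * sig[1] + 2 * scan_interval
    rts = _scan_rts((max(lo, scan_interval), hi), scan_interval)
    per_scan: list[list[tuple[float, float, Optional[str]]]] = [[] for _ in rts]
    n_noise = int(round(noise_density))
    mz = _snap(shared_mz, mz_grid)

    valley = math.inf
    for si, rt in enumerate(rts):
        g1 = t1.intensity_at(rt) if abs(rt - c1) <= 3 * sig[0] else 0.0
        g2 = t2.intensity_at(rt) if abs(rt - c2) <= 3 * sig[1] else 0.0
        if g1 > 0 or g2 > 0:
            label = "mode_1" if g1 >= g2 else "mode_2"
            total = g1 + g2
            per_scan[si].append((mz, total, label))
            if c1 < rt < c2:
                valley = min(valley, total)
        for _ in range(n_noise):
            nmz = _snap(rng.uniform(*mz_range), mz_grid)
            inten = rng.exponential(noise_mean) if noise_mean > 0 else 0.0
            per_scan[si].append((nmz, inten, None))

    if not (valley <= valley_depth_check * min(heights)):
        raise ValueError(
            f"summed profile has no valley at or below {valley_depth_check} x "
            f"the lower apex (min between modes: {valley:.4g}); widen the "
            "separation between rt_centers"
        )

    run, truth, noise_ids = _build_run(
        rts, per_scan, "centroid", source=f"synthetic-bimodal(seed={seed})"
    )
    return SyntheticRun(
        run=run,
        truth=AnnotatedXicSet(
            xics={k: tuple(v) for k, v in truth.items()}, label="truth"
        ),
        noise_point_ids=frozenset(noise_ids),
        traces=(t1, t2),
    )


# ---------------------------------------------------------------------------
# Scenario library: fixed specs and default seeds for the standard test
# conditions.  ``scenario(name)`` reproduces each bit-for-bit.
# ---------------------------------------------------------------------------


def _separated20(seed: int) -> SyntheticRun:
    traces = [
        TraceSpec(
            mz_center=100.5 + i * 1.0,
            rt_center=40.0 + i * 7.0,
            rt_sigma=3.0,
            apex_height=600.0 + 70.0 * i,
            mz_jitter_sd=0.003,
        )
        for i in range(20)
    ]
    return generate_run(
        traces,
        scan_interval=0.7,
        mz_grid=0.01,
        noise_density=10,
        noise_mean=50.0,
        mode="centroid",
        seed=seed,
        rt_range=(20.0, 195.0),
        mz_range=(100.0, 121.0),
    )


def _crowded(seed: int) -> SyntheticRun:
    traces = [
        TraceSpec(
            mz_center=100.2 + i * 0.35,
            rt_center=40.0 + (i % 10) * 12.0,
            rt_sigma=2.5,
            apex_height=400.0 + 40.0 * i,
            mz_jitter_sd=0.003,
        )
        for i in range(30)
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_run(
            traces,
            scan_interval=0.7,
            mz_grid=0.01,
            noise_density=10,
            noise_mean=50.0,
            mode="centroid",
            seed=seed,
            rt_range=(20.0, 175.0),
            mz_range=(99.0, 112.0),
        )


def _bimodal(seed: int) -> SyntheticRun:
    return generate_bimodal(
        shared_mz=150.0,
        rt_centers=(60.0, 78.0),
        rt_sigmas=(3.0, 3.0),
        heights=(1000.0, 800.0),
        seed=seed,
    )


def _pure_noise(seed: int) -> SyntheticRun:
    return generate_run(
        traces=[],
        scan_interval=0.7,
        mz_grid=0.01,
        noise_density=20,
        noise_mean=50.0,
        mode="centroid",
        seed=seed,
        rt_range=(0.7, 70.0),
        mz_range=(100.0, 110.0),
    )


def _low_contrast(seed: int) -> SyntheticRun:
    # Emulates runs where signal apexes sit only a small factor above the
    # noise floor, the regime where baseline-driven seeding gets hard.
    traces = [
        TraceSpec(
            mz_center=100.5 + i * 1.5,
            rt_center=40.0 + i * 14.0,
            rt_sigma=3.0,
            apex_height=200.0 + 10.0 * i,
            mz_jitter_sd=0.003,
        )
        for i in range(10)
    ]
    return generate_run(
        traces,
        scan_interval=0.7,
        mz_grid=0.01,
        noise_density=10,
        noise_mean=50.0,
        mode="centroid",
        seed=seed,
        rt_range=(20.0, 190.0),
        mz_range=(99.0, 116.0),
    )


def _separated5_profile(seed: int) -> SyntheticRun:
    traces = [
        TraceSpec(
            mz_center=102.0 + i * 2.0,
            rt_center=40.0 + i * 20.0,
            rt_sigma=3.0,
            apex_height=800.0 + 100.0 * i,
        )
        for i in range(5)
    ]
    return generate_run(
        traces,
        scan_interval=0.7,
        mz_grid=0.01,
        noise_density=6,
        noise_mean=40.0,
        mode="profile",
        seed=seed,
        rt_range=(20.0, 140.0),
        mz_range=(100.0, 112.0),
    )


def random_small_run(seed: int) -> SyntheticRun:
    """A small randomized run (at most ~1,000 points) for cross-checking.

    Draws 1-4 traces with randomized centers, widths and apex heights over
    a short RT range, in centroid mode 70% of the time and profile mode
    otherwise, plus a light exponential noise floor.  Bounded construction
    keeps the run under a thousand points, the size regime where the
    quadratic reference extractor is still practical.
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 5))
    traces = [
        TraceSpec(
            mz_center=float(100.5 + 2 * i + rng.uniform(-0.2, 0.2)),
            rt_center=float(rng.uniform(25, 55)),
            rt_sigma=float(rng.uniform(2.0, 4.0)),
            apex_height=float(rng.uniform(400, 1500)),
            mz_jitter_sd=0.003,
        )
        for i in range(k)
    ]
    mode = "centroid" if rng.random() < 0.7 else "profile"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_run(
            traces,
            scan_interval=0.7,
            mz_grid=0.01,
            noise_density=6,
            noise_mean=40.0,
            mode=mode,
            seed=seed,
            rt_range=(15.0, 65.0),
            mz_range=(99.0, 111.0),
        )


SCENARIOS = {
    "separated20": (20260, _separated20),
    "crowded": (551, _crowded),
    "bimodal": (4031, _bimodal),
    "pure_noise": (977, _pure_noise),
    "low_contrast": (1203, _low_contrast),
    "separated5_profile": (882, _separated5_profile),
}


def scenario(name: str, seed: Optional[int] = None) -> SyntheticRun:
    """Build one of the shipped scenarios (with its fixed default seed)."""
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(SCENARIOS))}"
        )
    default_seed, factory = SCENARIOS[name]
    return factory(default_seed if seed is None else seed)
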