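"""Self-calibration: baseline, m/z resolution and RT sampling-rate estimates.

The extractor derives everything it needs from the run itself:

* **baseline** -- the arithmetic mean intensity of *all* points in the run,
  computed before any filtering.  Points below it are excluded from
  clustering; points at or above twice the baseline may seed new XICs.
* **resolution** -- the minimum positive m/z separation between any two
  points belonging to the same scan.
* **sampling rate** -- the minimum RT separation between two consecutive
  scans.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Optional

from xiclink import constants
from xiclink.model import CalibrationError, EmptyRunError, Run

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class Calibration:
    """The self-calibrated quantities for one run.

    Attributes
    ----------
    baseline : float
        Mean intensity of all points (intensity units).
    seed_threshold : float
        Minimum intensity required to seed a new XIC; always exactly
        ``2 * baseline``.
    resolution_mz : float
        Estimated m/z resolution (Thomson).
    sampling_rate_rt : float
        Estimated RT sampling interval (seconds).
    mode : str
        ``"centroid"`` or ``"profile"``; selects the XIC size filter.
    """

    baseline: float
    seed_threshold: float
    resolution_mz: float
    sampling_rate_rt: float
    mode: str

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise CalibrationError(f"baseline must be > 0, got {self.baseline}")
        if self.seed_threshold != constants.SEED_BASELINE_MULTIPLE * self.baseline:
            raise CalibrationError(
                "seed_threshold must equal "
                f"{constants.SEED_BASELINE_MULTIPLE} x baseline"
            )
        if self.resolution_mz <= 0:
            raise CalibrationError("resolution_mz must be > 0")
        if self.sampling_rate_rt <= 0:
            raise CalibrationError("sampling_rate_rt must be > 0")
        if self.mode not in ("centroid", "profile"):
            raise CalibrationError(f"mode must be centroid or profile, got {self.mode!r}")


def make_calibration(
    baseline: float, resolution_mz: float, sampling_rate_rt: float, mode: str
) -> Calibration:
    """Assemble a Calibration, deriving the seed threshold from the baseline."""
    return Calibration(
        baseline=baseline,
        seed_threshold=constants.SEED_BASELINE_MULTIPLE * baseline,
        resolution_mz=resolution_mz,
        sampling_rate_rt=sampling_rate_rt,
        mode=mode,
    )


def estimate_baseline(run: Run) -> float:
    """Mean intensity of all points in the run.

    The mean deliberately includes sub-baseline noise points: it is the
    average over everything the instrument recorded (zero-intensity padding
    having been dropped at read time).
    """
    total = 0.0
    n = 0
    for p in run.iter_points():
        total += p.intensity
        n += 1
    if n == 0:
        raise EmptyRunError("cannot estimate baseline of an empty run")
    return total / n


def estimate_resolution(run: Run) -> float:
    """Minimum positive m/z gap between two points of the same scan.

    Scans store points sorted by m/z, so adjacent gaps suffice.  Zero gaps
    (coincident m/z values within one scan) are degenerate duplicates and
    are ignored: a resolution of 0 would collapse the search window.
    """
    best: Optional[float] = None
    for scan in run.scans:
        pts = scan.points
        for a, b in zip(pts, pts[1:]):
            gap = b.mz - a.mz
            if gap > 0 and (best is None or gap < best):
                best = gap
    if best is None:
        raise CalibrationError(
            "resolution estimate needs at least one scan with two points at "
            "distinct m/z"
        )
    return best


def estimate_sampling_rate(run: Run) -> float:
    """Minimum RT separation between two consecutive scans."""
    if run.n_scans < 2:
        raise CalibrationError("sampling-rate estimate needs at least 2 scans")
    return min(b.rt - a.rt for a, b in zip(run.scans, run.scans[1:]))


def _infer_mode(run: Run) -> str:
    """Fallback acquisition-mode heuristic when metadata is absent.

    Profile spectra carry the full sampled peak shape and are much denser
    than centroided ones, so a high median points-per-scan indicates
    profile acquisition.
    """
    counts = [len(s.points) for s in run.scans if s.points]
    med = statistics.median(counts) if counts else 0
    mode = "profile" if med >= constants.PROFILE_POINTS_PER_SCAN_CUTOFF else "centroid"
    logger.info(
        "acquisition mode unknown; median %d points/scan -> assuming %s", med, mode
    )
    return mode


def calibrate(run: Run, mode_override: Optional[str] = None) -> Calibration:
    """Derive the full Calibration for a run.

    ``mode_override`` takes precedence over the run's recorded mode; if the
    mode is still unknown, a documented points-per-scan heuristic decides.
    """
    if run.n_points == 0:
        raise EmptyRunError("cannot calibrate an empty run")
    if mode_override is not None:
        mode = mode_override
    elif run.mode != "unknown":
        mode = run.mode
    else:
        mode = _infer_mode(run)
    baseline = estimate_baseline(run)
    resolution = estimate_resolution(run)
    sampling = estimate_sampling_rate(run)
    calib = make_calibration(baseline, resolution, sampling, mode)
    logger.info(
        "calibration: baseline=%.6g seed_threshold=%.6g resolution_mz=%.6g "
        "sampling_rate_rt=%.6g mode=%s",
        calib.baseline,
        calib.seed_threshold,
        calib.resolution_mz,
        calib.sampling_rate_rt,
        calib.mode,
    )
    return calib
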