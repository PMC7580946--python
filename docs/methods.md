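# Methods

## The clustering model

`xiclink` treats ion-chromatogram extraction as single-pass clustering of
raw MS1 points. Its working assumptions are:

* the most intense points carry the most reliable m/z measurements, so
  intensity can stand in for confidence and high-intensity points should be
  placed first;
* an XIC is locally dense: consecutive points of one trace differ by at most
  a couple of instrument resolution steps in m/z and a couple of sampling
  intervals in RT;
* most points in a run are low-intensity noise, so the run-wide mean
  intensity is a usable noise baseline.

No elution-shape model is assumed anywhere: deconvolution of overlapping
peaks falls out of the intensity ordering alone.

## Self-calibration

Three quantities are estimated from the run; together with the two fixed
size thresholds they are everything the pipeline uses.

| quantity | definition | units |
|---|---|---|
| baseline `b` | arithmetic mean intensity of **all** points | intensity |
| resolution `r` | min positive m/z gap between two points of one scan | Th |
| sampling rate `s` | min RT gap between consecutive scans | seconds |

Notes:

* The mean is computed before any filtering; zero-intensity profile padding
  is dropped at read time so the denominator is well defined and
  reproducible across readers.
* Zero m/z gaps (coincident points within a scan) are excluded from the
  resolution minimum — a resolution of 0 would collapse the search window;
  such duplicates are degenerate artifacts.
* The seed threshold is exactly `2 b`: points below `b` are excluded from
  clustering entirely; points in `[b, 2b)` may join XICs but never start
  one.
* Acquisition mode (centroid/profile) is read from file metadata or an
  explicit override. When neither exists, a median of ≥ 2,000 points per
  scan is taken to indicate profile acquisition. The constant lives in
  `xiclink.constants`, not in any user-facing interface.

## Linking

Points at or above `b` are sorted by decreasing intensity (ties: ascending
RT, then m/z, then point id — a deterministic total order). Each point `p`
with intensity ≥ `2b` is visited in that order and offered the candidate
set `W`: baseline-surviving points within the closed window `|Δmz| ≤ 2r`,
`|Δrt| ≤ 2s`, with intensity strictly below `p`'s (an exact tie is admitted
only when the candidate's id orders after the center's, which keeps the
link relation acyclic).

Candidates are traversed in decreasing scaled distance

    d(p, w) = sqrt( (Δmz / r)² + (Δrt / s)² )

with a budget initialized to `p`'s intensity. For each candidate `w`:

    cost       = |budget − I(w)| · d(p, w)
    confidence = clamp(1 − cost / budget, 0, 1)
    budget     ← max(budget − cost, 0)

and a link `p → w` is recorded with the cost clamped to the remaining
budget. When the budget reaches zero, linking from `p` stops; the stored
intensities of points are never modified — budgets are per-center
bookkeeping. A point may receive links from several parents; conflicts are
resolved later.

Design choices made here, and why:

* **Budget recurrence uses the running budget.** The intensity difference
  in the cost term is taken against the current budget, not the center's
  original intensity: the budget is the remaining evidence the center can
  spend, and using it keeps the recurrence well defined (the updated value
  cannot appear inside its own update).
* **Confidence is the complement of the consumed fraction.** A neighbor
  that is close and of similar intensity consumes little budget and gets
  confidence near 1; a far or dissimilar one gets confidence near 0. The
  extraction step's preference for the highest-confidence link only makes
  sense with this orientation.
* **Distances are normalized before the Euclidean norm.** Raw distances
  over mixed units (Th vs. seconds) are dimensionally incoherent and would
  make the cost instrument-dependent; dividing each axis by its calibration
  estimate makes the cost dimensionless, in keeping with self-calibration.
* **Farthest candidates are processed first.** Decreasing-distance order is
  implemented literally. It has a real consequence: a candidate with
  intensity ≤ half the budget at scaled distance ≥ 2 has
  `cost = |budget − I|·d ≥ budget`, i.e. it exhausts the center in a single
  zero-confidence link. See *Limitations*.
* **The exhausting link is still emitted** (with its cost clamped to the
  remaining budget): exhaustion terminates the loop, it does not
  retroactively cancel the link that caused it. This preserves connectivity
  around apexes that would otherwise orphan their nearest neighbors.
* **Window half-widths are `2r` and `2s` per side** (closed interval). A
  full width of two sampling intervals would admit at most one adjacent
  scan per side and make the minimum XIC size nearly unreachable; the
  half-width reading supports the multi-scan linking the method is built
  for.

## Extraction

Each point keeps exactly its maximum-confidence incoming link (ties: higher
parent intensity, then smaller scaled distance, then ascending parent id).
The kept links form a forest — cycles are impossible because links always
descend in (intensity, id) order. A tree becomes an XIC iff

* its root (necessarily its intensity apex) has intensity ≥ `2b`; trees
  rooted below the seed threshold are discarded wholesale rather than
  re-rooted — seeding is a privilege of high-intensity points; and
* it has **more than** 5 points (centroid) or **more than** 15 (profile).

Points of discarded trees are not released for membership elsewhere.
Output XICs are disjoint by construction, sorted by descending total
intensity, with ids assigned in that order.

The implementation accelerates window queries with a uniform grid hash
(cell sizes = the window half-widths, 3×3 neighborhood probed, exact
predicate re-checked). Its contract is exact equality with a literal
quadratic scan; `xiclink.naive` implements that reference independently and
the test suite asserts identical XIC sets on randomized runs of up to 1,000
points (25 runs in the acceptance script, ~15,000 points total).

## Evaluation metric

For a candidate XIC `A` and a reference XIC `H`, the shared-intensity
fraction is `S = Σ intensity(A ∩ H) / Σ intensity(H)`; `A` matches `H` iff
`S > 0.5`, strictly — exactly half is a miss. Matching is directional: each
reference XIC is assigned its best-S candidate, and one candidate may match
several references. Comparing two sets in both directions therefore
distinguishes a tool that concatenates co-eluting peaks (it matches both
halves of the other set, while each of its merged XICs is at most half
covered in return). Recall is the fraction of reference XICs matched. When
several candidates exceed 0.5, the maximum-S one is recorded (ties by
ascending id).

Point identity across files uses point ids when both sides carry them,
otherwise coordinate equality within absolute tolerances of 1e-6 Th in m/z
and 1e-4 s in RT — wide enough to absorb decimal round-tripping of floats,
far too narrow to merge distinct instrument points.

## Synthetic runs

The generator emulates the data features the extractor relies on:

* Gaussian elution: one point per scan within ±3 σ of the trace center,
  intensity `apex · exp(−(rt − c)²/2σ²)`; optional Gaussian m/z jitter,
  optionally snapped to an instrument m/z grid.
* Profile acquisition: a 5-sample m/z cluster per trace and scan with a
  triangular taper (1/3, 2/3, 1, 2/3, 1/3) — the minimal footprint that
  puts profile traces past the 15-point size filter at realistic spans.
* Noise: a fixed number of points per scan, uniform in m/z, with
  exponentially distributed intensities — heavy mass near zero and a
  well-defined mean, so the baseline on synthetic runs is predictable.
* Bimodal overlaps: two traces on one m/z track with summed contributions,
  each point labeled by the dominant mode; generation fails unless the
  summed profile has a valley at or below a required fraction of the lower
  apex (default 0.5).

Shipped scenarios (fixed seeds, reproducible bit-for-bit): `separated20`
(20 traces, apexes 600–1930 ≥ 10× the 50-unit noise mean, σ = 3 s, 0.7 s
scans, 10 noise points/scan — ~3,000 points), `crowded`, `bimodal` (apexes
1000/800, 18 s = 6 σ apart), `pure_noise`, `low_contrast` (apexes only ~4×
the noise mean), and `separated5_profile`. Scenario sizes keep the full
test suite and the acceptance script in the seconds range.

What the generator does **not** emulate: isotopic envelope structure,
intensity-dependent m/z error, chromatographic tailing or fronting,
detector saturation, or electrospray spray instability. Perfect recovery on
these runs demonstrates the clustering logic under its own assumptions; it
does not certify recall on instrument data, where baseline adequacy and
window coverage are the binding constraints.

## Limitations

* **Budget blow-ups under farthest-first ordering.** Any window candidate
  with `I ≤ budget/2` at scaled distance ≥ 2 consumes the whole budget in
  one zero-confidence link. On centroid data with a sparse noise floor this
  costs an occasional parent and is absorbed by the redundancy of
  within-trace links; on profile data the cluster's own taper edges trigger
  it systematically, so profile traces tend to fragment into apex-centered
  XICs that pass the size filter but cover less than half of the trace's
  intensity. The profile scenario is therefore checked for structural
  invariants, not for recall.
* **Baseline sensitivity.** The mean-intensity baseline rises with dense
  signal and falls with dense low-level noise; traces whose apex sits below
  twice the baseline are invisible to seeding by construction
  (`low_contrast` probes the near side of this regime).
* **Tails below the baseline are unreachable.** A trace is recovered down
  to roughly the baseline within two scans of a seed-eligible point; the
  sub-baseline tails of the true elution are never assigned. The
  intensity-weighted matching metric is insensitive to this by design.
* Determinism is guaranteed by total tie-break orders everywhere (point id
  as the final key); repeated runs produce byte-identical exports.
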