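# xiclink

Parameter-free extraction of ion chromatograms (XICs) from MS1 LC-MS data.

An LC-MS run is a cloud of points, each with a mass-to-charge ratio (m/z,
Thomson), a retention time (RT, seconds) and an intensity. Every eluting
ionic species leaves a *trace* through that cloud — a narrow band in m/z,
roughly Gaussian in RT. Finding those traces (extracted ion chromatograms)
is the first step of MS1 feature detection in proteomics and metabolomics,
and most tools for it expose large parameter spaces that have to be re-tuned
per instrument and per run.

`xiclink` instead self-calibrates from the run and clusters points with a
single intensity-ordered pass:

1. **Calibration.** The noise *baseline* b is the mean intensity of all
   points; the m/z *resolution* r is the smallest positive m/z gap between
   two points of one scan; the RT *sampling rate* s is the smallest RT gap
   between consecutive scans. Nothing else is needed.
2. **Budget linking.** Points with intensity ≥ b, visited in decreasing
   intensity order down to 2b, link to the lower-intensity points inside a
   window of half-width 2r in m/z and 2s in RT, traversed in decreasing
   normalized distance d. Each link consumes part of the center's intensity
   budget,

       budget ← budget − |budget − I(w)| · d(center, w),

   and carries a confidence 1 − cost/budget ∈ [0, 1]: high for neighbors
   that are near in space and similar in intensity. Linking from a center
   stops when its budget is exhausted.
3. **Extraction.** Each point keeps only its highest-confidence incoming
   link; the kept links form a forest. Every tree whose root has intensity
   ≥ 2b becomes an XIC if it has more than 5 points (centroid data) or more
   than 15 (profile data). Because links only run from higher to lower
   intensity, each XIC's root is its apex — and two co-eluting peaks at the
   same m/z are deconvolved for free, each apex seeding its own tree.

The package also ships the matching metric used to score XIC sets against a
reference: the shared-intensity fraction

    S = Σ intensity(A ∩ H) / Σ intensity(H)

with a candidate XIC A matching a reference XIC H iff S > 0.5 (strict), and
a directional comparison table that exposes which of two tools failed to
separate co-eluting signals. A synthetic-run generator with exact
ground-truth labels (Gaussian traces, exponential noise floor, bimodal
overlaps, centroid and profile modes) makes the whole pipeline testable
without any instrument data.

## Worked example

```python
from xiclink import calibrate, extract, scenario
from xiclink.evaluate import match_sets, xics_to_annotated_set

sim = scenario("separated20")        # 20 Gaussian traces over a noise floor
calib = calibrate(sim.run)
xics = extract(sim.run)              # no parameters to set
report = match_sets(xics_to_annotated_set(xics, "extracted"), sim.truth)
```

Running `python examples/extract_synthetic_run.py` prints:

```
run: 3030 points, 251 scans, 20 true XICs
self-calibration: baseline=131.1, seed threshold=262.3, resolution=0.010 Th, sampling rate=0.70 s
extracted 20 XICs; five most intense:
  xic_00001:  15 points, m/z 119.50-119.51, RT 166-177 s, apex intensity 1920
  ...
ground-truth recall: 100% (20/20 true traces covered at S > 0.5)
```

The calibration line shows the three run-derived quantities (seeding starts
at twice the baseline); the recall line means every planted trace was
recovered as a single cluster holding more than half of its intensity.
`examples/deconvolve_bimodal.py` shows two peaks 6 σ apart on one m/z track
coming out as exactly two XICs (S = 0.98 each), and
`examples/directional_comparison.py` shows how the asymmetric match counts
flag a concatenated bimodal signal.

The same workflow is available from a shell (see `examples/cli_workflow.sh`):

```sh
xiclink simulate --scenario bimodal --out sim
xiclink extract  --input sim_points.csv --out run --mode centroid
xiclink evaluate --first run_points.csv --second sim_truth.csv --out eval
```

`extract` also reads mzML directly (MS1 spectra; RT units converted to
seconds; acquisition mode taken from the spectrum-representation metadata).

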