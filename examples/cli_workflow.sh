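#!/bin/sh
# Shell workflow: simulate a run, extract XICs, score against ground truth.
# The extract step takes no tuning parameters -- only an optional
# acquisition-mode override.
set -e
out=${TMPDIR:-/tmp}/xiclink_demo
mkdir -p "$out"

xiclink simulate --scenario bimodal --out "$out/sim"
xiclink extract --input "$out/sim_points.csv" --out "$out/run" --mode centroid --verbose
xiclink evaluate --first "$out/run_points.csv" --second "$out/sim_truth.csv" --out "$out/eval"

cat "$out/eval_summary.json"
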