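"""Internal constants.

The extraction algorithm itself is parameter-free: everything it needs is
estimated from the run.  The constants below are either printed thresholds
of the method itself or small artifact-level tolerances; none of them is
exposed as a tuning knob.
"""

# Seeding: only points with intensity at least this multiple of the noise
# baseline may start a new putative XIC.
SEED_BASELINE_MULTIPLE = 2.0

# Candidate window half-widths, as multiples of the self-calibrated m/z
# resolution and RT sampling-rate estimates (closed interval on each side
# of the center point).
WINDOW_HALFWIDTH_MULTIPLE = 2.0

# Minimum XIC size (strict: a putative XIC must contain MORE than this many
# points to be kept).
MIN_XIC_POINTS = {"centroid": 5, "profile": 15}

# Shared-intensity match rule: a candidate XIC matches a reference XIC iff
# the shared-intensity fraction S is STRICTLY greater than this.
MATCH_S_THRESHOLD = 0.5

# Coordinate-matching tolerances used when point identities must be
# reconciled across files by (m/z, RT) value rather than by point id.
# Chosen to absorb decimal round-tripping of floats without false merges.
MZ_MATCH_TOL = 1e-6  # Thomson
RT_MATCH_TOL = 1e-4  # seconds

# Acquisition-mode fallback heuristic when the source file carries no
# spectrum-representation metadata: a median points-per-scan at or above
# this cutoff is treated as profile data, below it as centroid.
PROFILE_POINTS_PER_SCAN_CUTOFF = 2000
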