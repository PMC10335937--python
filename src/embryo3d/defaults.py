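"""Canonical analysis defaults, collected in one table.

These are the working defaults of the whole pipeline; the CLI exposes each
of them and a test asserts the CLI never drifts from this table.
"""

QC_MIN_COUNTS = 200          # beads must exceed this many transcripts
QC_MAX_MITO = 0.20           # and stay below this mitochondrial fraction
QC_MIN_PREDICTION = 0.6      # label-transfer score below which beads drop
AP_BINS = 25                 # spatial bins along the anterior-posterior axis
DV_BINS = 8                  # bins along the dorso-ventral axis
BOUNDARY_MAX_DIST = 300.0    # µm: beads considered "at" a boundary
BOUNDARY_TOP_GENES = 40      # genes reported per boundary, ranked by FDR
VELOCITY_GRID = 50.0         # µm grid pitch for the velocity field
VELOCITY_K = 50              # nearest neighbours per velocity summary
DTW_K = 8                    # partitional clusters for module discovery
TREND_FDR = 0.01             # BH FDR cutoff for trend-test selection
TREND_LFC = 0.05             # |log2 FC| across the axis cutoff
SECTION_THICKNESS = 10.0     # µm
SECTION_GAP = 30.0           # µm between consecutive sections
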