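"""Pipeline-wide constants.

These are the defaults of the binning / modelling / benchmarking protocol:
bins-per-axis choices, the minimum library size for a bin to be analysed,
the floor applied to estimated size factors, the number of unwanted factors
for RUV-style normalization, and the pool of community-detection resolution
parameters swept in the benchmark.
"""

# Hexagons (or squares) along the x axis; 100 for standard fields, 200 for
# large-area panels.
DEFAULT_BINS_PER_AXIS = 100
LARGE_AREA_BINS_PER_AXIS = 200

# Bins with total detections below this are removed before analysis
# (strictly "less than", so a library size of exactly 3 survives).
DEFAULT_MIN_LIBSIZE = 3

# Size factors estimated below this are clamped to it.
SIZE_FACTOR_FLOOR = 1e-8

# Number of unwanted factors (K) for RUV-style normalization inputs.
RUV_N_UNWANTED_FACTORS = 1

# Fraction of genes drawn as negative controls when no curated list is given.
CONTROL_GENE_FRACTION = 0.10

# Fraction of occupied bins used as pseudo-replicate seed loci.
PSEUDO_REPLICATE_SEED_FRACTION = 0.005

# Resolution parameters explored for Louvain and Leiden community detection.
DEFAULT_RESOLUTIONS = (0.1, 0.225, 0.35, 0.475, 0.6, 0.725, 0.85, 0.975)

# Neighborhood sizes (k) for shared-nearest-neighbor graph construction.
DEFAULT_SNN_KS = (5, 10, 20, 30)

# Number of principal components retained before graph construction.
DEFAULT_N_PCS = 50

# Smallest positive normal double; chi-square p-values that underflow this
# are reported as "< 2.2e-308" rather than silently as 0.
SMALLEST_NORMAL_DOUBLE = 2.2250738585072014e-308
P_UNDERFLOW_DISPLAY = "< 2.2e-308"
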