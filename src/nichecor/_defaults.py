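"""Central table of shipped defaults.

Every tunable the pipeline exposes reads its default from here, so the
values printed into run manifests are guaranteed to match the ones the
library actually uses.
"""

DEFAULTS: dict = {
    # neighborhoods
    "knn_k": 50,                 # K-nearest-neighbor count
    "radius_mm": 0.05,           # radius-graph default, in the dataset's length units
    "include_self": True,        # a cell belongs to its own neighborhood
    # cell filtering / normalization
    "min_counts": 20,            # per-cell total-count filter (off unless requested)
    # conditional correlation
    "max_cells": 5000,           # subsample size for correlation estimation
    "zero_variance_tol": 1e-12,  # relative tolerance flagging zero conditional variance
    # module detection
    "edge_threshold": 0.2,       # conditional correlations below this are dropped
    "leiden_resolution": 1.0,
    "max_module_size": 20,       # larger modules are re-clustered once at 2x resolution
    "min_module_size": 3,        # smaller modules are discarded
    "min_avg_cor": 0.1,          # modules with lower mean pairwise correlation are discarded
    # multi-sample
    "min_cells_per_sample": 3000,
    "consensus_cor_threshold": 0.3,
    "consensus_min_frac": 17 / 19,   # min_samples = ceil(frac * n_samples)
    "variable_hi": 0.3,
    "variable_lo": 0.05,
    "variable_min_hi": 3,
    "variable_min_lo": 3,
}
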