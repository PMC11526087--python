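"""Two-stage TMT normalization: median centering, then R2 reference scaling.

On a zero-residual cohort with per-plex batch effects, the pipeline removes
the batch factors exactly: after normalization every sample channel of a
protein agrees across plexes to machine precision.
"""

import numpy as np

from pdecm import CohortConfig, generate_cohort, median_center, normalize_pipeline

cohort = generate_cohort(
    CohortConfig(n_proteins=300, batch_sd=0.7, noise_sd=0.0, seed=3)
)

stage1 = median_center(cohort.values)
med = np.log2(stage1).median()
print(f"stage 1: log2 median spread across channels = {med.max() - med.min():.2e}")

norm, qc = normalize_pipeline(cohort.values, cohort.design)
d = cohort.design.set_index("channel")
samples = norm[d.index[d["role"] == "sample"]]
dev = (samples.max(axis=1) - samples.min(axis=1)).abs().max()
print(f"stage 2: max cross-plex deviation of sample values = {dev:.2e}")
print(f"proteins bridged across all plexes: {qc['n_proteins_bridged']}")
# Both residuals are ~1e-16: the batch factor cancels exactly because every
# channel of a plex (references included) carries the same multiplier.
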