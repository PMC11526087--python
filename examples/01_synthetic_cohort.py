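"""Generate the default synthetic TMT cohort and describe its design.

Five 11-plexes, each with nine tissue samples plus two pooled-reference
channels (131N/131C); 45 samples split 19 tumor / 17 adjacent normal /
5 lymph-node metastasis / 4 normal.
"""

from pdecm import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n_proteins=500, seed=0))

print("intensity matrix:", cohort.values.shape, "(proteins x channels)")
print("channel roles:", cohort.design["role"].value_counts().to_dict())
print("tissue groups:", cohort.samples["tissue"].value_counts().to_dict())
print(
    "matrisome categories:",
    cohort.annotation["category"].value_counts().drop("none").to_dict(),
)
# The 55 columns are 45 sample channels + 10 reference channels; the
# matrisome categories follow the canonical core/associated split.
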