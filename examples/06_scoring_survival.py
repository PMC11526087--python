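"""Bulk gene-set scoring and survival stratification.

Generates a 375-patient bulk cohort whose hazard rises with a planted
standardized gene-set score, scores every patient with the rank-based
single-sample statistic, splits at the mean score, and compares survival
with the Kaplan-Meier estimate and log-rank test.
"""

from pdecm.survival import dichotomize, km_estimate, logrank_test, ssgsea_bulk
from pdecm.synthetic import generate_bulk_survival

geneset = {f"PEM{i:02d}" for i in range(27)}
bulk = generate_bulk_survival(375, geneset, hazard_log_ratio=1.0, seed=2)

scores = ssgsea_bulk(bulk.tpm, geneset)
labels = dichotomize(scores, rule="mean")
print("group sizes:", labels.value_counts().to_dict())

chi2, p = logrank_test(bulk.survival["time"], bulk.survival["event"], labels)
print(f"log-rank chi2 = {chi2:.1f}, p = {p:.2e}")

for g in ("high", "low"):
    km = km_estimate(
        bulk.survival.loc[labels == g, "time"], bulk.survival.loc[labels == g, "event"]
    )
    print(f"{g}-score group: S(36 months) = {km['S'].asof(36.0):.2f}")
# Patients with a high gene-set score die faster (lower 3-year survival),
# recovering the planted hazard direction with a decisive log-rank p.
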