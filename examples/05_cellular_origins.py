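"""Cellular-origin assignment and per-cell PEM scoring on single-cell data.

A gene's origin is the cell type where it is both statistically specific
(one-vs-rest Wilcoxon, BH-adjusted p < 0.01) and most highly expressed on
average. The planted PEM genes are fibroblast-origin by construction, and
the PCC-NOS-like fibroblast subpopulation scores higher for them.
"""

from pdecm.singlecell import assign_origin, find_markers, origin_fractions, sc_score
from pdecm.synthetic import PlantedTruth, generate_sc_data

truth = PlantedTruth(pem_true={f"PEM{i:02d}" for i in range(10)})
truth.origin_true = {g: "Fibroblast" for g in truth.pem_true}
cell_types = [
    "Fibroblast", "Epithelial", "Macrophage", "Endothelial",
    "T cell", "B cell", "Mast cell",
]
adata = generate_sc_data(100, cell_types, truth, seed=5)
print("cells x genes:", adata.shape)

markers = find_markers(adata)
genes = sorted(truth.pem_true)
origins = assign_origin(genes, adata, markers)
print("origin fractions:", origin_fractions(genes, origins).round(3).to_dict())

fib = adata[adata.obs["cell_type"] == "Fibroblast"].copy()
scores = sc_score(fib, truth.pem_true)
sub = fib.obs["pccnos_like"].to_numpy()
print(f"mean PEM score: PCC-NOS-like fibroblasts {scores[sub].mean():.1f} "
      f"vs other fibroblasts {scores[~sub].mean():.1f}")
# All planted genes map to fibroblasts (fraction 1.0), and the planted
# subpopulation separates cleanly on the rank-based score.
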