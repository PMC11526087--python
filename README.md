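# pdecm

Matrisome-centric analysis of multi-plex TMT proteomics from decellularized
(patient-derived ECM, "pdECM") tissue, with single-cell and survival
integration. The package is aimed at proteomics analysts who quantify the
extracellular matrix of tumor versus normal tissue across several isobaric
plexes and want a tested, reusable implementation of the full downstream
chain:

1. **Normalization** — within-channel median centering on the log2 scale,
   then cross-plex bridging through the second pooled-reference channel
   (R2): for protein *i* in plex *p*,
   `out[i,j] = in[i,j] / in[i,R2_p] × mean_p(in[i,R2_p])`.
2. **Matrisome profiling** — relative percent composition
   (RPC `= 100·x_is / Σ_k x_ks`), per-category compositions with Welch
   tests, 90%-cumulative-coverage counts, top-20 abundance lists,
   hierarchical clustering and PCA of matrisome profiles.
3. **Differential matrisome proteins (DEPs)** — Welch's *t* test on log2
   intensities with linear-scale fold change; a protein is a DEP when
   FC > √2 (|log2FC| > 0.5) and *p* < 0.05. PCC-NOS-enriched matrisome
   proteins (**PEMs**) are the DEPs on the PCC-NOS side of the PCC-NOS vs
   non-PCC-NOS tumor contrast.
4. **Cellular origins** — a gene's origin is the cell type where it is both
   specific (one-vs-rest Wilcoxon rank-sum, BH-adjusted *p* < 0.01, positive
   fold change) and most highly expressed on average in single-cell data.
5. **Gene-set scoring** — one audited single-sample rank-based enrichment
   scorer (ssGSEA, exponent α = 0.25) for cells and bulk cohorts:
   `ES = Σ_i (P_in(i) − P_out(i))` walking the within-sample expression
   ranking from top to bottom.
6. **Survival** — mean-score dichotomization, Kaplan–Meier estimate and
   log-rank test.

A first-class synthetic-data module generates every input with the
statistical structure the analysis assumes — five TMT 11-plexes (nine tissue
samples + 131N/131C references each; 19 TUM / 17 NAT / 5 LNM / 4 NN), a
7-cell-type single-cell matrix with a PCC-NOS-like fibroblast subpopulation,
and a bulk cohort whose hazard rises with a planted gene-set score — so the
whole pipeline is testable end-to-end with known ground truth.

## Worked example

```python
from pdecm.pipeline import RunConfig, run_all
report = run_all(RunConfig(seed=1, outdir="run1"))
```

prints (abridged from `run1/report.json`):

```
"n_sample_channels": 45,          # 5 plexes x 9 tissue samples
"dep_tumor_enriched": 28,         # planted 20 tumor-up (+ PEMs, which are
"dep_nat_enriched": 20,           #   tumor-enriched via their PCC-NOS arm)
"pem_size": 27,                   # the 27 planted PEMs ...
"pem_recovered_exactly": true,    # ... recovered exactly
"origin_fibroblast_fraction": 1.0,# all PEM genes map to fibroblasts
"logrank_chi2": 74.0,             # high- vs low-PEM-score survival split
"logrank_p": 7.8e-18
```

The DEP counts reflect the planted truth plus the fold-change/p interplay on
a finite cohort; the log-rank statistic shows the planted hazard direction
(high score → worse survival) is recovered. Shorter, per-capability
walkthroughs live in `examples/` (one script per stage; each prints what it
computes and what the numbers mean), and `pdecm --help` exposes the same
stages as a thin CLI.

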