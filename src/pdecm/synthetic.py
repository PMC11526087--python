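"""Synthetic data emulating the pdECM study design.

Three generators produce every input the pipeline consumes, together with
the planted ground truth needed for parameter-recovery tests:

* :func:`generate_cohort` — a multi-plex TMT protein intensity matrix with
  channel design, sample metadata and a matrisome annotation. The default
  configuration mirrors the study: five TMT 11-plexes, each carrying nine
  tissue samples plus two pooled-reference channels (131N = R1, 131C = R2);
  45 tissue samples split 19 tumor (TUM) / 17 adjacent normal (NAT) / 5
  lymph-node metastasis (LNM) / 4 normal (NN); 4838 proteins of which 376
  are matrisome, split over the six matrisome categories in the proportions
  37 COL / 102 GLY / 18 PRO / 99 REG / 55 AFF / 63 SEC.
* :func:`generate_sc_data` — a labeled single-cell count matrix with planted
  cell-type-specific genes and a PCC-NOS-like fibroblast subpopulation that
  over-expresses the planted PEM genes.
* :func:`generate_bulk_survival` — a bulk TPM cohort whose survival hazard
  increases with a planted standardized gene-set score.

Intensities follow a log-normal model, ``2**(log2 baseline + batch + effect
+ noise)``: per-plex multiplicative batch factors and Gaussian log2 residual
noise, with planted log2 effects restricted to TUM channels (tumor effects)
and PCC-NOS TUM channels (PCC-NOS effects). The pre-noise expected value of
both reference channels equals the pooled (arithmetic, linear-scale) mean of
all sample channels — the pooled common control mixed from equal amounts of
every sample. Reference channels receive independent noise draws.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "PlantedTruth",
    "CohortData",
    "BulkSurvival",
    "generate_cohort",
    "generate_sc_data",
    "generate_bulk_survival",
    "MATRISOME_CATEGORIES",
]

#: category -> (division, default protein count at the study scale)
MATRISOME_CATEGORIES: dict[str, tuple[str, int]] = {
    "COL": ("core matrisome", 37),
    "GLY": ("core matrisome", 102),
    "PRO": ("core matrisome", 18),
    "REG": ("matrisome-associated", 99),
    "AFF": ("matrisome-associated", 55),
    "SEC": ("matrisome-associated", 63),
}

_DEFAULT_WEIGHTS = {
    cat: n / sum(n for _, n in MATRISOME_CATEGORIES.values())
    for cat, (_, n) in MATRISOME_CATEGORIES.items()
}

#: TMT 11-plex reporter tags in channel order; 131N/131C carry the references.
TMT11_SAMPLE_TAGS = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C"]


@dataclass
class CohortConfig:
    """Configuration of the synthetic TMT cohort.

    Planted effect maps are keyed by protein symbol (symbols are
    deterministic: matrisome proteins ``MAT0001..``, others ``PRT0001..``)
    and give the log2 effect added to TUM channels (``planted_tumor_effects``)
    or to PCC-NOS TUM channels (``planted_pccnos_effects``).
    """

    n_plexes: int = 5
    samples_per_plex: int = 9
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"TUM": 19, "NAT": 17, "LNM": 5, "NN": 4}
    )
    n_proteins: int = 4838
    matrisome_fraction: float = 376 / 4838
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    n_pccnos: int = 4
    batch_sd: float = 0.5
    noise_sd: float = 0.3
    missing_rate: float = 0.0
    planted_tumor_effects: dict[str, float] = field(default_factory=dict)
    planted_pccnos_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_plexes, self.samples_per_plex, self.n_proteins) <= 0:
            raise ValueError("counts must be positive")
        if sum(self.group_sizes.values()) != self.n_plexes * self.samples_per_plex:
            raise ValueError(
                "sum of group sizes must equal n_plexes * samples_per_plex"
            )
        if not 0.0 <= self.matrisome_fraction <= 1.0:
            raise ValueError("matrisome_fraction must be in [0, 1]")
        if abs(sum(self.category_weights.values()) - 1.0) > 1e-9:
            raise ValueError("category_weights must sum to 1")
        if set(self.category_weights) - set(MATRISOME_CATEGORIES):
            raise ValueError("unknown matrisome category in category_weights")
        if self.batch_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_pccnos > self.group_sizes.get("TUM", 0):
            raise ValueError("n_pccnos exceeds the number of tumor samples")

    def protein_symbols(self) -> tuple[list[str], list[str]]:
        """Deterministic (matrisome, other) protein symbols for this config."""
        n_mat = int(round(self.n_proteins * self.matrisome_fraction))
        mat = [f"MAT{i + 1:04d}" for i in range(n_mat)]
        other = [f"PRT{i + 1:04d}" for i in range(self.n_proteins - n_mat)]
        return mat, other


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, for recovery tests."""

    tumor_up: set[str] = field(default_factory=set)
    tumor_down: set[str] = field(default_factory=set)
    pem_true: set[str] = field(default_factory=set)
    origin_true: dict[str, str] = field(default_factory=dict)
    caf_adi_genes: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if self.tumor_up & self.tumor_down:
            raise ValueError("tumor_up and tumor_down overlap")


CohortData = namedtuple(
    "CohortData", ["values", "design", "samples", "annotation", "truth"]
)

BulkSurvival = namedtuple("BulkSurvival", ["tpm", "survival", "latent"])


def _category_counts(n_mat: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of matrisome proteins to categories."""
    cats = sorted(weights)
    raw = {c: n_mat * weights[c] for c in cats}
    counts = {c: int(np.floor(raw[c])) for c in cats}
    short = n_mat - sum(counts.values())
    for c in sorted(cats, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def make_annotation(config: CohortConfig) -> pd.DataFrame:
    """Matrisome annotation table (gene, division, category) for the cohort."""
    mat, other = config.protein_symbols()
    counts = _category_counts(len(mat), config.category_weights)
    categories: list[str] = []
    for cat in sorted(counts):
        categories.extend([cat] * counts[cat])
    rows = [
        (g, MATRISOME_CATEGORIES[c][0], c) for g, c in zip(mat, categories)
    ] + [(g, "none", "none") for g in other]
    return pd.DataFrame(rows, columns=["gene", "division", "category"]).set_index(
        "gene"
    )


def _sample_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    patient_counter = {"TUM": 0, "NAT": 0, "LNM": 0}
    for tissue in ("TUM", "NAT", "LNM", "NN"):
        for _ in range(config.group_sizes.get(tissue, 0)):
            if tissue == "NN":
                patient = f"N{len(rows) + 1:02d}"
            else:
                patient_counter[tissue] += 1
                patient = f"P{patient_counter[tissue]:02d}"
            rows.append((f"S{len(rows) + 1:02d}", patient, tissue))
    samples = pd.DataFrame(rows, columns=["sample_id", "patient", "tissue"])
    pccnos_patients = {f"P{i + 1:02d}" for i in range(config.n_pccnos)}
    samples["histology"] = np.where(
        samples["tissue"] == "NN",
        "NA",
        np.where(
            samples["patient"].isin(pccnos_patients), "PCC-NOS", "non-PCC-NOS"
        ),
    )
    # Spread tissue classes across plexes so no plex is a pure group.
    order = rng.permutation(len(samples))
    plex = np.empty(len(samples), dtype=int)
    plex[order] = np.arange(len(samples)) % config.n_plexes + 1
    samples["plex"] = plex
    return samples.set_index("sample_id")


def generate_cohort(config: CohortConfig | None = None) -> CohortData:
    """Generate the TMT cohort: intensities, design, metadata, annotation, truth.

    Returns a :class:`CohortData` named tuple with

    * ``values`` — proteins x channels linear intensities (columns named
      ``plex<p>_<tag>``),
    * ``design`` — channel, plex, role (sample/R1/R2), sample_id,
    * ``samples`` — per-sample patient, tissue class, histology, plex,
    * ``annotation`` — gene, matrisome division and category,
    * ``truth`` — the planted effects as a :class:`PlantedTruth`.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    mat, other = config.protein_symbols()
    proteins = mat + other
    if len(set(proteins)) != len(proteins):
        raise ValueError("duplicate protein identifiers")
    unknown = (
        set(config.planted_tumor_effects) | set(config.planted_pccnos_effects)
    ) - set(proteins)
    if unknown:
        raise ValueError(f"planted effects reference unknown proteins: {sorted(unknown)}")

    samples = _sample_table(config, rng)
    annotation = make_annotation(config)

    # Matrisome proteins dominate total intensity in decellularized tissue,
    # so they get a higher log2 baseline (~62% intensity share at scale).
    base = np.where(
        annotation.loc[proteins, "category"] != "none",
        rng.normal(21.2, 1.5, len(proteins)),
        rng.normal(17.0, 1.5, len(proteins)),
    )

    # Per-sample planted log2 effects.
    eff = pd.DataFrame(0.0, index=proteins, columns=samples.index)
    is_tum = samples["tissue"] == "TUM"
    is_pccnos_tum = is_tum & (samples["histology"] == "PCC-NOS")
    for prot, e in config.planted_tumor_effects.items():
        eff.loc[prot, is_tum] += e
    for prot, e in config.planted_pccnos_effects.items():
        eff.loc[prot, is_pccnos_tum] += e

    sample_log2 = base[:, None] + eff.to_numpy()
    # Pooled common control: equal amounts of every sample (linear mean).
    ref_log2 = np.log2(np.mean(2.0 ** sample_log2, axis=1))

    batch = rng.normal(0.0, config.batch_sd, config.n_plexes)
    generic_tags = config.samples_per_plex != len(TMT11_SAMPLE_TAGS)

    columns: list[str] = []
    design_rows: list[tuple] = []
    log2_cols: list[np.ndarray] = []
    for p in range(1, config.n_plexes + 1):
        plex_samples = samples.index[samples["plex"] == p]
        tags = (
            [f"ch{i + 1}" for i in range(len(plex_samples))]
            if generic_tags
            else TMT11_SAMPLE_TAGS
        )
        for tag, sid in zip(tags, plex_samples):
            columns.append(f"plex{p}_{tag}")
            design_rows.append((columns[-1], p, "sample", sid))
            log2_cols.append(sample_log2[:, samples.index.get_loc(sid)] + batch[p - 1])
        for tag, role in (("131N", "R1"), ("131C", "R2")):
            columns.append(f"plex{p}_{tag}")
            design_rows.append((columns[-1], p, role, None))
            log2_cols.append(ref_log2 + batch[p - 1])

    log2_matrix = np.column_stack(log2_cols)
    if config.noise_sd > 0:
        log2_matrix = log2_matrix + rng.normal(0.0, config.noise_sd, log2_matrix.shape)
    values = pd.DataFrame(2.0 ** log2_matrix, index=proteins, columns=columns)
    values.index.name = "gene"
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.mask(mask)

    design = pd.DataFrame(design_rows, columns=["channel", "plex", "role", "sample_id"])
    truth = PlantedTruth(
        tumor_up={p for p, e in config.planted_tumor_effects.items() if e > 0},
        tumor_down={p for p, e in config.planted_tumor_effects.items() if e < 0},
        pem_true={p for p, e in config.planted_pccnos_effects.items() if e > 0},
    )
    truth.origin_true = {g: "Fibroblast" for g in truth.pem_true}
    truth.validate()
    return CohortData(values, design, samples, annotation, truth)


def generate_sc_data(
    n_cells_per_type: int,
    cell_types: list[str],
    planted: PlantedTruth,
    seed: int = 0,
    genes: list[str] | None = None,
    n_background: int = 200,
    fibro_type: str = "Fibroblast",
    pccnos_like_fraction: float = 0.3,
    origin_log2fc: float = 3.0,
    pem_sub_log2fc: float = 2.0,
    base_mean: float = 0.3,
) -> ad.AnnData:
    """Labeled single-cell count matrix with planted structure.

    Genes listed in ``planted.origin_true`` are expressed at an elevated mean
    (``2**origin_log2fc`` fold) in their assigned cell type and near-baseline
    elsewhere. A PCC-NOS-like subpopulation comprising ``pccnos_like_fraction``
    of the fibroblasts additionally over-expresses ``planted.pem_true`` genes
    by ``2**pem_sub_log2fc``. Counts are Poisson around log-normal gene means.

    Returns an :class:`anndata.AnnData` with raw counts in
    ``layers["counts"]``, a per-cell depth-normalized log1p layer in ``X``,
    ``obs["cell_type"]`` and the boolean ``obs["pccnos_like"]`` mask.
    """
    if not cell_types:
        raise ValueError("cell_types must be non-empty")
    unknown = set(planted.origin_true.values()) - set(cell_types)
    if unknown:
        raise ValueError(f"origin_true references unknown cell types: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    if genes is None:
        genes = sorted(set(planted.origin_true) | planted.pem_true) + [
            f"BG{i + 1:04d}" for i in range(n_background)
        ]
    genes = list(genes)
    missing = (set(planted.origin_true) | planted.pem_true) - set(genes)
    if missing:
        raise ValueError(f"planted genes absent from gene list: {sorted(missing)}")

    n_cells = n_cells_per_type * len(cell_types)
    labels = np.repeat(cell_types, n_cells_per_type)
    pccnos_like = np.zeros(n_cells, dtype=bool)
    fib = np.flatnonzero(labels == fibro_type)
    pccnos_like[fib[: int(round(len(fib) * pccnos_like_fraction))]] = True

    gene_base = base_mean * 2.0 ** rng.normal(0.0, 1.0, len(genes))
    mean = np.tile(gene_base, (n_cells, 1))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, ctype in planted.origin_true.items():
        mean[labels == ctype, gene_pos[g]] *= 2.0 ** origin_log2fc
    for g in planted.pem_true:
        mean[pccnos_like, gene_pos[g]] *= 2.0 ** pem_sub_log2fc

    counts = rng.poisson(mean).astype(np.float32)
    adata = ad.AnnData(
        X=counts.copy(),
        obs=pd.DataFrame(
            {"cell_type": pd.Categorical(labels), "pccnos_like": pccnos_like},
            index=[f"cell{i + 1:05d}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(index=genes),
    )
    adata.layers["counts"] = counts
    depth = counts.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    adata.X = np.log1p(counts / depth * 1e4)
    return adata


def generate_bulk_survival(
    n_patients: int,
    geneset: set[str],
    hazard_log_ratio: float,
    seed: int = 0,
    n_genes: int = 500,
    extra_genes: set[str] | None = None,
    baseline_hazard: float = 1 / 60.0,
    censor_horizon: float = 120.0,
    noise_sd: float = 0.5,
) -> BulkSurvival:
    """Bulk TPM cohort with survival driven by a planted gene-set score.

    A standard-normal latent score ``z`` per patient shifts the log2 mean of
    the gene-set genes by ``z`` (so the set's within-sample ranks rise with
    ``z``), and event times are exponential with log-hazard
    ``log(baseline_hazard) + hazard_log_ratio * z``. Censoring is uniform
    administrative on ``[0, censor_horizon]`` (months). TPM columns are
    normalized to sum to 1e6 per patient. ``extra_genes`` are included in
    the matrix by name (as background genes) without the planted shift.
    """
    if n_patients < 10:
        raise ValueError("n_patients must be at least 10")
    geneset = set(geneset)
    if not geneset:
        raise ValueError("gene set is empty")
    rng = np.random.default_rng(seed)

    named = sorted(geneset | ((extra_genes or set()) - geneset))
    genes = named + [f"G{i + 1:05d}" for i in range(max(0, n_genes - len(named)))]
    in_set = np.array([g in geneset for g in genes])
    patients = [f"T{i + 1:04d}" for i in range(n_patients)]

    z = rng.standard_normal(n_patients)
    base = rng.normal(6.0, 2.0, len(genes))  # log2 expression baseline
    log2_expr = (
        base[:, None]
        + np.where(in_set[:, None], z[None, :], 0.0)
        + rng.normal(0.0, noise_sd, (len(genes), n_patients))
    )
    expr = 2.0 ** log2_expr
    tpm = pd.DataFrame(
        expr / expr.sum(axis=0, keepdims=True) * 1e6, index=genes, columns=patients
    )
    tpm.index.name = "gene"

    hazard = baseline_hazard * np.exp(hazard_log_ratio * z)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.0, censor_horizon, n_patients)
    survival = pd.DataFrame(
        {
            "time": np.minimum(t_event, t_censor),
            "event": (t_event <= t_censor).astype(int),
        },
        index=pd.Index(patients, name="patient"),
    )
    return BulkSurvival(tpm, survival, pd.Series(z, index=patients, name="latent"))
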