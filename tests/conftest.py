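import numpy as np
import pandas as pd
import pytest

from pdecm.synthetic import CohortConfig, PlantedTruth, generate_cohort, generate_sc_data

CELL_TYPES = [
    "Fibroblast",
    "Epithelial",
    "Macrophage",
    "Endothelial",
    "T cell",
    "B cell",
    "Mast cell",
]


@pytest.fixture(scope="session")
def small_cohort():
    """Default-design cohort at reduced protein count (fast)."""
    return generate_cohort(CohortConfig(n_proteins=300, seed=11))


@pytest.fixture(scope="session")
def planted_truth():
    truth = PlantedTruth(pem_true={f"PEM{i:02d}" for i in range(10)})
    truth.origin_true = {g: "Fibroblast" for g in truth.pem_true}
    return truth


@pytest.fixture(scope="session")
def sc_data(planted_truth):
    return generate_sc_data(60, CELL_TYPES, planted_truth, seed=5)


def welch_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and two-sided p from first principles.

    Uses only means/variances and the t CDF, independent of the package's
    test routine.
    """
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return float(t), float(p)


def ssgsea_oracle(expr: pd.Series, geneset: set, alpha: float = 0.25) -> float:
    """Brute-force running-sum enumeration of the single-sample score.

    Walks the ranking position by position with explicit loops; ties in the
    walk order are broken by gene name, ranks are ascending average ranks.
    """
    from scipy.stats import rankdata

    expr = expr.sort_index()
    ranks = pd.Series(rankdata(expr.to_numpy()), index=expr.index)
    order = sorted(expr.index, key=lambda g: (-ranks[g], g))
    w_total = sum(ranks[g] ** alpha for g in order if g in geneset)
    n_out = sum(g not in geneset for g in order)
    es, p_in, p_out = 0.0, 0.0, 0.0
    for g in order:
        if g in geneset:
            p_in += ranks[g] ** alpha / w_total
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es
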