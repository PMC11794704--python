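"""Scoring for the fixed-cell siRNA x drug screen.

Covers growth/viability normalization (percent inhibition, normalized
growth rate), multinucleation statistics (two-sample proportions test),
assay validity (Z'-factor), phenotype-space distance from the
non-targeting control in z-scored feature space, and per-cell gating
(EdU/DNA-content cell-cycle gates, cleaved-PARP positivity threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def percent_inhibition(count: float, control_count: float) -> float:
    """100 * (1 - count / control) relative to the matched growth control."""
    if control_count <= 0:
        raise ValueError("control count must be positive")
    return float(100.0 * (1.0 - count / control_count))


def multinucleation_test(
    a_multi: int, a_total: int, b_multi: int, b_total: int
) -> tuple[float, float]:
    """Two-sample proportions test for fraction multinucleated.

    Chi-square test with Yates continuity correction on the 2x2 table
    (the common default of the proportions test).  Returns
    ``(statistic, p_value)``; the caller applies Bonferroni correction
    across its tested family.
    """
    for multi, total in ((a_multi, a_total), (b_multi, b_total)):
        if total <= 0:
            raise ValueError("total cell counts must be positive")
        if not 0 <= multi <= total:
            raise ValueError("multinucleated count must lie in [0, total]")
    table = np.array(
        [[a_multi, a_total - a_multi], [b_multi, b_total - b_multi]], dtype=float
    )
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni-adjusted p-values for one tested family (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)


def z_prime(pos_values: np.ndarray, neg_values: np.ndarray) -> float:
    """Z'-factor: 1 - 3(sd_pos + sd_neg) / |mean_pos - mean_neg|.

    Positive values indicate a screening assay with usable dynamic range
    between positive and negative controls.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 values per control group")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        raise ValueError("Z'-factor undefined: control means are equal")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep)


def feature_distance(
    vector: np.ndarray, reference: np.ndarray, population: np.ndarray
) -> float:
    """Euclidean distance in z-scored phenotype-feature space.

    Each feature is z-scored across the screened population (population
    mean and SD), then the distance between ``vector`` and ``reference``
    (typically the non-targeting control) is computed in that space.
    Zero-variance features carry no information and are dropped with a
    warning rather than producing infinities.
    """
    v = np.asarray(vector, dtype=float)
    r = np.asarray(reference, dtype=float)
    pop = np.atleast_2d(np.asarray(population, dtype=float))
    if pop.shape[0] < 2:
        raise ValueError("population must contain at least 2 vectors for z-scoring")
    if v.shape != r.shape or v.shape != (pop.shape[1],):
        raise ValueError("vector, reference and population features must align")
    mu = pop.mean(axis=0)
    sd = pop.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} zero-variance feature(s) from "
            "the z-scored distance",
            stacklevel=2,
        )
    if not np.any(keep):
        raise ValueError("all features have zero variance")
    return float(np.linalg.norm((v[keep] - r[keep]) / sd[keep]))


def phenotype_pca(population: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """PCA coordinates of z-scored phenotype vectors (optional report aid)."""
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    z = StandardScaler().fit_transform(population.to_numpy(float))
    coords = PCA(n_components=n_components).fit_transform(z)
    return pd.DataFrame(
        coords,
        index=population.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )


# ---------------------------------------------------------------------------
# per-cell gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateConfig:
    """Thresholds for EdU/DNA-content gating (derived per-plate upstream)."""

    edu_positive_cutoff: float
    dapi_2n_4n_boundary: float


def edu_gate(total_dapi: float, total_edu: float, gates: GateConfig) -> str:
    """Classify a fixed cell into 2N/EdU-, EdU+ or 4N/EdU-.

    EdU positivity takes precedence; EdU-negative cells are split by DNA
    content at the 2N/4N boundary.
    """
    if total_edu > gates.edu_positive_cutoff:
        return "EdU+"
    if total_dapi < gates.dapi_2n_4n_boundary:
        return "2N/EdU-"
    return "4N/EdU-"


def edu_gate_table(
    total_dapi: np.ndarray, total_edu: np.ndarray, gates: GateConfig
) -> np.ndarray:
    """Vectorized :func:`edu_gate`."""
    dapi = np.asarray(total_dapi, dtype=float)
    edu = np.asarray(total_edu, dtype=float)
    out = np.where(
        edu > gates.edu_positive_cutoff,
        "EdU+",
        np.where(dapi < gates.dapi_2n_4n_boundary, "2N/EdU-", "4N/EdU-"),
    )
    return out.astype(object)


def cparp_threshold(control_values: np.ndarray, quantile: float = 0.99) -> float:
    """Apoptosis-marker positivity cutoff: the 99th percentile of vehicle-
    control nuclear cPARP intensities."""
    vals = np.asarray(control_values, dtype=float)
    if vals.size == 0:
        raise ValueError("control values must be non-empty")
    return float(np.quantile(vals, quantile))


def growth_rate(
    count_t: float, count_0: float, ctrl_t: float, ctrl_0: float
) -> float:
    """Normalized growth rate: 2^(log2(c_t/c_0) / log2(ctrl_t/ctrl_0)) - 1.

    1 means the treated population doubled like the control, 0 is
    cytostasis (no net growth), negative values indicate net loss; the
    metric is bounded below by -1.
    """
    for name, v in (
        ("count_t", count_t), ("count_0", count_0),
        ("ctrl_t", ctrl_t), ("ctrl_0", ctrl_0),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if ctrl_t <= ctrl_0:
        raise ValueError("normalized growth rate undefined for a non-growing control")
    return float(2.0 ** (np.log2(count_t / count_0) / np.log2(ctrl_t / ctrl_0)) - 1.0)
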