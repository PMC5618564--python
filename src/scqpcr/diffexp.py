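"""Distribution-based differential expression for single-cell qPCR data.

Gene-wise comparisons use the standard two-sample Kolmogorov-Smirnov
test on the full per-cell log2 expression vectors, with floored
non-expresser values included as real observations: the point mass a
dropout-prone gene leaves at the expression floor is part of the
distributional shift being tested. Family-wise error over the gene panel
is controlled by Bonferroni correction, and each comparison carries
per-side medians and failed-amplification fractions for reporting.

The KS statistic D is the supremum of |ECDF_a - ECDF_b| evaluated at all
pooled sample points (exact under ties); the two-sided p-value uses the
asymptotic Kolmogorov distribution at sqrt(n_eff) * D with effective
sample size n_eff = |a||b| / (|a|+|b|). For small samples an exact
permutation p-value (exhaustive enumeration of label assignments) is
available and serves as the oracle in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix
from .subpop import ClusterResult

__all__ = [
    "DiffExpTable",
    "GaussianFit",
    "ks_two_sample",
    "ks_permutation_pvalue",
    "bonferroni",
    "compare_groups",
    "cluster_vs_rest",
    "gaussian_fit",
]


@dataclass
class DiffExpTable:
    """Per-gene KS comparison between two sets of cells.

    ``table`` has one row per tested gene with columns gene, ks_D, p_raw,
    p_adj, significant, median_<A>, median_<B>, failed_frac_<A>,
    failed_frac_<B>, direction; ``m`` is the Bonferroni family size
    (genes actually tested) and ``sides`` the two set labels (A, B).
    direction is the sign of median_A - median_B ("up" = higher in A).
    """

    table: pd.DataFrame
    m: int
    alpha: float
    sides: tuple[str, str]

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "gene"])


@dataclass
class GaussianFit:
    """Normal summary of a log2 expression sample, for display panels."""

    mu: float
    sigma: float
    n: int
    degenerate: bool


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns (D, p). D is computed exactly at all pooled sample points, so
    ties (including the floor point mass) are handled by evaluating both
    ECDFs at the tied value. p is the asymptotic two-sided Kolmogorov
    probability at sqrt(|a||b|/(|a|+|b|)) * D.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if min(n1, n2) < 5:
        warnings.warn(
            f"KS test with fewer than 5 observations per side ({n1} vs {n2}) "
            "has very low power",
            stacklevel=2,
        )
    pts = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pts, side="right") / n1
    cdf_b = np.searchsorted(b, pts, side="right") / n2
    d = float(np.abs(cdf_a - cdf_b).max())
    n_eff = n1 * n2 / (n1 + n2)
    p = float(np.clip(stats.kstwobign.sf(np.sqrt(n_eff) * d), 0.0, 1.0))
    return d, p


def _ks_d(a: np.ndarray, b: np.ndarray) -> float:
    a = np.sort(a)
    b = np.sort(b)
    pts = np.concatenate([a, b])
    return float(
        np.abs(
            np.searchsorted(a, pts, side="right") / len(a)
            - np.searchsorted(b, pts, side="right") / len(b)
        ).max()
    )


def ks_permutation_pvalue(a, b, max_enumeration: int = 200_000) -> float:
    """Exact permutation p-value for the two-sample KS statistic.

    Enumerates all C(|a|+|b|, |a|) assignments of the pooled values to the
    two labels and reports the fraction with D at least as large as the
    observed one. Intended for small samples; refuses enumerations larger
    than ``max_enumeration``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    total = comb(n1 + n2, n1)
    if total > max_enumeration:
        raise ValueError(
            f"{total} label assignments exceed max_enumeration={max_enumeration}"
        )
    pooled = np.concatenate([a, b])
    d_obs = _ks_d(a, b)
    idx = np.arange(n1 + n2)
    hits = 0
    for chosen in combinations(idx, n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(chosen)] = True
        if _ks_d(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def bonferroni(p_raw, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray, int]:
    """Bonferroni family-wise correction: p_adj = min(1, m * p_raw).

    ``m`` is the number of p-values supplied, i.e. the number of tests
    actually performed. Returns (p_adj, significant, m) with
    significant <=> p_adj < alpha.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(p.size)
    p_adj = np.minimum(1.0, m * p)
    return p_adj, p_adj < alpha, m


def _compare_sets(
    matrix: ExpressionMatrix,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    labels: tuple[str, str],
    alpha: float,
    exact: bool = False,
) -> DiffExpTable:
    name_a, name_b = labels
    rows = []
    for j, gene in enumerate(matrix.gene_ids):
        va = matrix.values[mask_a, j]
        vb = matrix.values[mask_b, j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d, p = ks_two_sample(va, vb)
            if exact:
                p = ks_permutation_pvalue(va, vb)
        med_a, med_b = float(np.median(va)), float(np.median(vb))
        rows.append(
            {
                "gene": gene,
                "ks_D": d,
                "p_raw": p,
                f"median_{name_a}": med_a,
                f"median_{name_b}": med_b,
                f"failed_frac_{name_a}": float(1 - matrix.expressed[mask_a, j].mean()),
                f"failed_frac_{name_b}": float(1 - matrix.expressed[mask_b, j].mean()),
                "direction": "up" if med_a > med_b else ("down" if med_a < med_b else "none"),
            }
        )
    frame = pd.DataFrame(rows)
    p_adj, significant, m = bonferroni(frame["p_raw"].to_numpy(), alpha=alpha)
    frame.insert(3, "p_adj", p_adj)
    frame.insert(4, "significant", significant)
    return DiffExpTable(table=frame, m=m, alpha=alpha, sides=(name_a, name_b))


def compare_groups(
    matrix: ExpressionMatrix, alpha: float = 0.05, groups=None, exact: bool = False
) -> DiffExpTable:
    """Gene-wise KS comparison between the two biological groups.

    Uses the matrix's own group annotation unless ``groups`` overrides it;
    exactly two groups are required. Floored non-expresser values enter the
    samples; Bonferroni m is the number of retained genes.
    """
    labels = np.asarray(matrix.group if groups is None else groups)
    if labels.shape != (matrix.n_cells,):
        raise ValueError("group labels must have one entry per cell")
    levels = list(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    mask_a = labels == levels[0]
    mask_b = labels == levels[1]
    return _compare_sets(
        matrix, mask_a, mask_b, (str(levels[0]), str(levels[1])), alpha, exact
    )


def cluster_vs_rest(
    matrix: ExpressionMatrix,
    clusters: ClusterResult,
    alpha: float = 0.05,
    exact: bool = False,
) -> dict[int, DiffExpTable]:
    """For each cluster, gene-wise KS of its cells against all other cells.

    Requires k >= 2 (with a single cluster there is no "rest"). A singleton
    cluster is still tested but flagged with a low-power warning. Direction
    is the sign of median(cluster) - median(rest).
    """
    if clusters.k < 2:
        raise ValueError("cluster-vs-rest needs at least two clusters")
    if len(clusters.labels) != matrix.n_cells:
        raise ValueError("cluster labels not aligned with matrix cells")
    out: dict[int, DiffExpTable] = {}
    for c in range(1, clusters.k + 1):
        mask = clusters.mask(c)
        if mask.sum() <= 1:
            warnings.warn(f"cluster {c} is a singleton; test has very low power")
        out[c] = _compare_sets(
            matrix, mask, ~mask, (f"cluster{c}", "rest"), alpha, exact
        )
    return out


def gaussian_fit(values) -> GaussianFit:
    """Normal fit (sample mean, n-1 sd) used for the display curve panels."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    mu = float(v.mean())
    sigma = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return GaussianFit(mu=mu, sigma=sigma, n=int(v.size), degenerate=(v.size < 2 or sigma == 0.0))
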