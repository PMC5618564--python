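"""Limit-of-detection-aware normalization of single-cell qPCR Ct values.

Raw cycle-threshold values are converted to log2 fold change from the
pooled per-gene median: one PCR cycle corresponds to one doubling, so
``median_ct - ct`` is already a base-2 logarithm of relative abundance
(lower Ct means more transcript, hence a positive value). Values are
clipped to an absolute bound of +/- B cycle thresholds from the median
(B = 5 by default, a 2**5 = 32-fold ceiling), and reactions that failed
to amplify ("non-expressers") are assigned exactly the -B floor.

The pooled median is taken over all cells from all groups and chips
combined, using successfully amplified reactions only (a configurable
policy), so group effects are preserved by the centering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_io import CtTable

__all__ = [
    "ExpressionMatrix",
    "pooled_gene_medians",
    "normalize",
    "expressed_fraction",
    "failed_fraction",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Clipped, median-centered log2 expression with an expressed mask.

    ``values`` lies in [-bound, +bound]; ``expressed`` is False exactly for
    entries whose raw reaction failed to amplify and which were therefore
    assigned the -bound floor. (An expressed entry may also sit at -bound
    through clipping; it keeps ``expressed == True``.)
    """

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    expressed: np.ndarray
    bound: float
    gene_median_ct: np.ndarray
    group: np.ndarray
    chip: np.ndarray
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def expressed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expressed, index=self.cell_ids, columns=self.gene_ids)


def pooled_gene_medians(table: CtTable, policy: str = "expressed") -> pd.Series:
    """Per-gene median Ct over the pooled sample (all cells, all chips).

    policy="expressed" (default) takes the median over successfully
    amplified reactions only; policy="floor_at_limit" instead counts failed
    reactions as sitting at the detection limit before taking the median.
    Genes with zero successful reactions get ``nan`` ("all-dropout") and are
    flagged by the caller. Even counts use the midpoint of the central pair
    (numpy's linear interpolation at the 0.5 quantile).
    """
    if policy not in ("expressed", "floor_at_limit"):
        raise ValueError(f"unknown median policy {policy!r}")
    ct = table.ct
    if policy == "floor_at_limit":
        ct = np.where(np.isnan(ct), table.max_cycles, ct)
    with warnings.catch_warnings():
        # nanmedian warns on an all-nan column; the returned nan is the flag
        warnings.filterwarnings("ignore", message="All-NaN slice")
        medians = np.nanmedian(ct, axis=0)
    return pd.Series(medians, index=table.gene_ids, name="median_ct")


def normalize(
    table: CtTable, bound: float = 5.0, median_policy: str = "expressed"
) -> ExpressionMatrix:
    """Convert Ct values to clipped, median-centered log2 expression.

    Expressed entries get ``clip(median_ct - ct, -bound, +bound)``; failed
    entries get exactly ``-bound`` with ``expressed=False``. Genes for which
    every reaction failed cannot be centered and are dropped with a logged
    warning.
    """
    if bound <= 0:
        raise ValueError(f"bound must be positive, got {bound}")
    if table.n_cells == 0 or table.n_genes == 0:
        raise ValueError("empty CtTable")
    medians = pooled_gene_medians(table, policy=median_policy)
    keep = ~np.isnan(medians.to_numpy())
    dropped = [g for g, k in zip(table.gene_ids, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d all-dropout gene(s) with no successful reaction: %s",
            len(dropped),
            ", ".join(dropped),
        )
    gene_ids = [g for g, k in zip(table.gene_ids, keep) if k]
    ct = table.ct[:, keep]
    med = medians.to_numpy()[keep]
    expressed = ~np.isnan(ct)
    values = np.clip(med[np.newaxis, :] - ct, -bound, bound)
    values = np.where(expressed, values, -bound)
    return ExpressionMatrix(
        cell_ids=list(table.cell_ids),
        gene_ids=gene_ids,
        values=values,
        expressed=expressed,
        bound=float(bound),
        gene_median_ct=med,
        group=table.group.copy(),
        chip=table.chip.copy(),
        dropped_genes=dropped,
    )


def _parts(matrix: ExpressionMatrix, by) -> dict[str, np.ndarray]:
    if isinstance(by, dict):
        parts = {str(k): np.asarray(v, dtype=bool) for k, v in by.items()}
        masks = np.stack(list(parts.values())) if parts else np.zeros((0, 0))
        if parts and (masks.sum(axis=0) != 1).any():
            raise ValueError("parts must form a disjoint cover of all cells")
    else:
        labels = np.asarray(by)
        if labels.shape != (matrix.n_cells,):
            raise ValueError("partition labels must have one entry per cell")
        parts = {str(lab): labels == lab for lab in pd.unique(labels)}
    return parts


def expressed_fraction(matrix: ExpressionMatrix, by) -> pd.DataFrame:
    """Per-gene fraction of cells with a successful reaction, per part.

    ``by`` is either a per-cell label array or a dict of boolean masks that
    partition the cells. An empty part yields ``nan`` and a logged warning.
    """
    parts = _parts(matrix, by)
    out = {}
    for name, mask in parts.items():
        if not mask.any():
            logger.warning("empty part %r: expressed fraction undefined", name)
            out[name] = np.full(matrix.n_genes, np.nan)
        else:
            out[name] = matrix.expressed[mask].mean(axis=0)
    return pd.DataFrame(out, index=matrix.gene_ids)


def failed_fraction(matrix: ExpressionMatrix, by) -> pd.DataFrame:
    """Complement of :func:`expressed_fraction`: fraction failing to amplify."""
    return 1.0 - expressed_fraction(matrix, by)
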