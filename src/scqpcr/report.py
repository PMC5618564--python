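"""Pipeline orchestration, figure rendering, and run manifests.

``run_pipeline`` chains the whole analysis — load, normalize, order for
heatmaps, choose k (or use a forced k), cluster, test group and
cluster-vs-rest contrasts, cross-tabulate composition — and writes every
table as CSV plus a JSON run manifest with content digests, so a run is
verifiable and exactly reproducible from its recorded parameters. A
single top-level seed fans out to per-stage seeds through numpy's
SeedSequence, so each stage is independently reproducible.

Heatmaps use the field's qPCR convention: a diverging yellow (high,
+2^B-fold over the pooled median) to blue (low) scale through black,
fixed to [-B, +B] regardless of the data range, with failed reactions in
gray. Gene panels show per-side Gaussian curve summaries with a bar pair
of failed-amplification fractions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap
from pydantic import BaseModel, Field
from scipy import stats

from . import __version__
from .ct_io import CtTable, read_ct_table, write_table
from .diffexp import DiffExpTable, cluster_vs_rest, compare_groups, gaussian_fit
from .preprocess import ExpressionMatrix, failed_fraction, normalize
from .subpop import composition, hierarchical_order, kmeans_partition, select_k

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "render_heatmap",
    "render_gene_panels",
    "verify_manifest",
]

logger = logging.getLogger(__name__)

_CMAP = LinearSegmentedColormap.from_list(
    "ct_blue_black_yellow", ["#1f4fd8", "#000000", "#ffe61a"]
)
_CMAP.set_bad("#9a9a9a")  # non-expressers


class PipelineConfig(BaseModel):
    """All parameters of an end-to-end analysis run."""

    input: str
    out: str
    bound: float = Field(default=5.0, gt=0)  # cycles (= log2 units)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    k: int | None = Field(default=None, ge=1)  # force cluster count
    k_max: int = Field(default=6, ge=1)
    n_restarts: int = Field(default=50, ge=1)
    n_reference: int = Field(default=50, ge=1)
    seed: int = 0
    linkage: str = "average"
    metric: str = "euclidean"
    exact: bool = False
    max_cycles: float = Field(default=40.0, gt=0)
    median_policy: str = "expressed"
    n_panel_genes: int = Field(default=21, ge=0)


@dataclass
class RunManifest:
    """Input digests, parameters, and an inventory of every output file."""

    input_path: str
    input_sha256: str
    parameters: dict
    version: str
    started: str
    finished: str = ""
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Derive per-stage seeds (< 2**31) from one top-level seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _write_diffexp(dx: DiffExpTable, path: Path) -> None:
    write_table(dx.table, path)


def render_heatmap(
    matrix: ExpressionMatrix,
    cell_order,
    gene_order,
    path,
    group_bar=None,
) -> str:
    """Heatmap of ordered log2 expression on the fixed [-B, +B] scale.

    Non-expressed entries are masked out and drawn gray (never the -B
    color); an optional annotation bar along the cell axis shows per-cell
    labels (group or cluster).
    """
    cell_order = np.asarray(cell_order)
    gene_order = np.asarray(gene_order)
    if sorted(cell_order) != list(range(matrix.n_cells)) or sorted(gene_order) != list(
        range(matrix.n_genes)
    ):
        raise ValueError("orders must be permutations of the matrix axes")
    values = matrix.values[np.ix_(cell_order, gene_order)]
    masked = np.ma.masked_where(~matrix.expressed[np.ix_(cell_order, gene_order)], values)
    b = matrix.bound
    fig, (ax_bar, ax) = plt.subplots(
        2,
        1,
        figsize=(max(6.0, matrix.n_genes * 0.18), max(4.0, matrix.n_cells * 0.035) + 0.3),
        gridspec_kw={"height_ratios": [1, 30]},
        constrained_layout=True,
    )
    im = ax.imshow(
        masked.T, cmap=_CMAP, vmin=-b, vmax=b, aspect="auto", interpolation="nearest"
    )
    ax.set_xlabel("cells")
    ax.set_ylabel("genes")
    ax.set_yticks(range(matrix.n_genes))
    ax.set_yticklabels([matrix.gene_ids[i] for i in gene_order], fontsize=4)
    ax.set_xticks([])
    if group_bar is not None:
        labels = np.asarray(group_bar)[cell_order]
        levels = list(dict.fromkeys(labels))
        colors = plt.get_cmap("tab10")
        codes = np.array([levels.index(x) for x in labels])
        ax_bar.imshow(
            codes[None, :],
            cmap=matplotlib.colors.ListedColormap([colors(i) for i in range(len(levels))]),
            aspect="auto",
            interpolation="nearest",
        )
        for i, lev in enumerate(levels):
            ax_bar.plot([], [], color=colors(i), lw=6, label=str(lev))
        ax_bar.legend(loc="center left", bbox_to_anchor=(1.0, 0.5), fontsize=6)
    ax_bar.set_xticks([])
    ax_bar.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.5, label="log2 fold change from median")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def render_gene_panels(
    matrix: ExpressionMatrix,
    mask_a,
    mask_b,
    genes,
    out_dir,
    labels: tuple[str, str] = ("A", "B"),
) -> list[str]:
    """Per-gene comparison panels: two Gaussian curves + failed-fraction bars.

    One file per selected gene. A degenerate fit (n < 2 or zero variance)
    is drawn as a vertical spike with a warning glyph.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    b = matrix.bound
    files = []
    for gene in genes:
        j = matrix.gene_ids.index(gene)
        fig, (ax_bar, ax) = plt.subplots(
            1, 2, figsize=(3.2, 2.2), gridspec_kw={"width_ratios": [1, 6]},
            constrained_layout=True,
        )
        x = np.linspace(-b - 1, b + 1, 256)
        for mask, color, name in ((mask_a, "black", labels[0]), (mask_b, "0.6", labels[1])):
            fit = gaussian_fit(matrix.values[mask, j])
            if fit.degenerate:
                ax.axvline(fit.mu, color=color, lw=2, label=f"{name} (!)")
            else:
                ax.plot(x, stats.norm.pdf(x, fit.mu, fit.sigma), color=color, label=name)
        frac_a = float(1 - matrix.expressed[mask_a, j].mean())
        frac_b = float(1 - matrix.expressed[mask_b, j].mean())
        ax_bar.bar([0, 1], [frac_a, frac_b], color=["black", "0.6"], width=0.8)
        ax_bar.set_ylim(0, 1)
        ax_bar.set_xticks([])
        ax_bar.set_ylabel("failed fraction", fontsize=6)
        ax_bar.tick_params(labelsize=6)
        ax.set_title(gene, fontsize=8)
        ax.set_xlabel("log2 fold change from median", fontsize=6)
        ax.tick_params(labelsize=6)
        ax.legend(fontsize=6)
        fname = out_dir / f"panel_{gene}.png"
        fig.savefig(fname, dpi=150)
        plt.close(fig)
        files.append(str(fname))
    return files


def run_pipeline(config: PipelineConfig, table: CtTable | None = None) -> RunManifest:
    """Run the full analysis and write all artifacts under ``config.out``.

    ``table`` may be supplied directly (e.g. fresh from the simulator);
    otherwise ``config.input`` is read. Returns the manifest, which is also
    written as ``manifest.json``.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    if table is None:
        table = read_ct_table(config.input, max_cycles=config.max_cycles)
    logger.info("loaded %d cells x %d genes", table.n_cells, table.n_genes)

    seeds = _stage_seeds(config.seed)
    matrix = normalize(table, bound=config.bound, median_policy=config.median_policy)
    logger.info(
        "normalized: %d genes retained, %d all-dropout gene(s) dropped",
        matrix.n_genes,
        len(matrix.dropped_genes),
    )

    outputs: list[Path] = []

    def save(frame, name: str) -> None:
        path = out / name
        write_table(frame, path)
        outputs.append(path)

    expr = matrix.to_frame().reset_index(names="cell_id")
    expr.insert(1, "group", matrix.group)
    expr.insert(2, "chip", matrix.chip)
    save(expr, "expression_matrix.csv")
    mask = matrix.expressed_frame().reset_index(names="cell_id")
    save(mask, "expressed_mask.csv")
    save(
        pd.DataFrame({"gene": matrix.gene_ids, "median_ct": matrix.gene_median_ct}),
        "gene_medians.csv",
    )

    # cluster-number selection and partitive clustering
    if config.k is not None:
        k = config.k
        ksel = None
    else:
        ksel = select_k(
            matrix,
            k_max=min(config.k_max, matrix.n_cells),
            n_reference=config.n_reference,
            seed=seeds[0],
        )
        k = ksel.chosen_k
        save(ksel.to_frame(), "k_selection.csv")
    clusters = kmeans_partition(matrix, k=k, seed=seeds[1], n_restarts=config.n_restarts)
    logger.info("clustered %d cells into k=%d (wcss=%.3f)", matrix.n_cells, k, clusters.wcss)
    save(
        pd.DataFrame(
            {
                "cell_id": matrix.cell_ids,
                "group": matrix.group,
                "chip": matrix.chip,
                "cluster": clusters.labels,
            }
        ),
        "clusters.csv",
    )

    comp = composition(clusters, matrix.group)
    comp_frame = comp.counts.copy()
    comp_frame.columns = [f"n_{c}" for c in comp_frame.columns]
    for c in comp.cluster_fractions.columns:
        comp_frame[f"frac_{c}"] = comp.cluster_fractions[c]
    save(comp_frame.reset_index(), "composition.csv")

    # differential expression: group contrast and cluster-vs-rest
    dx_groups = None
    if len(pd.unique(matrix.group)) == 2:
        dx_groups = compare_groups(matrix, alpha=config.alpha, exact=config.exact)
        path = out / "diffexp_groups.csv"
        _write_diffexp(dx_groups, path)
        outputs.append(path)
        logger.info(
            "group contrast: %d/%d genes significant at alpha=%g (Bonferroni m=%d)",
            int(dx_groups.table["significant"].sum()),
            dx_groups.m,
            config.alpha,
            dx_groups.m,
        )
    else:
        logger.warning("group contrast skipped: need exactly 2 groups")

    if k >= 2:
        per_cluster = cluster_vs_rest(matrix, clusters, alpha=config.alpha, exact=config.exact)
        for c, dx in per_cluster.items():
            path = out / f"diffexp_cluster{c}_vs_rest.csv"
            _write_diffexp(dx, path)
            outputs.append(path)

    save(failed_fraction(matrix, matrix.group).reset_index(names="gene"), "failed_fractions.csv")

    # figures
    cell_order = hierarchical_order(matrix, "cells", config.metric, config.linkage)
    gene_order = hierarchical_order(matrix, "genes", config.metric, config.linkage)
    heatmap = out / "heatmap.png"
    render_heatmap(matrix, cell_order, gene_order, heatmap, group_bar=matrix.group)
    outputs.append(heatmap)
    cluster_map = out / "heatmap_clusters.png"
    render_heatmap(
        matrix,
        np.argsort(clusters.labels, kind="stable"),
        gene_order,
        cluster_map,
        group_bar=clusters.labels,
    )
    outputs.append(cluster_map)

    if dx_groups is not None and config.n_panel_genes > 0:
        ranked = dx_groups.table.sort_values(["p_adj", "ks_D"], ascending=[True, False])
        panel_genes = list(ranked["gene"].head(config.n_panel_genes))
        levels = list(pd.unique(matrix.group))
        panels = render_gene_panels(
            matrix,
            matrix.group == levels[0],
            matrix.group == levels[1],
            panel_genes,
            out / "panels",
            labels=(str(levels[0]), str(levels[1])),
        )
        outputs.extend(Path(p) for p in panels)

    manifest = RunManifest(
        input_path=str(config.input),
        input_sha256=_sha256(Path(config.input)) if Path(config.input).is_file() else "",
        parameters=config.model_dump(),
        version=__version__,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
        outputs={str(p.relative_to(out)): _sha256(p) for p in outputs},
    )
    with open(out / "manifest.json", "w") as handle:
        handle.write(manifest.to_json())
    return manifest


def verify_manifest(manifest_path) -> tuple[bool, list[str]]:
    """Re-hash every file a manifest lists; return (ok, mismatches)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as handle:
        data = json.load(handle)
    root = manifest_path.parent
    bad = []
    for rel, digest in data["outputs"].items():
        path = root / rel
        if not path.is_file():
            bad.append(f"missing: {rel}")
        elif _sha256(path) != digest:
            bad.append(f"digest mismatch: {rel}")
    return (not bad, bad)
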