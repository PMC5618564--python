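"""Synthetic single-cell qPCR experiments with known ground truth.

Generates Ct-scale data with the statistical structure the analysis
pipeline assumes: latent subpopulations with per-gene Ct means and
standard deviations, group-biased subpopulation membership, stochastic
detection failure (dropout), and additive per-chip offsets. Generating
on the Ct scale (rather than the expression scale) exercises the whole
preprocessing path, including censoring at the detection limit.

The generative model, per cell: draw a subpopulation from the cell's
group mixing vector; assign a chip round-robin; per gene draw
Ct ~ Normal(subpop mean + chip offset, subpop sd) truncated to
(0, max_cycles]; then with the dropout probability replace the value by
a failed amplification. Dropout is either a fixed per-subpopulation
per-gene probability or a logistic function of the subpopulation mean Ct
(weakly expressed transcripts drop out more often). Everything is
reproducible from a single integer seed.

:func:`fak_study_spec` builds the default two-group keratinocyte
experiment used throughout: a 48-gene mechanotransduction / extracellular
matrix panel, wild-type (WT) and FAK-knockout (KO) groups of 80 cells,
and three subpopulations — a WT-dominant FAK-signaling profile, a
KO-dominant profile, and a KO-enriched "activated" minority profile
overexpressing collagen and MMP transcripts by 4 cycles (16-fold).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats

from .ct_io import CtTable

__all__ = [
    "Subpopulation",
    "GroupSpec",
    "LogisticDropout",
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "fak_study_spec",
    "null_spec",
    "spec_from_toml",
    "spec_to_toml",
    "KERATINOCYTE_PANEL",
    "MATRIX_REMODELING_BLOCK",
]

#: 48-gene keratinocyte mechanotransduction / ECM qPCR panel (one chip).
KERATINOCYTE_PANEL: tuple[str, ...] = (
    "Ptk2", "Pxn", "Src", "Bcar1", "Akt1", "Mapk1", "Mapk3", "Ilk",
    "Itga3", "Itga6", "Itga8", "Itgav", "Itgb1", "Itgb4", "Itgb6", "Itgb8",
    "Col1a1", "Col1a2", "Col3a1", "Col4a1", "Col4a2", "Col5a1", "Col7a1", "Col17a1",
    "Mmp2", "Mmp3", "Mmp9", "Mmp13", "Mmp14", "Timp1", "Timp2", "Timp3",
    "Krt1", "Krt5", "Krt6a", "Krt10", "Krt14", "Krt16", "Cd44", "Ccnd1",
    "Fn1", "Tnc", "Sparc", "Spp1", "Lamb1", "Tgfb1", "Tgfbr2", "Mycn",
)

#: Collagen/MMP block overexpressed by the activated minority subpopulation.
MATRIX_REMODELING_BLOCK: tuple[str, ...] = (
    "Col1a1", "Col1a2", "Col3a1", "Col4a1", "Mmp2", "Mmp9", "Mmp13", "Mmp14",
)

_FAK_BLOCK: tuple[str, ...] = (
    "Ptk2", "Pxn", "Src", "Itga6", "Mapk1", "Mapk3", "Timp1", "Timp2",
)

_KO_BLOCK: tuple[str, ...] = (
    "Ilk", "Itga8", "Itgb6", "Cd44", "Ccnd1", "Krt6a", "Krt16", "Spp1",
)


class LogisticDropout(BaseModel):
    """Dropout probability as a logistic function of the subpop mean Ct.

    p(mean_ct) = floor + (1 - floor) / (1 + exp(-slope * (mean_ct - midpoint)))
    """

    slope: float = Field(gt=0)
    midpoint: float  # cycles
    floor: float = Field(default=0.0, ge=0, le=1)

    def probability(self, mean_ct: np.ndarray) -> np.ndarray:
        core = 1.0 / (1.0 + np.exp(-self.slope * (np.asarray(mean_ct) - self.midpoint)))
        return self.floor + (1.0 - self.floor) * core


class Subpopulation(BaseModel):
    """One latent subpopulation: per-gene Ct mean, sd, and dropout."""

    name: str
    mean_ct: list[float]
    sd_ct: list[float]
    dropout: list[float]

    @field_validator("sd_ct")
    @classmethod
    def _sd_nonnegative(cls, v):
        if any(s < 0 for s in v):
            raise ValueError("sd_ct entries must be >= 0")
        return v

    @field_validator("dropout")
    @classmethod
    def _dropout_in_unit(cls, v):
        if any(not 0 <= p <= 1 for p in v):
            raise ValueError("dropout probabilities must lie in [0, 1]")
        return v


class GroupSpec(BaseModel):
    """A biological group: its size and mixing over subpopulations."""

    name: str
    n_cells: int = Field(ge=0)
    mixing: list[float]

    @field_validator("mixing")
    @classmethod
    def _mixing_simplex(cls, v):
        if any(p < 0 for p in v):
            raise ValueError("mixing probabilities must be >= 0")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"mixing must sum to 1, got {sum(v)}")
        return v


class SyntheticSpec(BaseModel):
    """Full generative description of a simulated qPCR experiment."""

    gene_ids: list[str]
    subpops: list[Subpopulation]
    groups: list[GroupSpec]
    logistic_dropout: LogisticDropout | None = None
    chip_sd: float = Field(default=0.0, ge=0)  # cycles
    n_chips: int = Field(default=1, ge=1)
    max_cycles: float = Field(default=40.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _consistent(self):
        g = len(self.gene_ids)
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids contains duplicates")
        for sp in self.subpops:
            for fname in ("mean_ct", "sd_ct", "dropout"):
                if len(getattr(sp, fname)) != g:
                    raise ValueError(
                        f"subpop {sp.name!r}: {fname} has "
                        f"{len(getattr(sp, fname))} entries, expected {g}"
                    )
        for grp in self.groups:
            if len(grp.mixing) != len(self.subpops):
                raise ValueError(
                    f"group {grp.name!r}: mixing has {len(grp.mixing)} entries, "
                    f"expected {len(self.subpops)}"
                )
        return self


@dataclass
class GroundTruth:
    """Latent state realized by :func:`generate`, aligned with its CtTable."""

    subpop_labels: np.ndarray  # per-cell subpopulation name
    subpop_index: np.ndarray  # per-cell 0-based subpopulation index
    mean_ct: np.ndarray  # subpops x genes true means (cycles)
    chip_offsets: dict[str, float]  # realized additive offset per chip (cycles)


def _truncnorm_draw(
    rng: np.random.Generator,
    loc: np.ndarray,
    scale: np.ndarray,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Normal draws truncated to (lo, hi]; degenerate where scale == 0."""
    out = np.array(loc, dtype=float, copy=True)
    pos = scale > 0
    if np.any(pos):
        a = (lo - loc[pos]) / scale[pos]
        b = (hi - loc[pos]) / scale[pos]
        out[pos] = stats.truncnorm.rvs(
            a, b, loc=loc[pos], scale=scale[pos], random_state=rng
        )
    return out


def generate(spec: SyntheticSpec) -> tuple[CtTable, GroundTruth]:
    """Simulate a CtTable (and its latent ground truth) from a spec."""
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_ids)
    g = len(genes)
    mean = np.array([sp.mean_ct for sp in spec.subpops])
    sd = np.array([sp.sd_ct for sp in spec.subpops])
    if spec.logistic_dropout is not None:
        drop = spec.logistic_dropout.probability(mean)
    else:
        drop = np.array([sp.dropout for sp in spec.subpops])

    cell_ids: list[str] = []
    group_labels: list[str] = []
    sub_idx: list[int] = []
    for grp in spec.groups:
        draws = rng.choice(len(spec.subpops), size=grp.n_cells, p=grp.mixing)
        sub_idx.extend(int(d) for d in draws)
        group_labels.extend([grp.name] * grp.n_cells)
        cell_ids.extend(f"{grp.name}_{i + 1:03d}" for i in range(grp.n_cells))
    n = len(cell_ids)
    sub_idx_arr = np.array(sub_idx, dtype=int)

    chip_names = [f"chip{c + 1}" for c in range(spec.n_chips)]
    offsets = rng.normal(0.0, spec.chip_sd, size=spec.n_chips) if spec.chip_sd > 0 else np.zeros(spec.n_chips)
    chip_of_cell = np.arange(n) % spec.n_chips

    loc = mean[sub_idx_arr] + offsets[chip_of_cell][:, None]
    scale = np.broadcast_to(sd[sub_idx_arr], (n, g))
    ct = _truncnorm_draw(rng, loc, scale, 0.0, spec.max_cycles)
    failed = rng.random((n, g)) < drop[sub_idx_arr]
    ct = np.where(failed, np.nan, ct)

    table = CtTable(
        cell_ids=cell_ids,
        gene_ids=genes,
        ct=ct,
        group=np.array(group_labels, dtype=object),
        chip=np.array([chip_names[c] for c in chip_of_cell], dtype=object),
        max_cycles=spec.max_cycles,
    )
    truth = GroundTruth(
        subpop_labels=np.array([spec.subpops[i].name for i in sub_idx_arr], dtype=object),
        subpop_index=sub_idx_arr,
        mean_ct=mean,
        chip_offsets=dict(zip(chip_names, offsets.tolist())),
    )
    return table, truth


def _block_means(baseline: float, shift: float, block: tuple[str, ...],
                 genes: tuple[str, ...], extra: dict[str, float] | None = None) -> list[float]:
    means = {g: baseline for g in genes}
    for g in block:
        means[g] = baseline - shift  # lower Ct = overexpressed
    if extra:
        means.update(extra)
    return [means[g] for g in genes]


def fak_study_spec(
    seed: int = 0,
    n_wt: int = 80,
    n_ko: int = 80,
    baseline_ct: float = 24.0,
    marker_shift: float = 4.0,
    sd_ct: float = 0.5,
    dropout: float = 0.15,
    dropout_slope: float = 0.4,
    chip_sd: float = 0.0,
    n_chips: int = 2,
) -> SyntheticSpec:
    """Default two-group keratinocyte experiment with three subpopulations.

    WT cells mix over subpopulations as (0.70, 0.20, 0.10) and KO cells as
    (0.15, 0.45, 0.40), so the minority "activated" subpopulation is about
    80% KO. Each subpopulation overexpresses its own 8-gene marker block by
    ``marker_shift`` cycles (4 cycles = 16-fold): a FAK-signaling block for
    the WT-dominant subpopulation, an ILK/adhesion block for the
    KO-dominant one, and the collagen/MMP matrix-remodeling block for the
    activated minority. FAK (Ptk2) itself is weakly detected outside the
    WT-dominant subpopulation.

    Dropout is expression-dependent: a logistic function of the
    subpopulation mean Ct with slope ``dropout_slope`` per cycle, anchored
    so the failure probability at ``baseline_ct`` equals ``dropout``
    (weakly expressed transcripts fail more often, abundant ones rarely).
    Set ``dropout_slope=0`` for a flat per-gene rate instead.
    """
    genes = KERATINOCYTE_PANEL
    fak_weak = {"Ptk2": 30.0}
    base_drop = [dropout] * len(genes)
    link = None
    if dropout_slope > 0 and 0 < dropout < 1:
        midpoint = baseline_ct + np.log((1 - dropout) / dropout) / dropout_slope
        link = LogisticDropout(slope=dropout_slope, midpoint=midpoint)
    subpops = [
        Subpopulation(
            name="fak_signaling",
            mean_ct=_block_means(baseline_ct, marker_shift, _FAK_BLOCK, genes),
            sd_ct=[sd_ct] * len(genes),
            dropout=base_drop,
        ),
        Subpopulation(
            name="ko_adhesion",
            mean_ct=_block_means(baseline_ct, marker_shift, _KO_BLOCK, genes, fak_weak),
            sd_ct=[sd_ct] * len(genes),
            dropout=base_drop,
        ),
        Subpopulation(
            name="activated_matrix",
            mean_ct=_block_means(
                baseline_ct, marker_shift, MATRIX_REMODELING_BLOCK, genes, fak_weak
            ),
            sd_ct=[sd_ct] * len(genes),
            dropout=base_drop,
        ),
    ]
    return SyntheticSpec(
        gene_ids=list(genes),
        subpops=subpops,
        groups=[
            GroupSpec(name="WT", n_cells=n_wt, mixing=[0.70, 0.20, 0.10]),
            GroupSpec(name="KO", n_cells=n_ko, mixing=[0.15, 0.45, 0.40]),
        ],
        logistic_dropout=link,
        chip_sd=chip_sd,
        n_chips=n_chips,
        seed=seed,
    )


def null_spec(
    seed: int = 0,
    n_genes: int = 96,
    n_per_group: int = 100,
    baseline_ct: float = 24.0,
    sd_ct: float = 0.5,
    dropout: float = 0.15,
    shifted_genes: dict[str, float] | None = None,
) -> SyntheticSpec:
    """Two groups drawn from one identical generator (no subpop structure).

    Used for type-I-error and power simulations: under the default there is
    no difference between groups; ``shifted_genes`` plants a per-gene Ct
    shift (cycles) in the second group only, implemented as a second
    subpopulation that only the second group uses.
    """
    genes = [f"g{i + 1:02d}" for i in range(n_genes)]
    base = Subpopulation(
        name="null",
        mean_ct=[baseline_ct] * n_genes,
        sd_ct=[sd_ct] * n_genes,
        dropout=[dropout] * n_genes,
    )
    subpops = [base]
    mix_a, mix_b = [1.0], [1.0]
    if shifted_genes:
        unknown = set(shifted_genes) - set(genes)
        if unknown:
            raise ValueError(f"unknown shifted genes: {sorted(unknown)}")
        shifted = Subpopulation(
            name="shifted",
            mean_ct=[baseline_ct - shifted_genes.get(g, 0.0) for g in genes],
            sd_ct=[sd_ct] * n_genes,
            dropout=[dropout] * n_genes,
        )
        subpops = [base, shifted]
        mix_a, mix_b = [1.0, 0.0], [0.0, 1.0]
    return SyntheticSpec(
        gene_ids=genes,
        subpops=subpops,
        groups=[
            GroupSpec(name="A", n_cells=n_per_group, mixing=mix_a),
            GroupSpec(name="B", n_cells=n_per_group, mixing=mix_b),
        ],
        seed=seed,
    )


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, list):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def spec_to_toml(spec: SyntheticSpec, path) -> str:
    """Serialize a SyntheticSpec as a TOML config readable by the CLI."""
    dump = spec.model_dump()
    lines: list[str] = []
    for key in ("gene_ids", "chip_sd", "n_chips", "max_cycles", "seed"):
        lines.append(f"{key} = {_toml_scalar(dump[key])}")
    if dump["logistic_dropout"] is not None:
        lines.append("\n[logistic_dropout]")
        for k, v in dump["logistic_dropout"].items():
            lines.append(f"{k} = {_toml_scalar(v)}")
    for section, items in (("groups", dump["groups"]), ("subpops", dump["subpops"])):
        for item in items:
            lines.append(f"\n[[{section}]]")
            for k, v in item.items():
                lines.append(f"{k} = {_toml_scalar(v)}")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")
    return str(path)


def spec_from_toml(path) -> SyntheticSpec:
    """Load a SyntheticSpec from a TOML config."""
    with open(path, "rb") as handle:
        data = tomllib.load(handle)
    return SyntheticSpec.model_validate(data)
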