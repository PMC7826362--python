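"""Expression data model, I/O, filtering and highly-variable-gene selection.

Matrices are FPKM gene-by-cell pandas DataFrames (gene ids on the index,
cell ids on the columns); annotations are tables keyed by cell_id with
embryo, stage (E3.5/E4.5), genotype (WT/HET/MUT) and lineage (EPI/PrE/TE/
ICM) columns. Variable genes are selected from the mean-CV² relationship:
a locally weighted trend of logCV² on average log2 expression, with
thresholds on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "HVGParams",
    "HVGResult",
    "read_expression",
    "write_expression",
    "filter_expressed",
    "log2_transform",
    "select_hvg",
]

ANNOTATION_COLS = ["cell_id", "embryo_id", "stage", "genotype", "lineage"]


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate cell ids: {dupes[:5]}")
    vals = matrix.to_numpy()
    if not np.isfinite(vals).all():
        gi, ci = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite FPKM at gene {matrix.index[gi]!r}, cell {matrix.columns[ci]!r}"
        )
    if (vals < 0).any():
        gi, ci = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative FPKM at gene {matrix.index[gi]!r}, cell {matrix.columns[ci]!r}"
        )


def read_expression(
    path, annotation_path=None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read an FPKM TSV (genes in rows, first column gene id) and optionally
    a cell-annotation CSV; validate ids and values.

    The annotation's cell_id set must match the matrix columns exactly;
    mismatches are reported with the offending ids.
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index.name = "gene_id"
    _validate_matrix(matrix)
    annotation = None
    if annotation_path is not None:
        annotation = pd.read_csv(annotation_path)
        if "cell_id" not in annotation.columns:
            raise ValueError("annotation must have a cell_id column")
        mat_cells = set(matrix.columns)
        ann_cells = set(annotation["cell_id"])
        if mat_cells != ann_cells:
            missing = sorted(mat_cells - ann_cells)
            extra = sorted(ann_cells - mat_cells)
            raise ValueError(
                f"annotation/matrix cell mismatch: missing from annotation "
                f"{missing[:5]}, unknown in annotation {extra[:5]}"
            )
    return matrix, annotation


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def filter_expressed(
    matrix: pd.DataFrame, groups: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Keep genes with FPKM > 0 in at least one condition.

    ``groups`` partitions cells into conditions; a gene is kept when its
    maximum FPKM within at least one group is positive. With exhaustive
    groups (or none given) this reduces to max over all cells > 0. Gene
    order is preserved; the operation is idempotent.
    """
    if groups is None:
        keep = (matrix.to_numpy() > 0).any(axis=1)
        return matrix.loc[keep]
    covered: set[str] = set()
    keep = np.zeros(len(matrix), dtype=bool)
    for name, cells in groups.items():
        if len(cells) == 0:
            raise ValueError(f"group {name!r} is empty")
        covered.update(cells)
        keep |= (matrix[list(cells)].to_numpy() > 0).any(axis=1)
    uncovered = set(matrix.columns) - covered
    if uncovered:
        raise ValueError(f"groups do not cover cells: {sorted(uncovered)[:5]}")
    return matrix.loc[keep]


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(FPKM + pseudocount); pseudocount must be positive."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2(matrix + pseudocount)


@dataclass
class HVGParams:
    """Thresholds and trend settings for variable-gene selection.

    ``min_mean`` bounds the average log2(FPKM+1); ``min_logcv2`` bounds
    log10 of the squared coefficient of variation of raw FPKM. With
    ``require_above_trend`` the gene must additionally sit above the fitted
    mean-CV² trend; switching it off reproduces the pure two-threshold rule.
    """

    min_mean: float = 0.5
    min_logcv2: float = 0.5
    trend_span: float = 0.3
    require_above_trend: bool = True
    log_base: float = 10.0


@dataclass
class HVGResult:
    table: pd.DataFrame  # per gene: mean_log2, logcv2, trend_value, residual, selected
    params: HVGParams

    @property
    def selected_genes(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()


def select_hvg(matrix: pd.DataFrame, params: HVGParams | None = None) -> HVGResult:
    """Select highly variable genes from the mean-CV² relationship.

    Per gene: mean_log2 = average log2(FPKM+1); CV² = var/mean² of raw FPKM
    across cells; logcv2 = log10(CV²) (base configurable). A lowess trend of
    logcv2 on mean_log2 is fitted; selection requires mean_log2 > min_mean,
    logcv2 > min_logcv2 and (by default) a positive residual above the trend.
    Deterministic and invariant to gene/cell relabeling.
    """
    params = params or HVGParams()
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    vals = matrix.to_numpy(dtype=float)
    mean_log2 = np.log2(vals + 1.0).mean(axis=1)
    mu = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, np.nan)
        logcv2 = np.where(cv2 > 0, np.log(cv2) / np.log(params.log_base), -np.inf)

    if (mu > 0).sum() < 10:
        raise ValueError("fewer than 10 genes with positive mean: trend unfittable")
    fit_mask = np.isfinite(logcv2) & (mu > 0)
    if fit_mask.sum() >= 2:
        # lowess returns fits at the sorted x; interpolate back to every gene
        fitted = lowess(
            logcv2[fit_mask], mean_log2[fit_mask],
            frac=params.trend_span, return_sorted=True,
        )
        trend = np.interp(mean_log2, fitted[:, 0], fitted[:, 1])
    else:
        # zero-variance degenerate input: no trend, nothing selectable
        trend = np.full(len(mu), np.nan)
    residual = np.where(
        np.isfinite(logcv2) & np.isfinite(trend), logcv2 - trend, -np.inf
    )

    selected = (mean_log2 > params.min_mean) & (logcv2 > params.min_logcv2)
    if params.require_above_trend:
        selected &= residual > 0

    table = pd.DataFrame(
        {
            "mean_log2": mean_log2,
            "logcv2": logcv2,
            "trend_value": trend,
            "residual": residual,
            "selected": selected,
        },
        index=matrix.index,
    )
    return HVGResult(table=table, params=params)
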