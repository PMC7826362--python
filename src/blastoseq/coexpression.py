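"""Weighted coexpression network modules and eigengenes.

The network is unsigned: adjacency a_ij = |Pearson cor|^beta with a soft
threshold beta (default 10). Genes are clustered on the topological-overlap
dissimilarity with average-linkage agglomeration, cut statically at a fixed
height (default 0.35); clusters smaller than the minimum module size
(default 30) are dissolved to unassigned. Each module is summarized by its
eigengene — the first principal component of the module's standardized
expression, sign-oriented to correlate positively with the module's mean
profile and scaled to unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

__all__ = [
    "CoexpressionParams",
    "ModuleAssignment",
    "adjacency_matrix",
    "topological_overlap_dissimilarity",
    "detect_modules",
    "module_eigengenes",
    "hierarchical_cluster",
]


@dataclass
class CoexpressionParams:
    power: float = 10.0  # soft-threshold exponent beta
    cut_height: float = 0.35  # static dendrogram cut on the TOM dissimilarity
    min_module_size: int = 30

    def validate(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0 < self.cut_height < 1:
            raise ValueError("cut_height must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class ModuleAssignment:
    """Gene-to-module map; module id 0 means unassigned."""

    labels: pd.Series  # gene -> module id (int)

    @property
    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, mod in self.labels.items():
            if mod != 0:
                out.setdefault(int(mod), []).append(gene)
        return out

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def adjacency_matrix(
    log_expression: pd.DataFrame, params: CoexpressionParams | None = None
) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor(g_i, g_j)|^beta (diagonal 1)."""
    params = params or CoexpressionParams()
    params.validate()
    if log_expression.shape[0] < 2 or log_expression.shape[1] < 3:
        raise ValueError("need >= 2 genes and >= 3 cells")
    vals = log_expression.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = log_expression.index[sd == 0].tolist()
        raise ValueError(f"zero-variance genes: {bad[:5]}")
    cor = np.corrcoef(vals)
    adj = np.abs(np.clip(cor, -1.0, 1.0)) ** params.power
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=log_expression.index, columns=log_expression.index)


def topological_overlap_dissimilarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """1 - TOM of an adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    connectivities k = row sums excluding the diagonal; the shared-neighbor
    sum likewise excludes i and j themselves. Diagonal dissimilarity is 0.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=1)
    shared = off @ off  # u = i and u = j terms vanish since the diagonal is zero
    num = shared + off
    denom = np.minimum.outer(k, k) + 1.0 - off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    dis = 1.0 - np.clip(tom, 0.0, 1.0)
    dis = (dis + dis.T) / 2.0
    np.fill_diagonal(dis, 0.0)
    return pd.DataFrame(dis, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    dissimilarity: pd.DataFrame, params: CoexpressionParams | None = None
) -> ModuleAssignment:
    """Average-linkage clustering of the TOM dissimilarity with a static cut.

    Clusters below ``min_module_size`` are dissolved to unassigned (id 0);
    surviving modules are renumbered 1, 2, ... by decreasing size (ties by
    first gene position, so the partition is deterministic).
    """
    params = params or CoexpressionParams()
    params.validate()
    d = dissimilarity.to_numpy(dtype=float)
    link = sch.linkage(squareform(d, checks=False), method="average")
    raw = sch.fcluster(link, t=params.cut_height, criterion="distance")

    sizes: dict[int, int] = {}
    first: dict[int, int] = {}
    for pos, c in enumerate(raw):
        sizes[c] = sizes.get(c, 0) + 1
        first.setdefault(c, pos)
    kept = [c for c, s in sizes.items() if s >= params.min_module_size]
    kept.sort(key=lambda c: (-sizes[c], first[c]))
    remap = {c: i + 1 for i, c in enumerate(kept)}
    labels = pd.Series(
        [remap.get(c, 0) for c in raw], index=dissimilarity.index, name="module"
    )
    return ModuleAssignment(labels=labels)


def module_eigengenes(
    log_expression: pd.DataFrame, modules: ModuleAssignment
) -> pd.DataFrame:
    """First-PC eigengene per module (rows modules, columns cells).

    Genes are z-scored across cells; the first right singular vector gives
    the eigengene, scaled to unit variance and sign-flipped when negatively
    correlated with the module's mean standardized profile.
    """
    mods = modules.modules
    if not mods:
        raise ValueError("no modules to summarize")
    rows = {}
    for mod_id in sorted(mods):
        sub = log_expression.loc[mods[mod_id]].to_numpy(dtype=float)
        sd = sub.std(axis=1)
        if (sd == 0).any():
            bad = [g for g, s in zip(mods[mod_id], sd) if s == 0]
            raise ValueError(f"module {mod_id} has zero-variance genes: {bad[:5]}")
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        # first right singular vector = first-PC score over cells
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        eig = (eig - eig.mean()) / eig.std()
        if np.corrcoef(eig, z.mean(axis=0))[0, 1] < 0:
            eig = -eig
        rows[f"ME{mod_id}"] = eig
    return pd.DataFrame(rows, index=log_expression.columns).T


def hierarchical_cluster(
    observations: pd.DataFrame,
    linkage: str = "average",
    n_clusters: int | None = None,
    cut_height: float | None = None,
) -> tuple[np.ndarray, pd.Series | None]:
    """Agglomerative clustering of observation rows (Euclidean metric).

    ``linkage`` is "average" or "ward.D2" (squared-distance Ward update, the
    convention where input Euclidean distances are squared inside the
    Lance-Williams recurrence). Returns the scipy linkage matrix and, when a
    cut is requested, the cluster labels.
    """
    vals = observations.to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError("need >= 2 observations")
    if not np.isfinite(vals).all():
        raise ValueError("NaN/inf in input")
    method = {"average": "average", "ward.D2": "ward"}.get(linkage)
    if method is None:
        raise ValueError(f"unsupported linkage {linkage!r}")
    link = sch.linkage(vals, method=method, metric="euclidean")
    labels = None
    if n_clusters is not None:
        labels = pd.Series(
            sch.fcluster(link, t=n_clusters, criterion="maxclust"),
            index=observations.index,
        )
    elif cut_height is not None:
        labels = pd.Series(
            sch.fcluster(link, t=cut_height, criterion="distance"),
            index=observations.index,
        )
    return link, labels
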