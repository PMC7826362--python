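"""Low-dimensional embeddings, pseudotime and trend curves.

PCA and diffusion maps embed cells from log2 expression; pseudotime is the
diffusion distance from an explicit root cell, min-max scaled to [0, 1].
Trajectory lines in embedding space are cubic smoothing splines (roughness
penalty lambda, default 0.01) against pseudotime, and per-gene expression
trends over pseudotime use locally weighted quadratic regression (tricube
weights, default span 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "EmbeddingParams",
    "DiffusionEmbedding",
    "PseudotimeResult",
    "CurveFit",
    "pca_embed",
    "diffusion_map",
    "pseudotime",
    "fit_trajectory_curve",
    "fit_gene_trend",
]


@dataclass
class EmbeddingParams:
    """Diffusion-map settings.

    ``kernel_sigma`` is the Gaussian kernel width; None means the median
    pairwise-distance heuristic. Density normalization divides the kernel by
    the product of row and column sums before the Markov normalization,
    removing sampling-density effects.
    """

    n_components: int = 3
    kernel_sigma: float | None = None
    density_normalize: bool = True


@dataclass
class DiffusionEmbedding:
    coordinates: pd.DataFrame  # cells x DC1..DCk, eigenvalue-scaled
    eigenvalues: np.ndarray  # descending, trivial eigenpair removed


@dataclass
class PseudotimeResult:
    values: pd.Series  # cell -> pseudotime in [0, 1]
    root: str


@dataclass
class CurveFit:
    kind: str  # "cubic_smoothing_spline" | "loess"
    smoothing: float  # lambda or span
    x: np.ndarray  # observed abscissae (sorted, deduplicated)
    fitted: np.ndarray  # fitted values at x (columns per output dim)
    grid_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    grid_fitted: np.ndarray = field(default_factory=lambda: np.empty(0))
    predict: object = None  # callable on new abscissae


def pca_embed(
    log_expression: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (unscaled) PCA of cells over a gene subset.

    Returns per-cell scores (PC1..PCk) and explained-variance fractions.
    Component signs follow a deterministic convention: the largest-magnitude
    gene loading of each component is positive.
    """
    x = log_expression.to_numpy(dtype=float).T  # cells x genes
    n_cells, n_genes = x.shape
    if n_components > min(n_cells, n_genes):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, cells)="
            f"{min(n_cells, n_genes)}"
        )
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for k in range(n_components):
        if vt[k, np.argmax(np.abs(vt[k]))] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u[:, :n_components] * s[:n_components]
    total_var = (s**2).sum()
    evf = s[:n_components] ** 2 / total_var if total_var > 0 else np.zeros(n_components)
    frame = pd.DataFrame(
        scores,
        index=log_expression.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return frame, evf


def _deterministic_sign(vec: np.ndarray) -> float:
    return 1.0 if vec[np.argmax(np.abs(vec))] >= 0 else -1.0


def diffusion_map(
    log_expression: pd.DataFrame,
    params: EmbeddingParams | None = None,
    distances: np.ndarray | None = None,
) -> DiffusionEmbedding:
    """Diffusion-map embedding of cells.

    A Gaussian kernel on Euclidean distances (optionally density-normalized)
    is row-normalized into a Markov transition matrix; the right
    eigenvectors 2..(n_components+1), scaled by their eigenvalues, form the
    embedding. Signs follow the largest-magnitude-entry convention so the
    result is deterministic.
    """
    params = params or EmbeddingParams()
    cells = list(log_expression.columns)
    if distances is None:
        d = squareform(pdist(log_expression.to_numpy(dtype=float).T))
    else:
        d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need >= 3 cells")

    sigma = params.kernel_sigma
    if sigma is None:
        off = d[np.triu_indices(n, 1)]
        sigma = float(np.median(off[off > 0])) if (off > 0).any() else 1.0
    if sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    with np.errstate(over="ignore", under="ignore", divide="ignore", invalid="ignore"):
        k = np.exp(-(d**2) / (2.0 * sigma**2))
    if not np.isfinite(k).all() or k.sum() == 0 or (k.sum(axis=1) == 0).any():
        raise ValueError("kernel numerically zero: increase kernel_sigma")

    if params.density_normalize:
        q = k.sum(axis=1)
        k = k / np.outer(q, q)

    row = k.sum(axis=1)
    # symmetric conjugate of the row-stochastic operator shares its spectrum
    s = k / np.sqrt(np.outer(row, row))
    evals, evecs = np.linalg.eigh((s + s.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(row)[:, None]  # right eigenvectors of the Markov matrix

    n_comp = min(params.n_components, n - 1)
    coords = np.empty((n, n_comp))
    kept = np.empty(n_comp)
    for j in range(n_comp):
        v = psi[:, j + 1]
        v = v / np.linalg.norm(v) * _deterministic_sign(v)
        coords[:, j] = evals[j + 1] * v
        kept[j] = evals[j + 1]
    frame = pd.DataFrame(
        coords, index=cells, columns=[f"DC{j + 1}" for j in range(n_comp)]
    )
    return DiffusionEmbedding(coordinates=frame, eigenvalues=kept)


def pseudotime(embedding: DiffusionEmbedding, root: str) -> PseudotimeResult:
    """Diffusion distance from the root cell, min-max scaled to [0, 1]."""
    coords = embedding.coordinates
    if root not in coords.index:
        raise KeyError(f"unknown root cell {root!r}")
    delta = coords.to_numpy() - coords.loc[root].to_numpy()
    dist = np.sqrt((delta**2).sum(axis=1))
    rng = dist.max() - dist.min()
    if rng == 0:
        raise ValueError("all cells equidistant from root: pseudotime undefined")
    vals = (dist - dist.min()) / rng
    return PseudotimeResult(values=pd.Series(vals, index=coords.index), root=root)


def _collapse_duplicates(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    ux, inv = np.unique(xs, return_inverse=True)
    out = np.zeros((len(ux), ys.shape[1] if ys.ndim > 1 else 1))
    counts = np.zeros(len(ux))
    np.add.at(out, inv, ys.reshape(len(ys), -1))
    np.add.at(counts, inv, 1.0)
    return ux, out / counts[:, None]


def fit_trajectory_curve(
    points: pd.DataFrame | np.ndarray,
    pseudotimes: np.ndarray,
    lam: float = 0.01,
) -> CurveFit:
    """Cubic smoothing spline of embedding coordinates against pseudotime.

    One spline per output coordinate, with a second-derivative roughness
    penalty weighted by ``lam``; duplicate abscissae are collapsed by
    averaging. As lam grows the fit tends to the least-squares line.
    """
    y = np.asarray(points, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(pseudotimes, dtype=float)
    ux, uy = _collapse_duplicates(x, y)
    if len(ux) < 5:
        raise ValueError("need >= 5 distinct abscissae for a cubic smoothing spline")
    splines = [make_smoothing_spline(ux, uy[:, j], lam=lam) for j in range(uy.shape[1])]
    fitted = np.column_stack([sp(ux) for sp in splines])
    grid = np.linspace(ux.min(), ux.max(), 100)
    grid_fitted = np.column_stack([sp(grid) for sp in splines])

    def predict(new_x):
        return np.column_stack([sp(np.asarray(new_x, dtype=float)) for sp in splines])

    return CurveFit(
        kind="cubic_smoothing_spline", smoothing=lam,
        x=ux, fitted=fitted, grid_x=grid, grid_fitted=grid_fitted, predict=predict,
    )


def _loess_quadratic(
    x: np.ndarray, y: np.ndarray, span: float, eval_x: np.ndarray
) -> np.ndarray:
    """Locally weighted quadratic regression with tricube weights."""
    n = len(x)
    window = max(int(np.ceil(span * n)), 1)
    out = np.empty(len(eval_x))
    for i, x0 in enumerate(eval_x):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:window]
        if len(idx) < 3:
            raise ValueError(
                "loess window has < 3 points: increase span or sample size"
            )
        h = d[idx].max()
        w = (1 - np.clip(d[idx] / h if h > 0 else 0.0, 0, 1) ** 3) ** 3
        if h == 0:
            w = np.ones(len(idx))
        xw = x[idx] - x0
        basis = np.column_stack([np.ones(len(idx)), xw, xw**2])
        wsq = np.sqrt(np.maximum(w, 1e-12))
        beta, *_ = np.linalg.lstsq(basis * wsq[:, None], y[idx] * wsq, rcond=None)
        out[i] = beta[0]
    return out


def fit_gene_trend(
    pt: pd.Series | np.ndarray,
    expression: pd.Series | np.ndarray,
    span: float = 0.5,
) -> CurveFit:
    """Loess trend of one gene's log2 expression over pseudotime.

    Locally weighted quadratic regression (tricube weights); evaluated at
    the observed pseudotimes and on a 100-point grid.
    """
    x = np.asarray(pt, dtype=float)
    y = np.asarray(expression, dtype=float)
    if len(x) < 5:
        raise ValueError("need >= 5 cells")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted = _loess_quadratic(xs, ys, span, xs)
    grid = np.linspace(xs.min(), xs.max(), 100)
    grid_fitted = _loess_quadratic(xs, ys, span, grid)

    def predict(new_x):
        return _loess_quadratic(xs, ys, span, np.asarray(new_x, dtype=float))

    return CurveFit(
        kind="loess", smoothing=span,
        x=xs, fitted=fitted, grid_x=grid, grid_fitted=grid_fitted.reshape(-1),
        predict=predict,
    )
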