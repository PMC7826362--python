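"""Quantitative-immunofluorescence spatial stage.

From a table of segmented nuclei (centroids, volumes, channel intensities)
the stage builds an in-silico embryo surface — the triangulated convex-hull
boundary of the 3-D Delaunay complex of all nuclear centroids — computes the
distance of every centroid to every surface triangle, and classifies nuclei
as inside (ICM: larger minimum distance, lower variance of distances) or
outside (TE) by 2-means clustering of the two features. Normalized channel
intensities can then be compared between genotypes with the nonparametric
Kruskal-Wallis test.

All processing is per embryo: surfaces and classifications never mix nuclei
across embryos.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.spatial
import scipy.stats

__all__ = [
    "DegenerateGeometryError",
    "EmbryoSurface",
    "SpatialFeatures",
    "LineageCall",
    "build_surface",
    "point_triangle_distance",
    "compute_spatial_features",
    "classify_inside_outside",
    "normalize_intensities",
    "kruskal_wallis",
]

COORD_COLS = ["x", "y", "z"]


class DegenerateGeometryError(ValueError):
    """Raised when centroids are too degenerate to triangulate."""


@dataclass
class EmbryoSurface:
    """Triangulated closed surface: hull vertices and triangle index triples."""

    vertices: np.ndarray  # (V, 3)
    triangles: np.ndarray  # (F, 3) indices into vertices

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_counts(self) -> dict[tuple[int, int], int]:
        """How many triangles share each undirected edge (2 ⇔ watertight)."""
        counts: dict[tuple[int, int], int] = {}
        for tri in self.triangles:
            for a, b in combinations(sorted(int(v) for v in tri), 2):
                counts[(a, b)] = counts.get((a, b), 0) + 1
        return counts

    def is_watertight(self) -> bool:
        return all(c == 2 for c in self.edge_counts().values())


@dataclass
class SpatialFeatures:
    """Per-nucleus distances to the embryo surface."""

    nucleus_ids: list[str]
    min_distance: np.ndarray  # um
    distance_variance: np.ndarray  # um^2, population variance over faces
    all_distances: np.ndarray | None = None  # (n_nuclei, n_faces)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nucleus_id": self.nucleus_ids,
                "min_distance": self.min_distance,
                "distance_variance": self.distance_variance,
            }
        )


@dataclass
class LineageCall:
    """Inside/outside calls plus the 2-means cluster summary."""

    nucleus_ids: list[str]
    labels: list[str]  # "inside" / "outside"
    cluster_means: pd.DataFrame  # rows inside/outside, cols feature means
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"nucleus_id": self.nucleus_ids, "label": self.labels})


def build_surface(nuclei: pd.DataFrame) -> EmbryoSurface:
    """Triangulated convex-hull boundary of one embryo's nuclear centroids.

    For a convex point cloud the boundary of the 3-D Delaunay complex is the
    convex hull, which is the unique watertight surface the construction
    defines; qhull is asked for triangulated output so every facet is a
    triangle and F = 2V - 4 holds.
    """
    embryos = nuclei["embryo_id"].unique() if "embryo_id" in nuclei else ["?"]
    if len(embryos) > 1:
        raise ValueError(f"build_surface expects a single embryo, got {list(embryos)}")
    pts = nuclei[COORD_COLS].to_numpy(dtype=float)
    if not np.isfinite(pts).all():
        raise ValueError("non-finite centroid coordinates")
    if len(pts) < 4:
        raise DegenerateGeometryError(
            f"embryo {embryos[0]}: need >= 4 centroids to build a surface"
        )
    try:
        hull = scipy.spatial.ConvexHull(pts, qhull_options="Qt")
    except scipy.spatial.QhullError as exc:
        raise DegenerateGeometryError(
            f"embryo {embryos[0]}: degenerate (coplanar/collinear) centroids"
        ) from exc
    # re-index vertices to the hull's own vertex list
    remap = {v: i for i, v in enumerate(hull.vertices)}
    tris = np.array([[remap[v] for v in simplex] for simplex in hull.simplices])
    return EmbryoSurface(vertices=hull.points[hull.vertices], triangles=tris)


def point_triangle_distance(p, tri) -> float:
    """Euclidean distance from a point to a closed 3-D triangle.

    Uses the standard barycentric region decomposition: the closest point is
    found in whichever of the seven Voronoi regions of the triangle (face,
    three edges, three vertices) contains the query's projection.
    """
    p = np.asarray(p, dtype=float)
    a, b, c = (np.asarray(v, dtype=float) for v in tri)
    ab, ac = b - a, c - a
    if np.linalg.norm(np.cross(ab, ac)) == 0.0:
        raise ValueError("degenerate (zero-area) triangle")

    ap = p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(p - a))

    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(p - b))

    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        t = d1 / (d1 - d3)
        return float(np.linalg.norm(p - (a + t * ab)))

    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(p - c))

    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        t = d2 / (d2 - d6)
        return float(np.linalg.norm(p - (a + t * ac)))

    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return float(np.linalg.norm(p - (b + t * (c - b))))

    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    closest = a + v * ab + w * ac
    return float(np.linalg.norm(p - closest))


def compute_spatial_features(
    nuclei: pd.DataFrame,
    surface: EmbryoSurface,
    keep_all_distances: bool = False,
) -> SpatialFeatures:
    """Distance of every nuclear centroid to every surface triangle.

    Records the minimum distance and the population variance of the
    per-face distance vector for each nucleus.
    """
    if surface.n_triangles == 0:
        raise ValueError("empty surface")
    pts = nuclei[COORD_COLS].to_numpy(dtype=float)
    dists = np.empty((len(pts), surface.n_triangles))
    tri_vertices = surface.vertices[surface.triangles]
    for j, tri in enumerate(tri_vertices):
        for i, p in enumerate(pts):
            dists[i, j] = point_triangle_distance(p, tri)
    return SpatialFeatures(
        nucleus_ids=list(nuclei["nucleus_id"]),
        min_distance=dists.min(axis=1),
        distance_variance=dists.var(axis=1),
        all_distances=dists if keep_all_distances else None,
    )


def _kmeans2(x: np.ndarray, max_iter: int = 300) -> np.ndarray:
    """Deterministic Lloyd 2-means with greedy farthest-point initialization.

    Center 1 starts at the point farthest from the data mean, center 2 at the
    point farthest from center 1 — deterministic and invariant to row
    permutation (up to exact ties), so no random restarts are needed.
    """
    c1 = x[np.argmax(np.linalg.norm(x - x.mean(axis=0), axis=1))]
    c2 = x[np.argmax(np.linalg.norm(x - c1, axis=1))]
    centers = np.stack([c1, c2])
    labels = None
    for _it in range(max_iter):
        d = np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=2)
        new = d.argmin(axis=1)
        if labels is not None and (new == labels).all():
            break
        labels = new
        for k in (0, 1):
            if (labels == k).any():
                centers[k] = x[labels == k].mean(axis=0)
    return labels


def classify_inside_outside(features: SpatialFeatures, seed: int = 0) -> LineageCall:
    """2-means inside/outside call on standardized (min distance, variance).

    The cluster with the larger mean minimum distance is labeled "inside"
    (ICM); ties broken toward the smaller mean distance variance. The seed is
    recorded for provenance; the clustering itself is deterministic.
    """
    x = np.column_stack([features.min_distance, features.distance_variance])
    if len(x) < 2:
        raise ValueError("need at least 2 nuclei to classify")
    if np.allclose(x, x[0]):
        raise ValueError("all feature vectors identical: clustering undefined")
    sd = x.std(axis=0)
    z = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = _kmeans2(z)

    mean_min = [x[km == k, 0].mean() if (km == k).any() else -np.inf for k in (0, 1)]
    mean_var = [x[km == k, 1].mean() if (km == k).any() else np.inf for k in (0, 1)]
    if mean_min[0] != mean_min[1]:
        inside = int(np.argmax(mean_min))
    else:
        inside = int(np.argmin(mean_var))
    labels = ["inside" if k == inside else "outside" for k in km]

    summary = pd.DataFrame(
        {
            "mean_min_distance": [mean_min[inside], mean_min[1 - inside]],
            "mean_distance_variance": [mean_var[inside], mean_var[1 - inside]],
        },
        index=["inside", "outside"],
    )
    return LineageCall(
        nucleus_ids=features.nucleus_ids, labels=labels,
        cluster_means=summary, seed=seed,
    )


def normalize_intensities(
    nuclei: pd.DataFrame,
    channel: str,
    method: str = "zscore",
    reference_channel: str | None = None,
) -> pd.DataFrame:
    """Normalize one fluorescence channel for cross-embryo comparison.

    ``zscore`` (default): log-transform then z-score within each embryo.
    ``reference``: divide by the per-embryo median of ``reference_channel``.
    Returns nucleus_id, embryo_id, normalized value and the method used.
    """
    if channel not in nuclei.columns:
        raise KeyError(f"channel {channel!r} not in table")
    out = nuclei[["nucleus_id", "embryo_id"]].copy()
    vals = np.empty(len(nuclei))
    for emb, idx in nuclei.groupby("embryo_id").groups.items():
        v = nuclei.loc[idx, channel].to_numpy(dtype=float)
        if method == "zscore":
            lv = np.log(v + 1.0)
            sd = lv.std()
            if sd == 0:
                raise ValueError(f"zero-variance channel in embryo {emb}")
            vals[nuclei.index.get_indexer(idx)] = (lv - lv.mean()) / sd
        elif method == "reference":
            ref = reference_channel or channel
            med = float(np.median(nuclei.loc[idx, ref]))
            if med == 0:
                raise ValueError(f"zero reference median in embryo {emb}")
            vals[nuclei.index.get_indexer(idx)] = v / med
        else:
            raise ValueError(f"unknown method {method!r}")
    out["normalized"] = vals
    out.attrs["method"] = method
    return out


def _h_statistic(values: np.ndarray, sizes: list[int]) -> float:
    """Kruskal-Wallis H with midrank tie correction for a flat value vector
    split into consecutive groups of the given sizes."""
    ranks = scipy.stats.rankdata(values)
    n = len(values)
    start, stat = 0, 0.0
    for s in sizes:
        r = ranks[start : start + s]
        stat += r.sum() ** 2 / s
        start += s
    h = 12.0 / (n * (n + 1)) * stat - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else np.nan


def kruskal_wallis(
    *groups, exact: bool = False
) -> tuple[float, float]:
    """Kruskal-Wallis H test across two or more groups.

    Returns (H, p). The p-value uses the chi-square approximation with
    df = #groups - 1; with ``exact=True`` (total n <= 10) the p-value is
    instead computed by full enumeration of all assignments of the pooled
    observations to groups of the observed sizes.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrs):
        raise ValueError("every group must be nonempty")
    h, p = scipy.stats.kruskal(*arrs)
    if not exact:
        return float(h), float(p)

    pooled = np.concatenate(arrs)
    n = len(pooled)
    if n > 10:
        raise ValueError("exact permutation p only supported for total n <= 10")
    sizes = [len(a) for a in arrs]
    idx_all = set(range(n))

    def assignments(remaining: frozenset, gi: int):
        if gi == len(sizes) - 1:
            yield [tuple(sorted(remaining))]
            return
        for pick in combinations(sorted(remaining), sizes[gi]):
            for rest in assignments(remaining - set(pick), gi + 1):
                yield [pick] + rest

    count = total = 0
    for parts in assignments(frozenset(idx_all), 0):
        vals = np.concatenate([pooled[list(part)] for part in parts])
        hp = _h_statistic(vals, sizes)
        total += 1
        if hp >= h - 1e-12:
            count += 1
    return float(h), count / total


def n_exact_assignments(sizes: list[int]) -> int:
    """Multinomial count of distinct group assignments (exact-test size)."""
    n = sum(sizes)
    out, rem = 1, n
    for s in sizes:
        out *= comb(rem, s)
        rem -= s
    return out
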