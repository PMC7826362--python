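"""Group-comparison and gene-set statistics.

Differential expression uses a two-sided Wilcoxon rank-sum test on
log2(FPKM+1) per gene with Benjamini-Hochberg adjustment — a documented
rank-based procedure standing in for error-model-based single-cell DE.
Also provided: lineage-marker derivation, ternary (compositional) expression
fractions with a permutation density-bias test, a cumulative-sum
relative-percentage pathway statistic, hypergeometric over-representation,
and preranked GSEA with a permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "benjamini_hochberg",
    "differential_expression",
    "derive_lineage_markers",
    "ternary_fractions",
    "ternary_density_bias_test",
    "pathway_relative_percentage_test",
    "hypergeometric_enrichment",
    "gsea_preranked",
    "GseaResult",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes...

    Set names must be unique and sets nonempty.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            sets[name] = genes
    if not sets:
        raise ValueError("no gene sets found")
    return sets


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two cell groups.

    Tests log2(FPKM+1); exact null distribution when the combined group size
    is <= 12, else the tie-corrected normal approximation. Effect is the
    difference of group means of log2(FPKM+1) (A minus B); p-values are BH
    adjusted across all tested genes.
    """
    if len(group_a) < min_group or len(group_b) < min_group:
        raise ValueError(f"each group needs >= {min_group} cells")
    la = np.log2(matrix[list(group_a)].to_numpy(dtype=float) + 1.0)
    lb = np.log2(matrix[list(group_b)].to_numpy(dtype=float) + 1.0)
    method = "exact" if la.shape[1] + lb.shape[1] <= 12 else "asymptotic"

    stats = np.empty(len(matrix))
    pvals = np.empty(len(matrix))
    for i in range(len(matrix)):
        a, b = la[i], lb[i]
        if np.ptp(np.concatenate([a, b])) == 0:
            stats[i], pvals[i] = len(a) * len(b) / 2.0, 1.0
            continue
        # ties force the asymptotic path even at small n
        m = method if len(np.unique(np.concatenate([a, b]))) == len(a) + len(b) else (
            "asymptotic"
        )
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=m)
        stats[i], pvals[i] = res.statistic, res.pvalue
    effect = la.mean(axis=1) - lb.mean(axis=1)
    return pd.DataFrame(
        {
            "effect": effect,
            "statistic": stats,
            "p_value": pvals,
            "p_adjusted": benjamini_hochberg(pvals),
        },
        index=matrix.index,
    )


def derive_lineage_markers(
    de: pd.DataFrame, direction: str = "up", alpha: float = 0.05
) -> list[str]:
    """Genes significant after adjustment and enriched in one direction."""
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    sig = de["p_adjusted"] < alpha
    enr = de["effect"] > 0 if direction == "up" else de["effect"] < 0
    return de.index[sig & enr].tolist()


def ternary_fractions(
    matrix: pd.DataFrame,
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-gene relative fractions of mean expression across three groups.

    Fractions sum to 1; genes whose three group means are all zero are
    dropped (their ids are available in ``result.attrs['dropped']``).
    """
    if len(groups) != 3:
        raise ValueError("ternary fractions need exactly 3 groups")
    names = list(groups)
    cells_seen: set[str] = set()
    for name, cells in groups.items():
        if len(cells) == 0:
            raise ValueError(f"group {name!r} is empty")
        overlap = cells_seen & set(cells)
        if overlap:
            raise ValueError(f"groups are not disjoint: {sorted(overlap)[:5]}")
        cells_seen.update(cells)
    means = np.column_stack(
        [matrix[list(groups[name])].mean(axis=1).to_numpy() for name in names]
    )
    total = means.sum(axis=1)
    keep = total > 0
    if not keep.any():
        raise ValueError("every gene has zero total expression")
    coords = means[keep] / total[keep, None]
    out = pd.DataFrame(coords, index=matrix.index[keep], columns=names)
    out.attrs["dropped"] = matrix.index[~keep].tolist()
    return out


def _ternary_region(frac: np.ndarray, apex_threshold: float = 0.6) -> str:
    """Assign one simplex point to apex/edge/center regions (a partition)."""
    i = int(np.argmax(frac))
    if frac[i] > apex_threshold:
        return f"apex_{i}"
    j = int(np.argmin(frac))
    if frac[j] < 0.15:
        pair = sorted({0, 1, 2} - {j})
        return f"edge_{pair[0]}{pair[1]}"
    return "center"


def ternary_density_bias_test(
    matrix: pd.DataFrame,
    groups: dict[str, list[str]],
    n_permutations: int = 1000,
    seed: int = 0,
    apex_threshold: float = 0.6,
) -> pd.DataFrame:
    """Permutation test for density bias of genes in ternary regions.

    The simplex is partitioned into three apex regions (largest fraction >
    ``apex_threshold``), three edge regions and a center. The null permutes
    cell group labels and recomputes region counts; per region p = fraction
    of permutations with a count >= observed (one-sided), BH adjusted across
    regions.
    """
    if n_permutations < 100:
        raise ValueError("need >= 100 permutations")
    names = list(groups)
    regions = [f"apex_{i}" for i in range(3)] + [
        "edge_01", "edge_02", "edge_12", "center",
    ]

    def region_counts(gdef: dict[str, list[str]]) -> pd.Series:
        coords = ternary_fractions(matrix, gdef)
        labels = [
            _ternary_region(row, apex_threshold) for row in coords.to_numpy()
        ]
        return pd.Series(labels).value_counts().reindex(regions, fill_value=0)

    observed = region_counts(groups)

    all_cells = [c for name in names for c in groups[name]]
    sizes = [len(groups[name]) for name in names]
    rng = np.random.default_rng(seed)
    exceed = pd.Series(0, index=regions)
    for _ in range(n_permutations):
        perm = rng.permutation(all_cells)
        gdef, start = {}, 0
        for name, s in zip(names, sizes):
            gdef[name] = list(perm[start : start + s])
            start += s
        exceed += (region_counts(gdef) >= observed).astype(int)
    pvals = (1 + exceed) / (n_permutations + 1)
    return pd.DataFrame(
        {
            "count": observed,
            "p_value": pvals,
            "p_adjusted": benjamini_hochberg(pvals.to_numpy()),
        }
    )


def pathway_relative_percentage_test(
    matrix: pd.DataFrame,
    pathway_genes: list[str],
    group_a: list[str],
    group_b: list[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Cumulative-sum relative-percentage pathway comparison.

    Per pathway gene g: r_g = 100 * mean_A(g) / (mean_A(g) + mean_B(g))
    (genes with zero total dropped). Reported alongside the cumulative-sum
    curve of the sorted r_g is the reduction T = sum(r_g - 50), compared with
    a two-sided null built by permuting cell group labels. Swapping the
    groups negates T (r -> 100 - r).
    """
    present = [g for g in pathway_genes if g in matrix.index]
    if len(present) < 3:
        raise ValueError("need >= 3 pathway genes present in the matrix")

    cells = list(group_a) + list(group_b)
    sub = matrix.loc[present, cells].to_numpy(dtype=float)
    na = len(group_a)

    def rel_percent(order: np.ndarray) -> np.ndarray:
        ma = sub[:, order[:na]].mean(axis=1)
        mb = sub[:, order[na:]].mean(axis=1)
        tot = ma + mb
        with np.errstate(invalid="ignore"):
            r = np.where(tot > 0, 100.0 * ma / np.where(tot > 0, tot, 1.0), np.nan)
        return r[~np.isnan(r)]

    ma = sub[:, :na].mean(axis=1)
    mb = sub[:, na:].mean(axis=1)
    keep = (ma + mb) > 0
    if not keep.any():
        raise ValueError("pathway empty after zero-expression filtering")
    r_obs = 100.0 * ma[keep] / (ma + mb)[keep]
    kept_genes = [g for g, k in zip(present, keep) if k]
    stat = float((r_obs - 50.0).sum())

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(cells))
        sp = (rel_percent(perm) - 50.0).sum()
        if abs(sp) >= abs(stat) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)

    r_sorted = np.sort(r_obs)
    return {
        "relative_percentages": pd.Series(r_obs, index=kept_genes),
        "cumulative_curve": np.cumsum(r_sorted),
        "statistic": stat,
        "p_value": float(p),
        "n_genes": int(len(r_obs)),
    }


def hypergeometric_enrichment(
    selection: set[str] | list[str],
    collection: dict[str, list[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set.

    Sets and the selection are intersected with the universe; the p-value is
    P[overlap >= observed] under sampling without replacement, BH adjusted
    across sets. Rows sorted by p-value.
    """
    universe = set(universe)
    selection = set(selection) & universe
    if not universe or not selection:
        raise ValueError("universe and selection must be nonempty")
    rows = []
    for name, genes in collection.items():
        gs = set(genes) & universe
        if not gs:
            continue
        overlap = len(gs & selection)
        p = float(
            scipy.stats.hypergeom.sf(
                overlap - 1, len(universe), len(gs), len(selection)
            )
        )
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(gs),
                "universe_size": len(universe),
                "selection_size": len(selection),
                "p_value": min(p, 1.0),
            }
        )
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    table = pd.DataFrame(rows)
    table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)


@dataclass
class GseaResult:
    es: float
    nes: float
    p_value: float
    running_sum: np.ndarray
    hit_positions: np.ndarray


def _running_sum(in_set: np.ndarray, scores: np.ndarray, weight: int) -> np.ndarray:
    n = len(in_set)
    n_hits = int(in_set.sum())
    if weight == 0:
        hit_inc = np.full(n, 1.0 / n_hits)
    else:
        w = np.abs(scores) ** weight
        tot = w[in_set].sum()
        hit_inc = w / tot if tot > 0 else np.full(n, 1.0 / n_hits)
    steps = np.where(in_set, hit_inc, -1.0 / (n - n_hits))
    return np.cumsum(steps)


def gsea_preranked(
    ranked_genes: list[str],
    scores,
    gene_set: set[str] | list[str],
    n_permutations: int = 1000,
    seed: int = 0,
    weight: int = 0,
) -> GseaResult:
    """Preranked GSEA enrichment score with a gene-label permutation null.

    The running sum increments by 1/#hits at set members (or by normalized
    |score|^weight for weight=1) and decrements by 1/(N - #hits) elsewhere;
    ES is the maximum-magnitude deviation. The null permutes set membership
    uniformly over list positions; NES = ES / mean(|null ES| of the same
    sign) and p is the same-sign tail fraction.
    """
    genes = list(ranked_genes)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked gene list must be unique")
    scores = np.asarray(scores, dtype=float)
    gs = set(gene_set)
    in_set = np.array([g in gs for g in genes])
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError("gene set does not overlap the ranked list")
    if n_hits == len(genes):
        raise ValueError("gene set covers the whole list: ES undefined")

    rs = _running_sum(in_set, scores, weight)
    es = float(rs[np.argmax(np.abs(rs))])

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    n = len(genes)
    for i in range(n_permutations):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_hits, replace=False)] = True
        r = _running_sum(mask, scores, weight)
        null[i] = r[np.argmax(np.abs(r))]
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same) == 0:
        nes, p = np.inf if es > 0 else -np.inf, 1.0 / (n_permutations + 1)
    else:
        nes = es / np.mean(np.abs(same))
        p = (1 + (np.abs(same) >= abs(es) - 1e-15).sum()) / (len(same) + 1)
    return GseaResult(
        es=es, nes=float(nes), p_value=float(p),
        running_sum=rs, hit_positions=np.flatnonzero(in_set),
    )
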