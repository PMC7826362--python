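"""Fraction-of-identity lineage deconvolution.

Each query expression profile is decomposed over reference lineage
signatures (per-class average FPKM) by simplex-constrained least squares:
minimize ||S f - x||^2 subject to f >= 0 and sum(f) = 1. The quadratic
program is solved as a nonnegative least-squares problem with the sum
constraint enforced by an augmented penalty row, then renormalized — robust
and verifiable against a dense simplex grid search.

The mixing model is linear in FPKM, so deconvolution runs on the linear
scale; genes must be expressed (FPKM above a threshold, default > 0) in the
query and, by default, in every signature column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

__all__ = [
    "IdentityFractions",
    "build_signature",
    "fraction_of_identity",
    "deconvolve_matrix",
    "summarize_fractions",
]

_PENALTY = 1e6  # weight of the sum-to-one row in the augmented NNLS system


@dataclass
class IdentityFractions:
    fractions: pd.Series  # class -> fraction, on the probability simplex
    n_genes_used: int
    rank_deficient: bool = False


def build_signature(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    class_definitions: dict[str, list[str]] | None = None,
    class_column: str = "class",
) -> pd.DataFrame:
    """Per-class average FPKM signature (genes x classes).

    ``class_definitions`` maps class name -> list of cell ids; when omitted,
    classes are taken from ``annotation[class_column]``.
    """
    if class_definitions is None:
        class_definitions = {
            str(c): annotation.loc[annotation[class_column] == c, "cell_id"].tolist()
            for c in annotation[class_column].unique()
        }
    cols = {}
    for name, cells in class_definitions.items():
        if len(cells) == 0:
            raise ValueError(f"class {name!r} has no cells")
        missing = [c for c in cells if c not in matrix.columns]
        if missing:
            raise ValueError(f"class {name!r}: unknown cells {missing[:5]}")
        cols[name] = matrix[cells].mean(axis=1)
    sig = pd.DataFrame(cols)
    if sig.shape[1] < 2:
        raise ValueError("need >= 2 reference classes")
    return sig


def _solve_simplex_lsq(s: np.ndarray, x: np.ndarray) -> np.ndarray:
    """min ||S f - x||^2 s.t. f >= 0, sum f = 1, via penalty-augmented NNLS."""
    scale = max(np.abs(s).max(), 1.0)
    aug = np.vstack([s / scale, np.full((1, s.shape[1]), _PENALTY)])
    rhs = np.concatenate([x / scale, [_PENALTY]])
    f, _ = scipy.optimize.nnls(aug, rhs)
    total = f.sum()
    if total <= 0:
        return np.full(s.shape[1], 1.0 / s.shape[1])
    return f / total


def fraction_of_identity(
    sample: pd.Series,
    signature: pd.DataFrame,
    min_fpkm: float = 0.0,
    require_positive_signature: bool = True,
) -> IdentityFractions:
    """Simplex mixing fractions of one query profile over the signatures.

    Uses genes with FPKM > ``min_fpkm`` in the query and (by default) in
    every signature column; a flag relaxes the overlap rule to query-only.
    """
    common = signature.index.intersection(sample.index)
    sig = signature.loc[common].to_numpy(dtype=float)
    x = sample.loc[common].to_numpy(dtype=float)
    mask = x > min_fpkm
    if require_positive_signature:
        mask &= (sig > min_fpkm).all(axis=1)
    k = signature.shape[1]
    if mask.sum() < k:
        raise ValueError(
            f"only {int(mask.sum())} usable genes for {k} classes: cannot deconvolve"
        )
    s_use, x_use = sig[mask], x[mask]
    rank = np.linalg.matrix_rank(s_use)
    deficient = rank < k
    if deficient:
        warnings.warn(
            "restricted signature matrix is rank-deficient; fractions are a "
            "minimum-norm solution",
            stacklevel=2,
        )
    f = _solve_simplex_lsq(s_use, x_use)
    return IdentityFractions(
        fractions=pd.Series(f, index=signature.columns),
        n_genes_used=int(mask.sum()),
        rank_deficient=deficient,
    )


def deconvolve_matrix(
    queries: pd.DataFrame, signature: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Fraction of identity for every query column; rows samples, columns
    classes plus n_genes_used."""
    rows = {}
    for col in queries.columns:
        res = fraction_of_identity(queries[col], signature, **kwargs)
        rows[col] = pd.concat(
            [res.fractions, pd.Series({"n_genes_used": res.n_genes_used})]
        )
    return pd.DataFrame(rows).T


def summarize_fractions(
    fractions: pd.DataFrame,
    group_labels: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group median fractions and pairwise Welch t-tests.

    ``fractions``: samples x classes; ``group_labels``: sample -> group.
    Returns (medians indexed by group, long table of pairwise tests per
    class with t statistic and p-value). Groups of identical values give
    t = 0, p = 1 by convention.
    """
    labels = group_labels.loc[fractions.index]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    medians = fractions.groupby(labels).median()

    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            a = fractions.loc[labels == ga]
            b = fractions.loc[labels == gb]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(
                    f"groups {ga!r}/{gb!r} need >= 2 samples for the t-test"
                )
            for cls in fractions.columns:
                av, bv = a[cls].to_numpy(), b[cls].to_numpy()
                if av.std() == 0 and bv.std() == 0 and av.mean() == bv.mean():
                    t, p = 0.0, 1.0
                else:
                    t, p = scipy.stats.ttest_ind(av, bv, equal_var=False)
                rows.append(
                    {"group_a": ga, "group_b": gb, "class": cls,
                     "t": float(t), "p_value": float(p)}
                )
    return medians, pd.DataFrame(rows)
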