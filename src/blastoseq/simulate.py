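"""Ground-truthed synthetic inputs for every pipeline stage.

Two kinds of data are emulated: blastocyst-like nuclear point clouds (an
outer trophectoderm shell plus an inner-cell-mass clump, with lineage-
dependent immunofluorescence channels) and FPKM gene-by-cell matrices with
planted class signatures, high-variance genes, coexpression modules,
pseudotime-dependent trends and known mixing fractions.

Every generator is a pure function of its parameters including the seed:
independent random sub-streams are derived per purpose, so e.g. adding inner
nuclei does not perturb the outer-shell draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmbryoSimParams",
    "ExpressionSimParams",
    "GroundTruth",
    "simulate_embryo",
    "simulate_expression",
    "simulate_mixtures",
    "write_nuclei_csv",
    "write_expression_tsv",
    "write_annotation_csv",
]


def _stream(seed: int, purpose: int) -> np.random.Generator:
    """Deterministic sub-stream: one generator per (seed, purpose) pair."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), purpose]))


# ---------------------------------------------------------------------------
# ground truth container


@dataclass
class GroundTruth:
    """Known truth recorded by the simulators.

    Only the fields relevant to a given generator are populated; the rest
    stay ``None``.
    """

    nucleus_labels: list[str] | None = None  # "inside" / "outside"
    gene_roles: dict[str, str] | None = None  # gene -> role string
    cell_classes: dict[str, str] | None = None  # cell -> class label
    mixing_fractions: np.ndarray | None = None  # samples x classes, simplex rows
    latent_order: np.ndarray | None = None  # pseudotime rank per cell
    module_latents: dict[int, np.ndarray] | None = None  # module -> factor per cell

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, dict):
                v = {
                    k: (x.tolist() if isinstance(x, np.ndarray) else x)
                    for k, x in v.items()
                }
            out[f.name] = v
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# embryo point clouds


@dataclass
class EmbryoSimParams:
    """Geometry and staining parameters of a simulated blastocyst.

    The shell is an axis-aligned ellipsoid (default sphere, radii
    ``outer_radius * axis_ratios``); blastocysts are roughly convex, which is
    the assumption behind the downstream surface construction. Channel
    intensities are lognormal with lineage-dependent log-means
    (``channel_effects[channel][lineage]``), emulating e.g. an ICM marker
    brighter inside and a TE marker brighter outside.
    """

    n_outer: int = 60
    n_inner: int = 15
    outer_radius: float = 30.0  # um
    shell_jitter: float = 1.0  # radial sd, um
    icm_offset: float = 0.45  # fraction of radius toward the +z pole
    icm_spread: float = 6.0  # clump sd, um
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "ch_icm": {"inside": 6.5, "outside": 4.5},
            "ch_te": {"inside": 4.5, "outside": 6.5},
        }
    )
    intensity_sd: float = 0.35  # log-intensity sd
    embryo_id: str = "sim_embryo"
    seed: int = 0

    def validate(self) -> None:
        if self.n_outer < 8:
            raise ValueError(
                "n_outer must be >= 8: the convex hull of fewer shell points "
                "cannot enclose interior nuclei robustly"
            )
        if self.n_inner < 0:
            raise ValueError("n_inner must be >= 0")
        if self.outer_radius <= 0:
            raise ValueError("outer_radius must be > 0")
        if self.icm_spread >= self.outer_radius:
            raise ValueError("icm_spread must be smaller than outer_radius")


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_embryo(params: EmbryoSimParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample a blastocyst-like nuclear point cloud.

    Outer (trophectoderm) nuclei sit on a radially jittered ellipsoidal
    shell; inner (ICM) nuclei form a compact Gaussian clump displaced toward
    the +z pole and rejected back inside a safety radius so that, for sane
    parameters, every inner nucleus lies strictly inside the convex hull of
    the shell.

    Returns the nuclei table (one row per nucleus: ids, xyz centroid, volume,
    channel intensities) and a :class:`GroundTruth` with inside/outside
    labels.
    """
    params.validate()
    axes = np.asarray(params.axis_ratios, dtype=float)

    rng_shell = _stream(params.seed, 0)
    dirs = _uniform_sphere(rng_shell, params.n_outer)
    radii = params.outer_radius + rng_shell.normal(
        0.0, params.shell_jitter, size=params.n_outer
    )
    outer = dirs * radii[:, None] * axes

    rng_inner = _stream(params.seed, 1)
    center = np.array([0.0, 0.0, params.icm_offset * params.outer_radius]) * axes
    # keep the clump strictly interior: stay clear of the shell (jitter) and
    # of the sagitta of hull facets between shell points
    safe = params.outer_radius - 3.0 * params.shell_jitter - 0.12 * params.outer_radius
    inner = np.empty((params.n_inner, 3))
    for i in range(params.n_inner):
        while True:
            p = center + rng_inner.normal(0.0, params.icm_spread, size=3) * axes
            if np.linalg.norm(p / axes) <= safe:
                inner[i] = p
                break

    pts = np.vstack([outer, inner]) if params.n_inner else outer
    labels = ["outside"] * params.n_outer + ["inside"] * params.n_inner
    n = len(labels)

    rng_vol = _stream(params.seed, 2)
    volume = np.exp(rng_vol.normal(np.log(600.0), 0.2, size=n))

    rng_int = _stream(params.seed, 3)
    intens = {}
    for ch, eff in params.channel_effects.items():
        mu = np.array([eff[lab] for lab in labels])
        intens[ch] = np.exp(mu + rng_int.normal(0.0, params.intensity_sd, size=n))

    table = pd.DataFrame(
        {
            "nucleus_id": [f"n{i:03d}" for i in range(n)],
            "embryo_id": params.embryo_id,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "volume": volume,
            **intens,
        }
    )
    return table, GroundTruth(nucleus_labels=labels)


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionSimParams:
    """Structure of a simulated FPKM gene-by-cell matrix.

    The log2 mean of gene g in cell c is
    ``baseline_g + signature effect + loading_g * latent_{m,c} + trend_g(c)``
    and FPKM = 2**(mean + noise) with Gaussian log2-scale noise of sd
    ``dispersion`` (times ``hvg_cv_multiplier`` for planted high-variance
    genes). Signature blocks, the HVG set, module blocks and trend genes are
    disjoint; remaining genes are background.
    """

    n_genes: int = 2000
    classes: Sequence[tuple[str, int]] = (("A", 20), ("B", 20))
    n_signature_per_class: int = 25
    signature_log2fc: float = 2.0
    n_hvg: int = 100
    hvg_cv_multiplier: float = 4.0
    n_modules: int = 4
    module_size: int = 40
    module_latent_sd: float = 6.0  # program strength (log2 units per unit latent)
    baseline_log2_mean_range: tuple[float, float] = (1.0, 6.0)
    dispersion: float = 1.0  # lognormal sd of FPKM, log2 scale
    pseudotime_genes: int = 0
    trend_amplitude: float = 4.0  # log2 span of a planted trend gene
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_genes,
            self.n_signature_per_class,
            self.n_hvg,
            self.n_modules,
            self.module_size,
            self.pseudotime_genes,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be nonnegative")
        if self.hvg_cv_multiplier <= 1 and self.n_hvg > 0:
            raise ValueError("hvg_cv_multiplier must exceed 1")
        special = (
            self.n_signature_per_class * len(self.classes)
            + self.n_hvg
            + self.n_modules * self.module_size
            + self.pseudotime_genes
        )
        if special > self.n_genes:
            raise ValueError(
                f"special genes ({special}) exceed n_genes ({self.n_genes}); "
                "the planted gene sets must be disjoint"
            )


def simulate_expression(
    params: ExpressionSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate an FPKM matrix (genes x cells), a cell annotation table and
    the ground truth of planted structure.

    Annotation columns: cell_id, embryo_id, stage, genotype, lineage, class.
    Class labels that are genotype names (WT/HET/MUT) or lineage names
    (EPI/PrE/TE/ICM) are propagated into the matching annotation column.
    """
    params.validate()

    genes = [f"g{i:04d}" for i in range(params.n_genes)]
    cells: list[str] = []
    classes: list[str] = []
    for label, n in params.classes:
        for j in range(n):
            cells.append(f"{label}_c{j:03d}")
            classes.append(label)
    n_cells = len(cells)
    if n_cells == 0:
        raise ValueError("at least one cell required")

    # disjoint planted gene sets, assigned front to back
    roles = {g: "background" for g in genes}
    cursor = 0
    for label, _ in params.classes:
        for g in genes[cursor : cursor + params.n_signature_per_class]:
            roles[g] = f"signature:{label}"
        cursor += params.n_signature_per_class
    hvg_genes = genes[cursor : cursor + params.n_hvg]
    for g in hvg_genes:
        roles[g] = "hvg"
    cursor += params.n_hvg
    for m in range(params.n_modules):
        for g in genes[cursor : cursor + params.module_size]:
            roles[g] = f"module:{m}"
        cursor += params.module_size
    trend_genes = genes[cursor : cursor + params.pseudotime_genes]
    for g in trend_genes:
        roles[g] = "trend"

    rng_base = _stream(params.seed, 10)
    lo, hi = params.baseline_log2_mean_range
    baseline = rng_base.uniform(lo, hi, size=params.n_genes)
    mean_log2 = np.tile(baseline[:, None], (1, n_cells))

    cls_arr = np.array(classes)
    for label, _ in params.classes:
        gmask = np.array([roles[g] == f"signature:{label}" for g in genes])
        mean_log2[np.ix_(gmask, cls_arr == label)] += params.signature_log2fc

    rng_mod = _stream(params.seed, 11)
    module_latents: dict[int, np.ndarray] = {}
    for m in range(params.n_modules):
        gmask = np.array([roles[g] == f"module:{m}" for g in genes])
        # two-state (on/off) program activity: lineage programs are roughly
        # binary across cells. Induction is one-sided — "off" cells stay at
        # baseline, "on" cells gain 2*module_latent_sd log2 units — so the
        # program never runs below the FPKM floor and the observed separation
        # is the same for every module gene regardless of its baseline.
        state = np.zeros(n_cells)
        on = rng_mod.permutation(n_cells)[: n_cells // 2]
        state[on] = 1.0
        latent = 2.0 * state - 1.0
        module_latents[m] = latent.copy()
        mean_log2[gmask] += np.outer(
            rng_mod.uniform(0.9, 1.0, size=int(gmask.sum())),
            params.module_latent_sd * (latent + 1.0),
        )

    rng_ord = _stream(params.seed, 12)
    latent_order = rng_ord.permutation(n_cells)
    if params.pseudotime_genes:
        t = latent_order / max(n_cells - 1, 1)
        gmask = np.array([roles[g] == "trend" for g in genes])
        signs = np.where(np.arange(gmask.sum()) % 2 == 0, 1.0, -1.0)
        mean_log2[gmask] += np.outer(signs * params.trend_amplitude, t)

    rng_noise = _stream(params.seed, 13)
    sd = np.full(params.n_genes, params.dispersion)
    sd[[roles[g] == "hvg" for g in genes]] *= params.hvg_cv_multiplier
    noise = rng_noise.normal(size=(params.n_genes, n_cells)) * sd[:, None]

    fpkm = np.maximum(np.exp2(mean_log2 + noise), 0.0)
    matrix = pd.DataFrame(fpkm, index=pd.Index(genes, name="gene_id"), columns=cells)

    genos = {"WT", "HET", "MUT"}
    lins = {"EPI", "PrE", "TE", "ICM"}
    annotation = pd.DataFrame(
        {
            "cell_id": cells,
            "embryo_id": [f"{c}_e{i // 8}" for c, (i, _) in
                          zip(classes, enumerate(cells))],
            "stage": "E3.5",
            "genotype": [c if c in genos else "NA" for c in classes],
            "lineage": [c if c in lins else "unassigned" for c in classes],
            "class": classes,
        }
    )
    truth = GroundTruth(
        gene_roles=roles,
        cell_classes=dict(zip(cells, classes)),
        latent_order=latent_order,
        module_latents=module_latents or None,
    )
    return matrix, annotation, truth


def simulate_mixtures(
    signature: pd.DataFrame,
    fractions: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Mix signature columns into synthetic query profiles.

    Each sample is ``signature @ fraction`` with multiplicative lognormal
    noise (log-scale sd ``noise_sd``). Fraction rows must lie on the
    probability simplex (tolerance 1e-9).
    """
    fr = np.atleast_2d(np.asarray(fractions, dtype=float))
    if fr.shape[1] != signature.shape[1]:
        raise ValueError(
            f"fraction vectors have {fr.shape[1]} entries but the signature "
            f"has {signature.shape[1]} classes"
        )
    if (fr < 0).any():
        raise ValueError("mixing fractions must be nonnegative")
    if not np.allclose(fr.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("mixing fractions must sum to 1 (tolerance 1e-9)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    clean = signature.to_numpy() @ fr.T
    rng = _stream(seed, 20)
    vals = clean * np.exp(rng.normal(0.0, noise_sd, size=clean.shape))
    samples = [f"mix{i:03d}" for i in range(fr.shape[0])]
    out = pd.DataFrame(vals, index=signature.index, columns=samples)
    return out, GroundTruth(mixing_fractions=fr)


# ---------------------------------------------------------------------------
# writers


def write_nuclei_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def write_annotation_csv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, index=False)
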