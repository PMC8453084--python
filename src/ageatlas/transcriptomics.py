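"""Transcriptomic annotation of a brain cluster.

Links a spatial cluster (for this pipeline: the most important lesion
network) to gene expression measured at scattered postmortem samples. Each
sample is represented by a 6-mm sphere around its MNI coordinate; samples
whose sphere lies more than 50% inside the background brain mask are
admitted and assigned to the cluster holding the largest share of sphere
voxels. Expression is normalized per donor (subtract, then divide by, the
donor median per gene) to remove donor-level scale differences, and genes
are tested by permutation: the observed mean normalized expression of the
in-cluster samples is compared with means of equally sized random sample
sets, with family-wise error controlled by the single-step max-statistic
procedure (Bonferroni available as an alternative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic_data import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SampleAssignment",
    "GeneAssociation",
    "voxelize_sphere",
    "map_samples_to_clusters",
    "normalize_expression",
    "collapse_probes",
    "permutation_gene_association",
    "select_genes",
]


@dataclass
class SampleAssignment:
    """Where one expression sample's sphere landed."""

    sample_index: int
    sphere_voxels: int
    overlap_fraction: float
    cluster: int | None    # None = unadmitted / unassigned


@dataclass
class GeneAssociation:
    """Permutation statistics for one gene in the annotated cluster."""

    gene_id: str
    t_obs: float           # mean normalized expression over in-cluster samples
    p_value: float
    p_fwe: float
    significant: bool


def voxelize_sphere(
    center_mm: np.ndarray,
    radius_mm: float,
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
) -> np.ndarray:
    """Voxels whose center lies within ``radius_mm`` of a world-space point.

    Returns an (m, 3) integer index array; empty (with a warning) when the
    sphere misses the grid entirely.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    center_mm = np.asarray(center_mm, dtype=float)
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    center_vox = inv[:3, :3] @ center_mm + inv[:3, 3]
    # conservative per-axis search half-width in voxel units
    col_norms = np.linalg.norm(affine[:3, :3], axis=0)
    half = radius_mm / np.where(col_norms > 0, col_norms, 1.0)
    lo = np.maximum(np.floor(center_vox - half).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + half).astype(int),
                    np.array(grid_shape) - 1)
    if np.any(lo > hi):
        logger.warning("sphere at %s lies entirely outside the grid",
                       np.round(center_mm, 2))
        return np.empty((0, 3), dtype=int)
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    box = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    world = box @ affine[:3, :3].T + affine[:3, 3]
    dist2 = np.sum((world - center_mm) ** 2, axis=1)
    inside = box[dist2 <= radius_mm ** 2]
    if inside.size == 0:
        logger.warning("sphere at %s covers no voxel centers",
                       np.round(center_mm, 2))
    return inside


def map_samples_to_clusters(
    sample_coords_mm: np.ndarray,
    background_mask: np.ndarray,
    cluster_labels: np.ndarray,
    affine: np.ndarray,
    radius_mm: float = 6.0,
    overlap_threshold: float = 0.5,
) -> list[SampleAssignment]:
    """Admit and assign samples by the sphere-overlap rule.

    A sample is admitted only when *strictly* more than ``overlap_threshold``
    of its sphere voxels fall inside the background mask; admitted samples
    go to the cluster owning the largest share of sphere voxels (ties break
    to the lowest cluster id, with a warning).
    """
    mask = np.asarray(background_mask).astype(bool)
    labels = np.asarray(cluster_labels)
    if mask.shape != labels.shape:
        raise ValueError("background mask and cluster labels must share a grid")
    coords = np.atleast_2d(np.asarray(sample_coords_mm, dtype=float))
    out: list[SampleAssignment] = []
    for i, c in enumerate(coords):
        sphere = voxelize_sphere(c, radius_mm, mask.shape, affine)
        if len(sphere) == 0:
            out.append(SampleAssignment(i, 0, 0.0, None))
            continue
        in_mask = mask[tuple(sphere.T)]
        frac = float(in_mask.mean())
        if not frac > overlap_threshold:
            out.append(SampleAssignment(i, len(sphere), frac, None))
            continue
        labs = labels[tuple(sphere.T)]
        labs = labs[labs > 0]
        if labs.size == 0:
            out.append(SampleAssignment(i, len(sphere), frac, None))
            continue
        counts = np.bincount(labs)
        best = int(np.flatnonzero(counts == counts.max())[0])
        if np.count_nonzero(counts == counts.max()) > 1:
            logger.warning(
                "sample %d: tie between clusters %s; assigning lowest id %d",
                i, np.flatnonzero(counts == counts.max()).tolist(), best,
            )
        out.append(SampleAssignment(i, len(sphere), frac, best))
    return out


def normalize_expression(dataset: ExpressionDataset) -> np.ndarray:
    """Per-donor median normalization: (x − median) / median per gene.

    The median is taken over all samples of one donor, separately per gene,
    so donor-level expression scale cancels. A zero median is an input
    error and is reported with the offending gene and donor.
    """
    expr = dataset.expr
    donors = np.asarray(dataset.donor_of_sample)
    norm = np.empty_like(expr)
    for d in dict.fromkeys(dataset.donor_of_sample):
        cols = donors == d
        med = np.median(expr[:, cols], axis=1)
        zero = np.flatnonzero(med == 0)
        if zero.size:
            raise ValueError(
                f"zero median expression for gene {dataset.gene_ids[zero[0]]!r} "
                f"in donor {d!r}; cannot normalize"
            )
        norm[:, cols] = (expr[:, cols] - med[:, None]) / med[:, None]
    return norm


def collapse_probes(
    probe_expr: np.ndarray, probe_gene: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Pick, per gene, the probe with the highest mean expression.

    Utility for probe-level input; the main pipeline assumes gene-level
    expression (collapsing already applied).
    """
    probe_expr = np.asarray(probe_expr, dtype=float)
    if probe_expr.shape[0] != len(probe_gene):
        raise ValueError("one gene id per probe row required")
    means = probe_expr.mean(axis=1)
    best: dict[str, int] = {}
    for i, g in enumerate(probe_gene):
        if g not in best or means[i] > means[best[g]]:
            best[g] = i
    genes = list(best)
    return probe_expr[[best[g] for g in genes]], genes


def permutation_gene_association(
    norm_expr: np.ndarray,
    assignments: list[SampleAssignment],
    cluster_id: int,
    gene_ids: list[str],
    n_perm: int = 999,
    seed: int = 0,
    fwe: str = "maxstat",
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> list[GeneAssociation]:
    """Permutation test of cluster-mean expression per gene, with FWE control.

    The observed statistic is the mean normalized expression over in-cluster
    samples. The null redraws the same number of samples uniformly without
    replacement from all *admitted* samples (cluster labels exchangeable
    across the brain), reusing the same permutations for every gene.
    p-values use the add-one estimator (1 + exceedances) / (n_perm + 1).

    FWE ``maxstat`` compares each gene's |T_obs − null mean| with the
    permutation distribution of the maximum of that quantity across genes
    (inherently two-sided); ``bonferroni`` multiplies the pointwise p by the
    gene count. Adjusted p is floored at the pointwise p.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if fwe not in ("maxstat", "bonferroni"):
        raise ValueError(f"unknown FWE method {fwe!r}")
    norm_expr = np.asarray(norm_expr, dtype=float)
    admitted = np.array([a.sample_index for a in assignments
                         if a.cluster is not None])
    in_cluster = np.array([a.sample_index for a in assignments
                           if a.cluster == cluster_id])
    if in_cluster.size < 2 or admitted.size - in_cluster.size < 2:
        raise ValueError(
            f"degenerate cluster sizes: {in_cluster.size} in cluster "
            f"{cluster_id}, {admitted.size - in_cluster.size} outside"
        )
    m = in_cluster.size
    t_obs = norm_expr[:, in_cluster].mean(axis=1)

    rng = np.random.default_rng(seed)
    E = norm_expr[:, admitted]                   # genes x admitted
    keys = rng.random((n_perm, admitted.size))
    sel = np.argpartition(keys, m - 1, axis=1)[:, :m]
    ind = np.zeros((n_perm, admitted.size))
    np.put_along_axis(ind, sel, 1.0, axis=1)
    t_null = (ind @ E.T) / m                     # n_perm x genes

    p_hi = (1.0 + np.sum(t_null >= t_obs, axis=0)) / (n_perm + 1.0)
    p_lo = (1.0 + np.sum(t_null <= t_obs, axis=0)) / (n_perm + 1.0)
    if alternative == "greater":
        p = p_hi
    elif alternative == "less":
        p = p_lo
    else:
        p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))

    if fwe == "maxstat":
        mu = t_null.mean(axis=0)
        d_obs = np.abs(t_obs - mu)
        max_null = np.abs(t_null - mu).max(axis=1)
        p_fwe = (1.0 + np.sum(max_null[:, None] >= d_obs, axis=0)) / (n_perm + 1.0)
    else:
        p_fwe = np.minimum(1.0, p * len(gene_ids))
    p_fwe = np.maximum(p_fwe, p)

    return [
        GeneAssociation(g, float(t), float(pv), float(pf), bool(pf < alpha))
        for g, t, pv, pf in zip(gene_ids, t_obs, p, p_fwe)
    ]


def select_genes(
    associations: list[GeneAssociation], alpha: float = 0.05
) -> list[str]:
    """Gene ids with FWE-adjusted p below alpha, sorted by adjusted p."""
    hits = [a for a in associations if a.p_fwe < alpha]
    hits.sort(key=lambda a: (a.p_fwe, a.p_value, a.gene_id))
    return [a.gene_id for a in hits]
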