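"""Synthetic cohorts, atlases, expression datasets and gene sets.

Every downstream stage of the pipeline (prediction, lesion analysis,
transcriptomic annotation, enrichment) is testable against these generators
because they plant a known ground truth: which network carries the aging
signal, which genes are differentially expressed there, and which gene-set
term collects those genes. All generators are pure functions of their
parameters and a seed.

The default cohort emulates a healthy adult lifespan sample: 492 subjects
aged 19-80 whose regional gray-matter volumes decline linearly with age,
with network-specific slopes and noise, on a 246-ROI atlas partitioned into
17 networks. The default expression dataset emulates a six-donor postmortem
atlas with a few hundred spatially localized samples per donor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .enrichment import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "AtlasFixture",
    "Cohort",
    "CohortTruth",
    "ExpressionDataset",
    "ExpressionTruth",
    "generate_atlas",
    "generate_cohort",
    "generate_expression",
    "generate_gene_sets",
]

DEFAULT_GRID: tuple[int, int, int] = (32, 38, 32)
DEFAULT_VOXEL_MM = 1.5

#: Latent per-subject aging offset (years). Individual brains deviate from
#: their chronological age by a stable amount shared across all regions;
#: this bounds the achievable out-of-fold age-prediction correlation at
#: sd(age)/sqrt(sd(age)^2 + SUBJECT_SD^2) ~= 0.90 for a 19-80 uniform
#: age range, independent of per-ROI measurement noise.
DEFAULT_SUBJECT_SD = 8.5


@dataclass
class AtlasFixture:
    """A labelled parcellation on a regular 3-D grid.

    ``label_grid`` holds one positive integer per brain voxel (0 is
    background); ``network_of_roi`` assigns every ROI to exactly one
    network id in 1..n_networks.
    """

    label_grid: np.ndarray
    voxel_size_mm: float
    roi_ids: list[int]
    network_of_roi: dict[int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid, dtype=np.int32)
        present = set(np.unique(self.label_grid)) - {0}
        if not present <= set(self.roi_ids):
            raise ValueError("label grid contains labels not in roi_ids")
        if set(self.network_of_roi) != set(self.roi_ids):
            raise ValueError("network_of_roi must cover exactly roi_ids")
        for roi in self.roi_ids:
            if roi not in present:
                raise ValueError(f"ROI {roi} has no voxels")

    @property
    def n_networks(self) -> int:
        return max(self.network_of_roi.values())

    @property
    def mask(self) -> np.ndarray:
        return self.label_grid > 0

    def network_grid(self) -> np.ndarray:
        """Voxel grid of network ids (0 outside the brain mask)."""
        lut = np.zeros(max(self.roi_ids) + 1, dtype=np.int32)
        for roi, net in self.network_of_roi.items():
            lut[roi] = net
        return lut[self.label_grid]

    def rois_of_network(self, network_id: int) -> list[int]:
        return [r for r in self.roi_ids if self.network_of_roi[r] == network_id]


@dataclass
class CohortTruth:
    """Generating parameters of a synthetic cohort (the planted ground truth).

    ``network_slopes`` are mean GMV change per year of (latent) age for each
    network, in volume units; ``network_noise_sd`` the per-ROI residual sd.
    The ``important_network`` receives ``important_slope_factor`` times the
    slope and ``important_noise_factor`` times the noise of its base values,
    concentrating age information there. ``subject_sd`` is the sd of the
    per-subject latent aging offset in years; ``sex_effect`` shifts that
    offset (in years) for sex code 1.
    """

    network_slopes: np.ndarray
    network_noise_sd: np.ndarray
    important_network: int
    subject_sd: float = DEFAULT_SUBJECT_SD
    sex_effect: float = 0.0
    important_slope_factor: float = 5.0
    important_noise_factor: float = 0.4
    female_fraction: float = 306 / 492
    seed: int = 0

    def __post_init__(self) -> None:
        self.network_slopes = np.asarray(self.network_slopes, dtype=float)
        self.network_noise_sd = np.asarray(self.network_noise_sd, dtype=float)
        if self.network_slopes.shape != self.network_noise_sd.shape:
            raise ValueError("slopes and noise sds must have equal length")
        if np.any(self.network_noise_sd < 0):
            raise ValueError("noise sds must be non-negative")
        n_networks = len(self.network_slopes)
        if not 1 <= self.important_network <= n_networks:
            raise ValueError(
                f"important_network {self.important_network} outside 1..{n_networks}"
            )

    @classmethod
    def default(
        cls,
        n_networks: int = 17,
        important_network: int = 1,
        seed: int = 0,
        **overrides,
    ) -> "CohortTruth":
        """All-negative slopes (aging atrophy) with mild network variation.

        Base slopes are shallow relative to the per-ROI noise, so most of
        the age information sits in the important network (whose slope and
        noise the factors boost and shrink); every network's mean GMV still
        correlates clearly negatively with age.
        """
        rng = np.random.default_rng(seed)
        slopes = -(0.08 + 0.04 * rng.random(n_networks))  # units / year
        noise = np.full(n_networks, 8.0)  # volume units per ROI
        return cls(slopes, noise, important_network, seed=seed, **overrides)


@dataclass
class Cohort:
    """Per-subject phenotypes and the subjects x ROI mean-GMV matrix."""

    subject_ids: list[str]
    age: np.ndarray          # years
    sex: np.ndarray          # 0 = female, 1 = male
    tiv: np.ndarray          # ml
    gmv: np.ndarray          # (n_subjects, n_rois)
    roi_ids: list[int]

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        for name in ("age", "sex", "tiv"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,) or not np.all(np.isfinite(arr.astype(float))):
                raise ValueError(f"{name} must be finite with one value per subject")
        self.gmv = np.asarray(self.gmv, dtype=float)
        if self.gmv.shape != (n, len(self.roi_ids)):
            raise ValueError("gmv shape must be (n_subjects, n_rois)")
        if not np.all(np.isfinite(self.gmv)):
            raise ValueError("gmv contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass
class ExpressionTruth:
    """Planted ground truth of a synthetic expression dataset."""

    signal_gene_ids: list[str]
    target_network: int
    effect_size: float = 0.5  # shift in log-expression units
    seed: int = 0


@dataclass
class ExpressionDataset:
    """Multi-donor expression matrix with spatial sample coordinates.

    ``expr`` is genes x samples (linear scale, strictly positive);
    ``sample_world_coords`` are mm coordinates in the atlas world frame.
    ``sample_network`` records the generating network of each sample
    (0 = none) and exists only for synthetic data, as the recovery target.
    """

    donor_of_sample: list[str]
    sample_world_coords: np.ndarray  # (n_samples, 3)
    expr: np.ndarray                 # (n_genes, n_samples)
    gene_ids: list[str]
    sample_network: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = len(self.donor_of_sample)
        self.sample_world_coords = np.asarray(self.sample_world_coords, dtype=float)
        self.expr = np.asarray(self.expr, dtype=float)
        if self.sample_world_coords.shape != (s, 3):
            raise ValueError("sample_world_coords must be (n_samples, 3)")
        if self.expr.shape != (len(self.gene_ids), s):
            raise ValueError("expr must be (n_genes, n_samples)")
        if not np.all(np.isfinite(self.expr)):
            raise ValueError("expression contains non-finite values")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.donor_of_sample)


def _ellipsoid_mask(grid_shape: Sequence[int]) -> np.ndarray:
    """Brain-like ellipsoid inscribed in the grid (semi-axes 90% of half-extent)."""
    axes = [np.arange(s) - (s - 1) / 2 for s in grid_shape]
    semi = [0.9 * s / 2 for s in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2 <= 1.0


def generate_atlas(
    n_rois: int = 246,
    n_networks: int = 17,
    grid_shape: Sequence[int] = DEFAULT_GRID,
    voxel_size_mm: float = DEFAULT_VOXEL_MM,
    seed: int = 0,
) -> AtlasFixture:
    """Voronoi parcellation of an ellipsoid mask into compact ROIs.

    ROI seed voxels are drawn at random inside the mask and every mask voxel
    is assigned to its nearest seed; because Voronoi cells are convex their
    intersection with the ellipsoid is connected, giving compact contiguous
    parcels. Networks are assigned round-robin over a shuffled ROI order,
    balanced up to remainder.
    """
    if not (n_rois >= n_networks >= 1):
        raise ValueError("need n_rois >= n_networks >= 1")
    mask = _ellipsoid_mask(grid_shape)
    coords = np.argwhere(mask)
    if len(coords) < n_rois:
        raise ValueError(
            f"grid {tuple(grid_shape)} hosts only {len(coords)} mask voxels; "
            f"cannot place {n_rois} nonempty ROIs"
        )
    rng = np.random.default_rng(seed)
    seeds = coords[rng.choice(len(coords), size=n_rois, replace=False)]
    _, nearest = cKDTree(seeds).query(coords)
    label_grid = np.zeros(tuple(grid_shape), dtype=np.int32)
    label_grid[tuple(coords.T)] = nearest + 1  # ROI ids 1..n_rois

    roi_ids = list(range(1, n_rois + 1))
    order = rng.permutation(n_rois)
    network_of_roi = {
        roi_ids[idx]: (pos % n_networks) + 1 for pos, idx in enumerate(order)
    }

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.array(grid_shape) - 1) / 2
    return AtlasFixture(label_grid, voxel_size_mm, roi_ids, network_of_roi, affine)


def generate_cohort(
    atlas: AtlasFixture,
    n_subjects: int = 492,
    age_range: tuple[float, float] = (19.0, 80.0),
    truth: CohortTruth | None = None,
) -> Cohort:
    """Simulate a lifespan cohort with linear age-related GMV decline.

    For ROI j in network m(j):
        gmv_ij = b0_j + b1_j * (age_i + g_i + sex_effect * sex_i) + eps_ij
    with b1_j ~ N(slope_m, 0.05), eps_ij ~ N(0, noise_m^2) and a per-subject
    latent aging offset g_i ~ N(0, subject_sd^2) shared across ROIs. The
    important network gets boosted |slope| and shrunken noise. TIV is drawn
    independently of the GMV residuals.
    """
    lo, hi = age_range
    if not lo < hi:
        raise ValueError("age_range must satisfy lo < hi")
    if n_subjects < 10:
        raise ValueError(
            f"n_subjects={n_subjects} too small for cross-validated analysis"
        )
    if truth is None:
        truth = CohortTruth.default(atlas.n_networks)
    if len(truth.network_slopes) != atlas.n_networks:
        raise ValueError("truth slopes do not match the atlas network count")

    rng = np.random.default_rng(truth.seed)
    n_rois = len(atlas.roi_ids)
    net_idx = np.array([atlas.network_of_roi[r] - 1 for r in atlas.roi_ids])

    slopes = truth.network_slopes.copy()
    noise = truth.network_noise_sd.copy()
    imp = truth.important_network - 1
    slopes[imp] *= truth.important_slope_factor
    noise[imp] *= truth.important_noise_factor

    age = rng.uniform(lo, hi, size=n_subjects)
    sex = (rng.random(n_subjects) >= truth.female_fraction).astype(int)  # 1 = male
    tiv = rng.normal(1450.0, 110.0, size=n_subjects)
    g = rng.normal(0.0, truth.subject_sd, size=n_subjects) if truth.subject_sd > 0 \
        else np.zeros(n_subjects)

    b0 = rng.normal(600.0, 40.0, size=n_rois)
    b1 = rng.normal(slopes[net_idx], 0.05)
    latent_age = age + g + truth.sex_effect * sex
    eps = rng.normal(0.0, 1.0, size=(n_subjects, n_rois)) * noise[net_idx]
    gmv = b0 + np.outer(latent_age, b1) + eps

    ids = [f"sub-{i + 1:04d}" for i in range(n_subjects)]
    return Cohort(ids, age, sex, tiv, gmv, list(atlas.roi_ids))


def generate_expression(
    atlas: AtlasFixture,
    n_donors: int = 6,
    samples_per_donor_range: tuple[int, int] = (60, 150),
    n_genes: int = 500,
    truth: ExpressionTruth | None = None,
) -> ExpressionDataset:
    """Simulate a multi-donor spatial expression dataset.

    Samples sit at voxel centers drawn uniformly inside the atlas mask and
    belong to the network their 6-mm sphere maps to under the same
    sphere-overlap rule the annotation stage applies (majority of sphere
    voxels, >50% inside the mask), so the planted truth and the analysis
    agree on membership. Baseline expression per gene is lognormal
    (location 1, sd 0.25 on the log scale) with multiplicative sample noise;
    signal genes gain ``truth.effect_size`` log-units in samples of the
    target network. At full scale the per-donor count range is (363, 946).
    """
    if truth is None:
        truth = ExpressionTruth(
            signal_gene_ids=[f"gene-{i:05d}" for i in range(1, 26)],
            target_network=1,
        )
    gene_ids = [f"gene-{i:05d}" for i in range(1, n_genes + 1)]
    if not set(truth.signal_gene_ids) <= set(gene_ids):
        raise ValueError("signal_gene_ids must be a subset of the generated genes")
    if not 1 <= truth.target_network <= atlas.n_networks:
        raise ValueError(f"target network {truth.target_network} not in the atlas")
    net_grid = atlas.network_grid()
    if not np.any(net_grid == truth.target_network):
        raise ValueError(f"target network {truth.target_network} has no voxels")

    rng = np.random.default_rng(truth.seed)
    lo, hi = samples_per_donor_range
    counts = rng.integers(lo, hi + 1, size=n_donors)
    coords = np.argwhere(atlas.mask)

    donors: list[str] = []
    vox: list[np.ndarray] = []
    for d, c in enumerate(counts):
        pick = coords[rng.choice(len(coords), size=c, replace=True)]
        vox.append(pick)
        donors.extend([f"donor-{d + 1}"] * c)
    vox_all = np.vstack(vox)
    world = vox_all @ atlas.affine[:3, :3].T + atlas.affine[:3, 3]
    # function-level import: transcriptomics depends on this module's types
    from .transcriptomics import map_samples_to_clusters

    assignments = map_samples_to_clusters(
        world, atlas.mask, net_grid, atlas.affine,
        radius_mm=6.0, overlap_threshold=0.5,
    )
    sample_net = np.array([a.cluster if a.cluster is not None else 0
                           for a in assignments])

    n_samples = len(donors)
    log_base = rng.normal(1.0, 0.25, size=n_genes)
    log_expr = log_base[:, None] + rng.normal(0.0, 0.25, size=(n_genes, n_samples))
    sig_idx = np.array([gene_ids.index(g) for g in truth.signal_gene_ids], dtype=int)
    in_target = sample_net == truth.target_network
    if truth.effect_size != 0 and sig_idx.size:
        log_expr[np.ix_(sig_idx, np.flatnonzero(in_target))] += truth.effect_size

    return ExpressionDataset(
        donor_of_sample=donors,
        sample_world_coords=world,
        expr=np.exp(log_expr),
        gene_ids=gene_ids,
        sample_network=sample_net,
    )


def generate_gene_sets(
    gene_ids: Sequence[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 60),
    planted_term_from: Sequence[str] = (),
    seed: int = 0,
) -> list[GeneSet]:
    """Random gene sets over a universe, with one term planted on the signal.

    The first term contains every planted (signal) gene plus random padding
    up to the lower bound of the size range; the remaining terms are uniform
    draws from the universe.
    """
    universe = list(gene_ids)
    lo, hi = term_size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError("term sizes must satisfy 1 <= lo <= hi <= |universe|")
    if not set(planted_term_from) <= set(universe):
        raise ValueError("planted genes must be in the universe")
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    if planted_term_from:
        planted = list(planted_term_from)
        pad_n = max(0, lo - len(planted))
        pool = [g for g in universe if g not in set(planted)]
        pad = list(rng.choice(pool, size=pad_n, replace=False)) if pad_n else []
        sets.append(GeneSet("planted_term", "planted signal gene set",
                            tuple(planted + pad)))
    while len(sets) < n_terms:
        size = int(rng.integers(lo, hi + 1))
        members = tuple(rng.choice(universe, size=size, replace=False))
        sets.append(GeneSet(f"term_{len(sets):03d}", "random gene set", members))
    return sets
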