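"""Computational lesion analysis of brain networks.

How much does each brain network contribute to age prediction? Remove its
regions from the feature set, re-run the identical repeated cross-validation
(same fold partitions, same initialization), and compare the lesioned
age–prediction correlation with the full model's using Steiger's Z test for
two dependent correlations sharing one variable (here: chronological age
correlated with two alternative predictions). The sign convention is
Z = (z_full − z_lesioned)·…, so a positive Z means the lesion degraded
performance and large Z marks an important network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, pearsonr

from .brainage import make_folds, pearson_r, run_cv
from .features import GMVTable
from .synthetic_data import AtlasFixture, Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "LesionNetworkResult",
    "NetworkAgeCorrelation",
    "lesion_feature_set",
    "steiger_z",
    "z_to_p",
    "run_lesion_analysis",
    "network_age_correlations",
]


@dataclass
class LesionNetworkResult:
    """Importance of one network: correlations, Steiger Z and its p."""

    network_id: int
    n_rois_removed: int
    r_full: float
    r_lesioned: float
    r_pred: float          # correlation between full and lesioned predictions
    n: int
    z: float               # positive = lesion degrades performance
    p: float
    z_per_repeat_mean: float = np.nan


@dataclass
class NetworkAgeCorrelation:
    """Pearson correlation of a network's mean GMV with chronological age."""

    network_id: int
    r: float
    p: float


def lesion_feature_set(
    gmv_table: GMVTable,
    network_of_roi: dict[int, int],
    network_id: int,
) -> GMVTable:
    """Drop the columns of one network; remaining column order is preserved.

    A network id inside the valid range that owns no ROIs is a warned
    no-op; an id outside 1..max(network ids) is an error.
    """
    if not 1 <= network_id <= max(network_of_roi.values()):
        raise ValueError(f"network {network_id} not present in the assignment")
    keep = [r for r in gmv_table.roi_ids if network_of_roi.get(r) != network_id]
    removed = len(gmv_table.roi_ids) - len(keep)
    if removed == 0:
        logger.warning("network %d has no assigned ROIs; table unchanged",
                       network_id)
        return GMVTable(list(gmv_table.subject_ids), list(gmv_table.roi_ids),
                        gmv_table.values.copy())
    if not keep:
        raise ValueError(
            f"removing network {network_id} leaves no features"
        )
    cols = [gmv_table.roi_ids.index(r) for r in keep]
    return GMVTable(list(gmv_table.subject_ids), keep,
                    gmv_table.values[:, cols])


def steiger_z(r1: float, r2: float, r12: float, n: int) -> float:
    """Steiger's (1980) Z for two dependent correlations sharing one variable.

    ``r1`` and ``r2`` each correlate the shared variable (age) with one of
    two measurements whose mutual correlation is ``r12``. Uses the Fisher
    z-transform and the pooled-correlation covariance approximation:

        z_i = artanh(r_i),  r̄ = (r1 + r2)/2
        ψ̄ = r12(1 − 2r̄²) − ½ r̄²(1 − 2r̄² − r12²)
        c = ψ̄ / (1 − r̄²)²
        Z = (z1 − z2) · sqrt(n − 3) / sqrt(2 − 2c)

    Positive Z means r1 > r2.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name}={r} must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar = 0.5 * (r1 + r2)
    psi = r12 * (1.0 - 2.0 * rbar ** 2) - 0.5 * rbar ** 2 * (
        1.0 - 2.0 * rbar ** 2 - r12 ** 2
    )
    c = psi / (1.0 - rbar ** 2) ** 2
    if c >= 1.0:
        raise ValueError(f"degenerate correlation structure (c={c:.6f} >= 1)")
    return float((z1 - z2) * np.sqrt(n - 3) / np.sqrt(2.0 - 2.0 * c))


def z_to_p(z: float) -> float:
    """Two-tailed normal p-value: 2·(1 − Φ(|Z|))."""
    if not np.isfinite(z):
        raise ValueError("Z must be finite")
    return float(2.0 * norm.sf(abs(z)))


def run_lesion_analysis(
    cohort: Cohort,
    atlas: AtlasFixture,
    k: int = 10,
    repeats: int = 100,
    seed: int = 0,
    kernel: str = "linear",
    full_result=None,
) -> list[LesionNetworkResult]:
    """Score every network's importance, ranked by Z descending.

    The full model and every lesioned model share bit-identical fold
    partitions and the same hyperparameter initialization rule, so the only
    difference between runs is the removed feature group; lesioned
    hyperparameters are re-optimized (the lesioned model is re-trained).
    Z uses the per-subject mean out-of-fold predictions; a per-repeat mean Z
    is retained as a secondary summary. A precomputed ``full_result`` (from
    :func:`ageatlas.brainage.run_cv`, carrying its folds) can be supplied to
    avoid refitting the full model.
    """
    table = GMVTable(list(cohort.subject_ids), list(cohort.roi_ids), cohort.gmv)
    n = cohort.n_subjects
    if full_result is None:
        folds = make_folds(n, k, repeats, seed)
        full = run_cv(table.values, cohort.age, k=k, repeats=repeats, seed=seed,
                      kernel=kernel, folds=folds)
    else:
        full = full_result
        folds = full.folds

    results: list[LesionNetworkResult] = []
    for net in range(1, atlas.n_networks + 1):
        lesioned_table = lesion_feature_set(table, atlas.network_of_roi, net)
        removed = len(table.roi_ids) - len(lesioned_table.roi_ids)
        if removed == 0:
            results.append(LesionNetworkResult(
                network_id=net, n_rois_removed=0, r_full=full.r,
                r_lesioned=full.r, r_pred=1.0, n=n, z=0.0, p=1.0,
                z_per_repeat_mean=0.0,
            ))
            continue
        les = run_cv(lesioned_table.values, cohort.age, k=k, repeats=repeats,
                     seed=seed, kernel=kernel, folds=folds)
        r_full = full.r
        r_les = pearson_r(cohort.age, les.mean_prediction)
        r_pred = pearson_r(full.mean_prediction, les.mean_prediction)
        if np.allclose(full.mean_prediction, les.mean_prediction):
            z = 0.0
        else:
            z = steiger_z(r_full, r_les, r_pred, n)
        z_reps = []
        for pf, pl in zip(full.predictions, les.predictions):
            if np.allclose(pf, pl):
                z_reps.append(0.0)
            else:
                z_reps.append(steiger_z(
                    pearson_r(cohort.age, pf), pearson_r(cohort.age, pl),
                    pearson_r(pf, pl), n,
                ))
        results.append(LesionNetworkResult(
            network_id=net, n_rois_removed=removed, r_full=r_full,
            r_lesioned=r_les, r_pred=r_pred, n=n, z=z, p=z_to_p(z),
            z_per_repeat_mean=float(np.mean(z_reps)),
        ))
    results.sort(key=lambda r: r.z, reverse=True)
    return results


def network_age_correlations(
    cohort: Cohort, atlas: AtlasFixture
) -> list[NetworkAgeCorrelation]:
    """Pearson r (and p) between each network's mean GMV and chronological age."""
    if cohort.n_subjects < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    col_of_roi = {r: i for i, r in enumerate(cohort.roi_ids)}
    out: list[NetworkAgeCorrelation] = []
    for net in range(1, atlas.n_networks + 1):
        rois = atlas.rois_of_network(net)
        if not rois:
            raise ValueError(f"network {net} has no ROIs")
        mean_gmv = cohort.gmv[:, [col_of_roi[r] for r in rois]].mean(axis=1)
        r, p = pearsonr(cohort.age, mean_gmv)
        out.append(NetworkAgeCorrelation(net, float(r), float(p)))
    return out
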