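"""ROI feature extraction from voxelwise gray-matter maps.

Turns modulated gray-matter probability/volume maps plus a labelled atlas
into the subjects x ROI mean-GMV table consumed by the age predictor, and
computes total intracranial volume (TIV) from tissue maps. Maps must be on
the atlas grid already — no resampling is attempted; mismatches fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_data import AtlasFixture

__all__ = ["GMVTable", "extract_roi_means", "build_gmv_table", "compute_tiv"]


@dataclass
class GMVTable:
    """Subjects x ROI matrix of mean gray-matter volume per region."""

    subject_ids: list[str]
    roi_ids: list[int]
    values: np.ndarray  # (n_subjects, n_rois)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.roi_ids)):
            raise ValueError("values shape does not match subject/ROI ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GMV table contains non-finite values")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=[f"roi_{r}" for r in self.roi_ids],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GMVTable":
        roi_ids = [int(c.removeprefix("roi_")) for c in df.columns]
        return cls(list(df.index.astype(str)), roi_ids, df.to_numpy(dtype=float))


def extract_roi_means(gm_map: np.ndarray, atlas: AtlasFixture) -> np.ndarray:
    """Mean of the map over each atlas ROI, ordered as ``atlas.roi_ids``.

    An ROI with no voxels in the label grid is an atlas error, never a
    silent zero.
    """
    gm_map = np.asarray(gm_map, dtype=float)
    if gm_map.shape != atlas.label_grid.shape:
        raise ValueError(
            f"map grid {gm_map.shape} does not match atlas grid "
            f"{atlas.label_grid.shape}"
        )
    labels = atlas.label_grid.ravel()
    flat = gm_map.ravel()
    n_lab = labels.max() + 1
    sums = np.bincount(labels, weights=flat, minlength=n_lab)
    counts = np.bincount(labels, minlength=n_lab)
    means = np.empty(len(atlas.roi_ids))
    for j, roi in enumerate(atlas.roi_ids):
        if roi >= n_lab or counts[roi] == 0:
            raise ValueError(f"ROI {roi} has no voxels in the atlas grid")
        means[j] = sums[roi] / counts[roi]
    return means


def build_gmv_table(
    gm_maps: Sequence[np.ndarray],
    subject_ids: Sequence[str],
    atlas: AtlasFixture,
) -> GMVTable:
    """Stack per-subject ROI mean vectors into a GMVTable (input order kept)."""
    if len(gm_maps) != len(subject_ids):
        raise ValueError("number of maps and subject ids differ")
    values = np.vstack([extract_roi_means(m, atlas) for m in gm_maps])
    return GMVTable(list(map(str, subject_ids)), list(atlas.roi_ids), values)


def compute_tiv(
    gray: np.ndarray,
    white: np.ndarray,
    csf: np.ndarray,
    voxel_volume_mm3: float,
) -> float:
    """Total intracranial volume in ml: (sum of gray+white+CSF) x voxel volume."""
    maps = [np.asarray(m, dtype=float) for m in (gray, white, csf)]
    if not (maps[0].shape == maps[1].shape == maps[2].shape):
        raise ValueError("tissue maps must share a grid")
    for name, m in zip(("gray", "white", "csf"), maps):
        if np.any(m < 0):
            raise ValueError(f"{name} map contains negative tissue fractions")
    total_mm3 = float(sum(m.sum() for m in maps)) * float(voxel_volume_mm3)
    return total_mm3 / 1000.0  # mm^3 -> ml
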