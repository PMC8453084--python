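"""Readers and writers for the pipeline's on-disk formats.

Tables are tab-separated text with headers; images are NIfTI (plain or
gzipped) via nibabel; gene sets are GMT (see :mod:`ageatlas.enrichment`).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features import GMVTable
from .synthetic_data import AtlasFixture, Cohort, ExpressionDataset

__all__ = [
    "write_atlas",
    "read_atlas",
    "write_cohort",
    "read_cohort",
    "write_gmv_table",
    "read_gmv_table",
    "write_expression",
    "read_expression",
    "load_gm_map",
]


def write_atlas(atlas: AtlasFixture, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(atlas.label_grid.astype(np.int32), atlas.affine),
             out / "atlas_labels.nii.gz")
    nib.save(nib.Nifti1Image(atlas.mask.astype(np.uint8), atlas.affine),
             out / "brain_mask.nii.gz")
    pd.DataFrame({
        "roi_id": atlas.roi_ids,
        "network_id": [atlas.network_of_roi[r] for r in atlas.roi_ids],
    }).to_csv(out / "networks.tsv", sep="\t", index=False)


def read_atlas(out_dir: str | Path) -> AtlasFixture:
    out = Path(out_dir)
    img = nib.load(out / "atlas_labels.nii.gz")
    labels = np.asarray(img.dataobj, dtype=np.int32)
    nets = pd.read_csv(out / "networks.tsv", sep="\t")
    voxel = float(np.linalg.norm(img.affine[:3, 0]))
    return AtlasFixture(
        label_grid=labels,
        voxel_size_mm=voxel,
        roi_ids=[int(r) for r in nets["roi_id"]],
        network_of_roi=dict(zip(nets["roi_id"].astype(int),
                                nets["network_id"].astype(int))),
        affine=np.asarray(img.affine),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "subject_id": cohort.subject_ids,
        "age": cohort.age,
        "sex": cohort.sex,
        "tiv": cohort.tiv,
    }).to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    GMVTable(cohort.subject_ids, cohort.roi_ids, cohort.gmv) \
        .to_dataframe().to_csv(out / "gmv.tsv", sep="\t")


def read_cohort(out_dir: str | Path) -> Cohort:
    out = Path(out_dir)
    pheno = pd.read_csv(out / "phenotypes.tsv", sep="\t")
    table = read_gmv_table(out / "gmv.tsv")
    return Cohort(
        subject_ids=list(pheno["subject_id"].astype(str)),
        age=pheno["age"].to_numpy(float),
        sex=pheno["sex"].to_numpy(int),
        tiv=pheno["tiv"].to_numpy(float),
        gmv=table.values,
        roi_ids=table.roi_ids,
    )


def write_gmv_table(table: GMVTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t")


def read_gmv_table(path: str | Path) -> GMVTable:
    return GMVTable.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))


def write_expression(ds: ExpressionDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = [f"sample-{i + 1:05d}" for i in range(ds.n_samples)]
    pd.DataFrame(ds.expr, index=pd.Index(ds.gene_ids, name="gene_id"),
                 columns=samples).to_csv(out / "expression.tsv", sep="\t")
    meta = pd.DataFrame({
        "sample_id": samples,
        "donor_id": ds.donor_of_sample,
        "mni_x": ds.sample_world_coords[:, 0],
        "mni_y": ds.sample_world_coords[:, 1],
        "mni_z": ds.sample_world_coords[:, 2],
    })
    if ds.sample_network is not None:
        meta["network_truth"] = ds.sample_network
    meta.to_csv(out / "samples.tsv", sep="\t", index=False)


def read_expression(out_dir: str | Path) -> ExpressionDataset:
    out = Path(out_dir)
    expr = pd.read_csv(out / "expression.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(out / "samples.tsv", sep="\t")
    return ExpressionDataset(
        donor_of_sample=list(meta["donor_id"].astype(str)),
        sample_world_coords=meta[["mni_x", "mni_y", "mni_z"]].to_numpy(float),
        expr=expr.to_numpy(float),
        gene_ids=list(expr.index.astype(str)),
        sample_network=(meta["network_truth"].to_numpy(int)
                        if "network_truth" in meta else None),
    )


def load_gm_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a gray-matter map; returns (data, affine)."""
    img = nib.load(path)
    return np.asarray(img.dataobj, dtype=float), np.asarray(img.affine)
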