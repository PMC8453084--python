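import logging

import numpy as np
import pytest

import ageatlas as aa

# sphere-assignment ties are expected on coarse synthetic atlases; keep the
# test output readable
logging.getLogger("ageatlas.transcriptomics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_atlas() -> aa.AtlasFixture:
    """24 ROIs in 4 networks on a 16x18x16 grid — fast but structurally real."""
    return aa.generate_atlas(n_rois=24, n_networks=4, grid_shape=(16, 18, 16),
                             seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_atlas) -> aa.Cohort:
    truth = aa.CohortTruth.default(4, important_network=2, seed=5)
    return aa.generate_cohort(small_atlas, n_subjects=80, truth=truth)


@pytest.fixture(scope="session")
def paper_scale_atlas() -> aa.AtlasFixture:
    """246 ROIs / 17 networks on the default grid."""
    return aa.generate_atlas(n_rois=246, n_networks=17, seed=1)


@pytest.fixture(scope="session")
def expression_with_truth(paper_scale_atlas):
    truth = aa.ExpressionTruth(
        signal_gene_ids=[f"gene-{i:05d}" for i in range(1, 26)],
        target_network=1, effect_size=0.5, seed=3,
    )
    ds = aa.generate_expression(paper_scale_atlas, n_donors=6,
                                samples_per_donor_range=(60, 150),
                                n_genes=500, truth=truth)
    return ds, truth
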