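"""Shared fixtures: one synthetic study at the default toy scale.

The heavy objects (genome, methylomes, contact matrices) are generated once
per session at seed 1 and shared read-only across test modules.
"""

import numpy as np
import pytest

from fpscape import genomeseg as gs
from fpscape import hicstruct as hs
from fpscape import synthetic as syn

SEED = 1


@pytest.fixture(scope="session")
def cfg():
    return syn.SyntheticConfig()


@pytest.fixture(scope="session")
def study(cfg):
    """Genome + ground truth + classified genes at seed 1."""
    track, truth, genes = syn.generate_genome(cfg, seed=SEED)
    return track, truth, genes


@pytest.fixture(scope="session")
def annotation(cfg, study):
    track, truth, _ = study
    return gs.annotate_bins(track, truth.domains, cfg.resolution)


@pytest.fixture(scope="session")
def methylomes(study):
    track, truth, _ = study
    normal = syn.generate_methylome(track, truth, "normal", seed=SEED)
    cancer = syn.generate_methylome(track, truth, "stage3", seed=SEED)
    return normal, cancer


@pytest.fixture(scope="session")
def open_sea(study):
    track, _, _ = study
    return gs.define_open_sea(track)


@pytest.fixture(scope="session")
def matrices(study):
    """Preprocessed normal and cancer contact matrices (full phenotype)."""
    track, truth, _ = study
    cm_n = syn.generate_contact_matrix(track, truth, "normal", seed=SEED)
    cm_c = syn.generate_contact_matrix(track, truth, "stage3", seed=SEED)
    return hs.preprocess(cm_n), hs.preprocess(cm_c)


def toy_matrix(values, resolution=40_000, chrom="chr1", arm_split=0):
    """Wrap a dense array as a balanced single-chromosome ContactMatrix."""
    mat = np.asarray(values, dtype=float)
    return hs.ContactMatrix(
        resolution=resolution,
        matrices={chrom: mat},
        bin_mask={chrom: np.zeros(len(mat), dtype=bool)},
        balanced=True,
        arm_split={chrom: arm_split} if arm_split else {},
    )
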