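"""Shared fixtures: rendered microtissues with known ground truth.

The expensive renders are session-scoped so the segmentation,
quantification, and acceptance tests reuse them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isletmt import synthetic as syn
from isletmt.pipeline import detect_spheroid, segment_nuclei

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@dataclass
class RenderedMT:
    """A rendered microtissue plus everything needed to check it."""

    truth: list[syn.GroundTruthCell]
    optics: syn.OpticsConfig
    phenotype: syn.PhenotypeModel
    spheroid_radius: float
    stack_shape: tuple[int, int, int]
    stacks: dict

    @property
    def voxel_size(self):
        return self.optics.voxel_size

    def true_centroid_label(self, labels: np.ndarray, cell) -> int:
        """Label value at a ground-truth cell center (stack frame)."""
        vox = np.array(self.voxel_size)
        ext = np.array(self.stack_shape) * vox
        zyx = (np.array([cell.center[2], cell.center[1], cell.center[0]]) + ext / 2) / vox
        idx = tuple(np.clip(zyx.astype(int), 0, np.array(self.stack_shape) - 1))
        return int(labels[idx])


def make_mt(seed: int, n_cells: int = 200, spheroid_radius: float = 40.0,
            phenotype: syn.PhenotypeModel | None = None,
            optics: syn.OpticsConfig | None = None,
            packing_tolerance: float = 1.0) -> RenderedMT:
    phenotype = phenotype or syn.PhenotypeModel()
    optics = optics or syn.OpticsConfig()
    geom = syn.generate_spheroid_geometry(
        n_cells, spheroid_radius, seed=seed, packing_tolerance=packing_tolerance)
    truth = syn.assign_phenotypes(geom, phenotype, seed=seed + 1)
    shape = syn.default_stack_shape(spheroid_radius, optics)
    stacks = syn.render_stack(
        truth, optics, shape, seed=seed + 2,
        spheroid=(spheroid_radius, {"dapi": phenotype.dapi_interstitial}))
    return RenderedMT(truth=truth, optics=optics, phenotype=phenotype,
                      spheroid_radius=spheroid_radius, stack_shape=shape,
                      stacks=stacks)


@pytest.fixture(scope="session")
def default_mt() -> RenderedMT:
    """Default synthetic microtissue: 200 nuclei, 40 µm radius, default
    generator and optics settings (the study conditions)."""
    return make_mt(seed=101)


@pytest.fixture(scope="session")
def default_mt_segmented(default_mt):
    spheroid = detect_spheroid(default_mt.stacks["dapi"])
    nuclei = segment_nuclei(default_mt.stacks["dapi"], spheroid)
    return default_mt, spheroid, nuclei


@pytest.fixture(scope="session")
def high_contrast_mt() -> RenderedMT:
    """Classification fixture: β amplitude >= 10x the non-β floor, default
    noise, nuclei kept from touching, and proliferation rates high enough
    that the proliferating-β class is well populated."""
    phenotype = syn.PhenotypeModel(prolif_rate_beta=0.15, prolif_rate_nonbeta=0.10,
                                   nkx_cv_beta=0.25)
    return make_mt(seed=101, phenotype=phenotype, packing_tolerance=1.2)


@pytest.fixture(scope="session")
def high_contrast_mt_segmented(high_contrast_mt):
    spheroid = detect_spheroid(high_contrast_mt.stacks["dapi"])
    nuclei = segment_nuclei(high_contrast_mt.stacks["dapi"], spheroid)
    return high_contrast_mt, spheroid, nuclei


@pytest.fixture(scope="session")
def sparse_mt() -> RenderedMT:
    """High-SNR microtissue of 50 well-separated nuclei (center spacing
    >= 4x nucleus radius): every nucleus should be found exactly once."""
    optics = syn.OpticsConfig(photon_scale=50.0, noise_gaussian_sd=0.5)
    phenotype = syn.PhenotypeModel(
        prolif_rate_beta=0.3, prolif_rate_nonbeta=0.3, nkx_cv_beta=0.2)
    return make_mt(seed=202, n_cells=50, phenotype=phenotype, optics=optics,
                   packing_tolerance=2.0)


@pytest.fixture(scope="session")
def sparse_mt_segmented(sparse_mt):
    spheroid = detect_spheroid(sparse_mt.stacks["dapi"])
    nuclei = segment_nuclei(sparse_mt.stacks["dapi"], spheroid)
    return sparse_mt, spheroid, nuclei
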