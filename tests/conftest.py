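"""Shared fixtures: small phantoms and libraries, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from snipegrade.grading import PatchConfig
from snipegrade.phantom import (
    PhantomSpec,
    SeverityProfile,
    make_structure_volume,
    make_template,
    make_template_library,
)


@pytest.fixture(scope="session")
def spec64() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def spec32() -> PhantomSpec:
    return PhantomSpec(grid_extent=32, noise_sigma=0.05)


@pytest.fixture(scope="session")
def library32(spec32):
    return make_template_library(3, 2, spec32, seed=2)


@pytest.fixture(scope="session")
def library64(spec64):
    return make_template_library(6, 6, spec64, seed=14)


@pytest.fixture(scope="session")
def template64(spec64):
    return make_template(spec64)


@pytest.fixture(scope="session")
def anatomy64(spec64):
    """A mid-severity anatomy with jitter, fixed seed."""
    return make_structure_volume(spec64, 0.4, np.random.default_rng(99))


@pytest.fixture()
def toy_cfg() -> PatchConfig:
    return PatchConfig(patch_radius=2, search_radius=1, preselection=False)


@pytest.fixture(scope="session")
def fast_cfg() -> PatchConfig:
    return PatchConfig(patch_radius=3, search_radius=1)


def make_toy_library(
    n_cn: int = 2,
    n_ad: int = 2,
    shape: tuple[int, int, int] = (16, 16, 16),
    seed: int = 0,
):
    """Hand-built random smooth toy library on tiny grids (engine tests)."""
    import scipy.ndimage as ndi

    from snipegrade.phantom import TemplateLibrary

    rng = np.random.default_rng(seed)
    intensities, labels, masks, tags = [], [], [], []
    for k in range(n_cn + n_ad):
        img = ndi.gaussian_filter(rng.normal(50, 20, shape), 1.5)
        img += rng.normal(0, 1.0, shape)
        lab = np.zeros(shape, dtype=np.int16)
        # a random ellipsoidal blob labeled 1, rest background
        c = rng.uniform(5, 11, 3)
        r = rng.uniform(3, 5, 3)
        ii, jj, kk = np.ogrid[: shape[0], : shape[1], : shape[2]]
        lab[
            ((ii - c[0]) / r[0]) ** 2
            + ((jj - c[1]) / r[1]) ** 2
            + ((kk - c[2]) / r[2]) ** 2
            <= 1
        ] = 1
        intensities.append(img.astype(np.float32))
        labels.append(lab)
        masks.append(np.ones(shape, dtype=bool))
        tags.append(1 if k < n_cn else 2)
    return TemplateLibrary(
        intensities=intensities,
        labels=labels,
        brain_masks=masks,
        group_tags=np.array(tags, dtype=np.int64),
        severities=np.zeros(n_cn + n_ad),
    )
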