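"""Shared fixtures: small tissue phantoms with planted anatomy."""

import pytest

from spatialviz.io_formats import AnalysisConfig
from spatialviz.synthetic_fixtures import (
    Band,
    MarkerProfile,
    Region,
    TissuePhantomSpec,
    generate_phantom,
)


def two_region_spec(seed: int = 7, size: int = 200, noise_sd: float = 0.0,
                    markers_per_region: int = 2) -> TissuePhantomSpec:
    """Two disjoint vertical bands; half the markers enriched in each."""
    gap = size // 20
    half = size // 2
    names = "ABCDEFGH"
    profiles = []
    for i in range(markers_per_region):
        profiles.append(MarkerProfile(names[i], 5.0, {1: 100.0 + 10 * i}))
    for i in range(markers_per_region):
        profiles.append(MarkerProfile(names[markers_per_region + i], 5.0,
                                      {2: 95.0 + 10 * i}))
    return TissuePhantomSpec(
        image_size=(size, size),
        regions=[
            Region(1, Band("col", 0, half - gap)),
            Region(2, Band("col", half + gap, size)),
        ],
        marker_profiles=profiles,
        cell_density={1: 4.0, 2: 4.0},
        cell_radius_px=3.0,
        intensity_noise_sd=noise_sd,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def phantom():
    """A 200x200 noise-free two-region phantom (stack, mask, cells, truth)."""
    return generate_phantom(two_region_spec())


@pytest.fixture()
def config():
    return AnalysisConfig(rng_seed=0)
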