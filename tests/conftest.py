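"""Shared fixtures: small phantoms and template libraries.

Everything is generated programmatically from fixed seeds; no data files.
"""
from __future__ import annotations

import numpy as np
import pytest

from mtlseg.imaging import LabelVolume, Volume3D
from mtlseg.library import build_library, build_template
from mtlseg.synthetic import PhantomSpec, make_phantom

LEVEL = 3  # 162 vertices per structure keeps the suite fast


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return PhantomSpec(level=LEVEL)


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    """One deterministic phantom: (volume, label, surface)."""
    return make_phantom(phantom_spec, seed=7)


@pytest.fixture(scope="session")
def small_library(phantom_spec):
    """Six-template library with subsampled features (fast profile)."""
    templates = []
    for i in range(6):
        vol, lab, surf = make_phantom(phantom_spec, seed=100 + i)
        templates.append(
            build_template(f"t{i:02d}", vol, lab, level=LEVEL, surface=surf,
                           max_samples_per_radius=150, fast_inside=True,
                           check_voxelization=False)
        )
    return build_library(templates)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture()
def random_volume(rng) -> Volume3D:
    return Volume3D(data=rng.normal(100.0, 10.0, size=(16, 16, 16)))


def ball_label(radius_mm: float = 6.0, shape=(32, 32, 32), code: int = 1,
               center=None) -> LabelVolume:
    """Analytic ball rasterized on a 1 mm grid (single-structure label)."""
    center = np.asarray(center if center is not None
                        else (np.asarray(shape) - 1) / 2.0, dtype=float)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij")
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    data = np.where(dist2 <= radius_mm**2, code, 0).astype(np.int16)
    return LabelVolume(data=data)
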