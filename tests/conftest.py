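"""Shared fixtures: small synthetic scenes and patch sets.

Unit tests use a 512x512 canvas at 20x (one full patch) so each scene
renders in well under a second; end-to-end tests build their own larger
datasets.
"""

from __future__ import annotations

import numpy as np
import pytest

from fibrostage.synthetic import SceneSpec, generate_scene, SCORES


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    return SceneSpec(width_px=512, height_px=512, seed=11)


@pytest.fixture(scope="session")
def scene_cache(small_spec):
    """Lazily rendered (score, seed) -> (image, ground truth) cache."""
    cache: dict = {}

    def get(score: str, seed: int = 11, spec: SceneSpec | None = None):
        import dataclasses

        base = spec or small_spec
        key = (score, seed, base.width_px, base.magnification)
        if key not in cache:
            cache[key] = generate_scene(
                score, dataclasses.replace(base, seed=seed)
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def all_scores():
    return SCORES


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
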