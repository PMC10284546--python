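"""Shared fixtures: small random codebooks and session-scoped trained maps.

The two SOM training runs (spec-default grid and a fixed 12x12 grid, both
on the default synthetic object space) are expensive relative to everything
else, so they are trained once per session and shared by every test that
needs a realistic trained map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import somtopo as st

SEED = 11


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_codebook(rng, W=5, H=4, F=7) -> st.Codebook:
    return st.Codebook(rng.standard_normal((W, H, F)))


@pytest.fixture
def small_codebook(rng) -> st.Codebook:
    return random_codebook(rng)


@pytest.fixture(scope="session")
def object_space():
    """Default synthetic object space: 960 samples, 256-D, planted 2x2."""
    fm, labels = st.generate_object_space(st.SynthConfig(seed=SEED))
    return fm, labels


@pytest.fixture(scope="session")
def trained_default(object_space):
    """SOM trained at spec defaults (400 units requested) on the object space."""
    fm, _ = object_space
    cfg = st.TrainConfig(seed=SEED)
    codebook, trace = st.train_som(fm.values, cfg)
    return codebook, trace, cfg


@pytest.fixture(scope="session")
def trained_12(object_space):
    """SOM trained on a fixed 12x12 grid on the object space."""
    fm, _ = object_space
    cfg = st.TrainConfig(seed=SEED, grid_shape=(12, 12))
    codebook, trace = st.train_som(fm.values, cfg)
    return codebook, trace, cfg


def tiny_labels(categories, n_per, animacy=None, size=None) -> pd.DataFrame:
    """Label table for synthetic toy designs."""
    rows = []
    for c in categories:
        for j in range(n_per):
            rows.append(
                {
                    "image_id": f"{c}_{j}",
                    "category": c,
                    "animacy": (animacy or {}).get(c, "animate"),
                    "size": (size or {}).get(c, "big"),
                    "split": "probe",
                }
            )
    return pd.DataFrame(rows)
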