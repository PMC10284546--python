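"""Synthetic object-space embeddings with planted animacy/size structure.

Emulates the statistical shape of a rectified CNN penultimate-layer
embedding over a 2 x 2 stimulus design (animate/inanimate x big/small):
nonnegative high-dimensional vectors whose dominant variance is spanned by
two latent factor axes (animacy and real-world size), with per-category
cluster structure and, nested inside the animate and inanimate zones, tight
focal clusters standing in for face- and scene-like categories. The
generator is the test bed for the whole pipeline: every planted property
(factor axes, category centroids, focal clusters) is recoverable by
construction, so map-training and map-statistics code can be validated
end to end without any pretrained network or image download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureMatrix

__all__ = [
    "FocalCategory",
    "SynthConfig",
    "generate_object_space",
    "generate_planar_manifold",
]

ANIMACY_LEVELS = ("animate", "inanimate")
SIZE_LEVELS = ("big", "small")
# cell order used when distributing categories over the 2 x 2 design
_CELLS = [
    ("animate", "big"),
    ("animate", "small"),
    ("inanimate", "big"),
    ("inanimate", "small"),
]


@dataclass(frozen=True)
class FocalCategory:
    """A tight category cluster nested inside one animacy x size cell."""

    label: str
    animacy: str
    size: str
    tightness: float

    def __post_init__(self) -> None:
        if self.animacy not in ANIMACY_LEVELS:
            raise ValueError(f"animacy must be one of {ANIMACY_LEVELS}")
        if self.size not in SIZE_LEVELS:
            raise ValueError(f"size must be one of {SIZE_LEVELS}")
        if self.tightness < 0:
            raise ValueError("tightness must be >= 0")


def _default_focal() -> list[FocalCategory]:
    return [
        FocalCategory("faces", "animate", "small", tightness=0.25),
        FocalCategory("scenes", "inanimate", "big", tightness=0.25),
    ]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic object space.

    Defaults produce 16 categories x 60 images = 960 samples in 256
    dimensions: 14 generic categories balanced over the four
    animacy x size cells plus the two focal clusters ("faces" in the
    animate/small cell, "scenes" in the inanimate/big cell).

    ``factor_gain_animacy`` / ``factor_gain_size`` set the half-separation
    of the two planted factor axes (animate vs inanimate, big vs small);
    ``category_spread`` is the sd of isotropic category-centroid offsets
    around the cell centers; ``image_noise_sd`` the within-category
    isotropic image noise; ``baseline_level`` lifts all coordinates so
    that the nonnegative clipping applied after noise (mimicking a
    rectified embedding) stays mild.
    """

    feature_dim: int = 256
    n_categories: int = 16
    images_per_category: int = 60
    factor_gain_animacy: float = 4.0
    factor_gain_size: float = 3.5
    category_spread: float = 1.0
    image_noise_sd: float = 0.5
    baseline_level: float = 3.0
    focal_categories: tuple[FocalCategory, ...] = field(
        default_factory=lambda: tuple(_default_focal())
    )
    nonneg_clip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_dim < 3:
            raise ValueError("feature_dim must be >= 3 to place orthogonal axes plus noise")
        if self.n_categories < 1 or self.images_per_category < 1:
            raise ValueError("category and image counts must be positive")
        for v in (
            self.factor_gain_animacy,
            self.factor_gain_size,
            self.category_spread,
            self.image_noise_sd,
            self.baseline_level,
        ):
            if v < 0:
                raise ValueError("gains, spreads, and sds must be >= 0")
        for f in self.focal_categories:
            if self.category_spread > 0 and f.tightness >= self.category_spread:
                raise ValueError("focal tightness must be below category_spread")
        if len(self.focal_categories) > self.n_categories:
            raise ValueError("more focal categories than total categories")

    def to_dict(self) -> dict:
        return {
            "feature_dim": self.feature_dim,
            "n_categories": self.n_categories,
            "images_per_category": self.images_per_category,
            "factor_gain_animacy": self.factor_gain_animacy,
            "factor_gain_size": self.factor_gain_size,
            "category_spread": self.category_spread,
            "image_noise_sd": self.image_noise_sd,
            "baseline_level": self.baseline_level,
            "focal_categories": [
                {"label": f.label, "animacy": f.animacy, "size": f.size, "tightness": f.tightness}
                for f in self.focal_categories
            ],
            "nonneg_clip": self.nonneg_clip,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        focal = d.pop("focal_categories", None)
        if focal is not None:
            d["focal_categories"] = tuple(FocalCategory(**f) for f in focal)
        return cls(**d)


def _orthonormal_pair(rng: np.random.Generator, dim: int) -> tuple[np.ndarray, np.ndarray]:
    q, _ = np.linalg.qr(rng.standard_normal((dim, 2)))
    return q[:, 0].copy(), q[:, 1].copy()


def _category_plan(config: SynthConfig) -> list[tuple[str, str, str, float]]:
    """(label, animacy, size, offset_sd) for every category, focal included.

    Generic categories fill each cell's quota (n_categories split as
    evenly as possible over the four cells) after reserving slots for
    the focal categories assigned to that cell.
    """
    quota = {
        cell: config.n_categories // 4 + (1 if i < config.n_categories % 4 else 0)
        for i, cell in enumerate(_CELLS)
    }
    for f in config.focal_categories:
        cell = (f.animacy, f.size)
        if quota.get(cell, 0) <= 0:
            raise ValueError(f"no category slot left in cell {cell} for focal '{f.label}'")
        quota[cell] -= 1

    plan: list[tuple[str, str, str, float]] = []
    k = 0
    for cell in _CELLS:
        for _ in range(quota[cell]):
            plan.append((f"cat{k:02d}", cell[0], cell[1], config.category_spread))
            k += 1
    for f in config.focal_categories:
        plan.append((f.label, f.animacy, f.size, f.tightness))
    return plan


def generate_object_space(config: SynthConfig) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Draw a feature matrix and label table with planted 2 x 2 structure.

    Two random orthonormal axes ``u_anim`` and ``u_size`` are drawn in
    feature space; each category centroid sits at
    ``baseline + a_c * g_a * u_anim + s_c * g_s * u_size + offset`` with
    signs ``a_c, s_c = +1`` for animate/big and ``-1`` for
    inanimate/small, and an isotropic offset (sd ``category_spread``, or
    the focal tightness). Images add isotropic noise (sd
    ``image_noise_sd``); negative entries are clipped to 0 when
    ``nonneg_clip`` is set. Fully determined by ``config.seed``.

    Returns the feature matrix and a label table with columns
    ``image_id, category, animacy, size, split``. The planted axes and
    exact (pre-noise) centroids are attached as ``FeatureMatrix.meta``.
    """
    rng = np.random.default_rng(config.seed)
    F = config.feature_dim
    u_anim, u_size = _orthonormal_pair(rng, F)
    base = np.full(F, config.baseline_level)

    plan = _category_plan(config)
    blocks, rows = [], []
    centroids = {}
    for label, animacy, size, offset_sd in plan:
        a_c = 1.0 if animacy == "animate" else -1.0
        s_c = 1.0 if size == "big" else -1.0
        offset = rng.normal(0.0, offset_sd, F) if offset_sd > 0 else np.zeros(F)
        centroid = (
            base
            + a_c * config.factor_gain_animacy * u_anim
            + s_c * config.factor_gain_size * u_size
            + offset
        )
        centroids[label] = centroid
        m = config.images_per_category
        images = centroid + rng.normal(0.0, config.image_noise_sd, (m, F))
        blocks.append(images)
        for j in range(m):
            rows.append(
                {
                    "image_id": f"{label}_{j:03d}",
                    "category": label,
                    "animacy": animacy,
                    "size": size,
                    "split": "train-manifold",
                }
            )
    values = np.vstack(blocks)
    if config.nonneg_clip:
        np.clip(values, 0.0, None, out=values)
    labels = pd.DataFrame(rows)
    fm = FeatureMatrix(ids=labels["image_id"].to_numpy(), values=values)
    fm.meta = {
        "u_anim": u_anim,
        "u_size": u_size,
        "centroids": centroids,
        "baseline": base,
    }
    return fm, labels


def generate_planar_manifold(
    n_points: int,
    feature_dim: int,
    seed: int = 0,
    jitter_sd: float | None = None,
    extent: tuple[float, float] = (2.0, 1.0),
) -> np.ndarray:
    """Points uniform on a 2D rectangle embedded in high dimensions.

    The rectangle (side lengths ``extent``) is carried into
    ``feature_dim`` dimensions by a random orthonormal pair; a tiny
    isotropic off-plane jitter (default sd = 1e-3 x the larger extent)
    keeps the sample full-rank without disturbing its planar geometry.
    Used as a fixture with known topology: a SOM trained on it should
    recover the 2D ordering.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    rng = np.random.default_rng(seed)
    u1, u2 = _orthonormal_pair(rng, feature_dim)
    if jitter_sd is None:
        jitter_sd = 1e-3 * max(extent)
    a = rng.uniform(0.0, extent[0], n_points)
    b = rng.uniform(0.0, extent[1], n_points)
    points = a[:, None] * u1 + b[:, None] * u2
    if jitter_sd > 0:
        points = points + rng.normal(0.0, jitter_sd, (n_points, feature_dim))
    return points
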