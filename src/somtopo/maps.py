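"""Spatial activation, preference, and selectivity maps over a trained SOM.

A trained codebook turns any probe feature vector into a spatial activation
profile (per-unit dot product with the unit's tuning vector). Averaging
activations within labelled conditions yields preference maps (which
condition wins on each unit, and by how much) and selectivity maps (d-prime
or a mean-normalized selectivity index for a target category against the
remaining images), mirroring standard fMRI localizer-contrast practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .som import Codebook

__all__ = [
    "ActivationMap",
    "ConditionStats",
    "PreferenceMap",
    "SelectivityMap",
    "activation_map",
    "condition_stats",
    "preference_map",
    "dprime_map",
    "si_map",
    "nonuniformity_score",
    "top_unit",
]


@dataclass
class ActivationMap:
    """One probe image's activation on every map unit, shape (W, H)."""

    values: np.ndarray
    image_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a W x H grid")
        if not np.isfinite(self.values).all():
            raise ValueError("activation values must be finite")


@dataclass
class ConditionStats:
    """Per-condition, per-unit activation moments.

    ``mean`` and ``var`` have shape (n_conditions, W, H); ``var`` is the
    unbiased (n-1) estimator. ``n_images`` gives the per-condition image
    count.
    """

    conditions: list[str]
    mean: np.ndarray
    var: np.ndarray
    n_images: dict[str, int]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.var = np.asarray(self.var, dtype=np.float64)
        if self.mean.shape != self.var.shape:
            raise ValueError("mean and var shapes differ")
        if self.mean.shape[0] != len(self.conditions):
            raise ValueError("first axis must index conditions")
        if (self.var < 0).any():
            raise ValueError("variances must be nonnegative")


@dataclass
class PreferenceMap:
    """Winning condition and winning margin per unit.

    ``preferred`` holds condition indices into ``conditions`` (shape W x H);
    ``strength`` is the absolute margin of the winner over the runner-up.
    Exact winner ties resolve toward the earlier condition in the list and
    are flagged in ``tie``.
    """

    preferred: np.ndarray
    strength: np.ndarray
    conditions: list[str]
    mode: str
    tie: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tie is None:
            self.tie = np.zeros(self.preferred.shape, dtype=bool)
        if self.preferred.shape != self.strength.shape:
            raise ValueError("preferred and strength shapes differ")
        if (self.strength < 0).any():
            raise ValueError("strength must be nonnegative")

    def labels(self) -> np.ndarray:
        """(W, H) array of winning condition labels."""
        return np.asarray(self.conditions, dtype=object)[self.preferred]


@dataclass
class SelectivityMap:
    """Per-unit selectivity of a target condition versus the rest.

    ``scores`` is (W, H); units where the metric's denominator vanishes
    are NaN with ``defined`` False — never silently coerced to 0.
    """

    scores: np.ndarray
    metric: str
    target_condition: str
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.defined is None:
            self.defined = np.isfinite(self.scores)
        if self.defined.shape != self.scores.shape:
            raise ValueError("defined mask shape mismatch")

    @property
    def all_defined(self) -> bool:
        return bool(self.defined.all())


# --------------------------------------------------------------------------
# activations
# --------------------------------------------------------------------------


def activation_map(codebook: Codebook, x: np.ndarray, image_id: str | None = None) -> ActivationMap:
    """Per-unit dot product of tuning with ``x`` — no normalization."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (codebook.feature_dim_F,):
        raise ValueError("feature vector length does not match codebook F")
    return ActivationMap(codebook.tuning @ x, image_id=image_id)


def _activations(codebook: Codebook, features: np.ndarray) -> np.ndarray:
    """All probe activations at once, shape (n_images, W, H)."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != codebook.feature_dim_F:
        raise ValueError("features must be (n, F) matching the codebook")
    acts = features @ codebook.flat().T  # (n, n_units)
    return acts.reshape(features.shape[0], codebook.grid_width_W, codebook.grid_height_H)


def _condition_labels(labels: pd.DataFrame, grouping: str, n: int) -> np.ndarray:
    if grouping not in labels.columns:
        raise ValueError(f"grouping column '{grouping}' missing from labels")
    col = labels[grouping]
    if len(col) != n:
        raise ValueError("label table length does not match feature count")
    if col.isna().any():
        raise ValueError(f"missing values in grouping column '{grouping}'")
    return col.to_numpy()


def condition_stats(
    codebook: Codebook,
    features: np.ndarray,
    labels: pd.DataFrame,
    grouping: str,
) -> ConditionStats:
    """Per-unit mean and unbiased variance of activation, per condition.

    ``grouping`` names a column of the label table (e.g. ``"animacy"`` or
    ``"category"``); every condition needs at least 2 images for the
    variance.
    """
    acts = _activations(codebook, features)
    cond = _condition_labels(labels, grouping, acts.shape[0])
    conditions = sorted(map(str, pd.unique(cond)))
    means, vars_, n_images = [], [], {}
    for c in conditions:
        mask = cond.astype(str) == c
        n_c = int(mask.sum())
        if n_c < 2:
            raise ValueError(f"condition '{c}' has {n_c} image(s); need >= 2 for variance")
        sub = acts[mask]
        means.append(sub.mean(axis=0))
        vars_.append(sub.var(axis=0, ddof=1))
        n_images[c] = n_c
    return ConditionStats(
        conditions=conditions,
        mean=np.stack(means),
        var=np.stack(vars_),
        n_images=n_images,
    )


# --------------------------------------------------------------------------
# preference maps
# --------------------------------------------------------------------------


def preference_map(
    stats: ConditionStats, conditions: list[str] | None = None
) -> PreferenceMap:
    """Winning condition per unit, with the margin over the runner-up.

    For two conditions the strength is the absolute difference of the two
    mean activations; for n-way contrasts it is the absolute difference
    between the preferred and second-most-activating condition.
    """
    if conditions is None:
        conditions = list(stats.conditions)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    idx = [stats.conditions.index(c) for c in conditions]
    means = stats.mean[idx]  # (C, W, H)
    winner = means.argmax(axis=0)  # first max: ties to earlier condition
    order = np.sort(means, axis=0)
    strength = np.abs(order[-1] - order[-2])
    tie = order[-1] == order[-2]
    return PreferenceMap(
        preferred=winner,
        strength=strength,
        conditions=list(conditions),
        mode="two-way" if len(conditions) == 2 else "n-way",
        tie=tie,
    )


# --------------------------------------------------------------------------
# selectivity maps
# --------------------------------------------------------------------------


def _target_rest_moments(
    codebook: Codebook,
    features: np.ndarray,
    labels: pd.DataFrame,
    target: str,
    grouping: str,
    exclude: list[str] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    acts = _activations(codebook, features)
    cond = _condition_labels(labels, grouping, acts.shape[0]).astype(str)
    tmask = cond == target
    rmask = ~tmask
    if exclude:
        rmask &= ~np.isin(cond, list(exclude))
    if tmask.sum() < 2:
        raise ValueError(f"target condition '{target}' needs >= 2 images")
    if rmask.sum() < 2:
        raise ValueError("non-target pool needs >= 2 images")
    t, r = acts[tmask], acts[rmask]
    return t.mean(axis=0), t.var(axis=0, ddof=1), r.mean(axis=0), r.var(axis=0, ddof=1)


def dprime_map(
    codebook: Codebook,
    features: np.ndarray,
    labels: pd.DataFrame,
    target: str,
    grouping: str = "category",
    exclude: list[str] | None = None,
) -> SelectivityMap:
    """Pooled-variance standardized contrast of target vs remaining images.

    d' = (mean_target - mean_rest) / sqrt((var_target + var_rest) / 2),
    computed unit-wise over per-image activations. ``exclude`` drops the
    named conditions from the non-target pool (e.g. to contrast bodies
    against everything except faces). Units with zero pooled variance are
    flagged undefined.
    """
    mt, vt, mr, vr = _target_rest_moments(codebook, features, labels, target, grouping, exclude)
    pooled = np.sqrt((vt + vr) / 2.0)
    defined = pooled > 0.0
    scores = np.full(mt.shape, np.nan)
    np.divide(mt - mr, pooled, out=scores, where=defined)
    return SelectivityMap(scores=scores, metric="dprime", target_condition=target, defined=defined)


def si_map(
    codebook: Codebook,
    features: np.ndarray,
    labels: pd.DataFrame,
    target: str,
    grouping: str = "category",
    exclude: list[str] | None = None,
) -> SelectivityMap:
    """Mean-normalized selectivity index.

    SI = (mean_target - mean_rest) / (mean_target + mean_rest); bounded in
    [-1, 1] when all mean activations are nonnegative. Units where the
    denominator is 0 are flagged undefined.
    """
    mt, _, mr, _ = _target_rest_moments(codebook, features, labels, target, grouping, exclude)
    denom = mt + mr
    defined = denom != 0.0
    scores = np.full(mt.shape, np.nan)
    np.divide(mt - mr, denom, out=scores, where=defined)
    return SelectivityMap(scores=scores, metric="SI", target_condition=target, defined=defined)


# --------------------------------------------------------------------------
# map-level summaries
# --------------------------------------------------------------------------


def nonuniformity_score(
    selectivity: SelectivityMap, *, jensen_shannon: bool = False
) -> float:
    """How far the softmax-normalized selectivity map is from uniform.

    The selectivity scores are softmax-normalized (temperature 1) into a
    distribution P over units and compared against the uniform
    distribution Q. The default statistic is the square root of the
    symmetrized KL divergence, sqrt(KL(P||Q)/2 + KL(Q||P)/2), in natural
    log; ``jensen_shannon=True`` gives the textbook Jensen-Shannon
    distance instead (KL against the mixture M = (P+Q)/2). Both are 0 iff
    all scores are equal, and both are invariant to adding a constant to
    every score.
    """
    if not selectivity.all_defined:
        raise ValueError("selectivity map contains undefined scores")
    s = selectivity.scores.ravel()
    z = s - s.max()  # shift-invariant softmax
    p = np.exp(z)
    p /= p.sum()
    q = np.full_like(p, 1.0 / p.size)
    if jensen_shannon:
        m = 0.5 * (p + q)
        kl_pm = float(np.sum(p * np.log(p / m)))
        kl_qm = float(np.sum(q * np.log(q / m)))
        return float(np.sqrt(max(kl_pm / 2.0 + kl_qm / 2.0, 0.0)))
    kl_pq = float(np.sum(p * np.log(p / q)))
    kl_qp = float(np.sum(q * np.log(q / p)))
    return float(np.sqrt(max(kl_pq / 2.0 + kl_qp / 2.0, 0.0)))


def top_unit(selectivity: SelectivityMap) -> tuple[int, int]:
    """Grid index of the maximally selective unit (row-major tie-break)."""
    scores = selectivity.scores.copy()
    scores[~selectivity.defined] = -np.inf
    if not np.isfinite(scores).any():
        raise ValueError("all selectivity scores are undefined")
    idx = int(np.argmax(scores.ravel()))
    return divmod(idx, scores.shape[1])
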