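"""Kohonen self-organizing map over a high-dimensional feature manifold.

A 2D grid of units, each carrying a "tuning vector" in the input feature
space, is initialized on the plane spanned by the top two principal
components of the data and then fine-tuned online so that neighboring grid
units come to encode nearby regions of the data manifold.

Conventions fixed here and used throughout the package:

* grid coordinates are 0-based ``(w, h)`` = (row, col);
* the codebook tensor has shape ``(W, H, F)``;
* best-matching-unit (BMU) ties break toward the smallest row-major index;
* the epoch index ``t`` runs over ``0 .. T-1`` and both the learning rate
  and the neighborhood radius are constant within an epoch.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "TrainConfig",
    "PrincipalPlane",
    "Codebook",
    "TrainingTrace",
    "estimate_principal_plane",
    "choose_grid_shape",
    "init_codebook",
    "learning_rate",
    "radius",
    "grid_distance",
    "neighborhood_weight",
    "find_bmu",
    "apply_update",
    "train_som",
    "quantization_error",
    "similarity_by_distance",
]


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of a SOM training run.

    Parameters
    ----------
    n_units_requested
        Target number of map units; the realized grid ``W x H`` is the
        factor pair closest to the data's principal-axis aspect ratio.
    epochs_T
        Total number of passes over the data. Schedules decay linearly
        to zero over this horizon.
    initial_learning_rate_L0
        Step size at epoch 0, in (0, 1].
    initial_radius_sigma0
        Neighborhood radius at epoch 0 in grid units; ``"auto"`` sets it
        to half the larger grid dimension, so the initial neighborhood
        covers roughly half of the map.
    batch_size
        Number of images per batch; BMUs are assigned against the codebook
        state at the start of each batch.
    init_sample_size
        Number of samples drawn (without replacement) to estimate the
        principal plane used for initialization.
    radius_floor_eps
        Lower bound on the radius, preventing a zero-width neighborhood
        in the final epochs.
    shuffle_each_epoch
        Reshuffle the sample presentation order every epoch.
    seed
        Seed for the init-sample draw and the epoch shuffles.
    radius_schedule
        ``"linear"`` follows sigma0 * (1 - t/T); ``"exponential"`` follows
        sigma0 * exp(-t/T * ln(sigma0 / radius_floor_eps)).
    grid_shape
        Optional explicit ``(W, H)`` override, bypassing the aspect-ratio
        heuristic.
    """

    n_units_requested: int = 400
    epochs_T: int = 100
    initial_learning_rate_L0: float = 0.3
    initial_radius_sigma0: float | Literal["auto"] = "auto"
    batch_size: int = 32
    init_sample_size: int = 400
    radius_floor_eps: float = 1e-6
    shuffle_each_epoch: bool = True
    seed: int = 0
    radius_schedule: Literal["linear", "exponential"] = "linear"
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.epochs_T < 1:
            raise ValueError("epochs_T must be >= 1")
        if not (0.0 < self.initial_learning_rate_L0 <= 1.0):
            raise ValueError("initial_learning_rate_L0 must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.init_sample_size < 3:
            raise ValueError("init_sample_size must be >= 3")
        if self.radius_floor_eps <= 0:
            raise ValueError("radius_floor_eps must be > 0")
        if self.initial_radius_sigma0 != "auto" and self.initial_radius_sigma0 <= 0:
            raise ValueError("initial_radius_sigma0 must be positive or 'auto'")
        if self.n_units_requested < 4:
            raise ValueError("n_units_requested must be >= 4")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["grid_shape"] is not None:
            d["grid_shape"] = list(d["grid_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if d.get("grid_shape") is not None:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass(frozen=True)
class PrincipalPlane:
    """Mean and top-two eigenpairs of a sample covariance."""

    data_mean: np.ndarray
    eigvec_1: np.ndarray
    eigvec_2: np.ndarray
    eigval_1: float
    eigval_2: float

    def __post_init__(self) -> None:
        if self.eigval_1 < self.eigval_2:
            raise ValueError("eigval_1 must be >= eigval_2")
        if abs(float(self.eigvec_1 @ self.eigvec_2)) >= 1e-8:
            raise ValueError("eigenvectors must be orthogonal")


@dataclass
class Codebook:
    """The complete set of map-unit tuning vectors, shape (W, H, F)."""

    tuning: np.ndarray

    def __post_init__(self) -> None:
        self.tuning = np.asarray(self.tuning, dtype=np.float64)
        if self.tuning.ndim != 3:
            raise ValueError("tuning must be a W x H x F tensor")
        if not np.isfinite(self.tuning).all():
            raise ValueError("tuning values must be finite")

    @property
    def grid_width_W(self) -> int:
        return self.tuning.shape[0]

    @property
    def grid_height_H(self) -> int:
        return self.tuning.shape[1]

    @property
    def feature_dim_F(self) -> int:
        return self.tuning.shape[2]

    @property
    def n_units(self) -> int:
        return self.tuning.shape[0] * self.tuning.shape[1]

    def flat(self) -> np.ndarray:
        """Row-major (n_units, F) view of the codebook."""
        return self.tuning.reshape(self.n_units, self.feature_dim_F)

    def copy(self) -> "Codebook":
        return Codebook(self.tuning.copy())


@dataclass
class TrainingTrace:
    """Per-epoch diagnostics of a training run."""

    qe_per_epoch: list[float] = field(default_factory=list)
    learning_rate_per_epoch: list[float] = field(default_factory=list)
    radius_per_epoch: list[float] = field(default_factory=list)
    qe_initial: float | None = None

    def validate(self) -> None:
        n = len(self.qe_per_epoch)
        if not (len(self.learning_rate_per_epoch) == len(self.radius_per_epoch) == n):
            raise ValueError("trace lists must have equal length")
        lr = np.asarray(self.learning_rate_per_epoch)
        rad = np.asarray(self.radius_per_epoch)
        if n > 1 and not (np.diff(lr) < 0).all():
            raise ValueError("learning rate must be strictly decreasing")
        if n > 1 and not (np.diff(rad) <= 0).all():
            raise ValueError("radius must be non-increasing")


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------


def estimate_principal_plane(sample: np.ndarray) -> PrincipalPlane:
    """Top-two eigenpairs of the covariance of a mean-centered sample.

    Raises ``ValueError`` on a degenerate sample (zero total variance).
    """
    sample = np.asarray(sample, dtype=np.float64)
    if sample.ndim != 2 or sample.shape[0] < 3:
        raise ValueError("sample must be 2D with at least 3 rows")
    if sample.shape[1] < 2:
        raise ValueError("feature dimension must be >= 2")
    mean = sample.mean(axis=0)
    centered = sample - mean
    cov = centered.T @ centered / (sample.shape[0] - 1)
    total_var = float(np.trace(cov))
    if total_var <= 0.0:
        raise ValueError("degenerate sample: zero total variance")
    vals, vecs = np.linalg.eigh(cov)
    # eigh returns ascending order
    e1, e2 = float(vals[-1]), float(vals[-2])
    v1, v2 = vecs[:, -1], vecs[:, -2]
    return PrincipalPlane(
        data_mean=mean,
        eigvec_1=v1,
        eigvec_2=v2,
        eigval_1=max(e1, 0.0),
        eigval_2=max(e2, 0.0),
    )


def choose_grid_shape(n_units_requested: int, plane: PrincipalPlane) -> tuple[int, int]:
    """Pick a ``(W, H)`` factor pair matching the data's aspect ratio.

    The target aspect ``W/H`` is ``sqrt(eigval_1)/sqrt(eigval_2)`` — grid
    axes are scaled by the square roots of the eigenvalues at
    initialization, so the aspect lives on that scale. Among candidate
    pairs whose product is as close as possible to the requested unit
    count, the pair with log-aspect closest to the target wins; remaining
    ties break toward the squarer shape, then toward W >= H.
    """
    if n_units_requested < 4:
        raise ValueError("n_units_requested must be >= 4")
    if plane.eigval_2 <= 0.0:
        target_log_ratio = math.inf
    else:
        target_log_ratio = 0.5 * math.log(plane.eigval_1 / plane.eigval_2)

    best = None
    best_key = None
    for w in range(1, n_units_requested + 1):
        for h in {
            max(1, n_units_requested // w),
            max(1, -(-n_units_requested // w)),  # ceil division
        }:
            log_ratio = math.log(w / h)
            if math.isinf(target_log_ratio):
                aspect_err = -log_ratio  # more elongated (w >> h) is better
            else:
                aspect_err = abs(log_ratio - target_log_ratio)
            key = (
                aspect_err,
                abs(w * h - n_units_requested),
                abs(log_ratio),
                -w,
            )
            if best_key is None or key < best_key:
                best_key = key
                best = (w, h)
    assert best is not None
    return best


def init_codebook(
    features: np.ndarray,
    config: TrainConfig,
    plane: PrincipalPlane | None = None,
) -> Codebook:
    """Place the map grid on the data's principal plane.

    Unit ``(w, h)`` starts at
    ``mean + a_w * sqrt(eigval_1) * v1 + b_h * sqrt(eigval_2) * v2``
    with ``a_w``, ``b_h`` linearly spaced over [-1, 1] along the two grid
    axes. The plane is estimated from ``init_sample_size`` rows drawn
    without replacement using the config seed (or from a caller-supplied
    plane).
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 3:
        raise ValueError("features must be 2D with at least 3 rows")
    if plane is None:
        rng = np.random.default_rng(config.seed)
        n = features.shape[0]
        k = min(config.init_sample_size, n)
        idx = rng.choice(n, size=k, replace=False)
        plane = estimate_principal_plane(features[idx])
    if config.grid_shape is not None:
        W, H = config.grid_shape
    else:
        W, H = choose_grid_shape(config.n_units_requested, plane)
    a = np.linspace(-1.0, 1.0, W) if W > 1 else np.zeros(1)
    b = np.linspace(-1.0, 1.0, H) if H > 1 else np.zeros(1)
    s1 = math.sqrt(plane.eigval_1)
    s2 = math.sqrt(plane.eigval_2)
    tuning = (
        plane.data_mean[None, None, :]
        + a[:, None, None] * s1 * plane.eigvec_1[None, None, :]
        + b[None, :, None] * s2 * plane.eigvec_2[None, None, :]
    )
    return Codebook(tuning)


# --------------------------------------------------------------------------
# schedules and neighborhood
# --------------------------------------------------------------------------


def learning_rate(t: int, config: TrainConfig) -> float:
    """Linearly decaying step size ``L0 * (1 - t/T)``."""
    T = config.epochs_T
    if not (0 <= t < T):
        raise ValueError(f"epoch index {t} outside [0, {T})")
    return config.initial_learning_rate_L0 * (1.0 - t / T)


def resolve_sigma0(config: TrainConfig, grid_shape: tuple[int, int]) -> float:
    """Resolve ``"auto"`` to half the larger grid dimension."""
    if config.initial_radius_sigma0 == "auto":
        return max(grid_shape) / 2.0
    return float(config.initial_radius_sigma0)


def radius(t: int, config: TrainConfig, grid_shape: tuple[int, int] | None = None) -> float:
    """Neighborhood radius at epoch ``t``, floored at ``radius_floor_eps``.

    The default schedule is the linear decay ``sigma0 * (1 - t/T)``; an
    exponential schedule decaying from sigma0 to the floor over the run
    is available via ``config.radius_schedule``.
    """
    T = config.epochs_T
    if not (0 <= t < T):
        raise ValueError(f"epoch index {t} outside [0, {T})")
    if config.initial_radius_sigma0 == "auto":
        if grid_shape is None:
            raise ValueError("grid_shape required to resolve sigma0='auto'")
        sigma0 = resolve_sigma0(config, grid_shape)
    else:
        sigma0 = float(config.initial_radius_sigma0)
    if config.radius_schedule == "linear":
        value = sigma0 * (1.0 - t / T)
    else:
        decay = math.log(sigma0 / config.radius_floor_eps)
        value = sigma0 * math.exp(-(t / T) * decay)
    return max(value, config.radius_floor_eps)


def grid_distance(unit_a: Sequence[int], unit_b: Sequence[int]) -> float:
    """Euclidean distance on grid coordinates, sqrt((w-i)^2 + (h-j)^2)."""
    dw = unit_a[0] - unit_b[0]
    dh = unit_a[1] - unit_b[1]
    return math.hypot(dw, dh)


def neighborhood_weight(
    bmu: Sequence[int], unit: Sequence[int], sigma: float
) -> float:
    """Gaussian neighborhood weight exp(-D^2 / (2 sigma^2)) in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = grid_distance(bmu, unit)
    return math.exp(-(d * d) / (2.0 * sigma * sigma))


def _grid_sq_distances(W: int, H: int) -> np.ndarray:
    """(n_units, n_units) squared grid distances, row-major unit order."""
    rows, cols = np.meshgrid(np.arange(W), np.arange(H), indexing="ij")
    coords = np.column_stack([rows.ravel(), cols.ravel()]).astype(np.float64)
    diff = coords[:, None, :] - coords[None, :, :]
    return (diff**2).sum(axis=2)


# --------------------------------------------------------------------------
# competition and update
# --------------------------------------------------------------------------


def find_bmu(codebook: Codebook, x: np.ndarray) -> tuple[int, int]:
    """Best matching unit: minimum Euclidean distance to ``x``.

    Ties break toward the smallest row-major (w, h) index.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (codebook.feature_dim_F,):
        raise ValueError(
            f"feature vector length {x.shape} does not match F={codebook.feature_dim_F}"
        )
    d2 = ((codebook.flat() - x) ** 2).sum(axis=1)
    idx = int(np.argmin(d2))  # argmin returns first occurrence: row-major tie-break
    return divmod(idx, codebook.grid_height_H)


def apply_update(
    codebook: Codebook,
    x: np.ndarray,
    bmu: tuple[int, int],
    Lt: float,
    sigma: float,
) -> Codebook:
    """Move every unit toward ``x`` by ``Lt * eta(unit, bmu)``.

    The BMU moves by exactly ``Lt * (x - tuning_bmu)``; since
    ``Lt * eta <= 1`` no unit overshoots past ``x``. Returns a new
    codebook; the input is not modified.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (codebook.feature_dim_F,):
        raise ValueError("feature vector length does not match codebook F")
    if not (0.0 < Lt <= 1.0):
        raise ValueError("Lt must be in (0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    W, H = codebook.grid_width_W, codebook.grid_height_H
    rows, cols = np.meshgrid(np.arange(W), np.arange(H), indexing="ij")
    d2 = (rows - bmu[0]) ** 2 + (cols - bmu[1]) ** 2
    eta = np.exp(-d2 / (2.0 * sigma * sigma))
    tuning = codebook.tuning + (Lt * eta)[:, :, None] * (x - codebook.tuning)
    return Codebook(tuning)


def quantization_error(codebook: Codebook, features: np.ndarray) -> float:
    """Mean Euclidean distance between samples and their BMU tunings."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ValueError("features must be a nonempty 2D array")
    d = cdist(features, codebook.flat())
    return float(d.min(axis=1).mean())


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------


def train_som(
    features: np.ndarray, config: TrainConfig
) -> tuple[Codebook, TrainingTrace]:
    """Fit a SOM to a feature matrix.

    Each epoch presents the full (optionally reshuffled) sample set in
    batches of ``batch_size``. BMUs for a batch are computed against the
    codebook state at the start of that batch; the per-image updates are
    then applied sequentially in batch order, all using that epoch's
    learning rate and radius. The quantization error is recorded at
    initialization and after every epoch. Fully reproducible given the
    config seed.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ValueError("features must be a nonempty 2D array")
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")

    rng = np.random.default_rng(config.seed)
    n = features.shape[0]
    k = min(config.init_sample_size, n)
    idx = rng.choice(n, size=k, replace=False)
    plane = estimate_principal_plane(features[idx])
    codebook = init_codebook(features, config, plane=plane)
    W, H = codebook.grid_width_W, codebook.grid_height_H

    trace = TrainingTrace(qe_initial=quantization_error(codebook, features))
    flat = codebook.flat().copy()  # (n_units, F), mutated in place
    d2_units = _grid_sq_distances(W, H)  # (n_units, n_units)
    order = np.arange(n)

    for t in range(config.epochs_T):
        Lt = learning_rate(t, config)
        sigma_t = radius(t, config, grid_shape=(W, H))
        eta_all = np.exp(-d2_units / (2.0 * sigma_t * sigma_t))  # rows: BMU index
        step_all = Lt * eta_all

        if config.shuffle_each_epoch:
            order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            batch = features[batch_idx]
            # BMUs against the codebook state at the start of the batch
            d = cdist(batch, flat, metric="sqeuclidean")
            bmus = d.argmin(axis=1)
            for x, bmu in zip(batch, bmus):
                flat += step_all[bmu][:, None] * (x - flat)

        cb_t = Codebook(flat.reshape(W, H, -1))
        trace.qe_per_epoch.append(quantization_error(cb_t, features))
        trace.learning_rate_per_epoch.append(Lt)
        trace.radius_per_epoch.append(sigma_t)

    codebook = Codebook(flat.reshape(W, H, -1))
    trace.validate()
    return codebook, trace


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------


def similarity_by_distance(
    codebook: Codebook,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Mean pairwise tuning correlation as a function of grid distance.

    Pairs of distinct units are binned by their grid distance rounded to
    the nearest integer; the self-pair bin at distance 0 is excluded.
    Pairs involving a constant (zero-variance) tuning vector have
    undefined correlation and are excluded from the means.

    Returns ``(bins, mean_similarity, counts, n_excluded)``.
    """
    n_units = codebook.n_units
    if n_units < 2:
        raise ValueError("need at least 2 units")
    flat = codebook.flat()
    sd = flat.std(axis=1)
    valid = sd > 0.0

    d2 = _grid_sq_distances(codebook.grid_width_W, codebook.grid_height_H)
    iu, ju = np.triu_indices(n_units, k=1)
    dist = np.sqrt(d2[iu, ju])
    bins_all = np.rint(dist).astype(int)

    pair_valid = valid[iu] & valid[ju]
    n_excluded = int((~pair_valid).sum())

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(flat)
    sims = corr[iu, ju]

    bins = np.unique(bins_all[pair_valid])
    means = np.empty(bins.shape, dtype=np.float64)
    counts = np.empty(bins.shape, dtype=np.int64)
    for i, b in enumerate(bins):
        mask = (bins_all == b) & pair_valid
        means[i] = sims[mask].mean()
        counts[i] = int(mask.sum())
    return bins, means, counts, n_excluded
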