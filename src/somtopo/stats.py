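"""Spatial overlap statistics and representational-geometry summaries.

The central question these tools answer: do the most category-selective
units of a map sit inside one large-scale preference zone rather than the
other? A threshold sweep over the most-selective units traces an ROC-style
curve between the fill proportions of the two zones; its area (AUC, chance
0.5) is a threshold-free overlap measure, and a permutation null (shuffling
selectivity across units while holding the preference map fixed) gives its
significance. Representational geometry utilities (correlation-distance
RDM, metric MDS) summarize the underlying feature space itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import PreferenceMap, SelectivityMap

__all__ = [
    "ROCResult",
    "PermutationResult",
    "roc_overlap",
    "permutation_test",
    "rdm",
    "mds_embed",
    "morans_i",
]


@dataclass
class ROCResult:
    """Threshold-sweep overlap curve between two preference zones.

    ``fill_zone_a[i]`` / ``fill_zone_b[i]`` give the proportion of all
    zone-a- (zone-b-) preferring units contained among the top
    ``thresholds[i]`` fraction of most-selective units. The curve is
    plotted as (fill_zone_b on x, fill_zone_a on y) with (0, 0) prepended,
    so ``auc > 0.5`` means selective units concentrate in zone a.
    ``auc_above_diagonal`` is the same information expressed as area
    between the curve and the diagonal (auc - 0.5).
    """

    thresholds: np.ndarray
    fill_zone_a: np.ndarray
    fill_zone_b: np.ndarray
    auc: float
    zone_a_label: str
    zone_b_label: str

    @property
    def auc_above_diagonal(self) -> float:
        return self.auc - 0.5

    def __post_init__(self) -> None:
        for arr in (self.fill_zone_a, self.fill_zone_b):
            if (np.diff(arr) < 0).any():
                raise ValueError("fill curves must be non-decreasing")
            if not np.isclose(arr[-1], 1.0):
                raise ValueError("fill curves must end at 1.0")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")


@dataclass
class PermutationResult:
    """Observed AUC against its shuffle null."""

    observed_auc: float
    null_aucs: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if len(self.null_aucs) != self.n_perm:
            raise ValueError("null_aucs length must equal n_perm")


# --------------------------------------------------------------------------
# ROC overlap
# --------------------------------------------------------------------------


def _zone_masks(
    preference: PreferenceMap, zone_a: str, zone_b: str
) -> tuple[np.ndarray, np.ndarray]:
    labels = preference.labels().ravel()
    in_a = labels == zone_a
    in_b = labels == zone_b
    if not in_a.any():
        raise ValueError(f"no units prefer zone '{zone_a}'")
    if not in_b.any():
        raise ValueError(f"no units prefer zone '{zone_b}'")
    return in_a, in_b


def _threshold_counts(n_units: int) -> np.ndarray:
    """Top-k unit counts for the 1%..100% threshold sweep (ceil rounding)."""
    pct = np.arange(1, 101)
    return np.ceil(pct / 100.0 * n_units).astype(int)


def _fill_curves(
    order: np.ndarray, in_a: np.ndarray, in_b: np.ndarray, ks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Zone-fill proportions at each top-k cut, given a descending sort order.

    ``order`` may be (n,) for a single sweep or (m, n) for m sweeps at
    once (used by the permutation null).
    """
    cum_a = np.cumsum(in_a[order], axis=-1)
    cum_b = np.cumsum(in_b[order], axis=-1)
    fa = cum_a[..., ks - 1] / in_a.sum()
    fb = cum_b[..., ks - 1] / in_b.sum()
    return fa, fb

def _auc_from_fills(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Trapezoidal area under (fb, fa) with the (0, 0) point prepended."""
    pad = [(0, 0)] * (fa.ndim - 1) + [(1, 0)]
    y = np.pad(fa, pad)
    x = np.pad(fb, pad)
    return np.trapezoid(y, x, axis=-1)


def _descending_order(scores: np.ndarray) -> np.ndarray:
    # stable sort on -scores: equal scores keep row-major order
    return np.argsort(-scores, axis=-1, kind="stable")


def roc_overlap(
    selectivity: SelectivityMap,
    preference: PreferenceMap,
    zone_a: str,
    zone_b: str,
) -> ROCResult:
    """Sweep the most-selective units and measure how they fill two zones.

    Units are sorted by selectivity, descending (row-major tie-break).
    For every threshold k = ceil(pct/100 * n_units), pct = 1..100, the
    proportion of all zone-a-preferring and zone-b-preferring units found
    in the top-k set is recorded; the AUC is the trapezoidal area under
    (fill_b, fill_a) after prepending (0, 0).
    """
    if not selectivity.all_defined:
        raise ValueError("selectivity map contains undefined scores")
    in_a, in_b = _zone_masks(preference, zone_a, zone_b)
    scores = selectivity.scores.ravel()
    if scores.shape != in_a.shape:
        raise ValueError("selectivity and preference grids differ in size")
    ks = _threshold_counts(scores.size)
    order = _descending_order(scores)
    fa, fb = _fill_curves(order, in_a, in_b, ks)
    auc = float(_auc_from_fills(fa, fb))
    return ROCResult(
        thresholds=np.arange(1, 101) / 100.0,
        fill_zone_a=fa,
        fill_zone_b=fb,
        auc=auc,
        zone_a_label=zone_a,
        zone_b_label=zone_b,
    )


def permutation_test(
    selectivity: SelectivityMap,
    preference: PreferenceMap,
    zone_a: str,
    zone_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    add_one_smoothing: bool = False,
) -> PermutationResult:
    """Shuffle selectivity across units and rebuild the AUC null.

    The preference map stays fixed; only the assignment of selectivity
    scores to units is permuted, ``n_perm`` times. The p-value is the
    plain proportion of null AUCs strictly greater than the observed one;
    ``add_one_smoothing`` switches to (b + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = roc_overlap(selectivity, preference, zone_a, zone_b)
    in_a, in_b = _zone_masks(preference, zone_a, zone_b)
    scores = selectivity.scores.ravel()
    n = scores.size
    ks = _threshold_counts(n)

    rng = np.random.default_rng(seed)
    # permuted score vectors, one per row; each yields one null AUC
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    shuffled = scores[perms]
    orders = _descending_order(shuffled)
    fa, fb = _fill_curves(orders, in_a, in_b, ks)
    null_aucs = _auc_from_fills(fa, fb)

    greater = int((null_aucs > observed.auc).sum())
    if add_one_smoothing:
        p = (greater + 1) / (n_perm + 1)
    else:
        p = greater / n_perm
    return PermutationResult(
        observed_auc=observed.auc,
        null_aucs=null_aucs,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
    )


# --------------------------------------------------------------------------
# representational geometry
# --------------------------------------------------------------------------


def rdm(features: np.ndarray, sample_ids: np.ndarray | list | None = None) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between sample feature vectors.

    Symmetric with an exactly zero diagonal; entries lie in [0, 2].
    Raises on any sample whose feature vector is constant (correlation
    undefined), naming the sample.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sd = features.std(axis=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        names = (
            [str(sample_ids[i]) for i in bad] if sample_ids is not None else [str(i) for i in bad]
        )
        raise ValueError(f"constant feature vector(s) for sample(s): {', '.join(names)}")
    d = 1.0 - np.corrcoef(features)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def mds_embed(
    d: np.ndarray, out_dim: int = 2, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Stress-minimizing metric MDS embedding of a dissimilarity matrix.

    Thin wrapper around scikit-learn's SMACOF MDS with a precomputed
    dissimilarity; returns (coordinates, final raw stress). Seeded.
    """
    import inspect

    from sklearn.manifold import MDS

    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    kwargs: dict = dict(
        n_components=out_dim,
        random_state=seed,
        n_init=8,
        max_iter=500,
        eps=1e-9,
        normalized_stress=False,
    )
    params = inspect.signature(MDS.__init__).parameters
    # precomputed-dissimilarity spelling changed across scikit-learn versions
    if "metric_mds" in params:
        kwargs.update(metric="precomputed", init="random")
    else:
        kwargs.update(dissimilarity="precomputed")
    model = MDS(**kwargs)
    coords = model.fit_transform(d)
    return coords, float(model.stress_)


# --------------------------------------------------------------------------
# spatial autocorrelation
# --------------------------------------------------------------------------


def morans_i(grid: np.ndarray, adjacency: str = "rook") -> float:
    """Moran's I spatial autocorrelation of values on a 2D grid.

    Binary 0/1 weights over rook (4-) or queen (8-) neighborhoods.
    Values near +1 indicate large contiguous zones of similar values;
    values near 0 indicate no spatial structure.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2:
        raise ValueError("grid must be 2D")
    z = grid - grid.mean()
    denom = float((z**2).sum())
    if denom == 0.0:
        raise ValueError("constant grid: Moran's I undefined")

    num = 0.0
    s0 = 0.0
    # horizontal and vertical joins
    for a, b in (
        (z[:, :-1], z[:, 1:]),
        (z[:-1, :], z[1:, :]),
    ):
        num += 2.0 * float((a * b).sum())
        s0 += 2.0 * a.size
    if adjacency == "queen":
        for a, b in (
            (z[:-1, :-1], z[1:, 1:]),
            (z[:-1, 1:], z[1:, :-1]),
        ):
            num += 2.0 * float((a * b).sum())
            s0 += 2.0 * a.size
    elif adjacency != "rook":
        raise ValueError("adjacency must be 'rook' or 'queen'")
    n = grid.size
    return (n / s0) * (num / denom)
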