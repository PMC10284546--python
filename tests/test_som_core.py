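"""SOM core: initialization geometry, schedules, competition, training."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import somtopo as st
from conftest import random_codebook

# --------------------------------------------------------------------------
# principal plane
# --------------------------------------------------------------------------


class TestPrincipalPlane:
    def test_matches_dense_eigendecomposition(self, rng):
        """Mean/top-2 eigenpairs agree with a full dense eig of the covariance."""
        X = rng.standard_normal((50, 10))
        plane = st.estimate_principal_plane(X)
        # independent oracle: full eigendecomposition of np.cov
        cov = np.cov(X, rowvar=False)
        vals, vecs = np.linalg.eig(cov)
        order = np.argsort(vals)[::-1]
        assert plane.eigval_1 == pytest.approx(float(vals[order[0]].real), abs=1e-10)
        assert plane.eigval_2 == pytest.approx(float(vals[order[1]].real), abs=1e-10)
        for got, want in [(plane.eigvec_1, vecs[:, order[0]].real), (plane.eigvec_2, vecs[:, order[1]].real)]:
            assert abs(abs(got @ want) - 1.0) < 1e-8  # up to sign
        assert plane.eigval_1 >= plane.eigval_2
        np.testing.assert_allclose(plane.data_mean, X.mean(axis=0))

    def test_axis_aligned_line(self, rng):
        """Points on a line along e1 (var 4) with tiny jitter on e2."""
        n = 400
        X = np.zeros((n, 5))
        X[:, 0] = rng.standard_normal(n) * 2.0
        X[:, 1] = rng.standard_normal(n) * 1e-6
        plane = st.estimate_principal_plane(X)
        assert abs(abs(plane.eigvec_1[0]) - 1.0) < 1e-6
        assert plane.eigval_1 == pytest.approx(np.var(X[:, 0], ddof=1), rel=1e-10)

    def test_init_sample_size_case(self, rng):
        """A 400-row sample orders its eigenvalues correctly."""
        plane = st.estimate_principal_plane(rng.standard_normal((400, 16)))
        assert plane.eigval_1 >= plane.eigval_2 >= 0

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.estimate_principal_plane(np.ones((5, 4)))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            st.estimate_principal_plane(np.zeros((2, 4)))


# --------------------------------------------------------------------------
# grid shape
# --------------------------------------------------------------------------


def _plane_with_ratio(sqrt_ratio: float) -> st.PrincipalPlane:
    v1 = np.array([1.0, 0.0])
    v2 = np.array([0.0, 1.0])
    return st.PrincipalPlane(np.zeros(2), v1, v2, sqrt_ratio**2, 1.0)


class TestGridShape:
    @pytest.mark.parametrize(
        "n,sqrt_ratio,expected",
        [(400, 1.0, (20, 20)), (4, 1.0, (2, 2))],
    )
    def test_square_cases(self, n, sqrt_ratio, expected):
        assert st.choose_grid_shape(n, _plane_with_ratio(sqrt_ratio)) == expected

    def test_elongated_matches_exhaustive_search(self):
        """Aspect 4 at n=400: oracle is an exhaustive factor-pair search."""
        n, ratio = 400, 4.0
        got = st.choose_grid_shape(n, _plane_with_ratio(ratio))
        # brute force: every (W, H) with product near n
        best, best_key = None, None
        for w in range(1, n + 1):
            for h in (n // w, math.ceil(n / w)):
                if h < 1:
                    continue
                key = (abs(math.log(w / h) - math.log(ratio)), abs(w * h - n))
                if best_key is None or key < best_key:
                    best_key, best = key, (w, h)
        assert got == best
        assert got == (40, 10)

    def test_tie_breaks_toward_squarer(self):
        # ratio sqrt(2): (W,H) candidates around 4x3 vs 3x4 etc.
        W, H = st.choose_grid_shape(12, _plane_with_ratio(math.sqrt(2)))
        assert W >= H  # wider axis follows the larger eigenvalue

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            st.choose_grid_shape(3, _plane_with_ratio(1.0))


# --------------------------------------------------------------------------
# init
# --------------------------------------------------------------------------


class TestInitCodebook:
    @pytest.fixture
    def cloud(self, rng):
        """2D Gaussian cloud embedded in 10-D."""
        basis = np.linalg.qr(rng.standard_normal((10, 2)))[0]
        ab = rng.standard_normal((300, 2)) * np.array([3.0, 1.0])
        return ab @ basis.T + 0.5

    def test_corners_and_centroid(self, cloud):
        cfg = st.TrainConfig(n_units_requested=24, init_sample_size=300, seed=0)
        cb = st.init_codebook(cloud, cfg)
        rng0 = np.random.default_rng(0)
        idx = rng0.choice(300, 300, replace=False)
        plane = st.estimate_principal_plane(cloud[idx])
        s1, s2 = math.sqrt(plane.eigval_1), math.sqrt(plane.eigval_2)
        corners = {
            (0, 0): -s1 * plane.eigvec_1 - s2 * plane.eigvec_2,
            (-1, -1): s1 * plane.eigvec_1 + s2 * plane.eigvec_2,
            (0, -1): -s1 * plane.eigvec_1 + s2 * plane.eigvec_2,
            (-1, 0): s1 * plane.eigvec_1 - s2 * plane.eigvec_2,
        }
        for (w, h), offset in corners.items():
            np.testing.assert_allclose(cb.tuning[w, h], plane.data_mean + offset, atol=1e-10)
        np.testing.assert_allclose(
            cb.flat().mean(axis=0), plane.data_mean, atol=1e-10
        )

    def test_projections_form_lattice(self, cloud):
        """Codebook projections onto (v1, v2) form a perfect W x H lattice."""
        cfg = st.TrainConfig(n_units_requested=24, init_sample_size=300, seed=0)
        cb = st.init_codebook(cloud, cfg)
        rng0 = np.random.default_rng(0)
        idx = rng0.choice(300, 300, replace=False)
        plane = st.estimate_principal_plane(cloud[idx])
        W, H = cb.grid_width_W, cb.grid_height_H
        centered = cb.tuning - plane.data_mean
        a = centered @ plane.eigvec_1 / math.sqrt(plane.eigval_1)
        b = centered @ plane.eigvec_2 / math.sqrt(plane.eigval_2)
        np.testing.assert_allclose(a, np.tile(np.linspace(-1, 1, W)[:, None], (1, H)), atol=1e-8)
        np.testing.assert_allclose(b, np.tile(np.linspace(-1, 1, H)[None, :], (W, 1)), atol=1e-8)
        # off-plane components vanish relative to the mean
        residual = centered - (
            (centered @ plane.eigvec_1)[..., None] * plane.eigvec_1
            + (centered @ plane.eigvec_2)[..., None] * plane.eigvec_2
        )
        assert np.abs(residual).max() < 1e-10


# --------------------------------------------------------------------------
# schedules
# --------------------------------------------------------------------------


class TestSchedules:
    def test_learning_rate_closed_form(self):
        cfg = st.TrainConfig(epochs_T=100, initial_learning_rate_L0=0.3)
        assert st.learning_rate(0, cfg) == pytest.approx(0.3)
        assert st.learning_rate(50, cfg) == pytest.approx(0.15)
        assert st.learning_rate(99, cfg) == pytest.approx(0.3 / 100)

    def test_radius_closed_form(self):
        cfg = st.TrainConfig(epochs_T=100, initial_radius_sigma0="auto")
        assert st.radius(0, cfg, grid_shape=(20, 20)) == pytest.approx(10.0)
        cfg10 = st.TrainConfig(epochs_T=100, initial_radius_sigma0=10.0)
        assert st.radius(50, cfg10) == pytest.approx(5.0)
        assert st.radius(99, cfg10) == pytest.approx(0.1)

    def test_strictly_decreasing_with_floor(self):
        cfg = st.TrainConfig(epochs_T=50, initial_radius_sigma0=3.0, radius_floor_eps=1e-6)
        lr = [st.learning_rate(t, cfg) for t in range(50)]
        rad = [st.radius(t, cfg) for t in range(50)]
        assert all(a > b for a, b in zip(lr, lr[1:]))
        assert all(a > b for a, b in zip(rad, rad[1:]))
        assert min(rad) >= 1e-6
        assert min(lr) > 0

    def test_exponential_schedule_decreasing(self):
        cfg = st.TrainConfig(
            epochs_T=20, initial_radius_sigma0=8.0, radius_schedule="exponential"
        )
        rad = [st.radius(t, cfg) for t in range(20)]
        assert rad[0] == pytest.approx(8.0)
        assert all(a > b for a, b in zip(rad, rad[1:]))
        assert min(rad) >= cfg.radius_floor_eps

    @pytest.mark.parametrize("t", [-1, 100, 150])
    def test_out_of_range_epoch_rejected(self, t):
        cfg = st.TrainConfig(epochs_T=100, initial_radius_sigma0=10.0)
        with pytest.raises(ValueError):
            st.learning_rate(t, cfg)
        with pytest.raises(ValueError):
            st.radius(t, cfg)


# --------------------------------------------------------------------------
# grid distance and neighborhood
# --------------------------------------------------------------------------


class TestNeighborhood:
    def test_grid_distance_cases(self, rng):
        assert st.grid_distance((0, 0), (0, 0)) == 0.0
        assert st.grid_distance((0, 0), (3, 4)) == pytest.approx(5.0)
        for _ in range(20):
            a = tuple(rng.integers(0, 10, 2))
            b = tuple(rng.integers(0, 10, 2))
            assert st.grid_distance(a, b) == pytest.approx(st.grid_distance(b, a))

    def test_weight_closed_form(self):
        assert st.neighborhood_weight((3, 3), (3, 3), sigma=2.0) == 1.0
        assert st.neighborhood_weight((0, 0), (10, 0), sigma=10.0) == pytest.approx(
            math.exp(-0.5)
        )

    def test_weight_is_one_only_at_bmu(self):
        assert st.neighborhood_weight((0, 0), (0, 1), sigma=5.0) < 1.0

    def test_full_grid_sum_matches_direct_summation(self):
        sigma, bmu = 3.0, (7, 4)
        total = sum(
            st.neighborhood_weight(bmu, (w, h), sigma)
            for w, h in itertools.product(range(20), range(20))
        )
        direct = sum(
            math.exp(-((w - 7) ** 2 + (h - 4) ** 2) / (2 * sigma**2))
            for w in range(20)
            for h in range(20)
        )
        assert total == pytest.approx(direct, rel=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            st.neighborhood_weight((0, 0), (1, 1), sigma=0.0)


# --------------------------------------------------------------------------
# BMU and update
# --------------------------------------------------------------------------


class TestFindBmu:
    def test_exact_match_unit(self, small_codebook):
        x = small_codebook.tuning[2, 3].copy()
        assert st.find_bmu(small_codebook, x) == (2, 3)

    def test_tie_breaks_row_major(self):
        tuning = np.zeros((2, 2, 3))
        tuning[0, 0] = [5, 5, 5]
        tuning[1, 1] = [-5, -5, -5]
        tuning[0, 1] = [1, 0, 0]
        tuning[1, 0] = [0, 1, 0]  # equidistant from x below
        cb = st.Codebook(tuning)
        assert st.find_bmu(cb, np.array([0.5, 0.5, 0.0])) == (0, 1)

    def test_matches_exhaustive_scan(self, rng):
        cb = random_codebook(rng, W=6, H=6, F=8)
        for _ in range(100):
            x = rng.standard_normal(8)
            got = st.find_bmu(cb, x)
            best, best_d = None, np.inf
            for w in range(6):
                for h in range(6):
                    d = np.sqrt(((cb.tuning[w, h] - x) ** 2).sum())
                    if d < best_d:
                        best_d, best = d, (w, h)
            assert got == best

    def test_dimension_mismatch_rejected(self, small_codebook):
        with pytest.raises(ValueError):
            st.find_bmu(small_codebook, np.zeros(3))


class TestApplyUpdate:
    def test_full_step_reaches_input(self, small_codebook, rng):
        x = rng.standard_normal(small_codebook.feature_dim_F)
        bmu = st.find_bmu(small_codebook, x)
        out = st.apply_update(small_codebook, x, bmu, Lt=1.0, sigma=0.5)
        np.testing.assert_allclose(out.tuning[bmu], x, atol=1e-12)

    def test_partial_step_closed_form(self):
        cb = st.Codebook(np.zeros((1, 1, 2)))
        out = st.apply_update(cb, np.array([1.0, 1.0]), (0, 0), Lt=0.3, sigma=1.0)
        np.testing.assert_allclose(out.tuning[0, 0], [0.3, 0.3])

    def test_never_increases_distance_to_input(self, rng):
        for _ in range(25):
            cb = random_codebook(rng, W=4, H=3, F=5)
            x = rng.standard_normal(5)
            bmu = st.find_bmu(cb, x)
            Lt = float(rng.uniform(0.05, 1.0))
            sigma = float(rng.uniform(0.2, 5.0))
            before = np.sqrt(((cb.tuning - x) ** 2).sum(axis=2))
            after_cb = st.apply_update(cb, x, bmu, Lt, sigma)
            after = np.sqrt(((after_cb.tuning - x) ** 2).sum(axis=2))
            assert (after <= before + 1e-12).all()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        Lt=hst.floats(0.01, 1.0),
        sigma=hst.floats(0.1, 10.0),
        seed=hst.integers(0, 1000),
    )
    def test_update_contracts_toward_input(self, Lt, sigma, seed):
        rng = np.random.default_rng(seed)
        cb = random_codebook(rng, W=3, H=3, F=4)
        x = rng.standard_normal(4)
        bmu = st.find_bmu(cb, x)
        before = np.sqrt(((cb.tuning - x) ** 2).sum(axis=2))
        after = np.sqrt(((st.apply_update(cb, x, bmu, Lt, sigma).tuning - x) ** 2).sum(axis=2))
        assert (after <= before + 1e-9).all()


# --------------------------------------------------------------------------
# quantization error
# --------------------------------------------------------------------------


class TestQuantizationError:
    def test_zero_when_samples_equal_units(self, small_codebook):
        feats = small_codebook.flat()[[0, 3, 7]]
        assert st.quantization_error(small_codebook, feats) == pytest.approx(0.0, abs=1e-12)

    def test_single_unit_mean_distance(self):
        cb = st.Codebook(np.zeros((1, 1, 2)))
        feats = np.array([[3.0, 0.0], [0.0, 5.0]])
        assert st.quantization_error(cb, feats) == pytest.approx(4.0)

    def test_matches_brute_force(self, rng):
        cb = random_codebook(rng, W=4, H=5, F=6)
        feats = rng.standard_normal((30, 6))
        brute = np.mean(
            [
                min(
                    np.sqrt(((cb.tuning[w, h] - f) ** 2).sum())
                    for w in range(4)
                    for h in range(5)
                )
                for f in feats
            ]
        )
        assert st.quantization_error(cb, feats) == pytest.approx(brute, abs=1e-10)


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------


class TestTrainSom:
    def test_determinism_and_seed_sensitivity(self, rng):
        X = rng.standard_normal((120, 8)) + 2.0
        cfg = st.TrainConfig(n_units_requested=9, epochs_T=5, init_sample_size=60, seed=3)
        cb1, tr1 = st.train_som(X, cfg)
        cb2, _ = st.train_som(X, cfg)
        np.testing.assert_array_equal(cb1.tuning, cb2.tuning)
        cb3, _ = st.train_som(X, st.TrainConfig(
            n_units_requested=9, epochs_T=5, init_sample_size=60, seed=4))
        assert not np.array_equal(cb1.tuning, cb3.tuning)

    def test_vanishing_learning_rate_freezes_codebook(self, rng):
        X = rng.standard_normal((60, 6)) + 1.0
        cfg = st.TrainConfig(
            n_units_requested=4,
            epochs_T=1,
            initial_learning_rate_L0=1e-12,
            init_sample_size=60,
            seed=0,
        )
        cb, trace = st.train_som(X, cfg)
        init = st.init_codebook(
            X,
            cfg,
            plane=st.estimate_principal_plane(
                X[np.random.default_rng(0).choice(60, 60, replace=False)]
            ),
        )
        np.testing.assert_allclose(cb.tuning, init.tuning, atol=1e-9)

    def test_trace_lengths_and_monotone_schedules(self, rng):
        X = rng.standard_normal((80, 5)) + 1.0
        cfg = st.TrainConfig(n_units_requested=4, epochs_T=7, init_sample_size=40, seed=1)
        _, trace = st.train_som(X, cfg)
        assert len(trace.qe_per_epoch) == 7
        assert len(trace.learning_rate_per_epoch) == 7
        assert len(trace.radius_per_epoch) == 7
        assert trace.qe_initial is not None
        lr = trace.learning_rate_per_epoch
        assert all(a > b for a, b in zip(lr, lr[1:]))

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            st.train_som(np.zeros((0, 4)), st.TrainConfig(n_units_requested=4))

    def test_planar_manifold_topographic_ordering(self):
        """Grid distance correlates with tuning distance after training."""
        from scipy.spatial.distance import pdist
        from scipy.stats import spearmanr

        X = st.generate_planar_manifold(300, 16, seed=5)
        cfg = st.TrainConfig(seed=5, grid_shape=(6, 6), epochs_T=20, init_sample_size=300)
        cb, _ = st.train_som(X, cfg)
        coords = np.array(list(itertools.product(range(6), range(6))), dtype=float)
        rho = spearmanr(pdist(coords), pdist(cb.flat())).statistic
        assert rho > 0.5


# --------------------------------------------------------------------------
# tuning similarity by grid distance
# --------------------------------------------------------------------------


class TestSimilarityByDistance:
    def test_smooth_codebook_decreases_with_distance(self):
        """Tuning = linear function of grid position -> decreasing similarity."""
        W, H, F = 6, 6, 12
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, F))
        base = rng.standard_normal(F)
        tuning = np.empty((W, H, F))
        for w in range(W):
            for h in range(H):
                tuning[w, h] = base + w * basis[0] + h * basis[1]
        bins, means, counts, nexc = st.similarity_by_distance(st.Codebook(tuning))
        assert nexc == 0
        assert 0 not in bins  # no self-pairs
        assert (np.diff(means) < 0).all()

    def test_matches_brute_force(self, rng):
        cb = random_codebook(rng, W=4, H=4, F=6)
        bins, means, counts, _ = st.similarity_by_distance(cb)
        units = list(itertools.product(range(4), range(4)))
        by_bin: dict[int, list[float]] = {}
        for i, a in enumerate(units):
            for b in units[i + 1 :]:
                d = round(math.hypot(a[0] - b[0], a[1] - b[1]))
                r = np.corrcoef(cb.tuning[a], cb.tuning[b])[0, 1]
                by_bin.setdefault(d, []).append(r)
        for bin_, mean_, count_ in zip(bins, means, counts):
            assert count_ == len(by_bin[bin_])
            assert mean_ == pytest.approx(np.mean(by_bin[bin_]), abs=1e-10)

    def test_constant_unit_excluded_with_count(self, rng):
        cb = random_codebook(rng, W=3, H=3, F=5)
        cb.tuning[0, 0] = 1.0  # constant tuning vector: undefined correlations
        _, _, counts, nexc = st.similarity_by_distance(cb)
        assert nexc == 8  # pairs involving the constant unit
        assert counts.sum() == 36 - 8
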