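"""Kohonen map: grid planning, initialization, training, diagnostics."""

import math

import numpy as np
import pytest

import somward as sw
from somward.som import bmu_indices, distortion, grid_coordinates


def brute_force_plan(data, target, lo_hi=0.05):
    """Independent search for the grid-planning optimum."""
    cov = np.cov(np.asarray(data, float), rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    ratio = 1.0 if eig[1] <= 0 else np.clip(eig[0] / eig[1], 1, 25)
    aspect = float(np.clip(math.sqrt(ratio), 1, 5))
    lo, hi = math.ceil(0.95 * target), math.floor(1.05 * target)
    best = None
    for r in range(1, hi + 1):
        for c in range(r, hi + 1):
            if lo <= r * c <= hi:
                key = (abs(c / r - aspect), abs(r * c - target), r, c)
                if best is None or key < best:
                    best = key
    return best[2], best[3]


class TestPlanGrid:
    def test_isotropic_square(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(200, 4))
        assert sw.plan_grid(data, 100) == (10, 10)

    def test_minimum_grid(self):
        rng = np.random.default_rng(0)
        assert sw.plan_grid(rng.normal(size=(50, 3)), 4) == (2, 2)

    @pytest.mark.parametrize("target", [100, 1000])
    def test_matches_brute_force_on_anisotropic_data(self, target):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(300, 5)) * np.array([3.0, 1.5, 1, 1, 1])
        assert sw.plan_grid(data, target) == brute_force_plan(data, target)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            sw.plan_grid(np.ones((1, 3)), 100)


class TestInitialize:
    def test_random_reproducible_from_seed(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(0, 10, size=(40, 6))
        cfg = sw.SOMConfig(rows=4, cols=5, init="random", seed=42)
        a = sw.initialize(cfg, data)
        b = sw.initialize(cfg, data)
        assert np.array_equal(a.weights, b.weights)

    def test_random_within_data_range(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(2, 7, size=(40, 3))
        m = sw.initialize(sw.SOMConfig(rows=6, cols=6, init="random", seed=0), data)
        assert (m.weights >= data.min(0)).all() and (m.weights <= data.max(0)).all()

    def test_linear_deterministic(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(size=(30, 4))
        cfg = sw.SOMConfig(rows=3, cols=7, init="linear")
        assert np.array_equal(sw.initialize(cfg, data).weights,
                              sw.initialize(cfg, data).weights)

    def test_linear_degenerate_data_collapses_to_mean(self):
        data = np.tile([1.0, 2.0, 3.0], (20, 1))
        m = sw.initialize(sw.SOMConfig(rows=3, cols=3, init="linear"), data)
        assert np.allclose(m.weights, [1, 2, 3])


class TestFindBMU:
    def test_exact_match_wins(self):
        w = np.arange(15, dtype=float).reshape(5, 3)
        m = sw.SOMap(weights=w, rows=5, cols=1)
        assert sw.find_bmu(m, w[3]) == 3

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        w = rng.normal(size=(30, 7))
        m = sw.SOMap(weights=w, rows=5, cols=6)
        for _ in range(20):
            x = rng.normal(size=7)
            expect = min(range(30), key=lambda j: np.linalg.norm(x - w[j]))
            assert sw.find_bmu(m, x) == expect

    def test_tie_breaks_to_lower_index(self):
        w = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 5.0]])
        m = sw.SOMap(weights=w, rows=3, cols=1)
        assert sw.find_bmu(m, np.zeros(2)) == 0

    def test_dimension_mismatch_rejected(self):
        m = sw.SOMap(weights=np.zeros((4, 3)), rows=2, cols=2)
        with pytest.raises(ValueError):
            sw.find_bmu(m, np.zeros(5))


class TestNeighborhood:
    def test_closed_form(self):
        assert sw.neighborhood(0.0, 1.3) == 1.0
        assert sw.neighborhood(2.0, 2.0) == pytest.approx(math.exp(-0.5))

    def test_strictly_decreasing(self):
        s = 1.7
        assert sw.neighborhood(2 * s, s) < sw.neighborhood(s, s) < sw.neighborhood(0, s)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            sw.neighborhood(1.0, 0.0)


class TestTrainSequential:
    def test_single_neuron_full_rate_one_step(self):
        x = np.array([[2.0, 5.0]])
        cfg = sw.SOMConfig(rows=1, cols=1, epochs=1, mode="sequential",
                           eta0=1.0, seed=0)
        m = sw.SOMap(weights=np.zeros((1, 2)), rows=1, cols=1)
        out = sw.train_sequential(m, x, cfg)
        assert np.allclose(out.weights, x)

    def test_single_point_contracts_all_weights(self):
        x = np.array([[4.0, 4.0, 4.0]])
        cfg = sw.SOMConfig(rows=3, cols=3, epochs=200, mode="sequential",
                           eta0=0.5, seed=1, sigma0=2.0, tension=2.0)
        m = sw.SOMap(weights=np.random.default_rng(0).uniform(size=(9, 3)),
                     rows=3, cols=3)
        out = sw.train_sequential(m, x, cfg)
        assert np.allclose(out.weights, 4.0, atol=1e-6)

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(0, 10, size=(30, 4))
        cfg = sw.SOMConfig(rows=4, cols=4, epochs=5, mode="sequential", seed=9)
        a = sw.train(data, cfg)
        b = sw.train(data, cfg)
        assert np.array_equal(a.weights, b.weights)


def lloyd_step(weights, data):
    """One independent k-means (Lloyd) update from the same assignment."""
    out = weights.copy()
    assign = np.array([np.argmin(((w - weights) ** 2).sum(1)) for w in data])
    for j in range(len(weights)):
        pts = data[assign == j]
        if len(pts):
            out[j] = pts.mean(axis=0)
    return out


class TestTrainBatch:
    def test_single_point_absorbs_all_weights(self):
        x = np.array([[1.0, 2.0, 3.0]])
        cfg = sw.SOMConfig(rows=4, cols=4, epochs=1)
        m = sw.initialize(sw.SOMConfig(rows=4, cols=4, init="random", seed=0), x)
        out = sw.train_batch(m, x, cfg)
        assert np.allclose(out.weights, x)

    def test_sigma_to_zero_equals_lloyd_step(self):
        """In the vanishing-neighborhood limit one batch epoch is one
        k-means Lloyd step from the same initial assignment."""
        rng = np.random.default_rng(21)
        data = rng.uniform(0, 10, size=(60, 4))
        init_cfg = sw.SOMConfig(rows=3, cols=4, init="random", seed=2)
        m = sw.initialize(init_cfg, data)
        cfg = sw.SOMConfig(rows=3, cols=4, epochs=1, sigma0=1e-4, tension=1e-4)
        out = sw.train_batch(m, data, cfg)
        expect = lloyd_step(m.weights, data)
        assert np.allclose(out.weights, expect, atol=1e-9)

    @pytest.mark.parametrize("sigma,seed", [(0.5, 0), (1.5, 1), (2.5, 2)])
    def test_update_step_reduces_frozen_distortion(self, sigma, seed):
        """For the assignment frozen at the start of an epoch, the batch
        weight update can never increase the smoothed distortion (the
        weighted mean is its exact minimizer)."""
        rng = np.random.default_rng(seed)
        data = np.vstack([rng.normal(2, 0.5, (25, 3)), rng.normal(7, 0.5, (25, 3))])
        cfg1 = sw.SOMConfig(rows=4, cols=5, epochs=1, sigma0=sigma, tension=sigma)
        m = sw.initialize(sw.SOMConfig(rows=4, cols=5, init="random", seed=seed),
                          data)
        kernel = sw.neighborhood(m.grid_distances(), sigma)

        def frozen(weights, bmus):
            d2 = ((data[:, None, :] - weights[None]) ** 2).sum(-1)
            return float((kernel[bmus] * d2).sum())

        for _ in range(5):
            bmus = bmu_indices(m, data)
            before = frozen(m.weights, bmus)
            m = sw.train_batch(m, data, cfg1)
            assert frozen(m.weights, bmus) <= before + 1e-9

    def test_distortion_non_increasing_small_sigma(self):
        """Across epochs at a small fixed radius (the near-k-means
        regime) the smoothed distortion decreases monotonically; larger
        radii admit limit cycles because the Euclidean winner rule has
        no energy function."""
        sigma = 0.5
        cfg1 = sw.SOMConfig(rows=4, cols=5, epochs=1, sigma0=sigma, tension=sigma)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            data = rng.uniform(0, 10, size=(50, 3))
            m = sw.initialize(sw.SOMConfig(rows=4, cols=5, init="linear"), data)
            prev = distortion(m, data, sigma)
            for _ in range(10):
                m = sw.train_batch(m, data, cfg1)
                cur = distortion(m, data, sigma)
                assert cur <= prev + 1e-9
                prev = cur

    def test_weights_stay_in_data_range(self, fixture_dataset):
        X = fixture_dataset.values
        cfg = sw.SOMConfig(rows=6, cols=6, epochs=10)
        out = sw.train(X, cfg)
        assert out.weights.min() >= X.min() - 1e-9
        assert out.weights.max() <= X.max() + 1e-9

    def test_bit_reproducible(self):
        rng = np.random.default_rng(8)
        data = rng.uniform(0, 10, size=(50, 5))
        cfg = sw.SOMConfig(rows=5, cols=5, init="random", seed=13, epochs=10)
        assert np.array_equal(sw.train(data, cfg).weights,
                              sw.train(data, cfg).weights)


class TestQuantizationError:
    def test_zero_for_exact_map(self):
        x = np.array([[1.0, 1.0]])
        m = sw.SOMap(weights=np.tile(x, (4, 1)), rows=2, cols=2)
        assert sw.quantization_error(m, x) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        data = rng.normal(size=(25, 3))
        m = sw.SOMap(weights=rng.normal(size=(6, 3)), rows=2, cols=3)
        expect = np.mean([
            min(np.linalg.norm(x - w) for w in m.weights) for x in data
        ])
        assert sw.quantization_error(m, data) == pytest.approx(expect, abs=1e-12)

    def test_empty_data_rejected(self):
        m = sw.SOMap(weights=np.zeros((4, 2)), rows=2, cols=2)
        with pytest.raises(ValueError):
            sw.quantization_error(m, np.empty((0, 2)))


class TestTopology:
    def test_bmu_monotone_along_1d_manifold(self):
        """On data along a line segment, BMU position is monotone in the
        point's position for at least 95% of adjacent pairs."""
        t = np.linspace(0, 1, 100)
        data = np.column_stack([t * 10, np.zeros(100)])
        cfg = sw.SOMConfig(rows=1, cols=25, lattice="rect", epochs=40,
                           init="linear", sigma0=12.0)
        m = sw.train(data, cfg)
        bmus = bmu_indices(m, data)
        diffs = np.diff(bmus.astype(int))
        direction = np.sign(np.median(diffs[diffs != 0])) or 1
        ok = np.mean(direction * diffs >= 0)
        assert ok >= 0.95


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, small_trained_map):
        m, _ = small_trained_map
        path = tmp_path / "map.csv"
        m.save(path, config=sw.SOMConfig(rows=m.rows, cols=m.cols))
        back = sw.SOMap.load(path)
        assert back.rows == m.rows and back.cols == m.cols
        assert back.lattice == m.lattice
        assert np.allclose(back.weights, m.weights, atol=1e-15)


def test_hex_grid_has_six_unit_neighbors():
    g = grid_coordinates(5, 5, "hex")
    m = sw.SOMap(weights=np.zeros((25, 2)), rows=5, cols=5, lattice="hex")
    nbrs = m.lattice_neighbors()
    assert len(nbrs[12]) == 6  # interior neuron
    assert all(
        abs(np.linalg.norm(g[12] - g[j]) - 1.0) < 1e-9 for j in nbrs[12]
    )
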