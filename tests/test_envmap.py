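"""Landscape generation: distance field, masks, patch statistics, AvgEnv."""

import numpy as np
import pytest

from marcpfs.envmap import (
    MapConfig,
    apply_masks,
    avg_env,
    build_distance_field,
    generate_field,
    patch_statistics,
)


class TestDistanceField:
    def test_island_cell_is_zero(self):
        d = build_distance_field((50, 50), 10.0, 100)
        assert d[50, 50] == 0.0

    @pytest.mark.parametrize(
        "cell,expected_km",
        [((50, 60), 100.0), ((53, 54), 50.0), ((60, 50), 100.0)],
    )
    def test_hand_computed_distances(self, cell, expected_km):
        # 10 cells east = 100 km; the (3, 4) offset is a 3-4-5 triangle
        d = build_distance_field((50, 50), 10.0, 100)
        assert d[cell] == pytest.approx(expected_km)


class TestMasks:
    def setup_method(self):
        self.dist = build_distance_field((50, 50), 10.0, 100)
        self.raw = np.ones((100, 100))

    def test_plateau_and_far_field_zero(self):
        out = apply_masks(self.raw, self.dist, 150.0, rng=0)
        assert (out[self.dist <= 50.0] == 0).all()
        assert (out[self.dist > 500.0] == 0).all()

    def test_beyond_dist_untouched(self):
        out = apply_masks(self.raw, self.dist, 150.0, rng=0)
        keep = (self.dist > 150.0) & (self.dist <= 500.0)
        assert (out[keep] == 1.0).all()

    def test_invalid_dist_raises(self):
        with pytest.raises(ValueError):
            apply_masks(self.raw, self.dist, 40.0, rng=0)
        with pytest.raises(ValueError):
            apply_masks(self.raw, self.dist, 600.0, rng=0)

    def test_retention_midpoint_frequency(self):
        # dist=100: a cell at 75 km sits halfway up the accessibility ramp,
        # so Bernoulli retention keeps it with frequency ~0.5
        ring = (self.dist > 73.0) & (self.dist < 77.0)
        kept = []
        for seed in range(300):
            out = apply_masks(self.raw, self.dist, 100.0, rng=seed,
                              mode="retention")
            kept.append(out[ring].mean())
        assert np.mean(kept) == pytest.approx(0.5, abs=0.03)

    def test_value_mode_is_deterministic_attenuation(self):
        a = apply_masks(self.raw, self.dist, 150.0, mode="value")
        b = apply_masks(self.raw, self.dist, 150.0, mode="value")
        assert np.array_equal(a, b)
        ring_near = (self.dist > 60) & (self.dist < 80)
        ring_far = (self.dist > 120) & (self.dist < 150)
        assert a[ring_near].mean() < a[ring_far].mean()


class TestPatchStatistics:
    def test_uniform_zero_map(self):
        ps = patch_statistics(np.zeros((20, 20)))
        assert ps.n_patches == 0

    def test_single_cell_patch(self):
        grid = np.zeros((20, 20))
        grid[5, 5] = 100.0
        ps = patch_statistics(grid)
        assert (ps.n_patches, ps.mean_patch_size) == (1, 1.0)

    def test_two_blob_grid_matches_flood_fill(self):
        # hand-built toy: a 2x2 blob and an L-shaped 3-cell blob, checked
        # against an independent brute-force flood fill
        grid = np.zeros((10, 10))
        for c in [(1, 1), (1, 2), (2, 1), (2, 2)]:
            grid[c] = 99.0
        for c in [(6, 6), (7, 6), (7, 7)]:
            grid[c] = 99.0

        def flood_sizes(mask):
            seen = set()
            sizes = []
            for i in range(mask.shape[0]):
                for j in range(mask.shape[1]):
                    if mask[i, j] and (i, j) not in seen:
                        stack, comp = [(i, j)], 0
                        while stack:
                            a, b = stack.pop()
                            if (a, b) in seen or not (
                                0 <= a < 10 and 0 <= b < 10 and mask[a, b]
                            ):
                                continue
                            seen.add((a, b))
                            comp += 1
                            stack += [(a + 1, b), (a - 1, b), (a, b + 1), (a, b - 1)]
                        sizes.append(comp)
            return sorted(sizes)

        ps = patch_statistics(grid, threshold=55.0)
        assert ps.n_patches == 2
        assert sorted([3, 4]) == flood_sizes(grid > 55.0)
        assert ps.mean_patch_size == pytest.approx(3.5)

    def test_diagonal_cells_are_separate_patches(self):
        grid = np.zeros((5, 5))
        grid[1, 1] = grid[2, 2] = 99.0
        assert patch_statistics(grid).n_patches == 2


class TestAvgEnv:
    def test_mean_of_positive_cells(self):
        grid = np.zeros((4, 4))
        grid[0, 0], grid[1, 1] = 2.0, 4.0
        assert avg_env(grid) == pytest.approx(3.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            avg_env(np.zeros((4, 4)))


class TestGenerateField:
    def test_determinism_bit_identical(self):
        cfg = MapConfig(aggreg=3, abund=180, dist=150, seed=7)
        a = generate_field(cfg)
        b = generate_field(cfg)
        assert np.array_equal(a.values, b.values)

    def test_zero_mask_invariant(self):
        m = generate_field(MapConfig(aggreg=4, abund=270, dist=200, seed=1))
        assert (m.values[m.dist_field <= 50.0] == 0).all()
        assert (m.values[m.dist_field > 500.0] == 0).all()
        assert (m.values >= 0).all()
        assert m.avg_env > 0

    def test_total_abundance_normalisation(self):
        m = generate_field(MapConfig(aggreg=3, abund=180, dist=150, seed=3))
        assert m.values.mean() == pytest.approx(180.0, abs=1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MapConfig(aggreg=5)
        with pytest.raises(ValueError):
            MapConfig(dist=30)

    def test_aggregation_monotonicity(self):
        # mean patch size grows and patch count falls with aggregation
        levels = (0, 3, 10)
        counts, sizes = [], []
        for a in levels:
            n, s = [], []
            for seed in range(15):
                ps = patch_statistics(
                    generate_field(MapConfig(aggreg=a, abund=180, dist=300,
                                             seed=seed)).values)
                n.append(ps.n_patches)
                s.append(ps.mean_patch_size)
            counts.append(np.mean(n))
            sizes.append(np.mean(s))
        assert counts[0] > counts[1] > counts[2]
        assert sizes[0] < sizes[1] < sizes[2]

    def test_roundtrip_csv(self, tmp_path, reference_map):
        f = tmp_path / "map.csv"
        reference_map.save(f)
        loaded = type(reference_map).load(f)
        assert np.allclose(loaded.values, reference_map.values, atol=1e-4)
        assert loaded.config.aggreg == reference_map.config.aggreg
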