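"""Raster pipeline, connectivity matrices, IIC/PC, top-k comparison."""

import math

import numpy as np
import pytest

from econnect import (
    CentralityResult,
    ConnectivityMatrix,
    ElevationRaster,
    KernelParams,
    PatchSet,
    coarse_grain,
    compare_topk,
    dispersal_probabilities,
    habitat_mask,
    hop_counts,
    iic,
    interpatch_distances,
    label_patches,
    pc,
    read_ascii_grid,
    write_ascii_grid,
)
from econnect.fixtures import synthetic_dem
from econnect.landscape import _max_product_matrix


def flood_fill_label_count(mask: np.ndarray, connectivity: int) -> int:
    """Independent labelling oracle: iterative flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    count = 0
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < rows and 0 <= cc < cols
                                and mask[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


def two_patch_set(gap_cells: int = 1, cell_size: float = 1.0) -> PatchSet:
    """Two single-cell patches on one row, `gap_cells` apart."""
    labels = np.zeros((1, gap_cells + 2), dtype=int)
    labels[0, 0], labels[0, -1] = 1, 2
    area = cell_size**2
    return PatchSet(
        labels=labels,
        cell_size=cell_size,
        areas=np.array([area, area]),
        boundaries=[np.array([[0, 0]]), np.array([[0, gap_cells + 1]])],
        total_area=2 * area,
    )


class TestCoarseGrain:
    def test_constant_blocks_reduce_exactly(self):
        vals = np.kron(np.array([[1.0, 2.0], [3.0, 4.0]]), np.ones((2, 2)))
        r = ElevationRaster(vals, cell_size=1.0)
        out = coarse_grain(r, 2.0)
        np.testing.assert_array_equal(out.values,
                                      [[1.0, 2.0], [3.0, 4.0]])
        assert out.cell_size == 2.0

    def test_block_mean(self):
        r = ElevationRaster(np.array([[0.0, 1000.0], [1000.0, 2000.0]]),
                            cell_size=1.0)
        out = coarse_grain(r, 2.0)
        assert out.values[0, 0] == 1000.0

    def test_partial_edge_blocks(self):
        r = ElevationRaster(np.arange(6, dtype=float).reshape(2, 3),
                            cell_size=1.0)
        out = coarse_grain(r, 2.0)
        assert out.shape == (1, 2)
        assert out.values[0, 1] == pytest.approx((2 + 5) / 2)

    def test_target_below_native_rejected(self):
        r = ElevationRaster(np.zeros((4, 4)), cell_size=2.0)
        with pytest.raises(ValueError, match=">= native"):
            coarse_grain(r, 1.0)


class TestHabitatMask:
    def test_band_is_inclusive(self):
        r = ElevationRaster(np.array([[499.0, 500.0, 2000.0, 2001.0]]),
                            cell_size=1.0)
        np.testing.assert_array_equal(
            habitat_mask(r, 500, 2000)[0], [False, True, True, False]
        )

    def test_all_ocean_is_empty(self):
        r = ElevationRaster(np.full((3, 3), -500.0), cell_size=1.0)
        assert not habitat_mask(r, 500, 2000).any()

    def test_nodata_never_habitat(self):
        r = ElevationRaster(np.array([[1000.0, -9999.0]]), cell_size=1.0,
                            nodata=-9999.0)
        np.testing.assert_array_equal(habitat_mask(r, 500, 2000)[0],
                                      [True, False])

    def test_inverted_band_rejected(self):
        r = ElevationRaster(np.zeros((2, 2)), cell_size=1.0)
        with pytest.raises(ValueError):
            habitat_mask(r, 2000, 500)


class TestLabelPatches:
    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.array([[1, 0], [0, 1]], dtype=bool)
        assert label_patches(mask, 1.0, connectivity=8).n_patches == 1
        assert label_patches(mask, 1.0, connectivity=4).n_patches == 2

    def test_single_cell_patch(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        ps = label_patches(mask, 2.0)
        assert ps.n_patches == 1
        assert ps.areas[0] == 4.0  # cell area = cell_size^2
        np.testing.assert_array_equal(ps.boundaries[0], [[1, 1]])

    def test_empty_mask_is_valid(self):
        ps = label_patches(np.zeros((2, 2), dtype=bool), 1.0)
        assert ps.n_patches == 0
        assert ps.total_area == 4.0

    def test_boundary_excludes_interior(self):
        mask = np.ones((3, 3), dtype=bool)
        ps = label_patches(mask, 1.0)
        # centre cell has 4 member neighbours -> interior
        assert [1, 1] not in ps.boundaries[0].tolist()
        assert len(ps.boundaries[0]) == 8

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(10))
    def test_random_masks_match_flood_fill(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 15)) < 0.4
        ps = label_patches(mask, 1.0, connectivity=connectivity)
        assert ps.n_patches == flood_fill_label_count(mask, connectivity)
        assert ps.areas.sum() == mask.sum()  # cell_size 1


class TestInterpatchDistances:
    def test_three_cells_apart_on_a_row(self):
        ps = two_patch_set(gap_cells=3)
        assert interpatch_distances(ps).d[0, 1] == 4.0  # centre-to-centre

    def test_adjacent_patches_one_cell_size(self):
        ps = two_patch_set(gap_cells=0, cell_size=2.5)
        assert interpatch_distances(ps).d[0, 1] == 2.5

    def test_matches_brute_force_over_boundary_pairs(self):
        raster, _ = synthetic_dem(rows=40, cols=40, n_bumps=3, seed=4,
                                  cell_size=1.0)
        mask = habitat_mask(raster, 500, 2000)
        ps = label_patches(mask, 1.0)
        cm = interpatch_distances(ps)
        for i in range(ps.n_patches):
            for j in range(i + 1, ps.n_patches):
                brute = min(
                    math.hypot(*(a - b))
                    for a in ps.boundaries[i].astype(float)
                    for b in ps.boundaries[j].astype(float)
                )
                assert cm.d[i, j] == pytest.approx(brute)


class TestDispersalKernel:
    def test_zero_distance_is_certain(self):
        cm = ConnectivityMatrix(d=np.zeros((2, 2)))
        cm = dispersal_probabilities(cm, KernelParams(0.03))
        assert np.all(cm.p == 1.0)

    def test_printed_kernel_value(self):
        cm = ConnectivityMatrix(d=np.array([[0.0, 100.0], [100.0, 0.0]]))
        cm = dispersal_probabilities(cm, KernelParams(alpha=0.03))
        assert cm.p[0, 1] == pytest.approx(math.exp(-3.0))
        assert cm.p[0, 1] == pytest.approx(0.049787, abs=1e-6)

    def test_monotone_decay(self):
        d = np.array([[0.0, 10.0, 50.0], [10.0, 0.0, 20.0],
                      [50.0, 20.0, 0.0]])
        cm = dispersal_probabilities(ConnectivityMatrix(d=d),
                                     KernelParams(0.1))
        assert cm.p[0, 1] > cm.p[1, 2] > cm.p[0, 2]

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            KernelParams(alpha=0.0)


class TestIndices:
    def test_single_patch_closed_form(self):
        labels = np.array([[1, 0], [0, 0]])
        ps = PatchSet(labels=labels, cell_size=1.0, areas=np.array([1.0]),
                      boundaries=[np.array([[0, 0]])], total_area=4.0)
        cm = interpatch_distances(ps)
        assert iic(ps, cm, threshold=1.0) == pytest.approx(1.0 / 16.0)

    def test_two_adjacent_patches(self):
        ps = two_patch_set(gap_cells=0)
        cm = interpatch_distances(ps)
        assert iic(ps, cm, threshold=1.0) == pytest.approx(0.75)
        cm = dispersal_probabilities(cm, KernelParams(1e-12))
        # p ~ 1 at tiny decay: PC approaches (sum a)^2 / A_L^2 = 1
        assert pc(ps, cm) == pytest.approx(1.0, abs=1e-9)
        cm.p = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert pc(ps, cm) == pytest.approx(0.75)

    def test_unreachable_patches_contribute_nothing(self):
        ps = two_patch_set(gap_cells=5)
        cm = interpatch_distances(ps)
        assert iic(ps, cm, threshold=1.0) == pytest.approx(0.5)

    def test_iic_monotone_in_added_edges(self):
        ps = two_patch_set(gap_cells=2)
        cm = interpatch_distances(ps)
        disconnected = iic(ps, cm, threshold=1.0)
        connected = iic(ps, cm, threshold=5.0)
        assert connected > disconnected

    def test_pc_monotone_in_probabilities(self):
        ps = two_patch_set(gap_cells=2)
        cm = interpatch_distances(ps)
        cm.p = np.array([[1.0, 0.2], [0.2, 1.0]])
        low = pc(ps, cm)
        cm.p = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert pc(ps, cm) > low

    def test_pc_at_least_iic_on_unit_probabilities(self):
        raster, _ = synthetic_dem(rows=40, cols=40, n_bumps=3, seed=4,
                                  cell_size=1.0)
        ps = label_patches(habitat_mask(raster, 500, 2000), 1.0)
        cm = interpatch_distances(ps)
        threshold = cm.d[cm.d > 0].max() + 1  # everything adjacent
        cm = hop_counts(cm, threshold)
        cm.p = np.where(cm.adjacency, 1.0, 0.0)
        np.fill_diagonal(cm.p, 1.0)
        assert pc(ps, cm) >= iic(ps, cm, threshold) - 1e-12

    def test_max_product_matrix_chains_through_stepping_stones(self):
        p = np.array([
            [1.0, 0.8, 0.5],
            [0.8, 1.0, 0.8],
            [0.5, 0.8, 1.0],
        ])
        pdot = _max_product_matrix(p)
        assert pdot[0, 2] == pytest.approx(0.64)
        assert np.all(pdot >= p - 1e-12)

    def test_max_product_matrix_matches_brute_force(self):
        from conftest import brute_force_max_product
        from econnect import EcoNetwork, EdgeSemantics
        rng = np.random.default_rng(11)
        n = 6
        d = rng.uniform(1, 60, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        cm = dispersal_probabilities(ConnectivityMatrix(d=d),
                                     KernelParams(0.05))
        pdot = _max_product_matrix(cm.p)
        nodes = tuple(str(i) for i in range(n))
        net = EcoNetwork(
            nodes=nodes,
            edges=[(nodes[i], nodes[j], float(cm.p[i, j]))
                   for i in range(n) for j in range(i + 1, n)],
            semantics=EdgeSemantics.probability(True),
        )
        for i in range(n):
            for j in range(i + 1, n):
                assert pdot[i, j] == pytest.approx(
                    brute_force_max_product(net, i, j), rel=1e-9
                )


class TestCompareTopK:
    def _result(self, scores):
        return CentralityResult(measure="BC", scores=scores, weighted=True)

    def test_identical_rankings(self):
        scores = {str(i): float(10 - i) for i in range(8)}
        out = compare_topk(self._result(scores), self._result(scores), k=5)
        assert out.overlap == 5
        assert out.jaccard == 1.0

    def test_disjoint_rankings(self):
        a = {"a": 3.0, "b": 2.0, "c": 0.0, "d": 0.0}
        b = {"a": 0.0, "b": 0.0, "c": 3.0, "d": 2.0}
        out = compare_topk(self._result(a), self._result(b), k=2)
        assert out.overlap == 0
        assert out.jaccard == 0.0

    def test_k_beyond_n_rejected(self):
        a = {"a": 1.0, "b": 0.5}
        with pytest.raises(ValueError, match="exceeds"):
            compare_topk(self._result(a), self._result(a), k=3)

    def test_tie_break_is_by_identifier(self):
        a = {"x": 1.0, "y": 1.0, "z": 1.0}
        out = compare_topk(self._result(a), self._result(a), k=2)
        assert out.top_a == ["x", "y"]


class TestRasterIO:
    def test_ascii_grid_round_trip(self, tmp_path):
        raster, _ = synthetic_dem(rows=10, cols=12, n_bumps=1, seed=2,
                                  cell_size=15.0)
        f = tmp_path / "dem.asc"
        write_ascii_grid(raster, f)
        back = read_ascii_grid(f)
        assert back.cell_size == raster.cell_size
        np.testing.assert_allclose(back.values, raster.values, rtol=1e-5)

    def test_header_mismatch_rejected(self, tmp_path):
        f = tmp_path / "bad.asc"
        f.write_text("ncols 3\nnrows 2\ncellsize 1\n1 2 3\n")
        with pytest.raises(ValueError, match="does not match"):
            read_ascii_grid(f)


class TestPipelineDeterminism:
    def test_same_raster_same_everything(self):
        results = []
        for _ in range(2):
            raster, _ = synthetic_dem(rows=40, cols=50, n_bumps=4, seed=9)
            ps = label_patches(habitat_mask(raster, 500, 2000),
                               raster.cell_size)
            cm = interpatch_distances(ps)
            cm = dispersal_probabilities(cm, KernelParams(0.03))
            results.append((ps.labels.copy(), iic(ps, cm, 100.0),
                            pc(ps, cm)))
        np.testing.assert_array_equal(results[0][0], results[1][0])
        assert results[0][1:] == results[1][1:]
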