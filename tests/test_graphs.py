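import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spicegcn import (
    CellTable,
    GeneRoleMap,
    ValidationError,
    build_dataset,
    build_radius_graph,
    compute_edge_attributes,
    load_graph,
    radius_edges,
    save_graph,
    split_by_group,
)
from .conftest import random_graph


def brute_force_edges(positions: np.ndarray, r: float) -> set[tuple[int, int]]:
    """O(n^2) reference edge set: directed pairs with 0 < d < r."""
    n = len(positions)
    out = set()
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(positions[i] - positions[j]) < r:
                out.add((i, j))
    return out


class TestRadiusEdges:
    def test_three_cell_example(self):
        pos = np.array([[0.0, 0.0], [3.0, 4.0], [10.0, 0.0]])
        edge_index, dist = radius_edges(pos, 6.0)
        pairs = set(map(tuple, edge_index.T))
        assert pairs == {(0, 1), (1, 0)}  # d01=5 < 6; d02=10; d12~8.06
        np.testing.assert_allclose(dist, [5.0, 5.0])

    def test_zero_radius_and_single_cell(self):
        pos = np.random.default_rng(0).uniform(0, 10, (5, 2))
        assert radius_edges(pos, 0.0)[0].shape == (2, 0)
        assert radius_edges(pos[:1], 30.0)[0].shape == (2, 0)

    def test_threshold_is_strict(self):
        pos = np.array([[0.0, 0.0], [5.0, 0.0]])
        assert radius_edges(pos, 5.0)[0].shape == (2, 0)
        assert radius_edges(pos, 5.0 + 1e-9)[0].shape == (2, 2)

    def test_empty_cell_set_rejected(self):
        with pytest.raises(ValidationError):
            radius_edges(np.zeros((0, 2)), 10.0)

    @pytest.mark.parametrize("n,seed", [(50, 0), (200, 1), (500, 2)])
    def test_matches_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 120, (n, 2))
        for r in (0.0, 5.0, 15.0, 30.0):
            edge_index, _ = radius_edges(pos, r)
            assert set(map(tuple, edge_index.T)) == brute_force_edges(pos, r)

    def test_edges_symmetric_and_sorted(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 60, (80, 2))
        edge_index, _ = radius_edges(pos, 20.0)
        pairs = set(map(tuple, edge_index.T))
        assert all((j, i) in pairs for i, j in pairs)
        order = np.lexsort((edge_index[1], edge_index[0]))
        np.testing.assert_array_equal(order, np.arange(edge_index.shape[1]))

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        r1=st.floats(0.0, 40.0),
        r2=st.floats(0.0, 40.0),
    )
    def test_monotone_in_radius(self, seed, r1, r2):
        """r <= r' implies the radius-r edge set is a subset of the radius-r' set."""
        lo, hi = sorted([r1, r2])
        pos = np.random.default_rng(seed).uniform(0, 100, (40, 2))
        small = set(map(tuple, radius_edges(pos, lo)[0].T))
        big = set(map(tuple, radius_edges(pos, hi)[0].T))
        assert small <= big


class TestEdgeAttributes:
    def test_polar_values(self):
        pos = np.array([[0.0, 0.0], [3.0, 4.0], [1.0, 0.0], [0.0, -2.0]])
        edges = np.array([[1, 2, 3], [0, 0, 0]])  # (src, dst): displacement dst->src
        attr = compute_edge_attributes(pos, edges)
        np.testing.assert_allclose(attr[0], [5.0, 0.9272952180016122], rtol=1e-12)
        np.testing.assert_allclose(attr[1], [1.0, 0.0], atol=1e-15)
        np.testing.assert_allclose(attr[2], [2.0, -np.pi / 2], rtol=1e-12)

    def test_distance_symmetric_angle_antisymmetric(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 50, (30, 2))
        edge_index, dist = radius_edges(pos, 25.0)
        attr = compute_edge_attributes(pos, edge_index)
        np.testing.assert_allclose(attr[:, 0], dist, rtol=1e-12)
        lookup = {(s, d): a for (s, d), a in zip(edge_index.T, attr)}
        for (s, d), a in lookup.items():
            rev = lookup[(d, s)]
            assert np.isclose(rev[0], a[0])
            assert np.isclose((a[1] - rev[1]) % (2 * np.pi), np.pi)

    def test_spherical_mode(self):
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]])
        attr = compute_edge_attributes(pos, np.array([[1], [0]]))
        np.testing.assert_allclose(attr[0], [2.0, 0.0, 0.0], atol=1e-15)

    def test_mode_dimension_mismatch_rejected(self):
        pos = np.zeros((2, 3))
        with pytest.raises(ValidationError):
            compute_edge_attributes(pos, np.array([[1], [0]]), mode="polar2d")

    def test_zero_displacement_rejected(self):
        pos = np.zeros((2, 2))
        with pytest.raises(ValidationError):
            compute_edge_attributes(pos, np.array([[1], [0]]))


def _two_slice_cells(n_per_slice=8, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(4):
        for i in range(n_per_slice):
            rows.append(
                {
                    "cell_id": f"s{s}i{i}",
                    "slice_id": f"slice{s}",
                    "animal_id": f"animal{s}",
                    "x": rng.uniform(0, 50),
                    "y": rng.uniform(0, 50),
                    "cell_type": rng.choice(["A", "B", "C", "D"]),
                    "L1": rng.exponential(1.0),
                    "Y1": rng.exponential(1.0),
                }
            )
    return CellTable(pd.DataFrame(rows)), GeneRoleMap({"L1": "ligand", "Y1": "response"})


class TestBuildDataset:
    def test_one_graph_per_slice_and_partition(self):
        cells, roles = _two_slice_cells()
        split = split_by_group(cells, "animal_id", fractions=(0.5, 0.25, 0.25), seed=0)
        graphs = build_dataset(cells, roles, split, r=20.0)
        assert len(graphs["train"]) == 2
        assert len(graphs["validation"]) == 1 and len(graphs["test"]) == 1
        total = sum(g.n_nodes for part in graphs.values() for g in part)
        assert total == cells.n_cells

    def test_cell_type_one_hot_widens_features(self):
        cells, roles = _two_slice_cells()
        split = split_by_group(cells, "animal_id", fractions=(0.5, 0.25, 0.25), seed=0)
        graphs = build_dataset(cells, roles, split, r=20.0, use_cell_types=True)
        g = graphs["train"][0]
        assert g.features.shape[1] == 1 + 4  # 1 predictor + 4 cell types
        # one-hot block rows sum to 1
        np.testing.assert_allclose(g.features[:, 1:].sum(axis=1), 1.0)

    def test_zero_radius_graphs_have_no_edges(self):
        cells, roles = _two_slice_cells()
        split = split_by_group(cells, "animal_id", fractions=(0.5, 0.25, 0.25), seed=0)
        graphs = build_dataset(cells, roles, split, r=0.0)
        assert all(g.n_edges == 0 for part in graphs.values() for g in part)
        g = graphs["train"][0]
        assert g.features.shape[0] == g.targets.shape[0] > 0


class TestGraphSerialization:
    def test_round_trip(self, tmp_path):
        g = random_graph(np.random.default_rng(0), 20, radius=40.0)
        save_graph(g, tmp_path / "g0")
        back = load_graph(tmp_path / "g0")
        np.testing.assert_array_equal(back.edge_index, g.edge_index)
        np.testing.assert_allclose(back.edge_attr, g.edge_attr)
        np.testing.assert_allclose(back.features, g.features)
        np.testing.assert_allclose(back.targets, g.targets)
        assert back.radius == g.radius
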