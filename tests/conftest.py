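import numpy as np
import pandas as pd
import pytest

from spicegcn import CellTable, GeneRoleMap, TissueGraph
from spicegcn.graphs import compute_edge_attributes, radius_edges


@pytest.fixture
def tiny_cells() -> CellTable:
    """Three cells, one slice, two genes."""
    df = pd.DataFrame(
        {
            "cell_id": ["a", "b", "c"],
            "slice_id": "s0",
            "x": [0.0, 3.0, 10.0],
            "y": [0.0, 4.0, 0.0],
            "LigA": [0.5, 1.0, 0.0],
            "RespB": [2.0, 0.0, 7.3],
        }
    )
    return CellTable(df)


@pytest.fixture
def tiny_roles() -> GeneRoleMap:
    return GeneRoleMap({"LigA": "ligand", "RespB": "response"})


def random_graph(
    rng: np.random.Generator,
    n_nodes: int,
    n_features: int = 3,
    n_responses: int = 2,
    radius: float = 50.0,
    extent: float = 100.0,
) -> TissueGraph:
    """A random tissue graph for operator-level tests."""
    positions = rng.uniform(0, extent, size=(n_nodes, 2))
    edge_index, _ = radius_edges(positions, radius)
    edge_attr = (
        compute_edge_attributes(positions, edge_index)
        if edge_index.size
        else np.zeros((0, 2))
    )
    return TissueGraph(
        node_ids=np.array([f"c{i}" for i in range(n_nodes)]),
        positions=positions,
        features=rng.normal(size=(n_nodes, n_features)),
        targets=rng.normal(size=(n_nodes, n_responses)),
        edge_index=edge_index,
        edge_attr=edge_attr,
        radius=radius,
        feature_names=[f"f{i}" for i in range(n_features)],
        response_names=[f"r{i}" for i in range(n_responses)],
        slice_id="s0",
        group="s0",
    )
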