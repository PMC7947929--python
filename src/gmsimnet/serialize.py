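"""Plain-text serialization of networks, matrices and parcellations."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .simnet import BinaryNetwork, CubeParcellation, SimilarityMatrix

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_edge_list_tsv",
    "write_graphml",
    "read_graphml",
    "write_provenance_json",
    "write_parcellation_json",
    "read_parcellation_json",
]


def write_matrix_tsv(matrix: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(np.asarray(matrix, dtype=float)).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.10g"
    )
    return path


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).values.astype(float)


def write_edge_list_tsv(
    matrix: np.ndarray | SimilarityMatrix, path: str | Path
) -> Path:
    """Upper-triangle (node_i, node_j, value) rows, tab-separated."""
    m = matrix.rho if isinstance(matrix, SimilarityMatrix) else np.asarray(matrix)
    i, j = np.triu_indices(m.shape[0], k=1)
    df = pd.DataFrame({"node_i": i, "node_j": j, "value": m[i, j].astype(float)})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def write_graphml(network: BinaryNetwork, path: str | Path) -> Path:
    g = nx.from_numpy_array(network.adjacency.astype(np.uint8))
    g.graph["threshold_used"] = float(network.threshold_used)
    g.graph["null_method"] = network.null_method
    nx.write_graphml(g, str(path))
    return Path(path)


def read_graphml(path: str | Path) -> np.ndarray:
    g = nx.read_graphml(str(path), node_type=str)
    order = sorted(g.nodes, key=lambda x: int(x))
    return nx.to_numpy_array(g, nodelist=order) > 0


def write_provenance_json(network: BinaryNetwork, path: str | Path) -> Path:
    prov = {
        k: v for k, v in network.provenance.items()
        if not isinstance(v, np.ndarray)
    }
    payload = {
        "threshold_used": float(network.threshold_used),
        "null_method": network.null_method,
        "n_nodes": network.n,
        "n_edges": network.n_edges,
        "density": network.density,
        **prov,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
    return Path(path)


def write_parcellation_json(parc: CubeParcellation, path: str | Path) -> Path:
    payload = {
        "cube_origins": parc.cube_origins.tolist(),
        "cube_roi": parc.cube_roi.tolist(),
    }
    Path(path).write_text(json.dumps(payload))
    return Path(path)


def read_parcellation_json(path: str | Path) -> CubeParcellation:
    payload = json.loads(Path(path).read_text())
    return CubeParcellation(
        np.asarray(payload["cube_origins"], dtype=int),
        np.asarray(payload["cube_roi"], dtype=np.int32),
    )
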