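"""Subject-level 90-node functional connectivity and sparsity thresholding.

The node time series are parcel means of the cleaned (bandpassed) BOLD
data; their pairwise Pearson matrix is thresholded into binary undirected
graphs over the sparsity grid 0.05..0.50 (step 0.01). Edges are ranked by
|r| with deterministic lexicographic tie-breaks, so the 46 graphs are
nested by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

ALLOWED_NETWORKS = frozenset({
    "Visual", "Somatomotor", "Dorsal Attention", "Ventral Attention",
    "Limbic", "Frontoparietal Control", "Default Mode", "Subcortical",
})

SPARSITY_GRID = np.round(np.arange(0.05, 0.50 + 1e-9, 0.01), 2)


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson matrix with a Fisher-z copy and node metadata."""

    r: np.ndarray
    z: np.ndarray | None = None
    node_labels: list[str] = field(default_factory=list)
    network_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("|r| must be <= 1")

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass
class BinaryGraph:
    """Undirected binary adjacency at one sparsity threshold."""

    adjacency: np.ndarray
    sparsity: float
    edge_count: int

    def __post_init__(self):
        A = self.adjacency
        if A.dtype != bool or not (A == A.T).all() or A.diagonal().any():
            raise ValueError("adjacency must be boolean symmetric with zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


class MissingNodeError(ValueError):
    def __init__(self, labels):
        self.labels = list(labels)
        super().__init__(f"atlas labels without in-mask voxels: {self.labels}")


def extract_roi_timeseries(run, atlas) -> np.ndarray:
    """T x n_rois matrix of parcel-mean series (label order 1..n)."""
    if atlas.labels.shape != run.data.shape[:3]:
        raise ValueError("atlas grid does not match run grid")
    labels = atlas.labels
    missing = [l for l in range(1, atlas.n_rois + 1)
               if not ((labels == l) & run.mask).any()]
    if missing:
        raise MissingNodeError(missing)
    out = np.empty((run.n_volumes, atlas.n_rois), float)
    for l in range(1, atlas.n_rois + 1):
        out[:, l - 1] = run.data[(labels == l) & run.mask].mean(axis=0)
    return out


def pearson_matrix(ts: np.ndarray, node_labels: list[str] | None = None,
                   network_labels: list[str] | None = None) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of the columns of a T x n matrix."""
    ts = np.asarray(ts, float)
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = [int(v) for v in np.flatnonzero(sd == 0) + 1]
        raise ValueError(f"zero-variance node series: {bad}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, node_labels=node_labels or [],
                              network_labels=network_labels or [])


def fisher_z(matrix: ConnectivityMatrix, clip: float = 1e-7) -> ConnectivityMatrix:
    """Fill the Fisher-z copy, clipping |r| at 1 - clip to keep z finite."""
    r = matrix.r
    z = np.arctanh(np.sign(r) * np.minimum(np.abs(r), 1.0 - clip))
    np.fill_diagonal(z, 0.0)
    matrix.z = z
    return matrix


def max_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def _ranked_edges(r: np.ndarray):
    """Upper-triangle edges sorted by descending |r|, ties by (i, j)."""
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = np.abs(r[iu, ju])
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def sparsity_threshold(matrix: ConnectivityMatrix, S: float) -> BinaryGraph:
    """Keep the floor(S * max_edges) strongest-|r| edges as a binary graph."""
    if not (0 < S <= 0.5):
        raise ValueError("sparsity must lie in (0, 0.5]")
    n = matrix.n_nodes
    m = int(np.floor(S * max_edges(n) + 1e-9))
    iu, ju = _ranked_edges(matrix.r)
    A = np.zeros((n, n), bool)
    A[iu[:m], ju[:m]] = True
    A |= A.T
    return BinaryGraph(A, float(S), m)


def graph_series(matrix: ConnectivityMatrix, s_min: float = 0.05,
                 s_max: float = 0.50, step: float = 0.01) -> list[BinaryGraph]:
    """Nested binary graphs across the sparsity grid (46 by default)."""
    if step <= 0 or s_min <= 0 or s_max > 0.5 or s_min > s_max:
        raise ValueError("invalid sparsity grid")
    grid = np.round(np.arange(s_min, s_max + step / 2, step),
                    10)
    n = matrix.n_nodes
    iu, ju = _ranked_edges(matrix.r)
    graphs = []
    for S in grid:
        m = int(np.floor(S * max_edges(n) + 1e-9))
        A = np.zeros((n, n), bool)
        A[iu[:m], ju[:m]] = True
        A |= A.T
        graphs.append(BinaryGraph(A, float(S), m))
    return graphs


def load_network_labels(lookup: pd.DataFrame | str | None = None) -> pd.DataFrame:
    """Node -> large-scale network table (90 rows: node, name, network).

    The packaged default is a synthetic/approximate hand-made assignment of
    the 90 standard anatomical parcels to the seven canonical cortical
    networks plus a Subcortical network (thalamus, caudate, putamen,
    pallidum, hippocampus, amygdala); it stands in for an overlap-derived
    template assignment.
    """
    if lookup is None:
        with resources.files("connectoscope.data").joinpath(
                "aal90_networks.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
    elif isinstance(lookup, pd.DataFrame):
        table = lookup.copy()
    else:
        table = pd.read_csv(lookup, sep="\t")
    required = {"node", "name", "network"}
    if not required.issubset(table.columns):
        raise ValueError(f"lookup must have columns {sorted(required)}")
    table = table.sort_values("node").reset_index(drop=True)
    expected = set(range(1, 91))
    got = set(int(v) for v in table["node"])
    if got != expected:
        raise ValueError(f"lookup must cover nodes 1..90; missing "
                         f"{sorted(expected - got)}, extra {sorted(got - expected)}")
    unknown = set(table["network"]) - ALLOWED_NETWORKS
    if unknown:
        raise ValueError(f"unknown network labels: {sorted(unknown)}")
    return table


def attach_network_labels(matrix: ConnectivityMatrix,
                          lookup: pd.DataFrame | str | None = None) -> ConnectivityMatrix:
    table = load_network_labels(lookup)
    if matrix.n_nodes != 90:
        raise ValueError("network lookup is defined for 90-node matrices")
    matrix.node_labels = list(table["name"])
    matrix.network_labels = list(table["network"])
    return matrix
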