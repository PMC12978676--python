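"""Per-participant functional connectivity matrices.

Pairwise Pearson correlations between node time courses are Fisher
z-transformed (atanh); the diagonal and all negative entries are set to zero.
Only the strict upper triangle carries unique information and can be
vectorized for pattern analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import filter_atlas


class DegenerateSignalError(ValueError):
    """A node time course is constant, so its correlations are undefined."""


class NodeLookupError(KeyError):
    """A requested node id is absent from the matrix."""


@dataclass
class TimeSeriesMatrix:
    """One participant's node-by-volume BOLD-like signal."""

    participant: str
    data: np.ndarray          # shape (n_nodes, n_volumes)
    node_ids: list[str]
    tr_seconds: float
    group: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be 2-D (nodes x volumes)")
        if self.data.shape[0] != len(self.node_ids):
            raise ValueError("node_ids length must match number of rows")

    def signal(self, node_id: str) -> np.ndarray:
        try:
            return self.data[self.node_ids.index(node_id)]
        except ValueError as exc:
            raise NodeLookupError(node_id) from exc


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity with zeroed diagonal and clipped negatives."""

    participant: str
    nodes: list[str]
    z_matrix: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def submatrix(self, subset: list[str]) -> np.ndarray:
        try:
            idx = [self._index[n] for n in subset]
        except KeyError as exc:
            raise NodeLookupError(f"node {exc.args[0]!r} not in matrix") from exc
        return self.z_matrix[np.ix_(idx, idx)]


def compute_connectivity(ts: TimeSeriesMatrix, atlas: pd.DataFrame) -> ConnectivityMatrix:
    """Fisher-z connectivity restricted to included atlas nodes, in atlas order.

    entry(i, j) = max(0, atanh(pearson(ts_i, ts_j))) for i != j; diagonal 0.
    Correlations numerically at +-1 are clamped to 1 - 1e-12 in magnitude so
    the transform stays finite.
    """
    kept = filter_atlas(atlas)
    order = kept["node_id"].tolist()
    if ts.data.shape[1] < 3:
        raise ValueError("need at least 3 volumes to correlate")
    rows = []
    for nid in order:
        sig = ts.signal(nid)
        if np.ptp(sig) == 0:
            raise DegenerateSignalError(f"constant signal at node {nid!r}")
        rows.append(sig)
    x = np.vstack(rows)
    r = np.corrcoef(x)
    eps = 1e-12
    if np.any(np.abs(r[~np.eye(len(order), dtype=bool)]) >= 1.0):
        warnings.warn("correlation magnitude >= 1 clamped before Fisher transform",
                      stacklevel=2)
    r = np.clip(r, -1 + eps, 1 - eps)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z[z < 0] = 0.0
    z = (z + z.T) / 2.0  # enforce exact symmetry against float round-off
    return ConnectivityMatrix(participant=ts.participant, nodes=order, z_matrix=z)


def edge_vector(cm: ConnectivityMatrix, subset: list[str] | None = None) -> np.ndarray:
    """Strict upper-triangle entries of the (sub)matrix, row-major; length n(n-1)/2."""
    nodes = list(cm.nodes) if subset is None else list(subset)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to form edges")
    sub = cm.submatrix(nodes)
    iu = np.triu_indices(len(nodes), k=1)
    return sub[iu]


def edge_labels(nodes: list[str]) -> list[str]:
    iu = np.triu_indices(len(nodes), k=1)
    return [f"{nodes[i]}|{nodes[j]}" for i, j in zip(*iu)]


def write_connectivity_csv(cm: ConnectivityMatrix, path) -> None:
    pd.DataFrame(cm.z_matrix, index=cm.nodes, columns=cm.nodes).to_csv(path)


def read_connectivity_csv(path, participant: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(participant=participant,
                              nodes=[str(c) for c in df.columns],
                              z_matrix=df.to_numpy(dtype=float))
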