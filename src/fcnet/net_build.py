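"""Network construction: ROI time series -> Fisher-z connectivity -> binarized graphs.

The construction pipeline mirrors the standard functional-connectome recipe:
regional BOLD time series are correlated pairwise (Pearson), the correlation
matrix is variance-stabilized with Fisher's r-to-z transform, and the z matrix
is thresholded at a sweep of sparsity levels so that every subject's network
has exactly the same number of nodes and edges at each level.

Thresholding operates on |z|; because atanh is odd and strictly increasing,
ranking by |z| and by |r| are identical, so the choice is a convention, not a
modelling decision.  Negative correlations are kept by magnitude and their
sign is discarded after binarization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "ZConnectivity",
    "SparsityGrid",
    "BinaryNetwork",
    "compute_connectivity",
    "binarize_at_sparsity",
    "sweep",
    "check_min_sparsity",
    "edge_count_for_sparsity",
]


def _default_labels(n: int) -> list[str]:
    return [f"ROI{i + 1:03d}" for i in range(n)]


@dataclass
class RoiTimeSeries:
    """One subject's cleaned regional BOLD matrix (time points x regions)."""

    subject_id: str
    values: np.ndarray
    tr_seconds: float = 2.0
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D array (time x regions)")
        t, n = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 time points, got {t}")
        if n < 3:
            raise ValueError(f"need at least 3 regions, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"subject {self.subject_id}: non-finite values in time series")
        if not self.region_labels:
            self.region_labels = _default_labels(n)
        if len(self.region_labels) != n:
            raise ValueError("region_labels length does not match number of columns")
        sd = self.values.std(axis=0)
        flat = np.nonzero(sd == 0)[0]
        if flat.size:
            names = ", ".join(self.region_labels[i] for i in flat[:5])
            raise ValueError(
                f"subject {self.subject_id}: zero-variance region(s): {names}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ZConnectivity:
    """Symmetric N x N Fisher-z connectivity matrix; diagonal stored as 0."""

    z: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("connectivity must be a square matrix")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectivity contains non-finite entries")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("connectivity must be symmetric")
        if np.any(np.diag(self.z) != 0):
            self.z = self.z.copy()
            np.fill_diagonal(self.z, 0.0)
        if not self.region_labels:
            self.region_labels = _default_labels(self.z.shape[0])
        if len(self.region_labels) != self.z.shape[0]:
            raise ValueError("region_labels length mismatch")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class SparsityGrid:
    """Ordered sweep of sparsity thresholds S_1..S_n.

    Default matches the common connectome convention of 0.11 to 0.34 in steps
    of 0.01 (24 levels), chosen so the sparsest network keeps the mean degree
    above 2 ln N while the densest still shows small-world structure.
    """

    s_min: float = 0.11
    s_max: float = 0.34
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.s_min <= self.s_max < 1):
            raise ValueError("grid bounds must satisfy 0 < s_min <= s_max < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.step)) + 1
        vals = self.s_min + self.step * np.arange(n)
        return np.round(vals, 10)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def width(self) -> float:
        """Integration width S_n - S_1 of the sweep."""
        v = self.values
        return float(v[-1] - v[0])


@dataclass
class BinaryNetwork:
    """Undirected simple graph at one sparsity level, as a 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def edge_count_for_sparsity(s: float, n_nodes: int) -> int:
    """Target edge count K = round(S * N(N-1)/2), half-up."""
    return int(math.floor(s * n_nodes * (n_nodes - 1) / 2 + 0.5))


def compute_connectivity(ts: RoiTimeSeries) -> ZConnectivity:
    """Pairwise Pearson correlation of regions followed by Fisher's r-to-z.

    Raises if any pair of distinct regions correlates at |r| = 1 (the z
    transform diverges; in practice this signals duplicated or degenerate
    signals rather than genuine connectivity).
    """
    r = np.corrcoef(ts.values, rowvar=False)
    off = ~np.eye(ts.n_regions, dtype=bool)
    bad = np.abs(r[off]) >= 1.0 - 1e-12
    if bad.any():
        i, j = np.nonzero(off & (np.abs(r) >= 1.0 - 1e-12))
        a, b = int(i[0]), int(j[0])
        raise ValueError(
            f"subject {ts.subject_id}: |r| = 1 between regions "
            f"{ts.region_labels[a]} and {ts.region_labels[b]}; z transform diverges"
        )
    z = np.arctanh(np.where(off, r, 0.0))
    z = (z + z.T) / 2.0  # enforce exact symmetry against float asymmetry
    np.fill_diagonal(z, 0.0)
    return ZConnectivity(z=z, region_labels=list(ts.region_labels))


def _ranked_pairs(conn: ZConnectivity) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs ranked by descending |z|, ties by ascending (i, j)."""
    n = conn.n_regions
    iu, ju = np.triu_indices(n, k=1)
    absz = np.abs(conn.z[iu, ju])
    # np.lexsort sorts by the last key first: primary -|z|, then i, then j
    order = np.lexsort((ju, iu, -absz))
    return iu[order], ju[order]


def binarize_at_sparsity(conn: ZConnectivity, s: float) -> BinaryNetwork:
    """Keep exactly round(s * N(N-1)/2) strongest |z| edges.

    Ties at the threshold boundary are broken deterministically by ascending
    (i, j) lexicographic order so repeated runs build identical networks.
    """
    if not (0.0 < s < 1.0):
        raise ValueError(f"sparsity must lie in (0, 1), got {s}")
    n = conn.n_regions
    total = n * (n - 1) // 2
    k = edge_count_for_sparsity(s, n)
    if k == 0 or k == total:
        warnings.warn(
            f"sparsity {s} rounds to {'an empty' if k == 0 else 'a complete'} graph "
            f"({k} of {total} edges)",
            stacklevel=2,
        )
    iu, ju = _ranked_pairs(conn)
    adj = np.zeros((n, n), dtype=np.uint8)
    sel_i, sel_j = iu[:k], ju[:k]
    adj[sel_i, sel_j] = 1
    adj[sel_j, sel_i] = 1
    return BinaryNetwork(adjacency=adj, sparsity=s)


def sweep(conn: ZConnectivity, grid: SparsityGrid | None = None) -> list[BinaryNetwork]:
    """Binarize at every grid level; one |z| ranking is shared by all levels,
    so edge sets are nested across the sweep."""
    if grid is None:
        grid = SparsityGrid()
    n = conn.n_regions
    iu, ju = _ranked_pairs(conn)
    nets = []
    for s in grid.values:
        k = edge_count_for_sparsity(float(s), n)
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[iu[:k], ju[:k]] = 1
        adj[ju[:k], iu[:k]] = 1
        nets.append(BinaryNetwork(adjacency=adj, sparsity=float(s)))
    return nets


def check_min_sparsity(net: BinaryNetwork) -> bool:
    """True iff the mean nodal degree exceeds 2 ln N.

    Below this bound a thresholded network tends to fragment and small-world
    estimates become unstable, so the lowest sweep level should satisfy it.
    """
    n = net.n_nodes
    mean_degree = 2.0 * net.n_edges / n
    return bool(mean_degree > 2.0 * math.log(n))
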