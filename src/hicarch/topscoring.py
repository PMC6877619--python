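"""Non-parametric selection and clustering of top-scoring interactions.

For every cis diagonal (distance >= 2 bins) independently, cells whose
normalized value is strictly above the diagonal's percentile threshold
(default 95th) are selected. Because the threshold is per diagonal, the
selection is insensitive to the distance decay and to global coverage
differences. Selected points are then single-linkage clustered under
Euclidean distance in bin coordinates; with the default 25-kb link
distance and 25-kb bins this links only immediately neighbouring points.
The fraction of points in clusters of size >= 2 ("clustered fraction")
summarizes how organized the top-scoring pattern is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .matrix import ContactMatrix


@dataclass
class TopPointSet:
    chromosome: str
    points: np.ndarray  # (k, 2) local bin coordinates, bin_i < bin_j
    values: np.ndarray
    bin_size: int
    threshold_pct: float = 95.0
    max_dist: int | None = None  # bp
    cluster_id: np.ndarray | None = None


def select_top_interactions(
    m: ContactMatrix, pct: float = 95.0, max_dist: int | None = None
) -> dict[str, TopPointSet]:
    """Per-diagonal percentile selection of cis interactions per chromosome.

    The percentile (linear-interpolation convention) is computed over the
    full diagonal including structurally absent cells as zeros; cells
    strictly greater than the threshold are selected, so constant
    diagonals yield nothing. Diagonals 0 and 1 are never scanned;
    ``max_dist`` (bp) truncates the scanned distance range.
    """
    if not (0 < pct < 100):
        raise ValueError("pct must be in (0, 100)")
    if m.kind not in ("balanced", "frequency"):
        raise ValueError("select_top_interactions expects a balanced or frequency matrix")
    bs = m.genome.bin_size
    out: dict[str, TopPointSet] = {}
    for c in m.genome.chrom_names:
        dense = m.cis_dense(c)
        n = dense.shape[0]
        dmax = n - 1
        if max_dist is not None:
            dmax = min(dmax, max_dist // bs)
        pts, vals = [], []
        for d in range(2, dmax + 1):
            diag = np.diagonal(dense, d)
            thr = np.percentile(diag, pct)
            sel = np.flatnonzero(diag > thr)
            if sel.size:
                pts.append(np.column_stack([sel, sel + d]))
                vals.append(diag[sel])
        points = np.vstack(pts) if pts else np.empty((0, 2), dtype=np.int64)
        values = np.concatenate(vals) if vals else np.empty(0)
        out[c] = TopPointSet(c, points, values, bs, pct, max_dist)
    return out


def cluster_interactions(s: TopPointSet, link_dist: int = 25000) -> TopPointSet:
    """Single-linkage clustering of top-scoring points.

    Two points are linked when their Euclidean distance in bin coordinates
    times the bin size is <= ``link_dist``; clusters are the connected
    components of the link graph.
    """
    k = len(s.points)
    if k == 0:
        return TopPointSet(
            s.chromosome, s.points, s.values, s.bin_size, s.threshold_pct, s.max_dist,
            cluster_id=np.empty(0, dtype=np.int64),
        )
    r_bins = link_dist / s.bin_size
    tree = cKDTree(s.points.astype(float))
    pairs = tree.query_pairs(r_bins + 1e-9, output_type="ndarray")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(k, k)
    )
    _, labels = connected_components(adj, directed=False)
    return TopPointSet(
        s.chromosome, s.points, s.values, s.bin_size, s.threshold_pct, s.max_dist,
        cluster_id=labels.astype(np.int64),
    )


def clustered_fraction(s: TopPointSet) -> float:
    """Fraction of points belonging to clusters of size >= 2."""
    if s.cluster_id is None:
        raise ValueError("point set is not clustered")
    if len(s.points) == 0:
        raise ValueError(f"chromosome {s.chromosome!r}: empty point set")
    sizes = np.bincount(s.cluster_id)
    return float((sizes[s.cluster_id] >= 2).sum() / len(s.points))


def clustered_fraction_difference(a: TopPointSet, b: TopPointSet) -> float:
    """Difference of clustered fractions, fraction(a) − fraction(b)."""
    if (a.threshold_pct, a.max_dist) != (b.threshold_pct, b.max_dist):
        raise ValueError("point sets selected with different parameters")
    return clustered_fraction(a) - clustered_fraction(b)
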