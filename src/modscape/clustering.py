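"""Density-based partitioning of the 2-D projection.

Three routes to the same ``ClusterAssignment`` contract:

* :func:`cluster_density` — exact hierarchical density clustering
  (HDBSCAN), optionally with complete ("soft") assignment of noise
  points;
* :func:`cluster_density_histogram` — an approximate sketch for very
  large inputs: a multiplicity-weighted 2-D histogram thresholded at a
  density quantile, with connected foreground bins forming clusters;
* :func:`select_polygon` — manual extraction by polygon contour.

Cluster ids are always consecutive integers from 0, ordered by each
cluster's first member record, so labels are stable under record
permutation; -1 marks noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import HDBSCAN
from sklearn.neighbors import NearestNeighbors

from .embedding import Projection

logger = logging.getLogger("modscape")


@dataclass
class ClusterAssignment:
    labels: np.ndarray                      # per-record int, -1 = noise
    method: str
    params: dict = field(default_factory=dict)
    soft_memberships: np.ndarray | None = None   # n x n_clusters

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0


def _canonical_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber non-noise labels 0..C-1 in order of first appearance."""
    out = np.full_like(labels, -1)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_density(
    proj: Projection,
    min_cluster_size: int = 20,
    min_samples: int | None = None,
    soft: bool = False,
) -> ClusterAssignment:
    """HDBSCAN partition of the projection.

    ``soft=True`` performs complete assignment: every noise point takes the
    label of its nearest clustered point, and approximate membership vectors
    (inverse centroid distance, normalised) are attached.
    """
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    coords = proj.coords[:, :2]
    n = coords.shape[0]
    if n == 0:
        raise ValueError("empty projection")
    params = {"min_cluster_size": min_cluster_size,
              "min_samples": min_samples, "soft": soft}

    if min_cluster_size > n:
        labels = np.full(n, -1)
    else:
        model = HDBSCAN(min_cluster_size=min_cluster_size, min_samples=min_samples,
                        copy=True)
        labels = model.fit_predict(coords)
    labels = _canonical_relabel(np.asarray(labels))

    memberships = None
    if soft and (labels >= 0).any():
        noise = labels == -1
        if noise.any():
            nn = NearestNeighbors(n_neighbors=1).fit(coords[~noise])
            _, idx = nn.kneighbors(coords[noise])
            labels = labels.copy()
            labels[noise] = labels[~noise][idx[:, 0]]
            labels = _canonical_relabel(labels)
        n_clusters = labels.max() + 1
        centroids = np.vstack([coords[labels == c].mean(axis=0)
                               for c in range(n_clusters)])
        dist = np.linalg.norm(coords[:, None, :] - centroids[None, :, :], axis=2)
        inv = 1.0 / (dist + 1e-12)
        memberships = inv / inv.sum(axis=1, keepdims=True)
    elif soft:
        logger.warning("cluster_density: soft assignment requested but no "
                       "clusters were found; all records remain noise")

    return ClusterAssignment(labels, method="hdbscan", params=params,
                             soft_memberships=memberships)


def cluster_density_histogram(
    proj: Projection,
    multiplicities: np.ndarray | None = None,
    bins: int = 512,
    density_quantile: float = 0.90,
    connectivity: int = 8,
) -> ClusterAssignment:
    """Approximate clustering via a weighted density histogram.

    The projection plane is binned; bin weight is the summed site
    multiplicity (a k-mer shared by 1000 sites weighs as 1000 co-located
    points).  Bins at or above the ``density_quantile`` of nonzero bin
    weights are foreground; connected foreground components become clusters
    and records in background bins are noise.
    """
    if bins < 16:
        raise ValueError("bins must be >= 16")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    coords = proj.coords[:, :2]
    n = coords.shape[0]
    if n == 0:
        raise ValueError("empty projection")
    weights = np.ones(n) if multiplicities is None else np.asarray(multiplicities, float)

    hist, xedges, yedges = np.histogram2d(coords[:, 0], coords[:, 1],
                                          bins=bins, weights=weights)
    nonzero = hist[hist > 0]
    threshold = np.quantile(nonzero, density_quantile)
    foreground = hist >= threshold

    structure = (np.ones((3, 3), dtype=int) if connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    components, n_components = ndimage.label(foreground, structure=structure)

    ix = np.clip(np.digitize(coords[:, 0], xedges) - 1, 0, bins - 1)
    iy = np.clip(np.digitize(coords[:, 1], yedges) - 1, 0, bins - 1)
    labels = components[ix, iy] - 1          # background component 0 -> -1
    labels = _canonical_relabel(labels)
    logger.info("cluster_density_histogram: %d foreground component(s), "
                "%d/%d records clustered", n_components, int((labels >= 0).sum()), n)
    return ClusterAssignment(labels, method="density_histogram",
                             params={"bins": bins, "density_quantile": density_quantile,
                                     "connectivity": connectivity})


# ---------------------------------------------------------------------------
# Manual extraction
# ---------------------------------------------------------------------------

def _on_segment(px, py, ax, ay, bx, by, eps=1e-12) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > eps * max(1.0, abs(bx - ax) + abs(by - ay)):
        return False
    return (min(ax, bx) - eps <= px <= max(ax, bx) + eps
            and min(ay, by) - eps <= py <= max(ay, by) + eps)


def _point_in_polygon(px: float, py: float, poly: np.ndarray) -> bool:
    """Even-odd (ray casting) test; boundary points count as inside."""
    m = poly.shape[0]
    inside = False
    for i in range(m):
        ax, ay = poly[i]
        bx, by = poly[(i + 1) % m]
        if _on_segment(px, py, ax, ay, bx, by):
            return True
        if (ay > py) != (by > py):
            x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_cross:
                inside = not inside
    return inside


def select_polygon(proj: Projection, polygon) -> np.ndarray:
    """Boolean membership mask of projection points inside a polygon.

    Uses the even-odd rule, so self-intersecting polygons are legal;
    boundary points are inside.  A zero-area polygon is rejected.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    # a self-intersecting polygon can have zero *signed* area, so degeneracy
    # is collinearity of the vertices, not a zero shoelace sum
    if np.linalg.matrix_rank(poly - poly[0]) < 2:
        raise ValueError("degenerate zero-area polygon")
    coords = proj.coords[:, :2]
    return np.array([_point_in_polygon(px, py, poly) for px, py in coords])


def merge_clusters(assign: ClusterAssignment, mapping: dict[int, int]) -> ClusterAssignment:
    """Relabel clusters through ``mapping`` (old id -> new id) and renumber.

    The mapping must cover every non-noise id; noise points are untouched and
    the record count never changes.
    """
    present = set(int(l) for l in np.unique(assign.labels) if l != -1)
    missing = present - set(mapping)
    if missing:
        raise ValueError(f"mapping missing cluster id(s): {sorted(missing)}")
    labels = np.array([mapping[int(l)] if l != -1 else -1 for l in assign.labels])
    labels = _canonical_relabel(labels)
    return ClusterAssignment(labels, method=assign.method + "+merge",
                             params={**assign.params, "merge_mapping": dict(mapping)})


def write_cluster_table(proj: Projection, assign: ClusterAssignment, path) -> None:
    soft_max = (assign.soft_memberships.max(axis=1)
                if assign.soft_memberships is not None else None)
    with open(path, "w") as fh:
        fh.write("id\tx\ty\tlabel\tsoft_membership_max\n")
        for i, seq in enumerate(proj.row_index):
            sm = f"{soft_max[i]:.4f}" if soft_max is not None else "NA"
            fh.write(f"{seq}\t{proj.coords[i, 0]:.6f}\t{proj.coords[i, 1]:.6f}"
                     f"\t{assign.labels[i]}\t{sm}\n")
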