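"""2-D embedding of encoded k-mers.

Sequence similarity between one-hot rows is approximated by Euclidean
distance in a low-dimensional projection.  The default reducer is UMAP
with a fixed random state; the backend is pluggable through the
``reducer`` parameter so any callable satisfying the contract
(matrix -> n x 2 coordinates) can be substituted.

Rows are canonically sorted by sequence before reduction, so the
projection is independent of the order records arrive in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .sites_io import EncodedMatrix, KmerSet, SiteRecord, collapse_duplicates

logger = logging.getLogger("modscape")

DEFAULT_REDUCER_PARAMS = {
    "n_neighbors": 15,
    "min_dist": 0.1,
    "metric": "euclidean",
    "random_state": 42,
    "n_components": 2,
}


@dataclass
class Projection:
    coords: np.ndarray            # n x d (d = 2 by default)
    reducer_name: str
    params: dict = field(default_factory=dict)
    row_index: list[str] = field(default_factory=list)   # k-mer sequences per row

    def __post_init__(self) -> None:
        if self.row_index and len(self.row_index) != self.coords.shape[0]:
            raise ValueError("projection row index does not match coordinate count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("projection contains non-finite coordinates")


def _umap_backend(matrix: np.ndarray, params: dict) -> np.ndarray:
    import umap

    reducer = umap.UMAP(
        n_neighbors=min(params["n_neighbors"], matrix.shape[0] - 1),
        min_dist=params["min_dist"],
        metric=params["metric"],
        random_state=params["random_state"],
        n_components=params["n_components"],
    )
    return np.asarray(reducer.fit_transform(matrix), dtype=float)


def _pca_backend(matrix: np.ndarray, params: dict) -> np.ndarray:
    from sklearn.decomposition import PCA

    pca = PCA(n_components=params["n_components"], random_state=params["random_state"])
    return np.asarray(pca.fit_transform(matrix), dtype=float)


_BACKENDS: dict[str, Callable[[np.ndarray, dict], np.ndarray]] = {
    "umap": _umap_backend,
    "pca": _pca_backend,
}


def reduce_dimensions(
    encoded: EncodedMatrix,
    params: dict | None = None,
    reducer: str | Callable[[np.ndarray, dict], np.ndarray] = "umap",
) -> Projection:
    """Project encoded k-mers to 2-D (deterministic under a fixed seed).

    ``reducer`` may name a built-in backend ("umap", "pca") or be a callable
    ``(matrix, params) -> coords``.  Rows are sorted by sequence before the
    backend runs and un-sorted afterwards, so coordinates do not depend on
    input order.
    """
    merged = dict(DEFAULT_REDUCER_PARAMS)
    if params:
        merged.update(params)
    n = encoded.values.shape[0]
    if n < 10:
        raise ValueError(f"too few records for embedding: {n} < 10")
    if not np.all(np.isfinite(encoded.values)):
        raise ValueError("encoded matrix contains non-finite values")

    order = np.argsort(np.asarray(encoded.row_index), kind="stable")
    inverse = np.empty_like(order)
    inverse[order] = np.arange(n)

    backend = _BACKENDS[reducer] if isinstance(reducer, str) else reducer
    name = reducer if isinstance(reducer, str) else getattr(reducer, "__name__", "custom")
    coords_sorted = backend(encoded.values[order], merged)
    coords = coords_sorted[inverse]
    logger.info("reduce_dimensions: %s on %d records -> %d-D", name, n,
                merged["n_components"])
    return Projection(coords, reducer_name=name, params=merged,
                      row_index=list(encoded.row_index))


def flag_background(encoded: EncodedMatrix, n_neighbors: int = 15,
                    z_cutoff: float = 3.5) -> np.ndarray:
    """Flag records whose encoded-space neighborhood is background-like.

    Sequences with no shared motif have no close neighbors in one-hot
    space: their mean distance to the ``n_neighbors`` nearest records sits
    well above the bulk of motif-bearing records.  Records whose mean
    neighbor distance exceeds the robust z-score cutoff (median +
    ``z_cutoff`` MAD-scaled deviations) are flagged as background so the
    clustering stage can keep them out of motif clusters.  On homogeneous
    data nothing is flagged (the distance distribution has no outliers).
    """
    from sklearn.neighbors import NearestNeighbors

    n = encoded.values.shape[0]
    if n <= n_neighbors:
        return np.zeros(n, dtype=bool)
    dist, _ = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(
        encoded.values).kneighbors(encoded.values)
    mean_dist = dist[:, 1:].mean(axis=1)
    median = np.median(mean_dist)
    mad = 1.4826 * np.median(np.abs(mean_dist - median))
    if mad == 0:
        return np.zeros(n, dtype=bool)
    flagged = (mean_dist - median) / mad > z_cutoff
    if flagged.any():
        logger.info("flag_background: %d/%d record(s) flagged as background",
                    int(flagged.sum()), n)
    return flagged


def attach_projection(
    sites: Sequence[SiteRecord],
    kmers: KmerSet,
    proj: Projection,
) -> pd.DataFrame:
    """Annotate each site with the coordinates of its (possibly shared) k-mer.

    Sites collapsed onto one distinct k-mer inherit that k-mer's coordinates,
    which is how per-site density is recovered from a projection of distinct
    sequences only.
    """
    # pass the *uncollapsed* KmerSet here: after collapsing, only the first
    # site of each duplicate group remains as source_site
    seq_by_site: dict[str, str] = {}
    for rec in kmers:
        seq_by_site.setdefault(rec.source_site, rec.sequence)
    coord_by_seq = {seq: proj.coords[i] for i, seq in enumerate(proj.row_index)}

    rows = []
    for site in sites:
        seq = seq_by_site.get(site.site_id)
        if seq is None or seq not in coord_by_seq:
            raise ValueError(
                f"site {site.site_id!r} has no k-mer in the projection "
                "(mismatched provenance?)"
            )
        x, y = coord_by_seq[seq][:2]
        rows.append((site.site_id, site.chrom, site.pos0, site.strand, seq, x, y))
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos0", "strand",
                                       "kmer", "x", "y"])


def write_projection(proj: Projection, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tx\ty\n")
        for seq, (x, y) in zip(proj.row_index, proj.coords[:, :2]):
            fh.write(f"{seq}\t{x:.6f}\t{y:.6f}\n")
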