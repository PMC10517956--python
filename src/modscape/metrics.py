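"""Projection- and clustering-quality metrics.

Two bespoke projection metrics quantify how well labeled groups behave
in the 2-D plane:

* **outgroup-ingroup score** — ratio of the coefficient of variation of
  point-to-foreign-centroid distances over the CV of point-to-own-centroid
  distances.  Condensed, well-separated groups score high.
* **boundary score** — fraction of points whose 50 nearest neighbors
  contain more than 10% foreign-label points.  Crisp group boundaries
  score low.

Clustering is evaluated against truth labels with per-cluster precision /
recall (majority matching) and the adjusted Rand index, computed from the
pair-counting contingency-table definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.neighbors import NearestNeighbors

from .clustering import ClusterAssignment
from .motifs import PWM, pwm_divergence


@dataclass
class MetricReport:
    score: float
    per_group: dict | None = None
    params: dict = field(default_factory=dict)


def _coords_of(proj) -> np.ndarray:
    coords = proj.coords if hasattr(proj, "coords") else np.asarray(proj, float)
    return coords[:, :2]


def outgroup_ingroup_score(proj, labels) -> MetricReport:
    """CV ratio of outgroup over ingroup centroid distances (higher = better).

    Ingroup distance: each point to its own group centroid.  Outgroup
    distance: each point to every other group's centroid.  Distances are
    pooled across groups before taking SD/mean (population SD, ddof 0).
    """
    coords = _coords_of(proj)
    labels = np.asarray(labels)
    groups = [g for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    centroids = {}
    for g in groups:
        members = coords[labels == g]
        if members.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 points")
        centroids[g] = members.mean(axis=0)

    ingroup, outgroup = [], []
    for g in groups:
        members = coords[labels == g]
        ingroup.extend(np.linalg.norm(members - centroids[g], axis=1))
        for h in groups:
            if h == g:
                continue
            outgroup.extend(np.linalg.norm(members - centroids[h], axis=1))
    ingroup = np.array(ingroup)
    outgroup = np.array(outgroup)

    sd_in, mean_in = ingroup.std(ddof=0), ingroup.mean()
    sd_out, mean_out = outgroup.std(ddof=0), outgroup.mean()
    if 0 in (sd_in, mean_in, sd_out, mean_out):
        raise ValueError("degenerate geometry: zero SD or mean distance")
    score = (sd_out / mean_out) / (sd_in / mean_in)
    return MetricReport(score, params={"sd_convention": "population (ddof 0)",
                                       "pooling": "across groups"})


def boundary_score(proj, labels, k: int = 50, p_threshold: float = 0.1) -> MetricReport:
    """Fraction of points with > ``p_threshold`` foreign k-NN (lower = better).

    For each point, P is the proportion of its ``k`` nearest Euclidean
    neighbors (self excluded) carrying a different label; the score is the
    fraction of points with P > ``p_threshold``.
    """
    coords = _coords_of(proj)
    labels = np.asarray(labels)
    n = coords.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neighbor_labels = labels[idx[:, 1:]]            # drop self
    p = (neighbor_labels != labels[:, None]).mean(axis=1)
    score = float((p > p_threshold).mean())
    return MetricReport(score, params={"k": k, "p_threshold": p_threshold})


def precision_recall(assign: ClusterAssignment, truth,
                     match: str = "majority") -> pd.DataFrame:
    """Per-cluster precision/recall against truth labels by majority matching.

    Each cluster is assigned the truth class holding its plurality;
    precision is the majority fraction of the cluster, recall the majority
    count over the total class size.  Noise records belong to no cluster but
    still count in class sizes, so heavy noise depresses recall.
    """
    if match != "majority":
        raise ValueError(f"unknown matching scheme {match!r}")
    truth = np.asarray(truth)
    labels = assign.labels
    if truth.shape[0] != labels.shape[0]:
        raise ValueError("truth does not cover all records")
    if truth.shape[0] == 0:
        raise ValueError("empty cluster set")
    class_sizes = pd.Series(truth).value_counts()

    rows = []
    for c in range(assign.n_clusters):
        members = truth[labels == c]
        counts = pd.Series(members).value_counts()
        majority = counts.index[0]
        rows.append({
            "cluster": c,
            "size": len(members),
            "majority_class": majority,
            "precision": counts.iloc[0] / len(members),
            "recall": counts.iloc[0] / class_sizes[majority],
        })
    df = pd.DataFrame(rows, columns=["cluster", "size", "majority_class",
                                     "precision", "recall"])
    return df


def per_class_precision_recall(assign: ClusterAssignment, truth) -> pd.DataFrame:
    """Aggregate cluster-level matches per truth class.

    Clusters sharing a majority class are pooled: precision is the pooled
    majority count over pooled cluster size, recall the pooled majority
    count over the class size.  Classes captured by no cluster get
    precision NaN and recall 0.
    """
    truth = np.asarray(truth)
    per_cluster = precision_recall(assign, truth) if assign.n_clusters else \
        pd.DataFrame(columns=["cluster", "size", "majority_class",
                              "precision", "recall"])
    class_sizes = pd.Series(truth).value_counts()
    rows = []
    for cls, size in class_sizes.items():
        matched = per_cluster[per_cluster["majority_class"] == cls]
        if matched.empty:
            rows.append({"class": cls, "n_clusters": 0,
                         "precision": np.nan, "recall": 0.0})
            continue
        majority_total = (matched["precision"] * matched["size"]).sum()
        rows.append({
            "class": cls,
            "n_clusters": len(matched),
            "precision": majority_total / matched["size"].sum(),
            "recall": majority_total / size,
        })
    return pd.DataFrame(rows)


def adjusted_rand_index(a, b) -> float:
    """ARI from the pair-counting contingency table:
    ``(Index - Expected) / (Max - Expected)``."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("labelings differ in length")
    n = a.shape[0]
    contingency = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    sum_comb = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    total_pairs = comb(n, 2)
    expected = sum_a * sum_b / total_pairs if total_pairs else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:     # both labelings trivial (all-one-cluster etc.)
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def motif_kl_divergence(pwm_a: PWM, pwm_b: PWM, pseudocount: float = 0.01) -> float:
    """Mean per-position symmetrized KL divergence between two motifs (bits).

    Lower values indicate more similar motifs; 0 for identical PWMs.
    """
    return pwm_divergence(pwm_a, pwm_b, pseudocount=pseudocount)
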