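"""Sliding-window motif discovery and winscore enrichment validation.

Two independent uses of windows:

* **Position-free motif discovery** — when motif position relative to a
  reported site is unknown, every input sequence is cut into short
  overlapping windows, the windows are embedded and clustered like
  centered k-mers, and clusters with informative PWMs mark their source
  sequences as motif-positive.

* **winscore** — an IP-over-input enrichment score for antibody-based
  modification sequencing (e.g. m6A-seq).  Each gene is tiled into
  fixed-width windows and scored as

      winscore = log2( (MeanWinIP / MedianGeneIP)
                     / (MeanWinControl / MedianGeneControl) )

  i.e. window coverage in each track normalised by that track's gene
  median, so the score is invariant to library-depth scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("modscape")


# ---------------------------------------------------------------------------
# Window generation and sliding-window discovery
# ---------------------------------------------------------------------------

def generate_windows(sequences: Mapping[str, str], width: int = 20,
                     step: int = 1) -> pd.DataFrame:
    """Tile each sequence with [i, i+width) windows at the given step.

    A sequence of length L yields ``floor((L - width)/step) + 1`` windows
    (zero, with a warning, when L < width).  Provenance columns keep the
    source id and start offset.
    """
    if width < 4:
        raise ValueError("width must be >= 4")
    if step < 1:
        raise ValueError("step must be >= 1")
    rows = []
    for gene_id, seq in sequences.items():
        L = len(seq)
        if L < width:
            logger.warning("generate_windows: %s shorter than width (%d < %d)",
                           gene_id, L, width)
            continue
        for start in range(0, L - width + 1, step):
            rows.append((gene_id, start, start + width, seq[start:start + width]))
    return pd.DataFrame(rows, columns=["gene_id", "win_start", "win_end", "sequence"])


def sliding_window_pipeline(
    sequences: Mapping[str, str],
    width: int = 20,
    step: int = 1,
    reducer_params: dict | None = None,
    cluster_params: dict | None = None,
    min_total_ic: float = 8.0,
    vote_threshold: float = 0.1,
    max_offset: int = 5,
    group_divergence: float = 0.5,
) -> dict:
    """Position-free motif discovery over sliding windows.

    Windows are one-hot encoded, embedded and density-clustered; a cluster
    is a *motif cluster* when its PWM carries at least ``min_total_ic`` bits
    of information — the default (8 bits, i.e. four fully conserved
    positions) sits well above the sampling IC that small clusters of
    mutually overlapping background windows accumulate.  A sequence is called motif-positive when at least
    ``max(1, ceil(vote_threshold * n_windows))`` of its windows land in
    motif clusters (so ``vote_threshold=0`` means "any window").  Motif
    cluster PWMs are then offset-aligned and grouped by divergence.

    Returns a dict with the window table (labels attached), per-sequence
    calls, motif-cluster PWMs and their consensus groups.
    """
    from .clustering import cluster_density
    from .embedding import DEFAULT_REDUCER_PARAMS, Projection, _BACKENDS
    from .motifs import build_pwm, information_content
    from .sites_io import KmerRecord, encode_sequences

    table = generate_windows(sequences, width=width, step=step)
    if table.empty:
        raise ValueError("no windows generated")
    matrix, kept = encode_sequences(list(table["sequence"]))
    table = table.iloc[kept].reset_index(drop=True)

    # windows may have even width, so embed the raw matrix directly
    # (canonically sorted, like reduce_dimensions does for KmerSets)
    merged = dict(DEFAULT_REDUCER_PARAMS)
    if reducer_params:
        merged.update(reducer_params)
    backend = merged.pop("reducer", "umap")
    if isinstance(backend, str):
        backend = _BACKENDS[backend]
    order = np.argsort(table["sequence"].to_numpy(), kind="stable")
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    coords = backend(matrix[order], merged)[inverse]
    proj = Projection(coords, reducer_name="window-reduce", params=merged,
                      row_index=list(table["sequence"]))

    assign = cluster_density(proj, **(cluster_params or {}))
    table = table.assign(label=assign.labels)

    motif_clusters = {}
    for c in range(assign.n_clusters):
        seqs = table.loc[table["label"] == c, "sequence"]
        records = [KmerRecord(s, f"w{i}") for i, s in enumerate(seqs)]
        # window widths may be even; build the PWM from raw counts
        counts_set = _RawSet(records, width)
        pwm = build_pwm(counts_set, pseudocount=0.0, weight_by_multiplicity=False)
        if information_content(pwm) >= min_total_ic:
            motif_clusters[c] = pwm

    per_seq = []
    for gene_id, sub in table.groupby("gene_id", sort=False):
        n_win = len(sub)
        n_hit = int(sub["label"].isin(motif_clusters).sum())
        per_seq.append((gene_id, n_win, n_hit,
                        n_hit >= votes_needed(vote_threshold, n_win)))
    calls = pd.DataFrame(per_seq, columns=["gene_id", "n_windows",
                                           "n_motif_windows", "motif_positive"])

    groups = _group_pwms(motif_clusters, max_offset, group_divergence)
    return {"windows": table, "calls": calls, "motif_pwms": motif_clusters,
            "consensus_groups": groups, "projection": proj, "assignment": assign}


def votes_needed(vote_threshold: float, n_windows: int) -> int:
    """Motif-cluster windows required to call a sequence positive.

    At least one window always; a threshold of 0 therefore means "any
    window in a motif cluster".
    """
    return max(1, int(np.ceil(vote_threshold * n_windows)))


class _RawSet:
    """Duck-typed k-mer container that tolerates even widths (internal)."""

    def __init__(self, records, k):
        self.records, self.k = records, k

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _group_pwms(pwms: dict, max_offset: int, threshold: float) -> list[list[int]]:
    """Single-link grouping of PWMs by best-offset divergence."""
    from .motifs import align_pwms_offset

    ids = list(pwms)
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_pos, a in enumerate(ids):
        for b in ids[a_pos + 1:]:
            try:
                _, div = align_pwms_offset(pwms[a], pwms[b], max_offset=max_offset)
            except ValueError:
                continue
            if div <= threshold:
                parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


# ---------------------------------------------------------------------------
# winscore
# ---------------------------------------------------------------------------

@dataclass
class WindowScore:
    gene_id: str
    win_start: int
    win_end: int
    winscore: float
    mean_win_ip: float
    mean_win_control: float
    median_gene_ip: float
    median_gene_control: float
    input_rpkm: float


def winscore(
    ip: Mapping[str, np.ndarray],
    control: Mapping[str, np.ndarray],
    width: int = 50,
    step: int | None = None,
    min_input_rpkm: float = 1.0,
    library_size: float | None = None,
    read_length: float = 50.0,
    median_over: str = "all",
) -> pd.DataFrame:
    """Per-window IP/input enrichment scores across genes.

    ``ip`` and ``control`` map gene id to per-base coverage over the same
    transcript coordinates.  Windows are non-overlapping by default
    (``step = width``).  Gene medians are taken over all positions
    (``median_over='all'``) or covered positions only (``'covered'``).
    Genes whose median is zero in either track are dropped with a warning;
    windows with input RPKM below ``min_input_rpkm`` are filtered.  When
    ``library_size`` is None it is estimated from the control track
    (total coverage / read length).
    """
    if set(ip) != set(control):
        raise ValueError("ip and control must cover the same gene models")
    if median_over not in ("all", "covered"):
        raise ValueError("median_over must be 'all' or 'covered'")
    step = width if step is None else step
    if library_size is None:
        library_size = max(1.0, sum(float(np.sum(v)) for v in control.values())
                           / read_length)

    rows = []
    for gene_id in ip:
        cov_ip = np.asarray(ip[gene_id], dtype=float)
        cov_in = np.asarray(control[gene_id], dtype=float)
        if cov_ip.shape != cov_in.shape:
            raise ValueError(f"gene {gene_id}: track lengths differ")
        if median_over == "all":
            med_ip, med_in = np.median(cov_ip), np.median(cov_in)
        else:
            med_ip = np.median(cov_ip[cov_ip > 0]) if (cov_ip > 0).any() else 0.0
            med_in = np.median(cov_in[cov_in > 0]) if (cov_in > 0).any() else 0.0
        if med_ip == 0 or med_in == 0:
            logger.warning("winscore: gene %s filtered (zero gene median)", gene_id)
            continue
        L = cov_ip.shape[0]
        for start in range(0, L - width + 1, step):
            w_ip = cov_ip[start:start + width].mean()
            w_in = cov_in[start:start + width].mean()
            reads_in = cov_in[start:start + width].sum() / read_length
            rpkm = reads_in / ((width / 1e3) * (library_size / 1e6))
            if rpkm < min_input_rpkm:
                continue
            if w_ip <= 0 or w_in <= 0:
                continue
            score = float(np.log2((w_ip / med_ip) / (w_in / med_in)))
            rows.append(WindowScore(gene_id, start, start + width, score,
                                    w_ip, w_in, med_ip, med_in, rpkm))
    return pd.DataFrame([vars(r) for r in rows])


def ks_compare(scores_a: Sequence[float], scores_b: Sequence[float]):
    """Two-sample two-sided Kolmogorov-Smirnov test (statistic, p-value)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Coverage-track I/O (bedGraph + BED12)
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> dict[str, np.ndarray]:
    """Load a bedGraph into dense per-contig coverage arrays."""
    spans: dict[str, list[tuple[int, int, float]]] = {}
    maxima: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            start, end = int(start), int(end)
            spans.setdefault(chrom, []).append((start, end, float(value)))
            maxima[chrom] = max(maxima.get(chrom, 0), end)
    out = {}
    for chrom, items in spans.items():
        arr = np.zeros(maxima[chrom])
        for start, end, value in items:
            arr[start:end] = value
        out[chrom] = arr
    return out


def write_bedgraph(coverage: Mapping[str, np.ndarray], path) -> None:
    """Write dense coverage as run-length-compressed bedGraph."""
    with open(path, "w") as fh:
        for chrom, arr in coverage.items():
            arr = np.asarray(arr)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def read_bed12(path) -> list[dict]:
    """Parse BED12 gene models (exon blocks, strand, name)."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}, row {ln}: BED12 requires 12 columns")
            chrom, start = f[0], int(f[1])
            sizes = [int(v) for v in f[10].rstrip(",").split(",")]
            offsets = [int(v) for v in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append({"gene_id": f[3], "chrom": chrom, "strand": f[5],
                          "exons": exons})
    return genes


def gene_coverage(track: Mapping[str, np.ndarray], genes: Sequence[dict]
                  ) -> dict[str, np.ndarray]:
    """Concatenate exon coverage into transcript coordinates (5'->3')."""
    out = {}
    for gene in genes:
        arr = track.get(gene["chrom"])
        if arr is None:
            out[gene["gene_id"]] = np.zeros(sum(e - s for s, e in gene["exons"]))
            continue
        pieces = []
        for s, e in gene["exons"]:
            piece = np.zeros(e - s)
            lo, hi = max(0, s), min(arr.size, e)
            if hi > lo:
                piece[lo - s:hi - s] = arr[lo:hi]
            pieces.append(piece)
        cov = np.concatenate(pieces) if pieces else np.zeros(0)
        if gene["strand"].replace("−", "-") == "-":
            cov = cov[::-1]
        out[gene["gene_id"]] = cov
    return out
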