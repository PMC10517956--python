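"""Phase matching and spike-in tracking.

Some detection chemistries (notably Nanopore signal-based callers)
report positions offset by a base or two from the truly modified base,
so a single motif appears as several clusters shifted against the window
center.  Phase matching inspects each cluster's PWM for the target base
(e.g. A for m6A) at small offsets around the center, then recenters the
cluster's sites onto that base and re-extracts their windows.

Spiked analysis appends k-mers of *known* modified positions to a noisy
candidate set before embedding; after clustering, the clusters holding
spikes inherit their modification identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .motifs import PWM
from .sites_io import BASE_INDEX, KmerRecord, KmerSet, SiteRecord, extract_kmers

logger = logging.getLogger("modscape")


@dataclass
class SpikeRecord:
    """A known-modification k-mer to be tracked through the pipeline."""

    name: str
    kmer: str
    modification: str


@dataclass
class PhaseResult:
    cluster_id: int
    offset: int
    matched: bool
    recentered_sites: list[SiteRecord] = field(default_factory=list)
    recentered_kmers: KmerSet | None = None
    n_skipped: int = 0


def infer_phase_offset(cluster_pwm: PWM, target_base: str,
                       shifts: Iterable[int] = range(-2, 3),
                       min_center_freq: float = 0.8) -> int | None:
    """Shift maximising the target-base frequency near the window center.

    Returns the shift ``s`` (within ``shifts``, a subset of -2..+2) at which
    the PWM frequency of ``target_base`` at ``center + s`` is maximal and at
    least ``min_center_freq``; ties prefer the smaller |s|, then the negative
    one.  None when no shift qualifies — such clusters are not phase-matched
    (typically clusters genuinely centered on another base).
    """
    if target_base not in BASE_INDEX:
        raise ValueError(f"target base {target_base!r} not in alphabet")
    shifts = sorted(shifts, key=lambda s: (abs(s), s))
    if any(abs(s) > 2 for s in shifts):
        raise ValueError("shifts must lie within [-2, +2]")
    center = (cluster_pwm.k - 1) // 2
    probs = cluster_pwm.probs
    best: tuple[float, int] | None = None
    for s in shifts:
        freq = probs[center + s, BASE_INDEX[target_base]]
        if freq >= min_center_freq and (best is None or freq > best[0] + 1e-12):
            best = (float(freq), s)
    return None if best is None else best[1]


def phase_match_cluster(cluster_sites: Sequence[SiteRecord],
                        genome: Mapping[str, object],
                        offset: int,
                        flank: int = 10,
                        cluster_id: int = 0) -> PhaseResult:
    """Recenter a cluster's sites by ``offset`` (sense orientation).

    A plus-strand site moves to ``pos0 + offset``; a minus-strand site moves
    genomically by ``-offset`` so the shift is the same in sense coordinates.
    Windows are re-extracted at the new coordinates, which is equivalent to
    sliding the old window by ``offset``.  Shifted sites leaving the contig
    are skipped with a warning.
    """
    shifted = []
    for site in cluster_sites:
        delta = offset if site.strand == "+" else -offset
        new_pos = site.pos0 + delta
        if new_pos < 0:
            continue
        shifted.append(SiteRecord(site.chrom, new_pos, site.strand, site.site_id,
                                  truth_label=site.truth_label, attrs=dict(site.attrs)))
    kmers = extract_kmers(shifted, genome, flank=flank)
    kept_ids = {r.source_site for r in kmers}
    kept_sites = [s for s in shifted if s.site_id in kept_ids]
    n_skipped = len(cluster_sites) - len(kept_sites)
    if n_skipped:
        logger.warning("phase_match_cluster %d: %d site(s) left the contig after "
                       "shifting by %+d", cluster_id, n_skipped, offset)
    return PhaseResult(cluster_id=cluster_id, offset=offset, matched=True,
                       recentered_sites=kept_sites, recentered_kmers=kmers,
                       n_skipped=n_skipped)


def spike_in(kmers: KmerSet, spikes: Sequence[SpikeRecord]) -> KmerSet:
    """Append known-modification k-mers (multiplicity 1, flagged) to a set."""
    for sp in spikes:
        if len(sp.kmer) != kmers.k:
            raise ValueError(
                f"spike {sp.name!r} has length {len(sp.kmer)}, pipeline k = {kmers.k}")
    names = [sp.name for sp in spikes]
    if len(set(names)) != len(names):
        raise ValueError("spike names must be unique")
    records = list(kmers.records)
    records += [KmerRecord(sp.kmer, sp.name, multiplicity=1, is_spike=True)
                for sp in spikes]
    return KmerSet(records, k=kmers.k, n_skipped=kmers.n_skipped)


def locate_spikes(assign: ClusterAssignment, kmers: KmerSet,
                  modifications: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-cluster spike and novel-site counts (noise as cluster -1).

    ``modifications`` optionally maps spike name (``source_site``) to a
    modification type, adding one count column per type.
    """
    if len(kmers) != assign.labels.shape[0]:
        raise ValueError("assignment and k-mer set are not aligned")
    mod_names = sorted(set((modifications or {}).values()))
    rows = {}
    for label in sorted(set(int(l) for l in assign.labels)):
        rows[label] = {"cluster": label, "n_total": 0, "n_spike": 0, "n_novel": 0,
                       **{f"spike_{m}": 0 for m in mod_names}}
    for rec, label in zip(kmers, assign.labels):
        row = rows[int(label)]
        row["n_total"] += 1
        if rec.is_spike:
            row["n_spike"] += 1
            mod = (modifications or {}).get(rec.source_site)
            if mod is not None:
                row[f"spike_{mod}"] += 1
        else:
            row["n_novel"] += 1
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["cluster"]))


def phase_match_pipeline(
    sites: Sequence[SiteRecord],
    genome: Mapping[str, object],
    target_base: str = "A",
    flank: int = 10,
    min_center_freq: float = 0.8,
    reducer: str = "umap",
    reducer_params: dict | None = None,
    cluster_params: dict | None = None,
    soft: bool = True,
) -> tuple[list[PhaseResult], "pd.DataFrame"]:
    """Cluster reported sites, infer each cluster's phase, and recenter.

    Runs the standard encode/embed/cluster pipeline with complete (soft)
    assignment, calls the phase of every cluster whose PWM reaches the
    target-base frequency threshold within ±2 of the center, and recenters
    those clusters' sites.  Clusters centered on other bases are left
    untouched (matched=False).  Returns the per-cluster results plus a
    per-site table (site_id, cluster, offset, new_pos0, recentered_kmer).
    """
    from .motifs import build_pwm
    from .pipeline import analyze_kmers

    kmers = extract_kmers(sites, genome, flank=flank)
    kept = {r.source_site for r in kmers}
    sites_kept = [s for s in sites if s.site_id in kept]
    result = analyze_kmers(kmers, reducer=reducer, reducer_params=reducer_params,
                           cluster_params=cluster_params, soft=soft)
    labels = result.assignment.labels

    results: list[PhaseResult] = []
    rows = []
    for c in range(result.assignment.n_clusters):
        members = [sites_kept[i] for i in np.flatnonzero(labels == c)]
        offset = infer_phase_offset(result.cluster_pwms[c], target_base,
                                    min_center_freq=min_center_freq)
        if offset is None:
            results.append(PhaseResult(cluster_id=c, offset=0, matched=False))
            continue
        pr = phase_match_cluster(members, genome, offset, flank=flank, cluster_id=c)
        results.append(pr)
        kmer_by_site = {r.source_site: r.sequence for r in pr.recentered_kmers}
        for s in pr.recentered_sites:
            rows.append((s.site_id, c, offset, s.pos0, kmer_by_site[s.site_id]))
    table = pd.DataFrame(rows, columns=["site_id", "cluster", "offset",
                                        "new_pos0", "recentered_kmer"])
    return results, table


def read_spike_table(path) -> list[SpikeRecord]:
    """Read a spike list TSV with columns name, kmer, modification."""
    spikes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["name", "kmer", "modification"]:
            raise ValueError(f"{path}: expected header 'name\\tkmer\\tmodification'")
        for line in fh:
            name, kmer, mod = line.rstrip("\n").split("\t")[:3]
            spikes.append(SpikeRecord(name, kmer.upper().replace("U", "T"), mod))
    return spikes


def write_phase_report(results: Sequence[PhaseResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\toffset\tmatched\tn_recentered\tn_skipped\n")
        for r in results:
            fh.write(f"{r.cluster_id}\t{r.offset}\t{int(r.matched)}"
                     f"\t{len(r.recentered_sites)}\t{r.n_skipped}\n")
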