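"""End-to-end orchestration: encode -> embed -> cluster -> summarise.

:func:`analyze_kmers` is the in-memory core shared by the CLI, the tests
and downstream scripts; :func:`run_pipeline` wraps it with file I/O and a
run manifest so a run can be reproduced exactly from its configuration.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import (ClusterAssignment, cluster_density,
                         cluster_density_histogram, write_cluster_table)
from .embedding import (Projection, flag_background, reduce_dimensions,
                        write_projection)
from .metrics import per_class_precision_recall, precision_recall
from .motifs import (PWM, build_pwm, consensus_iupac, write_logo_matrix,
                     write_meme_minimal)
from .phasing import locate_spikes, read_spike_table, spike_in
from .sites_io import (KmerSet, collapse_duplicates, extract_kmers,
                       one_hot_encode, read_site_table, write_kmer_table)

logger = logging.getLogger("modscape")

#: collapse identical k-mers automatically above this many records
AUTO_COLLAPSE_THRESHOLD = 100_000


@dataclass
class RunConfig:
    sites: str = ""
    dialect: str = "bed"
    genome: str = ""
    flank: int = 10
    collapse: str = "auto"              # auto | on | off
    ambiguity_policy: str = "drop"
    reducer: str = "umap"
    reducer_params: dict = field(default_factory=dict)
    cluster_method: str = "hdbscan"     # hdbscan | histogram
    cluster_params: dict = field(default_factory=dict)
    soft: bool = False
    spike_file: str = ""
    pseudocount: float = 0.0
    outdir: str = "modscape_out"
    seed: int = 42


@dataclass
class PipelineResult:
    kmers: KmerSet
    working: KmerSet                    # after optional collapse / spike-in
    projection: Projection
    assignment: ClusterAssignment
    cluster_pwms: dict[int, PWM]
    consensus: dict[int, str]
    spikes: object = None               # DataFrame when spikes were tracked


def analyze_kmers(
    kmers: KmerSet,
    reducer: str = "umap",
    reducer_params: dict | None = None,
    cluster_method: str = "hdbscan",
    cluster_params: dict | None = None,
    soft: bool = False,
    collapse: str = "off",
    ambiguity_policy: str = "drop",
    pseudocount: float = 0.0,
    denoise: bool = True,
    denoise_z: float = 3.5,
) -> PipelineResult:
    """Embed and cluster a k-mer set; summarise each cluster as PWM + consensus.

    ``denoise=True`` (hard clustering only) flags background-like records —
    those with no close neighbors in the encoded space — and forces their
    cluster label to noise, so motif clusters are not diluted by sequences
    without any shared pattern.  Soft (complete-assignment) runs skip the
    filter since every record must receive a cluster.
    """
    working = kmers
    do_collapse = collapse == "on" or (
        collapse == "auto" and len(kmers) > AUTO_COLLAPSE_THRESHOLD)
    if do_collapse:
        working = collapse_duplicates(working)
        logger.info("collapsed %d records to %d distinct k-mers",
                    len(kmers), len(working))

    encoded = one_hot_encode(working, ambiguity_policy=ambiguity_policy)
    kept_seqs = set(encoded.row_index)
    if len(encoded.row_index) != len(working):
        working = KmerSet([r for r in working.records if r.sequence in kept_seqs],
                          k=working.k, n_skipped=working.n_skipped)

    proj = reduce_dimensions(encoded, params=reducer_params, reducer=reducer)

    params = dict(cluster_params or {})
    if cluster_method == "hdbscan":
        assign = cluster_density(proj, soft=soft, **params)
    elif cluster_method == "histogram":
        assign = cluster_density_histogram(proj, multiplicities=working.multiplicities(),
                                           **params)
    else:
        raise ValueError(f"unknown cluster method {cluster_method!r}")

    if denoise and not soft:
        background = flag_background(encoded, z_cutoff=denoise_z)
        if background.any():
            from .clustering import _canonical_relabel
            labels = assign.labels.copy()
            labels[background] = -1
            assign = ClusterAssignment(_canonical_relabel(labels),
                                       method=assign.method + "+denoise",
                                       params={**assign.params,
                                               "denoise_z": denoise_z})

    cluster_pwms: dict[int, PWM] = {}
    consensus: dict[int, str] = {}
    for c in range(assign.n_clusters):
        members = [working.records[i] for i in np.flatnonzero(assign.labels == c)]
        sub = KmerSet(members, k=working.k)
        pwm = build_pwm(sub, pseudocount=pseudocount)
        cluster_pwms[c] = pwm
        consensus[c] = consensus_iupac(pwm)

    spikes = None
    if any(r.is_spike for r in working):
        spikes = locate_spikes(assign, working)

    return PipelineResult(kmers=kmers, working=working, projection=proj,
                          assignment=assign, cluster_pwms=cluster_pwms,
                          consensus=consensus, spikes=spikes)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-driven pipeline run; writes all tabular outputs and a manifest."""
    import pyfaidx

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("sites_io")
        sites = read_site_table(config.sites, config.dialect)
        genome = pyfaidx.Fasta(config.genome)
        kmers = extract_kmers(sites, genome, flank=config.flank)
        if config.spike_file:
            spikes = read_spike_table(config.spike_file)
            kmers = spike_in(kmers, spikes)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage sites_io: {exc}") from exc

    params = dict(config.reducer_params)
    params.setdefault("random_state", config.seed)
    try:
        result = analyze_kmers(
            kmers,
            reducer=config.reducer,
            reducer_params=params,
            cluster_method=config.cluster_method,
            cluster_params=config.cluster_params,
            soft=config.soft,
            collapse={"auto": "auto", "on": "on", "off": "off"}[config.collapse],
            ambiguity_policy=config.ambiguity_policy,
            pseudocount=config.pseudocount,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage embed/cluster: {exc}") from exc

    _stage("outputs")
    write_kmer_table(result.working, outdir / "kmers.tsv")
    write_projection(result.projection, outdir / "coords.tsv")
    write_cluster_table(result.projection, result.assignment, outdir / "clusters.tsv")
    if result.cluster_pwms:
        names = [f"cluster_{c}" for c in result.cluster_pwms]
        write_meme_minimal(result.cluster_pwms.values(), names,
                           outdir / "motifs.meme")
        for c, pwm in result.cluster_pwms.items():
            write_logo_matrix(pwm, outdir / f"logo_cluster{c}.tsv")
        with open(outdir / "consensus.tsv", "w") as fh:
            fh.write("cluster\tn\tconsensus\n")
            for c, cons in result.consensus.items():
                fh.write(f"{c}\t{len([l for l in result.assignment.labels if l == c])}"
                         f"\t{cons}\n")
    if result.spikes is not None:
        result.spikes.to_csv(outdir / "spike_report.tsv", sep="\t", index=False)

    truth = [s.truth_label for s in sites]
    if all(t is not None for t in truth) and result.assignment.n_clusters:
        seq_truth = {}
        for s, r in zip(sites, kmers):
            seq_truth.setdefault(r.sequence, s.truth_label)
        aligned = [seq_truth.get(r.sequence, "NA") for r in result.working]
        precision_recall(result.assignment, aligned).to_csv(
            outdir / "metrics_per_cluster.tsv", sep="\t", index=False)
        per_class_precision_recall(result.assignment, aligned).to_csv(
            outdir / "metrics_per_class.tsv", sep="\t", index=False)

    manifest = {
        "modscape_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "n_sites": len(sites),
        "n_kmers": len(result.working),
        "n_skipped": result.working.n_skipped,
        "n_clusters": result.assignment.n_clusters,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return result
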