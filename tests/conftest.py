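"""Shared fixtures: small deterministic datasets and one full pipeline run.

The mixture fixture reproduces the package's standard benchmark: 8,000
21-mers from three motif families (70/20/10 of the motif-bearing 90%)
plus 10% random background, with six known-m6A spike-in k-mers tracked
through the pipeline.  It is session-scoped because the UMAP embedding
dominates test runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

import modscape as m
from modscape.simulate import _plant

MIXTURE_MOTIFS = [
    m.MotifSpec("RRACH", "RRACH", 0.63),
    m.MotifSpec("CUCCA", "CTCCA", 0.18),
    m.MotifSpec("UUCGA", "TTCGA", 0.09),
]


def make_mixture_spec(n: int, seed: int) -> m.SimSpec:
    return m.SimSpec(motifs=list(MIXTURE_MOTIFS), n=n,
                     noise_fraction=0.10, seed=seed)


def make_spikes(n_spikes: int = 6, seed: int = 99) -> list[m.SpikeRecord]:
    """Known-m6A spikes: RRACH instances centered like the planted motif."""
    rng = np.random.default_rng(seed)
    return [
        m.SpikeRecord(f"m6A_spike_{i}",
                      _plant(rng, 21, (0.25,) * 4, "RRACH", 2, 0)[0], "m6A")
        for i in range(n_spikes)
    ]


@pytest.fixture(scope="session")
def mixture_run():
    """Full spiked pipeline run on the standard 8,000-sequence mixture."""
    spec = make_mixture_spec(n=8000, seed=42)
    kmers, truth = m.simulate_motif_dataset(spec)
    spikes = make_spikes()
    spiked = m.spike_in(kmers, spikes)
    result = m.analyze_kmers(spiked, cluster_params={"min_cluster_size": 50})
    return {"kmers": kmers, "truth": truth, "spikes": spikes,
            "result": result, "n_sites": len(kmers)}


@pytest.fixture(scope="session")
def two_blob_projection():
    """Two well-separated Gaussian blobs with ground-truth labels."""
    rng = np.random.default_rng(0)
    pts = np.vstack([rng.normal(0, 0.1, (200, 2)),
                     rng.normal(100, 0.1, (200, 2))])
    truth = np.array([0] * 200 + [1] * 200)
    return m.Projection(pts, "synthetic"), truth
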