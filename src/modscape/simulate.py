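"""Synthetic data with known truth for every pipeline stage.

The generator emulates the statistical structure the pipeline assumes:
a mixture of motif-bearing sequence families (each family an IUPAC
pattern or PWM planted at a known phase around the window center, with
random flanks) plus fully random background sequences.  Class counts
follow a largest-remainder allocation so the stated proportions are hit
exactly, and everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import PWM
from .sites_io import (BASES, IUPAC_SETS, KmerRecord, KmerSet, SiteRecord,
                       reverse_complement)


@dataclass
class MotifSpec:
    """One sequence family: a pattern, its share, and its phase distribution."""

    name: str
    pattern: str | PWM
    proportion: float
    phase_probs: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    anchor: int | None = None        # pattern index of the modified base

    def __post_init__(self) -> None:
        if self.anchor is None:
            length = self.pattern.k if isinstance(self.pattern, PWM) else len(self.pattern)
            self.anchor = length // 2
        total = sum(self.phase_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"motif {self.name}: phase probabilities sum to {total}")


@dataclass
class SimSpec:
    motifs: list[MotifSpec]
    n: int
    k: int = 21
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError("k must be odd")
        total = sum(m.proportion for m in self.motifs) + self.noise_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions + noise_fraction must sum to 1, got {total}")


def largest_remainder(proportions: Sequence[float], n: int) -> list[int]:
    """Integer allocation of ``n`` by proportion, exact total by largest remainder."""
    raw = [p * n for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    remainders = sorted(range(len(raw)), key=lambda i: (raw[i] - counts[i], -i),
                        reverse=True)
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def _sample_background(rng: np.random.Generator, length: int,
                       background: Sequence[float]) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=list(background)))


def _sample_instance(rng: np.random.Generator, pattern) -> str:
    if isinstance(pattern, PWM):
        probs = pattern.probs
        return "".join(BASES[rng.choice(4, p=probs[j] / probs[j].sum())]
                       for j in range(pattern.k))
    return "".join(rng.choice(list(IUPAC_SETS[c])) for c in pattern)


def _plant(rng, k, background, pattern, anchor, phase) -> str:
    """A k-mer with a sampled pattern instance anchored at center + phase."""
    length = pattern.k if isinstance(pattern, PWM) else len(pattern)
    center = (k - 1) // 2
    start = center + phase - anchor
    if start < 0 or start + length > k:
        raise ValueError(f"motif of length {length} at phase {phase} exceeds k={k}")
    instance = _sample_instance(rng, pattern)
    seq = list(_sample_background(rng, k, background))
    seq[start:start + length] = instance
    return "".join(seq), instance


def simulate_motif_dataset(spec: SimSpec) -> tuple[KmerSet, pd.DataFrame]:
    """Generate a labeled k-mer mixture.

    Returns the k-mer set (one record per sequence, ids ``seq0..``) and a
    truth table with the embedded motif name ("noise" for background),
    phase and instance string per sequence.
    """
    rng = np.random.default_rng(spec.seed)
    proportions = [m.proportion for m in spec.motifs] + [spec.noise_fraction]
    counts = largest_remainder(proportions, spec.n)

    records: list[KmerRecord] = []
    truth_rows = []
    idx = 0
    for motif, count in zip(spec.motifs, counts[:-1]):
        phases = sorted(motif.phase_probs)
        probs = [motif.phase_probs[p] for p in phases]
        for _ in range(count):
            phase = int(rng.choice(phases, p=probs))
            seq, instance = _plant(rng, spec.k, spec.background,
                                   motif.pattern, motif.anchor, phase)
            records.append(KmerRecord(seq, f"seq{idx}"))
            truth_rows.append((f"seq{idx}", motif.name, phase, instance))
            idx += 1
    for _ in range(counts[-1]):
        seq = _sample_background(rng, spec.k, spec.background)
        records.append(KmerRecord(seq, f"seq{idx}"))
        truth_rows.append((f"seq{idx}", "noise", 0, ""))
        idx += 1

    truth = pd.DataFrame(truth_rows, columns=["site_id", "motif", "phase", "instance"])
    return KmerSet(records, k=spec.k), truth


def simulate_shifted_dataset(
    spec: SimSpec,
    shift_probs: Mapping[int, float] | None = None,
    spacer: int = 30,
) -> tuple[list[SiteRecord], dict[str, str], pd.DataFrame]:
    """A synthetic genome whose reported site coordinates are phase-shifted.

    Each sequence family instance is written into one contig-spanning
    genome; the *reported* position of every site is the true modified base
    displaced by a shift drawn from ``shift_probs`` (sense orientation),
    emulating detection chemistries whose signal is offset from the
    modified base.  Roughly half the sites are placed on the minus strand.
    Returns (reported sites, genome, truth) where truth records the true
    position and sampled shift.
    """
    if shift_probs is None:
        shift_probs = {0: 1.0}
    if abs(sum(shift_probs.values()) - 1.0) > 1e-9:
        raise ValueError("shift_probs must sum to 1")
    rng = np.random.default_rng(spec.seed)
    proportions = [m.proportion for m in spec.motifs] + [spec.noise_fraction]
    counts = largest_remainder(proportions, spec.n)
    shifts = sorted(shift_probs)
    shift_p = [shift_probs[s] for s in shifts]

    slot = spec.k + 2 * spacer
    chrom = "chrS"
    pieces: list[str] = []
    sites: list[SiteRecord] = []
    truth_rows = []
    idx = 0

    def emit(seq_kmer: str, motif_name: str, instance: str) -> None:
        nonlocal idx
        offset = idx * slot
        strand = "+" if rng.random() < 0.5 else "-"
        left = _sample_background(rng, spacer, spec.background)
        right = _sample_background(rng, spacer, spec.background)
        body = seq_kmer if strand == "+" else reverse_complement(seq_kmer)
        pieces.append(left + body + right)
        true_pos = offset + spacer + (spec.k - 1) // 2
        shift = int(rng.choice(shifts, p=shift_p))
        reported = true_pos + shift if strand == "+" else true_pos - shift
        sites.append(SiteRecord(chrom, reported, strand, f"site{idx}",
                                truth_label=motif_name))
        truth_rows.append((f"site{idx}", motif_name, shift, true_pos, strand, instance))
        idx += 1

    for motif, count in zip(spec.motifs, counts[:-1]):
        for _ in range(count):
            seq, instance = _plant(rng, spec.k, spec.background,
                                   motif.pattern, motif.anchor, 0)
            emit(seq, motif.name, instance)
    for _ in range(counts[-1]):
        emit(_sample_background(rng, spec.k, spec.background), "noise", "")

    genome = {chrom: "".join(pieces)}
    truth = pd.DataFrame(truth_rows, columns=["site_id", "motif", "shift",
                                              "true_pos0", "strand", "instance"])
    return sites, genome, truth


def simulate_coverage(
    gene_lengths: Mapping[str, int],
    enriched: Sequence[tuple[str, int, float]] = (),
    depth: float = 10.0,
    width: int = 50,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Paired IP/control coverage: Poisson(depth) background, Poisson(depth*fold)
    in the IP track inside each enriched (gene, start) window."""
    rng = np.random.default_rng(seed)
    control, ip = {}, {}
    for gene, L in gene_lengths.items():
        control[gene] = rng.poisson(depth, size=L).astype(float)
        ip[gene] = rng.poisson(depth, size=L).astype(float)
    for gene, start, fold in enriched:
        if fold <= 0:
            raise ValueError("enrichment folds must be > 0")
        ip[gene][start:start + width] = rng.poisson(depth * fold, size=width)
    return ip, control
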