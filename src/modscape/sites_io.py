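"""Site tables, strand-aware k-mer extraction and one-hot encoding.

A *site* is a single modified base on a genome or transcriptome contig
(0-based position plus strand).  Each site contributes one fixed-length,
odd-width sequence window (*k-mer*) centered on the modified base in
sense orientation; the k-mer set is the unit every downstream stage
(embedding, clustering, phase matching) operates on.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("modscape")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC degeneracy codes over the DNA alphabet (RNA input is normalised U->T).
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_FROM_SET = {frozenset(v): k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U to the internal DNA alphabet."""
    return seq.upper().replace("U", "T")


def _normalize_strand(strand: str) -> str:
    # tolerate the unicode minus sign some exports use
    s = strand.strip().replace("−", "-")
    if s not in ("+", "-"):
        raise ValueError(f"strand required, got {strand!r}")
    return s


@dataclass
class SiteRecord:
    """One putative modification site (single base)."""

    chrom: str
    pos0: int
    strand: str
    site_id: str
    truth_label: str | None = None
    attrs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError(f"site {self.site_id}: pos0 must be >= 0")
        self.strand = _normalize_strand(self.strand)


@dataclass
class KmerRecord:
    """A center-anchored sequence context of one (or several collapsed) sites."""

    sequence: str
    source_site: str
    multiplicity: int = 1
    is_spike: bool = False

    @property
    def center_index(self) -> int:
        return (len(self.sequence) - 1) // 2


@dataclass
class KmerSet:
    """Fixed-width k-mer collection; ``n_skipped`` counts contig-edge drops."""

    records: list[KmerRecord]
    k: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError(f"k must be odd, got {self.k}")
        for r in self.records:
            if len(r.sequence) != self.k:
                raise ValueError(
                    f"k-mer {r.source_site!r} has length {len(r.sequence)}, expected {self.k}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[KmerRecord]:
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def multiplicities(self) -> np.ndarray:
        return np.array([r.multiplicity for r in self.records], dtype=float)

    def total_multiplicity(self) -> int:
        return int(sum(r.multiplicity for r in self.records))


@dataclass
class EncodedMatrix:
    """One-hot (or fractionally encoded) k-mers, one row per record."""

    values: np.ndarray          # n x 4k
    row_index: list[str]        # k-mer sequences, aligned with rows
    k: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_index), 4 * self.k):
            raise ValueError("encoded matrix shape inconsistent with row index")


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

def read_site_table(path, dialect: str) -> list[SiteRecord]:
    """Read a site table.

    ``dialect='bed'``: BED6, 0-based half-open single-base intervals, strand
    in column 6.  ``dialect='tsv1'``: 1-based ``chrom pos strand [site_id]
    [truth_label]`` columns.  Both map the same base to the same ``pos0``.
    """
    if dialect not in ("bed", "tsv1"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[SiteRecord] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "bed":
                    if len(fields) < 6:
                        raise ValueError("strand required (BED6 column 6 missing)")
                    chrom, start, end, name, _score, strand = fields[:6]
                    start, end = int(start), int(end)
                    if end - start != 1:
                        raise ValueError(
                            f"sites are single bases: interval width {end - start} != 1"
                        )
                    records.append(SiteRecord(chrom, start, strand, name or f"site{ln}"))
                else:
                    if len(fields) < 3:
                        raise ValueError("strand required (need chrom, pos, strand)")
                    chrom, pos1, strand = fields[:3]
                    site_id = fields[3] if len(fields) > 3 else f"site{ln}"
                    truth = fields[4] if len(fields) > 4 else None
                    records.append(
                        SiteRecord(chrom, int(pos1) - 1, strand, site_id, truth_label=truth)
                    )
            except ValueError as exc:
                raise ValueError(f"{path}, row {ln}: {exc}") from exc
    ids = [r.site_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate site_id values")
    return records


def extract_kmers(
    sites: Sequence[SiteRecord],
    genome: Mapping[str, object],
    flank: int = 10,
) -> KmerSet:
    """Extract strand-aware ``2*flank+1``-mers centered on each site.

    Plus-strand k-mer is ``genome[pos0-flank : pos0+flank+1]``; minus-strand
    is its reverse complement, so the center base is always the modified base
    read in sense orientation.  Sites closer than ``flank`` to a contig edge
    are skipped (counted in ``KmerSet.n_skipped``) rather than padded.
    """
    if flank < 5:
        raise ValueError("flank must be >= 5")
    k = 2 * flank + 1
    if k > 51:
        raise ValueError("k = 2*flank+1 must be <= 51")
    records: list[KmerRecord] = []
    skipped = 0
    for site in sites:
        contig = genome[site.chrom]
        clen = len(contig)
        lo, hi = site.pos0 - flank, site.pos0 + flank + 1
        if lo < 0 or hi > clen:
            skipped += 1
            continue
        window = normalize_sequence(str(contig[lo:hi]))
        if site.strand == "-":
            window = reverse_complement(window)
        records.append(KmerRecord(window, site.site_id))
    if skipped:
        logger.warning("extract_kmers: skipped %d site(s) within %d nt of a contig edge",
                       skipped, flank)
    return KmerSet(records, k=k, n_skipped=skipped)


def collapse_duplicates(kmers: KmerSet) -> KmerSet:
    """Merge identical k-mers into one record carrying their site count.

    Multiplicity feeds density weighting downstream, so the collapsed set
    represents the same number of sites as the input.  Spike-in records never
    merge with genuine sites.
    """
    groups: "OrderedDict[tuple[str, bool], KmerRecord]" = OrderedDict()
    for r in kmers:
        key = (r.sequence, r.is_spike)
        if key in groups:
            groups[key].multiplicity += r.multiplicity
        else:
            groups[key] = KmerRecord(r.sequence, r.source_site, r.multiplicity, r.is_spike)
    return KmerSet(list(groups.values()), k=kmers.k, n_skipped=kmers.n_skipped)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_sequences(sequences: Sequence[str], ambiguity_policy: str = "drop"):
    """One-hot encode equal-length sequences (base order A,C,G,T).

    Returns ``(matrix, kept_indices)``.  ``drop`` removes sequences with any
    ambiguous base; ``uniform`` spreads an ambiguity code's weight equally
    over its base set (N -> 0.25 each).
    """
    if ambiguity_policy not in ("drop", "uniform"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    if not sequences:
        return np.zeros((0, 0)), []
    width = len(sequences[0])
    rows: list[np.ndarray] = []
    kept: list[int] = []
    for i, seq in enumerate(sequences):
        if len(seq) != width:
            raise ValueError(f"record {i}: length {len(seq)} != {width}")
        row = np.zeros(4 * width)
        ok = True
        for j, base in enumerate(seq):
            if base in BASE_INDEX:
                row[4 * j + BASE_INDEX[base]] = 1.0
            elif base in IUPAC_SETS:
                if ambiguity_policy == "drop":
                    ok = False
                    break
                members = IUPAC_SETS[base]
                for m in members:
                    row[4 * j + BASE_INDEX[m]] = 1.0 / len(members)
            else:
                raise ValueError(f"record {i}: non-IUPAC character {base!r}")
        if ok:
            rows.append(row)
            kept.append(i)
    matrix = np.vstack(rows) if rows else np.zeros((0, 4 * width))
    return matrix, kept


def one_hot_encode(kmers: KmerSet, ambiguity_policy: str = "drop") -> EncodedMatrix:
    """Encode a KmerSet; row order follows the record order of kept k-mers."""
    seqs = kmers.sequences()
    matrix, kept = encode_sequences(seqs, ambiguity_policy)
    dropped = len(seqs) - len(kept)
    if dropped:
        logger.warning("one_hot_encode: dropped %d record(s) with ambiguous bases", dropped)
    return EncodedMatrix(matrix, [seqs[i] for i in kept], k=kmers.k)


def decode_one_hot(encoded: EncodedMatrix) -> list[str]:
    """Invert one-hot encoding (exact for N-free rows)."""
    out = []
    for row in encoded.values:
        cols = row.reshape(encoded.k, 4)
        out.append("".join(BASES[int(j)] for j in cols.argmax(axis=1)))
    return out


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_kmer_table(kmers: KmerSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tkmer\tmultiplicity\tis_spike\n")
        for r in kmers:
            fh.write(f"{r.source_site}\t{r.sequence}\t{r.multiplicity}\t{int(r.is_spike)}\n")


def read_kmer_table(path) -> KmerSet:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("site_id"):
            raise ValueError(f"{path}: missing k-mer table header")
        for line in fh:
            site_id, kmer, mult, spike = line.rstrip("\n").split("\t")
            records.append(KmerRecord(kmer, site_id, int(mult), bool(int(spike))))
    if not records:
        raise ValueError(f"{path}: empty k-mer table")
    return KmerSet(records, k=len(records[0].sequence))


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
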