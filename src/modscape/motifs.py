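"""Per-cluster motif summaries: PWMs, degenerate consensus, IUPAC pattern
matching, offset alignment and MEME-minimal output."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sites_io import BASES, BASE_INDEX, IUPAC_FROM_SET, IUPAC_SETS, KmerSet

# information content of a column against a uniform background, in bits
_LOG2_ALPHABET = 2.0


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities over A,C,G,T.

    ``probs[j, b] = (counts[j, b] + pseudocount) / (n + 4 * pseudocount)``
    where ``n`` is the (multiplicity-weighted) sequence count.
    """

    counts: np.ndarray        # k x 4
    n: float
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be k x 4")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def probs(self) -> np.ndarray:
        return (self.counts + self.pseudocount) / (self.n + 4 * self.pseudocount)

    @classmethod
    def from_probs(cls, probs: np.ndarray, n: float = 1.0) -> "PWM":
        probs = np.asarray(probs, dtype=float)
        return cls(counts=probs * n, n=n, pseudocount=0.0)


def build_pwm(kmers: KmerSet, pseudocount: float = 0.0,
              weight_by_multiplicity: bool = True) -> PWM:
    """Tally base counts per position, optionally weighted by site multiplicity."""
    if len(kmers) == 0:
        raise ValueError("cannot build a PWM from an empty k-mer set")
    counts = np.zeros((kmers.k, 4))
    total = 0.0
    for rec in kmers:
        w = rec.multiplicity if weight_by_multiplicity else 1.0
        for j, base in enumerate(rec.sequence):
            if base in BASE_INDEX:
                counts[j, BASE_INDEX[base]] += w
            else:  # spread ambiguity codes over their base set
                members = IUPAC_SETS[base]
                for m in members:
                    counts[j, BASE_INDEX[m]] += w / len(members)
        total += w
    return PWM(counts, n=total, pseudocount=pseudocount)


def consensus_iupac(pwm: PWM, include_threshold: float = 0.25,
                    dominant_threshold: float = 0.8) -> str:
    """Degenerate consensus string.

    A position becomes a single base when one base reaches the dominant
    threshold; otherwise the IUPAC code covering all bases at or above the
    include threshold; "N" when that set is empty or all four.
    """
    out = []
    for row in pwm.probs:
        if row.max() >= dominant_threshold:
            out.append(BASES[int(row.argmax())])
            continue
        members = frozenset(BASES[i] for i in range(4) if row[i] >= include_threshold)
        if not members or len(members) == 4:
            out.append("N")
        else:
            out.append(IUPAC_FROM_SET[members])
    return "".join(out)


def iupac_match(base: str, code: str) -> bool:
    return base in IUPAC_SETS[code]


def match_consensus(kmer, pattern: str, anchor: int,
                    phases=range(-2, 3)) -> int | None:
    """Best phase at which an IUPAC pattern matches a centered k-mer.

    The pattern is slid so its anchor position sits at ``center + phase``;
    the smallest-|phase| match wins (negative first on ties).  Returns None
    when no tested phase matches.
    """
    seq = kmer if isinstance(kmer, str) else kmer.sequence
    for code in pattern:
        if code not in IUPAC_SETS:
            raise ValueError(f"non-IUPAC code {code!r} in pattern")
    if not (0 <= anchor < len(pattern)):
        raise ValueError("anchor must index into the pattern")
    center = (len(seq) - 1) // 2
    for phase in sorted(phases, key=lambda s: (abs(s), s)):
        start = center + phase - anchor
        if start < 0 or start + len(pattern) > len(seq):
            continue
        if all(iupac_match(seq[start + i], pattern[i]) for i in range(len(pattern))):
            return phase
    return None


def _column_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetrized KL of one position, bits."""
    return 0.5 * float(np.sum(p * np.log2(p / q) + q * np.log2(q / p)))


def _regularize(probs: np.ndarray, pseudocount: float) -> np.ndarray:
    if pseudocount > 0:
        return (probs + pseudocount) / (1 + 4 * pseudocount)
    if np.any(probs <= 0):
        raise ValueError("zero probability without pseudocount")
    return probs


def pwm_divergence(a: PWM, b: PWM, pseudocount: float = 0.01) -> float:
    """Mean per-position symmetrized KL divergence between equal-length PWMs."""
    if a.k != b.k:
        raise ValueError(f"PWM lengths differ: {a.k} vs {b.k}")
    pa = _regularize(a.probs, pseudocount)
    pb = _regularize(b.probs, pseudocount)
    return float(np.mean([_column_kl(pa[j], pb[j]) for j in range(a.k)]))


def align_pwms_offset(a: PWM, b: PWM, max_offset: int = 5,
                      pseudocount: float = 0.01) -> tuple[int, float]:
    """Exhaustive offset search minimising mean symmetrized KL on the overlap.

    Offset ``s`` compares ``a[j]`` with ``b[j - s]``; every tested offset
    must leave an overlap of at least 4 positions.
    """
    pa = _regularize(a.probs, pseudocount)
    pb = _regularize(b.probs, pseudocount)
    best: tuple[int, float] | None = None
    for s in sorted(range(-max_offset, max_offset + 1), key=lambda v: (abs(v), v)):
        lo = max(0, s)
        hi = min(a.k, b.k + s)
        if hi - lo < 4:
            raise ValueError(
                f"max_offset {max_offset} leaves overlap {hi - lo} < 4 positions")
        div = float(np.mean([_column_kl(pa[j], pb[j - s]) for j in range(lo, hi)]))
        if best is None or div < best[1] - 1e-12:
            best = (s, div)
    assert best is not None
    return best


def logo_matrix(pwm: PWM) -> np.ndarray:
    """k x 4 letter heights in bits: ``p * IC`` with ``IC = 2 + sum p log2 p``."""
    probs = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    ic = _LOG2_ALPHABET + plogp.sum(axis=1)
    return probs * ic[:, None]


def information_content(pwm: PWM) -> float:
    """Total information content of the motif in bits."""
    return float(logo_matrix(pwm).sum())


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def write_meme_minimal(pwms, names, path,
                       background=(0.25, 0.25, 0.25, 0.25)) -> None:
    """Write motifs in MEME minimal text format (DNA alphabet)."""
    pwms = list(pwms)
    names = list(names)
    if not pwms:
        raise ValueError("no PWMs to write")
    if len(pwms) != len(names):
        raise ValueError("pwms and names differ in length")
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*background))
        for pwm, name in zip(pwms, names):
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.k} "
                     f"nsites= {int(round(pwm.n))} E= 0\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme_minimal(path) -> tuple[list[PWM], list[str]]:
    pwms: list[PWM] = []
    names: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            names.append(line.split()[1])
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability matrix"):
                i += 1
            header = lines[i].strip()
            tokens = header.replace("=", " = ").split()
            width = int(tokens[tokens.index("w") + 2])
            nsites = 1
            if "nsites" in tokens:
                nsites = int(tokens[tokens.index("nsites") + 2])
            rows = []
            for j in range(1, width + 1):
                rows.append([float(v) for v in lines[i + j].split()])
            pwms.append(PWM.from_probs(np.array(rows), n=nsites))
            i += width + 1
        else:
            i += 1
    if not pwms:
        raise ValueError(f"{path}: no motifs found")
    return pwms, names


def write_logo_matrix(pwm: PWM, path) -> None:
    mat = logo_matrix(pwm)
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\n")
        for j, row in enumerate(mat):
            fh.write(f"{j}\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
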