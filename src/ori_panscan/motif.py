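"""ACS motif modelling and scanning.

The ARS consensus sequence (ACS) is the ~11 bp T-rich element recognized by
the origin recognition complex.  From a set of aligned ACS instances this
module builds a count matrix, pseudocounted probability matrix and log-odds
(bits) matrix, derives the degenerate IUPAC consensus, scans target sequences
on both strands, and computes ACS-centered base-frequency profiles across a
set of origins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats_io import reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# base-set -> IUPAC code
IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
IUPAC_EXPANSION = {code: sorted(bases) for bases, code in IUPAC_CODES.items()}

UNIFORM_BACKGROUND = {b: 0.25 for b in BASES}


@dataclass
class MotifModel:
    """Position count / probability / log-odds model of a fixed-width motif."""

    counts: np.ndarray  # 4 x width integers, rows ordered A,C,G,T
    pseudocount: float
    background: dict[str, float]
    n_sequences: int
    probabilities: np.ndarray = field(init=False)  # pseudocounted
    log_odds: np.ndarray = field(init=False)  # bits vs background
    frequencies: np.ndarray = field(init=False)  # raw, no pseudocount

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        n = counts.sum(axis=0)
        self.frequencies = np.where(n > 0, counts / np.maximum(n, 1), 0.0)
        self.probabilities = (counts + self.pseudocount) / (
            n + 4.0 * self.pseudocount
        )
        bg = np.array([self.background[b] for b in BASES])[:, None]
        with np.errstate(divide="ignore"):  # pseudocount 0 -> -inf log-odds
            self.log_odds = np.log2(self.probabilities / bg)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def best_word(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    def score_window(self, window: str) -> float:
        """Log-odds score of one width-length window; NaN if it contains N."""
        total = 0.0
        for j, base in enumerate(window):
            i = _BASE_INDEX.get(base)
            if i is None:
                return float("nan")
            total += self.log_odds[i, j]
        return total


@dataclass
class MotifHit:
    seq_id: str
    start: int  # 1-based on the forward strand of the scanned sequence
    strand: str
    score: float
    matched_sequence: str  # as read 5'->3' on the hit strand


def build_motif(
    aligned_sequences: Sequence[str],
    pseudocount: float = 0.5,
    background: Mapping[str, float] | None = None,
) -> MotifModel:
    """Tally aligned equal-length ACGT sequences into a :class:`MotifModel`.

    Probabilities are (count + pseudocount) / (n + 4*pseudocount); log-odds
    are log2(probability / background).  Sequences containing characters
    outside ACGT are rejected with the offending ids listed.
    """
    if not aligned_sequences:
        raise ValueError("no input sequences")
    seqs = [s.upper() for s in aligned_sequences]
    width = len(seqs[0])
    bad_len = [i for i, s in enumerate(seqs) if len(s) != width]
    if bad_len:
        raise ValueError(f"sequences with unequal length at indices {bad_len}")
    bad_alpha = [i for i, s in enumerate(seqs) if set(s) - set(BASES)]
    if bad_alpha:
        raise ValueError(
            f"sequences with non-ACGT characters at indices {bad_alpha}"
        )
    counts = np.zeros((4, width))
    for s in seqs:
        for j, base in enumerate(s):
            counts[_BASE_INDEX[base], j] += 1
    bg = dict(background) if background is not None else dict(UNIFORM_BACKGROUND)
    return MotifModel(
        counts=counts, pseudocount=pseudocount, background=bg, n_sequences=len(seqs)
    )


def degenerate_consensus(model: MotifModel, include_threshold: float = 0.25) -> str:
    """IUPAC consensus covering, per column, all bases at frequency >= threshold.

    Raw (pre-pseudocount) frequencies are used.  A column where no base
    reaches the threshold falls back to N.
    """
    out = []
    for j in range(model.width):
        included = frozenset(
            BASES[i] for i in range(4) if model.frequencies[i, j] >= include_threshold
        )
        out.append(IUPAC_CODES.get(included, "N") if included else "N")
    return "".join(out)


def scan(
    model: MotifModel,
    sequence: str,
    seq_id: str = "seq",
    threshold_fraction_of_max: float = 0.8,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Slide the log-odds matrix over ``sequence`` (and its reverse complement).

    A window is a hit when its score reaches ``threshold_fraction_of_max``
    of the maximum attainable score; windows containing N are skipped.  Hit
    starts are 1-based on the forward strand regardless of hit strand.
    """
    sequence = sequence.upper()
    w = model.width
    L = len(sequence)
    if L < w:
        return []
    threshold = threshold_fraction_of_max * model.max_score
    hits: list[MotifHit] = []

    def _scan_strand(seq: str, strand: str) -> None:
        for pos in range(len(seq) - w + 1):
            window = seq[pos : pos + w]
            score = model.score_window(window)
            if np.isnan(score) or score < threshold:
                continue
            if strand == "+":
                start = pos + 1
            else:
                # map position on the reverse complement back to forward coords
                start = L - (pos + w) + 1
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    start=start,
                    strand=strand,
                    score=float(score),
                    matched_sequence=window,
                )
            )

    _scan_strand(sequence, "+")
    if both_strands:
        _scan_strand(reverse_complement(sequence), "-")
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def best_hit(model: MotifModel, sequence: str, seq_id: str = "seq") -> MotifHit | None:
    """Highest-scoring window on either strand, regardless of threshold."""
    hits = scan(model, sequence, seq_id, threshold_fraction_of_max=-np.inf)
    if not hits:
        return None
    return max(hits, key=lambda h: h.score)


def centered_base_profile(
    sequences: Mapping[str, str],
    acs_hits: Mapping[str, MotifHit],
    flank_bp: int,
    width: int,
) -> np.ndarray:
    """Base frequencies around each sequence's best ACS hit.

    Each sequence is oriented so its ACS reads 5'->3' on the hit strand
    (T-rich orientation), then aligned on the ACS start.  Returns a
    4 x (2*flank_bp + width) frequency matrix; columns with partial coverage
    (flanks clipped at sequence ends) are normalized over the sequences that
    cover them.
    """
    if not acs_hits:
        raise ValueError("no ACS hits provided")
    span = 2 * flank_bp + width
    counts = np.zeros((4, span))
    coverage = np.zeros(span)
    for seq_id, hit in acs_hits.items():
        seq = sequences[seq_id].upper()
        if hit.strand == "-":
            # reorient so the ACS strand is the forward strand
            seq = reverse_complement(seq)
            acs_pos = len(seq) - (hit.start - 1) - width  # 0-based on flipped seq
        else:
            acs_pos = hit.start - 1
        offset = acs_pos - flank_bp  # seq coordinate of profile column 0
        for col in range(span):
            p = offset + col
            if 0 <= p < len(seq):
                i = _BASE_INDEX.get(seq[p])
                if i is not None:
                    counts[i, col] += 1
                    coverage[col] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(coverage > 0, counts / np.maximum(coverage, 1), 0.0)


def expand_iupac(consensus: str) -> list[list[str]]:
    """Per-position base choices implied by an IUPAC string."""
    return [IUPAC_EXPANSION[c] for c in consensus.upper()]


def sample_from_consensus(consensus: str, rng: np.random.Generator) -> str:
    """Draw one word uniformly within each position's degeneracy."""
    return "".join(rng.choice(choices) for choices in expand_iupac(consensus))
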