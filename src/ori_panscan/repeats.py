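"""Exact maximal-repeat detection within origin sequences.

Finds maximal exact repeats in four modes — forward (a substring occurring
twice), reverse (matching its reversal elsewhere), complement (matching the
base-wise complement) and palindromic (matching the reverse complement) — at
a minimum length, reporting the longest ``max_hits`` per sequence.
Significance is by length threshold alone; no E-value model is attached.

The search runs per diagonal of the (sequence x transformed-sequence)
comparison, so every reported hit is maximal by construction: extending
either copy by one base in either direction breaks the mode's relation.
Origin sequences are short (tens of bp to ~2 kb), so the O(n^2 / 64)
vectorized diagonal sweep is fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import at_content

MODES = ("forward", "reverse", "complement", "palindromic")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class RepeatHit:
    seq_id: str
    mode: str
    pos1: int  # 1-based start of first copy
    pos2: int  # 1-based start of second copy
    length: int
    repeat_at_content: float
    sequence: str  # the pos1 copy


def _transform(seq: str, mode: str) -> str:
    if mode == "forward":
        return seq
    if mode == "reverse":
        return seq[::-1]
    if mode == "complement":
        return seq.translate(_COMPLEMENT)
    if mode == "palindromic":
        return seq.translate(_COMPLEMENT)[::-1]
    raise ValueError(f"unknown repeat mode {mode!r}")


def _map_back(j: int, length: int, n: int, mode: str) -> int:
    """0-based start in the original sequence of B[j : j+length]."""
    if mode in ("forward", "complement"):
        return j
    return n - j - length


def _diagonal_runs(a: np.ndarray, b: np.ndarray, min_length: int):
    """Yield (i, j, length) maximal equal runs between code arrays a and b."""
    n, m = len(a), len(b)
    for d in range(-(n - min_length), m - min_length + 1):
        i0 = max(0, -d)
        j0 = i0 + d
        span = min(n - i0, m - j0)
        if span < min_length:
            continue
        eq = a[i0 : i0 + span] == b[j0 : j0 + span]
        # run-length encode the boolean diagonal
        boundaries = np.flatnonzero(np.diff(eq.astype(np.int8)))
        starts = np.concatenate([[0], boundaries + 1])
        ends = np.concatenate([boundaries + 1, [span]])
        for s, e in zip(starts, ends):
            if eq[s] and e - s >= min_length:
                yield i0 + s, j0 + s, int(e - s)


def find_repeats(
    sequence: str,
    seq_id: str = "seq",
    min_length: int = 8,
    modes: Iterable[str] = MODES,
    max_hits: int = 50,
) -> list[RepeatHit]:
    """Maximal exact repeats of ``sequence`` in the requested modes.

    A hit pairs two distinct loci (pos1, pos2); a locus matching its own
    transform (e.g. a palindrome at a single position) is not a repeat.  For
    the symmetric modes each unordered pair is reported once with
    pos1 < pos2 (forward keeps pos1 < pos2 as well).  Hits are ranked by
    length (descending), ties by (pos1, pos2), truncated to ``max_hits``.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < min_length:
        return []
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits: list[RepeatHit] = []
    seen: set[tuple[str, int, int, int]] = set()
    for mode in modes:
        if mode not in MODES:
            raise ValueError(f"unknown repeat mode {mode!r}")
        b = np.frombuffer(_transform(seq, mode).encode(), dtype=np.uint8)
        for i, j, length in _diagonal_runs(code, b, min_length):
            p1 = i
            p2 = _map_back(j, length, n, mode)
            if p1 == p2:
                continue  # a locus is not a repeat of itself
            if p1 > p2:
                p1, p2 = p2, p1
            key = (mode, p1, p2, length)
            if key in seen:
                continue
            seen.add(key)
            copy = seq[p1 : p1 + length]
            if "N" in copy:
                continue
            hits.append(
                RepeatHit(
                    seq_id=seq_id,
                    mode=mode,
                    pos1=p1 + 1,
                    pos2=p2 + 1,
                    length=length,
                    repeat_at_content=at_content(copy),
                    sequence=copy,
                )
            )
    hits.sort(key=lambda h: (-h.length, h.pos1, h.pos2, MODES.index(h.mode)))
    return hits[:max_hits]


def repeat_summary(
    hits_by_seq: Mapping[str, Sequence[RepeatHit]],
    segment_ids: Iterable[str] | None = None,
) -> dict:
    """Summarize repeat content across a set of sequences.

    ``hits_by_seq`` maps every analyzed sequence id (ARSs and, optionally,
    gene-overlap segments) to its repeat hits.  ``segment_ids`` marks which
    ids are overlap segments; the rest are treated as whole origins.
    Returns the fraction of sequences carrying >=1 repeat and mean repeat
    AT content per stratum.
    """
    segment_ids = set(segment_ids or ())
    n_total = len(hits_by_seq)
    n_with = sum(1 for h in hits_by_seq.values() if h)
    at_origin = [
        h.repeat_at_content
        for sid, hs in hits_by_seq.items()
        if sid not in segment_ids
        for h in hs
    ]
    at_segment = [
        h.repeat_at_content
        for sid, hs in hits_by_seq.items()
        if sid in segment_ids
        for h in hs
    ]
    return {
        "n_sequences": n_total,
        "fraction_with_repeats": n_with / n_total if n_total else float("nan"),
        "mean_repeat_at_origin": float(np.mean(at_origin)) if at_origin else float("nan"),
        "mean_repeat_at_segment": float(np.mean(at_segment)) if at_segment else float("nan"),
    }
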