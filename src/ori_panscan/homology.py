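"""Mapping origin sequences onto strain genomes.

Two engines feed the same downstream contracts:

* an adapter that ingests 12-column tabular output from an external local
  aligner and applies the identity / coverage / E-value cutoffs, and
* a built-in exact-seed (k = 12), ungapped-extension search for desk-scale
  runs with no external dependency.  Its E-values are a Karlin-Altschul-style
  approximation used for ranking only; filtering under this engine is by
  identity and coverage alone.

Hits from one origin that overlap on one strain chromosome are merged into a
single presence event before anything downstream counts them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ars_dataset import ARSDataset, ARSRecord, reciprocal_overlap
from .formats_io import (
    FeatureRecord,
    GenomeAssembly,
    TabularHit,
    reverse_complement,
    write_gff3,
)

logger = logging.getLogger(__name__)

SEED_K = 12
# ungapped DNA scoring (+1 match / -2 mismatch) Karlin-Altschul parameters
_KA_LAMBDA = 1.33
_KA_K = 0.621


@dataclass
class FilterThresholds:
    min_identity: float = 90.0  # percent
    min_coverage: float = 90.0  # percent of the query covered
    max_e_value: float = 5e-10

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100 and 0 < self.min_coverage <= 100):
            raise ValueError("identity/coverage thresholds must be in (0, 100]")
        if self.max_e_value <= 0:
            raise ValueError("max_e_value must be positive")


@dataclass
class HomologyHit:
    ars_id: str
    strain_id: str
    subject_chrom: str
    s_start: int  # 1-based inclusive
    s_end: int
    strand: str
    identity: float  # percent
    coverage: float  # percent of query length
    e_value: float

    @property
    def length(self) -> int:
        return self.s_end - self.s_start + 1

    # interval protocol used by reciprocal_overlap
    @property
    def chrom(self) -> str:
        return self.subject_chrom

    @property
    def start(self) -> int:
        return self.s_start

    @property
    def end(self) -> int:
        return self.s_end


def filter_hits(
    raw_hits: Iterable[TabularHit],
    ars_lengths: Mapping[str, int],
    thresholds: FilterThresholds | None = None,
    strain_id: str = "strain",
) -> list[HomologyHit]:
    """Apply identity / coverage / E-value cutoffs to tabular aligner output.

    Coverage is 100 * alignment length / query length, capped at 100 for
    gapped alignments longer than the query.
    """
    thresholds = thresholds or FilterThresholds()
    kept = []
    for hit in raw_hits:
        if hit.query_id not in ars_lengths:
            raise ValueError(f"unknown query id {hit.query_id!r}")
        coverage = min(100.0, 100.0 * hit.aln_length / ars_lengths[hit.query_id])
        if (
            hit.pct_identity >= thresholds.min_identity
            and coverage >= thresholds.min_coverage
            and hit.e_value <= thresholds.max_e_value
        ):
            kept.append(
                HomologyHit(
                    ars_id=hit.query_id,
                    strain_id=strain_id,
                    subject_chrom=hit.subject_id,
                    s_start=hit.s_start,
                    s_end=hit.s_end,
                    strand=hit.strand,
                    identity=hit.pct_identity,
                    coverage=coverage,
                    e_value=hit.e_value,
                )
            )
    return kept


# ---------------------------------------------------------------------------
# built-in seed-and-extend engine
# ---------------------------------------------------------------------------

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer value of every k-window; windows containing N get -1."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    values = windows @ powers
    values[(windows == 4).any(axis=1)] = -1
    return values


def _approx_e_value(matches: int, mismatches: int, m: int, n: int) -> float:
    score = matches - 2 * mismatches
    if score <= 0:
        return float("inf")
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def scan_genome(
    queries: Sequence[ARSRecord],
    genome: GenomeAssembly,
    thresholds: FilterThresholds | None = None,
    seed_k: int = SEED_K,
) -> list[HomologyHit]:
    """Search every query origin against one genome (both strands).

    Exact ``seed_k``-mer seeds anchor ungapped full-length placements of the
    query on the subject; each distinct placement is scored by direct base
    comparison.  Hits passing the identity and coverage thresholds are
    returned; overlapping placements of one query on one chromosome are
    merged into a single presence event.  E-values are approximate and do
    not participate in filtering under this engine.
    """
    thresholds = thresholds or FilterThresholds()
    short = [q.ars_id for q in queries if q.length < seed_k]
    if short:
        raise ValueError(f"queries shorter than seed size {seed_k}: {short}")

    # index query seeds on both strands
    seed_map: dict[int, list[tuple[int, int, str]]] = {}
    encoded: dict[tuple[int, str], np.ndarray] = {}
    for qi, rec in enumerate(queries):
        if not rec.sequence:
            raise ValueError(f"{rec.ars_id} has no sequence attached")
        for strand, seq in (("+", rec.sequence), ("-", reverse_complement(rec.sequence))):
            codes = _encode(seq)
            encoded[(qi, strand)] = codes
            for offset, value in enumerate(_kmer_values(codes, seed_k)):
                if value >= 0:
                    seed_map.setdefault(int(value), []).append((qi, offset, strand))
    query_kmers = np.fromiter(seed_map.keys(), dtype=np.int64, count=len(seed_map))
    genome_size = sum(genome.lengths.values())

    raw_hits: list[HomologyHit] = []
    for chrom, seq in genome.chromosomes.items():
        codes = _encode(seq)
        values = _kmer_values(codes, seed_k)
        if len(values) == 0:
            continue
        candidate_pos = np.flatnonzero(np.isin(values, query_kmers))
        seen: set[tuple[int, str, int]] = set()
        for pos in candidate_pos:
            for qi, offset, strand in seed_map[int(values[pos])]:
                diag = int(pos) - offset  # 0-based subject start of the placement
                key = (qi, strand, diag)
                if key in seen:
                    continue
                seen.add(key)
                qcodes = encoded[(qi, strand)]
                qlen = len(qcodes)
                g0 = max(diag, 0)
                g1 = min(diag + qlen, len(codes))
                q0 = g0 - diag
                aln_len = g1 - g0
                if aln_len < seed_k:
                    continue
                matches = int((codes[g0:g1] == qcodes[q0 : q0 + aln_len]).sum())
                identity = 100.0 * matches / aln_len
                coverage = 100.0 * aln_len / qlen
                if identity < thresholds.min_identity or coverage < thresholds.min_coverage:
                    continue
                raw_hits.append(
                    HomologyHit(
                        ars_id=queries[qi].ars_id,
                        strain_id=genome.strain_id,
                        subject_chrom=chrom,
                        s_start=g0 + 1,
                        s_end=g1,
                        strand=strand,
                        identity=identity,
                        coverage=coverage,
                        e_value=_approx_e_value(
                            matches, aln_len - matches, qlen, genome_size
                        ),
                    )
                )
    return merge_hits(raw_hits)


def internal_search(
    ars: ARSRecord,
    genome: GenomeAssembly,
    thresholds: FilterThresholds | None = None,
) -> list[HomologyHit]:
    """Seed-and-extend search of a single origin; see :func:`scan_genome`."""
    return scan_genome([ars], genome, thresholds)


def merge_hits(hits: Sequence[HomologyHit]) -> list[HomologyHit]:
    """Union overlapping hits of one origin on one strain chromosome.

    The merged event takes the interval union; identity and coverage are the
    maxima over the merged members (each member already passed the filters),
    the E-value the minimum, and the strand that of the best-identity member.
    """
    groups: dict[tuple[str, str, str], list[HomologyHit]] = {}
    for h in hits:
        groups.setdefault((h.ars_id, h.strain_id, h.subject_chrom), []).append(h)
    merged: list[HomologyHit] = []
    for (ars_id, strain_id, chrom), members in groups.items():
        members.sort(key=lambda h: (h.s_start, h.s_end))
        cluster = [members[0]]
        for h in members[1:]:
            if h.s_start <= cluster[-1].s_end:
                cluster.append(h)
            else:
                merged.append(_collapse(ars_id, strain_id, chrom, cluster))
                cluster = [h]
        merged.append(_collapse(ars_id, strain_id, chrom, cluster))
    merged.sort(key=lambda h: (h.ars_id, h.strain_id, h.subject_chrom, h.s_start))
    return merged


def _collapse(
    ars_id: str, strain_id: str, chrom: str, cluster: list[HomologyHit]
) -> HomologyHit:
    best = max(cluster, key=lambda h: h.identity)
    return HomologyHit(
        ars_id=ars_id,
        strain_id=strain_id,
        subject_chrom=chrom,
        s_start=min(h.s_start for h in cluster),
        s_end=max(h.s_end for h in cluster),
        strand=best.strand,
        identity=max(h.identity for h in cluster),
        coverage=max(h.coverage for h in cluster),
        e_value=min(h.e_value for h in cluster),
    )


@dataclass
class SelfSimilarityReport:
    unique_ars: list[str]
    multi_hit_ars: list[str]
    pairs: list[dict]  # ars_id, chrom/start/end of the non-self locus, label
    missing_self: list[str]

    @property
    def fraction_unique(self) -> float:
        total = len(self.unique_ars) + len(self.multi_hit_ars)
        return len(self.unique_ars) / total if total else float("nan")


def self_similarity(
    dataset: ARSDataset,
    reference: GenomeAssembly,
    thresholds: FilterThresholds | None = None,
    self_overlap_threshold: float = 0.5,
) -> SelfSimilarityReport:
    """Uniqueness of each origin within its own genome.

    An origin is *unique* when its only passing hit against the reference
    overlaps its own annotated locus (reciprocal overlap >= threshold).
    Every non-self locus of a multi-hit origin is reported as a pair,
    labelled intra- or inter-chromosomal.
    """
    hits = scan_genome(dataset.records, reference, thresholds)
    by_ars: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_ars.setdefault(h.ars_id, []).append(h)
    unique, multi, pairs, missing = [], [], [], []
    for rec in dataset.records:
        own = by_ars.get(rec.ars_id, [])
        self_hits = [
            h for h in own if reciprocal_overlap(h, rec) >= self_overlap_threshold
        ]
        non_self = [
            h for h in own if reciprocal_overlap(h, rec) < self_overlap_threshold
        ]
        if not self_hits:
            logger.warning("%s: no self hit against its own genome", rec.ars_id)
            missing.append(rec.ars_id)
        if non_self:
            multi.append(rec.ars_id)
            for h in non_self:
                pairs.append(
                    {
                        "ars_id": rec.ars_id,
                        "chrom": h.subject_chrom,
                        "start": h.s_start,
                        "end": h.s_end,
                        "strand": h.strand,
                        "identity": h.identity,
                        "label": (
                            "intra_chromosomal"
                            if h.subject_chrom == rec.chrom
                            else "inter_chromosomal"
                        ),
                    }
                )
        else:
            unique.append(rec.ars_id)
    return SelfSimilarityReport(
        unique_ars=unique, multi_hit_ars=multi, pairs=pairs, missing_self=missing
    )


def hits_to_features(hits: Sequence[HomologyHit]) -> list[FeatureRecord]:
    out = []
    for i, h in enumerate(hits):
        out.append(
            FeatureRecord(
                feature_id=f"{h.ars_id}_hit{i}",
                chrom=h.subject_chrom,
                start=h.s_start,
                end=h.s_end,
                strand=h.strand,
                feature_type="ARS_homolog",
                source="ori-panscan",
                attributes={
                    "Parent_ARS": h.ars_id,
                    "identity": f"{h.identity:.2f}",
                    "coverage": f"{h.coverage:.2f}",
                    "e_value": f"{h.e_value:.3g}",
                },
            )
        )
    return out


def hits_to_gff3(
    hits: Sequence[HomologyHit],
    out_dir: str | Path,
    split_by_strain: bool = True,
) -> list[Path]:
    """Write hits as GFF3, one file per strain when ``split_by_strain``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups: dict[str, list[HomologyHit]]
    if split_by_strain:
        groups = {}
        for h in hits:
            groups.setdefault(h.strain_id, []).append(h)
        if not groups:
            groups = {"all": []}
    else:
        groups = {"all": list(hits)}
    written = []
    for strain, strain_hits in sorted(groups.items()):
        feats = hits_to_features(
            sorted(strain_hits, key=lambda h: (h.subject_chrom, h.s_start))
        )
        path = out_dir / f"{strain}.gff3"
        write_gff3(feats, path)
        written.append(path)
    return written
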