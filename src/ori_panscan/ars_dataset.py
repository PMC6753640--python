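"""Non-redundant replication-origin dataset construction and summary.

The combined origin catalog starts from a primary annotation set (kept
verbatim) and adds records from supplementary sets, in priority order, that
are not redundant with anything already accepted.  Redundancy is reciprocal
interval overlap of at least a threshold fraction (default 0.5) on the same
chromosome — the catalog never states its own de-duplication rule, so this
positional predicate is the package's explicit, deterministic choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as _stats
from .formats_io import FeatureRecord, GenomeAssembly, gc_content, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class ARSRecord:
    """One replication-origin annotation placed on the reference."""

    ars_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    source: str  # SGD | OriDB | DeOri | synthetic | ...
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid interval for {self.ars_id}")
        if self.sequence and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.ars_id}: sequence length {len(self.sequence)} != span {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def gc_content(self) -> float:
        return gc_content(self.sequence) if self.sequence else float("nan")


@dataclass
class ARSDataset:
    records: list[ARSRecord]
    reference_id: str = "reference"
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.ars_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate origin ids: {dup}")
        if not self.provenance:
            self.provenance = {r.ars_id: r.source for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, ARSRecord]:
        return {r.ars_id: r for r in self.records}

    def lengths(self) -> dict[str, int]:
        return {r.ars_id: r.length for r in self.records}

    def to_features(self) -> list[FeatureRecord]:
        return [
            FeatureRecord(
                feature_id=r.ars_id,
                chrom=r.chrom,
                start=r.start,
                end=r.end,
                feature_type="ARS",
                source=r.source,
            )
            for r in self.records
        ]


def reciprocal_overlap(a: ARSRecord | FeatureRecord, b: ARSRecord | FeatureRecord) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when on different chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def attach_sequences(records: Sequence[ARSRecord], reference: GenomeAssembly) -> None:
    """Fill record sequences from the reference, validating coordinates."""
    for rec in records:
        if rec.chrom not in reference.chromosomes:
            raise ValueError(f"{rec.ars_id}: chromosome {rec.chrom} not in reference")
        if rec.end > reference.lengths[rec.chrom]:
            raise ValueError(
                f"{rec.ars_id}: interval extends past end of {rec.chrom}"
            )
        rec.sequence = reference.fetch(rec.chrom, rec.start, rec.end)


def place_by_exact_match(
    ars_id: str, sequence: str, reference: GenomeAssembly, source: str = "DeOri"
) -> ARSRecord | None:
    """Place a coordinate-less record by a unique exact-match scan.

    Both strands are searched.  Zero or multiple (>=2) matching loci reject
    the record with a logged reason.
    """
    seq = sequence.upper()
    loci: list[tuple[str, int, str]] = []
    for chrom, ref_seq in reference.chromosomes.items():
        for probe, strand in ((seq, "+"), (reverse_complement(seq), "-")):
            pos = ref_seq.find(probe)
            while pos != -1:
                loci.append((chrom, pos + 1, strand))
                if len(loci) > 1:
                    break
                pos = ref_seq.find(probe, pos + 1)
        if len(loci) > 1:
            break
    if len(loci) != 1:
        logger.info(
            "%s rejected: %s exact-match loci", ars_id, "no" if not loci else ">=2"
        )
        return None
    chrom, start, _strand = loci[0]
    return ARSRecord(
        ars_id=ars_id,
        chrom=chrom,
        start=start,
        end=start + len(seq) - 1,
        source=source,
        sequence=seq,
    )


def merge_nonredundant(
    primary: Sequence[ARSRecord],
    supplements: Sequence[Sequence[ARSRecord]],
    overlap_fraction_threshold: float = 0.5,
    reference_id: str = "reference",
) -> ARSDataset:
    """Merge origin sets into a non-redundant catalog.

    Primary records are kept verbatim.  Supplement sets are processed in
    priority order; a record joins the catalog only when its reciprocal
    overlap with every accepted record is below the threshold.  Merging a
    dataset with itself is a no-op (idempotence).
    """
    accepted: list[ARSRecord] = list(primary)
    by_chrom: dict[str, list[ARSRecord]] = {}
    for rec in accepted:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for supplement in supplements:
        for rec in supplement:
            redundant = any(
                reciprocal_overlap(rec, other) >= overlap_fraction_threshold
                for other in by_chrom.get(rec.chrom, [])
            )
            if redundant:
                logger.debug("%s redundant, skipped", rec.ars_id)
                continue
            accepted.append(rec)
            by_chrom.setdefault(rec.chrom, []).append(rec)
    return ARSDataset(records=accepted, reference_id=reference_id)


def dataset_summary(
    dataset: ARSDataset,
    reference: GenomeAssembly | None = None,
    length_band: tuple[int, int] = (70, 250),
) -> dict:
    """Headline length/GC statistics of the origin catalog.

    Reports per-chromosome counts and median lengths, the global length
    range, the fraction of origins inside ``length_band``, and mean origin
    GC against genome GC when a reference is supplied.
    """
    if not dataset.records:
        raise ValueError("empty dataset")
    lengths = np.array([r.length for r in dataset.records])
    per_chrom = pd.DataFrame(
        [(r.chrom, r.length) for r in dataset.records], columns=["chrom", "length"]
    )
    chrom_stats = (
        per_chrom.groupby("chrom")["length"].agg(count="count", median_length="median")
    )
    lo, hi = length_band
    in_band = int(((lengths >= lo) & (lengths <= hi)).sum())
    gcs = [r.gc_content for r in dataset.records if r.sequence]
    summary = {
        "n_ars": len(dataset.records),
        "min_length": int(lengths.min()),
        "max_length": int(lengths.max()),
        "median_length": float(np.median(lengths)),
        "fraction_in_band": in_band / len(lengths),
        "length_band": [lo, hi],
        "per_chromosome": chrom_stats,
        "mean_ars_gc": float(np.mean(gcs)) if gcs else float("nan"),
    }
    if reference is not None:
        summary["genome_gc"] = float(
            gc_content("".join(reference.chromosomes.values()))
        )
    return summary


def count_vs_length_regression(
    dataset: ARSDataset, chrom_lengths: dict[str, int]
) -> tuple[float, float, float]:
    """OLS of per-chromosome origin count on chromosome length.

    Chromosomes without origins contribute a zero count.  Returns
    (slope, intercept, pearson_r); requires >=3 chromosomes.
    """
    if len(chrom_lengths) < 3:
        raise ValueError("need at least 3 chromosomes")
    counts = {c: 0 for c in chrom_lengths}
    for rec in dataset.records:
        if rec.chrom in counts:
            counts[rec.chrom] += 1
    x = np.array([chrom_lengths[c] for c in chrom_lengths], dtype=float)
    y = np.array([counts[c] for c in chrom_lengths], dtype=float)
    if np.ptp(y) == 0:
        # degenerate flat response: slope and r are zero by convention
        return 0.0, float(y[0]), 0.0
    return _stats.linear_fit(x, y)
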