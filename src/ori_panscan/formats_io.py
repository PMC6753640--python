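"""Readers and writers for the plain-text formats the pipeline touches.

All interfaces speak 1-based inclusive coordinates, the convention shared by
GFF3 and 12-column tabular alignment output.  FASTA parsing is delegated to
Biopython; GFF3 and tabular-hit handling are thin line-oriented codecs because
the pipeline only needs the nine standard columns plus a handful of
attributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_STRANDS = {"+", "-", "."}
# IUPAC ambiguity codes other than N are collapsed to N; U (RNA) maps to T.
_NORMALIZE = str.maketrans(
    {c: "N" for c in "RYSWKMBDHV"} | {"U": "T"}
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeAssembly:
    """One strain genome: ordered chromosomes of uppercase A/C/G/T/N."""

    strain_id: str
    chromosomes: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Extract [start, end] (1-based inclusive) from *chrom*."""
        seq = self.chromosomes[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start},{end}] outside {chrom} (length {len(seq)})"
            )
        return seq[start - 1 : end]


@dataclass
class FeatureRecord:
    """One annotated interval (gene, ARS, homolog hit ...) in GFF3 terms."""

    feature_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."
    feature_type: str = "region"
    source: str = "."
    score: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"invalid interval [{self.start},{self.end}] for {self.feature_id}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.feature_id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TabularHit:
    """One row of 12-column tabular alignment output.

    Subject coordinates are normalized to s_start <= s_end; a subject
    interval reported in descending order encodes a minus-strand hit.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    strand: str = "+"


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase, map U->T and non-N ambiguity codes to N.

    Returns the normalized sequence and the number of bases that were
    collapsed to N.
    """
    up = seq.upper().translate(_NORMALIZE)
    n_mapped = sum(1 for a, b in zip(seq.upper(), up) if a != b and b == "N")
    bad = set(up) - set("ACGTN")
    if bad:
        raise FormatError(f"illegal characters in sequence: {sorted(bad)}")
    return up, n_mapped


def read_fasta(path: str | Path, strain_id: str | None = None) -> GenomeAssembly:
    """Read a (multi-)FASTA file into a :class:`GenomeAssembly`.

    Sequences are uppercased; U becomes T and ambiguity codes other than N
    become N (count logged).  Record order is preserved.
    """
    path = Path(path)
    chromosomes: dict[str, str] = {}
    mapped_total = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chromosomes:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq, n_mapped = normalize_sequence(str(rec.seq))
        mapped_total += n_mapped
        chromosomes[rec.id] = seq
    if not chromosomes:
        raise FormatError(f"no FASTA records in {path}")
    if mapped_total:
        logger.info("%s: %d ambiguity bases mapped to N", path, mapped_total)
    return GenomeAssembly(strain_id=strain_id or path.stem, chromosomes=chromosomes)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in assembly.chromosomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if col9 in (".", ""):
        return attrs
    for part in col9.rstrip(";").split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(
    path: str | Path, feature_types: Iterable[str] | None = None
) -> list[FeatureRecord]:
    """Parse a GFF3 file into :class:`FeatureRecord` objects.

    Records are returned sorted by (chrom, start), with the original line
    order breaking ties.  ``feature_types`` optionally restricts column 3.
    Coordinates are kept verbatim (1-based inclusive).
    """
    wanted = set(feature_types) if feature_types is not None else None
    records: list[tuple[str, int, int, FeatureRecord]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, source, ftype, start_s, end_s, score, strand, _phase, col9 = cols
            if wanted is not None and ftype not in wanted:
                continue
            start, end = int(start_s), int(end_s)
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            if strand not in _VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_attributes(col9)
            fid = attrs.get("ID") or f"{ftype}_{chrom}_{lineno}"
            records.append(
                (
                    chrom,
                    start,
                    lineno,
                    FeatureRecord(
                        feature_id=fid,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        feature_type=ftype,
                        source=source,
                        score=score,
                        attributes=attrs,
                    ),
                )
            )
    records.sort(key=lambda t: (t[0], t[1], t[2]))
    return [r for _, _, _, r in records]


def write_gff3(records: Sequence[FeatureRecord], path: str | Path) -> None:
    """Write records as GFF3 v3; round-trips through :func:`read_gff3`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = dict(rec.attributes)
            attrs.setdefault("ID", rec.feature_id)
            col9 = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                "\t".join(
                    [
                        rec.chrom,
                        rec.source,
                        rec.feature_type,
                        str(rec.start),
                        str(rec.end),
                        rec.score,
                        rec.strand,
                        ".",
                        col9 or ".",
                    ]
                )
                + "\n"
            )


def read_tabular_hits(path: str | Path) -> list[TabularHit]:
    """Parse standard 12-column tabular alignment output.

    A subject interval with s_start > s_end marks a minus-strand hit; the
    coordinates are swapped so s_start <= s_end and ``strand`` records the
    orientation.
    """
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(cols)}"
                )
            s_start, s_end = int(cols[8]), int(cols[9])
            strand = "+"
            if s_start > s_end:
                strand = "-"
                s_start, s_end = s_end, s_start
            hits.append(
                TabularHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=s_start,
                    s_end=s_end,
                    e_value=float(cols[10]),
                    bit_score=float(cols[11]),
                    strand=strand,
                )
            )
    return hits


def read_tsv(path: str | Path):
    """Read a header-bearing TSV into a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t")


def write_tsv(df, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def gc_content(seq: str) -> float:
    """GC fraction over non-N bases (N excluded from the denominator)."""
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / denom


def at_content(seq: str) -> float:
    """AT fraction over non-N bases; complements :func:`gc_content`."""
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return (counts["A"] + counts["T"]) / denom


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def apply_alias(chrom: str, alias: Mapping[str, str] | None) -> str:
    """Map a strain chromosome name to the reference name (identity default)."""
    if alias is None:
        return chrom
    return alias.get(chrom, chrom)
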