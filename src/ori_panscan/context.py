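"""Positional context of replication origins against gene annotations.

Classifies each origin as *intergenic* (no base shared with any
protein-coding gene) or *intersected* (partial or complete gene overlap),
finds the nearest flanking genes and gap sizes, flags subtelomeric location
(within a fixed window of either chromosome end), extracts origin-gene
overlap segments, and aggregates adjacency across a strain panel into
conserved-adjacent-gene calls.  Gene strand is ignored throughout; adjacency
is purely positional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import FeatureRecord, GenomeAssembly
from . import stats as _stats

logger = logging.getLogger(__name__)


@dataclass
class PositionalContext:
    """Adjacency record of one origin against the gene annotation."""

    ars_id: str
    chrom: str
    start: int
    end: int
    subtelomeric: bool
    left_gene: str | None = None
    right_gene: str | None = None
    left_distance: int | None = None  # bases strictly between gene and origin
    right_distance: int | None = None
    overlap_genes: list[tuple[str, int, float]] = field(default_factory=list)
    tied_neighbors: list[str] = field(default_factory=list)

    @property
    def cls(self) -> str:
        return "intersected" if self.overlap_genes else "intergenic"


@dataclass
class AdjacentGeneCall:
    gene_id: str
    ars_id: str
    n_strains_adjacent: int
    n_strains: int
    cls: str  # conserved | non_conserved
    essential: bool | None = None
    expression: float | None = None


def flag_subtelomeric(start: int, end: int, chrom_length: int, window_bp: int = 20000) -> bool:
    """True when the interval lies within ``window_bp`` of either chromosome end.

    The window covers positions [1, window_bp] and
    [chrom_length - window_bp + 1, chrom_length].
    """
    if window_bp >= chrom_length / 2:
        logger.warning(
            "subtelomere window %d covers the whole %d bp chromosome",
            window_bp,
            chrom_length,
        )
    return start <= window_bp or end >= chrom_length - window_bp + 1


def _overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def adjacent_genes(
    ars: FeatureRecord,
    genes_on_chrom: Sequence[FeatureRecord],
    chrom_length: int | None = None,
    subtel_window_bp: int = 20000,
) -> PositionalContext:
    """Positional context of one origin against the genes of its chromosome.

    Overlap genes share >=1 bp with the origin.  The left neighbor is the
    non-overlapping gene with the largest end < origin start (gap = origin
    start - gene end - 1); right is symmetric.  A gap tie is broken toward
    the gene with the smaller start; all tied genes are recorded.
    """
    overlaps: list[tuple[str, int, float]] = []
    left_cands: list[tuple[int, int, str]] = []  # (gap, start, id)
    right_cands: list[tuple[int, int, str]] = []
    ars_len = ars.end - ars.start + 1
    for gene in genes_on_chrom:
        if gene.chrom != ars.chrom:
            continue
        ov = _overlap_bp(ars.start, ars.end, gene.start, gene.end)
        if ov > 0:
            overlaps.append((gene.feature_id, ov, ov / ars_len))
        elif gene.end < ars.start:
            left_cands.append((ars.start - gene.end - 1, gene.start, gene.feature_id))
        else:
            right_cands.append((gene.start - ars.end - 1, gene.start, gene.feature_id))
    ties: list[str] = []

    def _pick(cands: list[tuple[int, int, str]]):
        if not cands:
            return None
        best = min(cands)
        ties.extend(c[2] for c in cands if c[0] == best[0] and c[2] != best[2])
        return best

    left_best = _pick(left_cands)
    right_best = _pick(right_cands)
    overlaps.sort(key=lambda t: (-t[1], t[0]))
    subtel = (
        flag_subtelomeric(ars.start, ars.end, chrom_length, subtel_window_bp)
        if chrom_length is not None
        else False
    )
    return PositionalContext(
        ars_id=ars.feature_id,
        chrom=ars.chrom,
        start=ars.start,
        end=ars.end,
        subtelomeric=subtel,
        left_gene=left_best[2] if left_best else None,
        right_gene=right_best[2] if right_best else None,
        left_distance=left_best[0] if left_best else None,
        right_distance=right_best[0] if right_best else None,
        overlap_genes=overlaps,
        tied_neighbors=ties,
    )


def contexts_for_dataset(
    ars_records: Sequence[FeatureRecord],
    genes: Sequence[FeatureRecord],
    chrom_lengths: Mapping[str, int] | None = None,
    subtel_window_bp: int = 20000,
) -> list[PositionalContext]:
    """Vector version of :func:`adjacent_genes` over a whole origin set."""
    by_chrom: dict[str, list[FeatureRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for ars in ars_records:
        length = chrom_lengths.get(ars.chrom) if chrom_lengths else None
        out.append(
            adjacent_genes(
                ars, by_chrom.get(ars.chrom, []), length, subtel_window_bp
            )
        )
    return out


def overlap_segments(
    contexts: Sequence[PositionalContext],
    genes_by_id: Mapping[str, FeatureRecord],
    reference: GenomeAssembly,
) -> list[dict]:
    """Exact origin-gene overlap intervals with extracted sequence.

    One record per (intersected origin, overlapping gene) pair.
    """
    out = []
    for ctx in contexts:
        for gene_id, _ov, _frac in ctx.overlap_genes:
            gene = genes_by_id[gene_id]
            seg_start = max(ctx.start, gene.start)
            seg_end = min(ctx.end, gene.end)
            chrom_len = reference.lengths[ctx.chrom]
            if seg_start < 1 or seg_end > chrom_len:
                raise ValueError(
                    f"overlap segment [{seg_start},{seg_end}] outside {ctx.chrom}"
                )
            out.append(
                {
                    "ars_id": ctx.ars_id,
                    "gene_id": gene_id,
                    "chrom": ctx.chrom,
                    "start": seg_start,
                    "end": seg_end,
                    "length": seg_end - seg_start + 1,
                    "sequence": reference.fetch(ctx.chrom, seg_start, seg_end),
                }
            )
    return out


def conserved_adjacent_genes(
    per_strain_contexts: Mapping[str, Sequence[PositionalContext]],
    ortholog_map: Mapping[str, Mapping[str, str]] | None = None,
    threshold_fraction: float = 0.90,
    essential: Iterable[str] | None = None,
    expression: Mapping[str, float] | None = None,
) -> list[AdjacentGeneCall]:
    """Count, per (reference gene, origin) adjacency, the strains supporting it.

    A gene is *adjacent* to an origin in a strain when it is that origin
    homolog's left or right neighbor or overlaps it.  ``ortholog_map`` maps
    strain gene ids to reference gene ids per strain (identity when absent);
    a strain gene with no mapping counts as absent.  Adjacencies present in
    strictly more than ``threshold_fraction`` of the strains are conserved —
    the same strict >90% rule used for origin conservation.
    """
    n_strains = len(per_strain_contexts)
    counts: dict[tuple[str, str], int] = {}
    for strain, contexts in per_strain_contexts.items():
        omap = (ortholog_map or {}).get(strain)
        seen: set[tuple[str, str]] = set()
        for ctx in contexts:
            gene_ids = [g for g, _, _ in ctx.overlap_genes]
            gene_ids += [g for g in (ctx.left_gene, ctx.right_gene) if g]
            for gid in gene_ids:
                if omap is not None:
                    ref_gid = omap.get(gid)
                    if ref_gid is None:
                        logger.debug("strain %s gene %s has no ortholog", strain, gid)
                        continue
                else:
                    ref_gid = gid
                seen.add((ref_gid, ctx.ars_id))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    essential_set = set(essential or ())
    calls = []
    for (gene_id, ars_id), count in sorted(counts.items()):
        calls.append(
            AdjacentGeneCall(
                gene_id=gene_id,
                ars_id=ars_id,
                n_strains_adjacent=count,
                n_strains=n_strains,
                cls=(
                    "conserved"
                    if count > threshold_fraction * n_strains
                    else "non_conserved"
                ),
                essential=(gene_id in essential_set) if essential is not None else None,
                expression=(expression or {}).get(gene_id),
            )
        )
    return calls


def join_annotations(
    contexts: Sequence[PositionalContext],
    essential: Iterable[str] | None = None,
    expression: Mapping[str, float] | None = None,
) -> dict:
    """Join essential-gene and expression tables onto origin contexts.

    Reports origins overlapping essential genes and compares mean
    adjacent-gene expression between intersected- and intergenic-class
    origins (one-sided rank test: intersected-adjacent lower).
    """
    essential_set = set(essential or ())
    essential_overlaps = [
        (ctx.ars_id, gid)
        for ctx in contexts
        for gid, _, _ in ctx.overlap_genes
        if gid in essential_set
    ]

    def _adjacent_gene_ids(ctx: PositionalContext) -> list[str]:
        ids = [g for g, _, _ in ctx.overlap_genes]
        ids += [g for g in (ctx.left_gene, ctx.right_gene) if g]
        return ids

    comparison = None
    if expression:
        groups: dict[str, list[float]] = {"intergenic": [], "intersected": []}
        for ctx in contexts:
            vals = [expression[g] for g in _adjacent_gene_ids(ctx) if g in expression]
            if vals:
                groups[ctx.cls].append(float(np.mean(vals)))
        if groups["intergenic"] and groups["intersected"]:
            report = _stats.mann_whitney_u(
                groups["intersected"], groups["intergenic"], alternative="less"
            )
            comparison = report.as_dict()
        else:
            logger.info("expression comparison skipped: one class has no data")
    else:
        logger.info("expression comparison skipped: no expression table")
    return {
        "essential_overlap_pairs": essential_overlaps,
        "n_intersected_with_essential": len({a for a, _ in essential_overlaps}),
        "expression_comparison": comparison,
    }


def ars_feature_table(
    dataset,
    contexts: Sequence[PositionalContext],
    homolog_counts: Mapping[str, int] | None = None,
    timing: Mapping[str, float] | None = None,
    expression: Mapping[str, float] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    missing_policy: str = "drop",
) -> pd.DataFrame:
    """Numeric per-origin feature matrix for PCA.

    Columns: length, gc_content, intersected indicator, relative chromosomal
    position of the midpoint, homolog count, replication timing, mean
    adjacent-gene expression.  ``missing_policy`` is ``drop`` or
    ``mean_impute``.
    """
    ctx_by_id = {c.ars_id: c for c in contexts}
    rows = {}
    for rec in dataset.records:
        ctx = ctx_by_id.get(rec.ars_id)
        if ctx is None:
            continue
        rel_pos = np.nan
        if chrom_lengths and rec.chrom in chrom_lengths:
            rel_pos = ((rec.start + rec.end) / 2) / chrom_lengths[rec.chrom]
        adj = [g for g, _, _ in ctx.overlap_genes]
        adj += [g for g in (ctx.left_gene, ctx.right_gene) if g]
        expr_vals = [expression[g] for g in adj if expression and g in expression]
        rows[rec.ars_id] = {
            "length": rec.length,
            "gc_content": rec.gc_content,
            "intersected": 1.0 if ctx.cls == "intersected" else 0.0,
            "relative_position": rel_pos,
            "homolog_count": (homolog_counts or {}).get(rec.ars_id, np.nan),
            "timing": (timing or {}).get(rec.ars_id, np.nan),
            "adjacent_expression": float(np.mean(expr_vals)) if expr_vals else np.nan,
        }
    if not rows:
        raise ValueError("no origins shared between dataset and contexts")
    df = pd.DataFrame.from_dict(rows, orient="index")
    if missing_policy == "drop":
        df = df.dropna()
    elif missing_policy == "mean_impute":
        df = df.fillna(df.mean())
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    return df
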