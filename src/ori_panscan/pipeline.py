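"""End-to-end orchestration: dataset -> scan -> conservation -> context ->
motif -> repeats -> statistics, with a machine-readable JSON report.

The report carries every headline quantity the analysis produces (uniqueness
fraction, conserved fraction and core size, subtelomere bias test, timing
correlation, intergenic fraction, ACS-in-overlap counts, repeat summary) plus
a manifest of the thresholds and seeds used, so a rerun with the same config
and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import context as _context
from . import conservation as _conservation
from . import homology as _homology
from . import motif as _motif
from . import repeats as _repeats
from . import stats as _stats
from .ars_dataset import ARSDataset, count_vs_length_regression, dataset_summary
from .formats_io import GenomeAssembly
from .synthetic_data import Panel

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """All tunable thresholds of one pipeline run."""

    thresholds: _homology.FilterThresholds = field(
        default_factory=_homology.FilterThresholds
    )
    conservation_threshold: float = 0.90
    subtel_window_bp: int = 20_000
    motif_pseudocount: float = 0.5
    motif_scan_threshold: float = 0.8
    repeat_min_length: int = 8
    repeat_max_hits: int = 50
    n_permutations: int = 200
    seed: int = 0


def _jsonify(obj):
    """Recursively convert numpy scalars so the report serializes cleanly."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def analyze_panel(
    panel: Panel,
    params: AnalysisParams | None = None,
    acs_library: Sequence[str] | None = None,
) -> dict:
    """Run the full analysis on a strain panel and return the report dict.

    ``acs_library`` is the set of aligned ACS instances used to build the
    motif model; by default the panel's planted ACS words stand in for a
    published ACS collection.
    """
    params = params or AnalysisParams()
    dataset = panel.dataset
    reference = panel.reference
    genes = panel.genes

    report: dict = {"manifest": _manifest(params)}

    # dataset stage
    summary = dataset_summary(dataset, reference)
    per_chrom = summary.pop("per_chromosome")
    report["dataset"] = dict(summary)
    report["dataset"]["per_chromosome_counts"] = per_chrom["count"].to_dict()
    if len(reference.lengths) >= 3:
        slope, intercept, r = count_vs_length_regression(dataset, reference.lengths)
        report["dataset"]["count_vs_length"] = {
            "slope": slope, "intercept": intercept, "pearson_r": r,
        }
    else:
        report["dataset"]["count_vs_length"] = None  # needs >= 3 chromosomes

    # self-similarity on the reference
    self_rep = _homology.self_similarity(dataset, reference, params.thresholds)
    duplicate_loci = {}
    for pair in self_rep.pairs:
        duplicate_loci.setdefault(pair["ars_id"], set()).add(pair["chrom"])
    report["self_similarity"] = {
        "fraction_unique": self_rep.fraction_unique,
        "n_multi_hit": len(self_rep.multi_hit_ars),
        "n_inter_chromosomal_pairs": sum(
            1 for p in self_rep.pairs if p["label"] == "inter_chromosomal"
        ),
        "n_intra_chromosomal_pairs": sum(
            1 for p in self_rep.pairs if p["label"] == "intra_chromosomal"
        ),
    }

    # homolog scan across strains
    all_hits = []
    for strain in panel.strains:
        all_hits.extend(
            _homology.scan_genome(dataset.records, strain, params.thresholds)
        )
    strain_ids = [s.strain_id for s in panel.strains]

    matrix = _conservation.build_presence_matrix(
        all_hits,
        dataset,
        strain_ids,
        restrict_to_corresponding_chrom=True,
        duplicate_loci=duplicate_loci,
    )
    calls = _conservation.classify_conservation(matrix, params.conservation_threshold)
    core = _conservation.core_ars_set(matrix)
    curves = _conservation.pan_core_curves(
        matrix, n_permutations=params.n_permutations, seed=params.seed, fit=True
    )
    n_conserved = sum(1 for c in calls if c.cls == "conserved")
    report["conservation"] = {
        "n_ars": len(calls),
        "n_strains": matrix.n_strains,
        "n_conserved": n_conserved,
        "conserved_fraction": n_conserved / len(calls),
        "core_size": len(core),
        "pan_final_median": float(curves.pan_median[-1]),
        "core_final_median": float(curves.core_median[-1]),
        "fit_params": curves.fit_params,
        "presence_fractions": {c.ars_id: c.fraction for c in calls},
    }

    # positional context against the reference annotation
    contexts = _context.contexts_for_dataset(
        dataset.to_features(), genes, reference.lengths, params.subtel_window_bp
    )
    n_intergenic = sum(1 for c in contexts if c.cls == "intergenic")
    report["context"] = {
        "n_intergenic": n_intergenic,
        "n_intersected": len(contexts) - n_intergenic,
        "intergenic_fraction": n_intergenic / len(contexts),
    }

    bias = _conservation.subtelomere_bias_test(calls, contexts)
    report["subtelomere_bias"] = bias

    timing = dict(
        zip(panel.truth.timing.ars_id, panel.truth.timing.trep_minutes)
    )
    report["timing"] = _conservation.timing_correlation(calls, timing)

    report["by_niche"] = (
        _conservation.summarize_by_group(matrix, panel.truth.strain_metadata, "niche")
        .reset_index()
        .to_dict(orient="records")
    )

    # per-strain adjacency -> conserved adjacent genes
    hits_by_strain: dict[str, list] = {s: [] for s in strain_ids}
    for h in all_hits:
        hits_by_strain.setdefault(h.strain_id, []).append(h)
    per_strain_contexts = {}
    for strain in panel.strains:
        feats = _homology.hits_to_features(hits_by_strain[strain.strain_id])
        for f, h in zip(feats, hits_by_strain[strain.strain_id]):
            f.feature_id = h.ars_id  # adjacency is per origin, not per hit
        per_strain_contexts[strain.strain_id] = _context.contexts_for_dataset(
            feats, genes, strain.lengths, params.subtel_window_bp
        )
    gene_calls = _context.conserved_adjacent_genes(
        per_strain_contexts,
        threshold_fraction=params.conservation_threshold,
        essential=panel.essential_genes,
        expression=panel.expression,
    )
    n_cons_adj = sum(1 for c in gene_calls if c.cls == "conserved")
    report["adjacent_genes"] = {
        "n_adjacency_pairs": len(gene_calls),
        "n_conserved": n_cons_adj,
        "n_conserved_genes": len({c.gene_id for c in gene_calls if c.cls == "conserved"}),
    }

    joined = _context.join_annotations(
        contexts, essential=panel.essential_genes, expression=panel.expression
    )
    report["essential_expression"] = {
        "n_intersected_with_essential": joined["n_intersected_with_essential"],
        "expression_comparison": joined["expression_comparison"],
    }

    # ACS motif stage
    library = list(acs_library) if acs_library is not None else list(
        panel.truth.ars.acs_word
    )
    model = _motif.build_motif(library, pseudocount=params.motif_pseudocount)
    consensus = _motif.degenerate_consensus(model)
    genes_by_id = {g.feature_id: g for g in genes}
    segments = _context.overlap_segments(contexts, genes_by_id, reference)
    n_with_acs = 0
    for seg in segments:
        if _motif.scan(
            model, seg["sequence"], threshold_fraction_of_max=params.motif_scan_threshold
        ):
            n_with_acs += 1
    ars_seqs = {r.ars_id: r.sequence for r in dataset.records}
    best_hits = {}
    for ars_id, seq in ars_seqs.items():
        hit = _motif.best_hit(model, seq, ars_id)
        if hit is not None:
            best_hits[ars_id] = hit
    profile = _motif.centered_base_profile(ars_seqs, best_hits, flank_bp=30, width=model.width)
    report["motif"] = {
        "consensus": consensus,
        "n_library": model.n_sequences,
        "n_overlap_segments": len(segments),
        "n_segments_with_acs": n_with_acs,
        "profile_central_T_fraction": float(
            profile[3, 30 : 30 + model.width].mean()
        ),
    }

    # repeats
    hits_by_seq = {
        r.ars_id: _repeats.find_repeats(
            r.sequence, r.ars_id, params.repeat_min_length, max_hits=params.repeat_max_hits
        )
        for r in dataset.records
    }
    seg_ids = []
    for seg in segments:
        sid = f"segment_{seg['ars_id']}_{seg['gene_id']}"
        seg_ids.append(sid)
        hits_by_seq[sid] = _repeats.find_repeats(
            seg["sequence"], sid, params.repeat_min_length, max_hits=params.repeat_max_hits
        )
    report["repeats"] = _repeats.repeat_summary(hits_by_seq, segment_ids=seg_ids)

    # PCA over origin features
    homolog_counts = matrix.homolog_counts
    table = _context.ars_feature_table(
        dataset,
        contexts,
        homolog_counts=homolog_counts,
        timing=timing,
        expression=panel.expression,
        chrom_lengths=reference.lengths,
        missing_policy="drop",
    )
    if len(table) >= 3:
        try:
            _scores, _loadings, explained = _stats.pca(table.values, standardize=True)
            report["pca"] = {
                "n_rows": len(table),
                "explained_variance": [float(v) for v in explained[:3]],
            }
        except ValueError as exc:  # constant column on degenerate panels
            report["pca"] = {"skipped": str(exc)}
    return _jsonify(report)


def _manifest(params: AnalysisParams) -> dict:
    return {
        "min_identity": params.thresholds.min_identity,
        "min_coverage": params.thresholds.min_coverage,
        "max_e_value": params.thresholds.max_e_value,
        "conservation_threshold": params.conservation_threshold,
        "subtel_window_bp": params.subtel_window_bp,
        "motif_pseudocount": params.motif_pseudocount,
        "motif_scan_threshold": params.motif_scan_threshold,
        "repeat_min_length": params.repeat_min_length,
        "repeat_max_hits": params.repeat_max_hits,
        "n_permutations": params.n_permutations,
        "seed": params.seed,
    }


def write_report(report: Mapping, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(
    panel: Panel,
    out_dir: str | Path,
    params: AnalysisParams | None = None,
) -> dict:
    """Analyze a panel and persist the JSON report under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = analyze_panel(panel, params)
    write_report(report, out_dir / "report.json")
    return report
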