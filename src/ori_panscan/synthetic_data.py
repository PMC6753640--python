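"""Synthetic strain panels with known ground truth.

Emulates the structure the pipeline is built to analyze: a reference genome
carrying AT-rich replication origins (~70% AT) that each contain one ACS-like
11-mer; protein-coding genes tiled between (and sometimes overlapping)
origins; a panel of strains derived from the reference by i.i.d. base
substitutions and origin deletions, with an elevated deletion probability in
subtelomeres; a handful of origins duplicated into subtelomeres of other
chromosomes; and replication-timing values decreasing with origin
conservation.  Everything derives from a single seed and is byte-for-byte
reproducible.

Deliberately not modelled: indels and rearrangements (deleted origins are
replaced in place by fresh background so strain coordinates stay aligned to
the reference), recombination, phylogenetic structure, aneuploidy.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .ars_dataset import ARSDataset, ARSRecord
from .formats_io import FeatureRecord, GenomeAssembly, write_fasta, write_gff3, write_tsv
from .motif import sample_from_consensus

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class PanelConfig:
    """Parameters of one synthetic panel.

    Defaults describe a small but structurally faithful panel: four 200 kb
    chromosomes at 38% GC with ten origins each (150-300 bp, 70% AT, one
    planted ACS word from the WTTTAYRTTTW consensus), ~0.5% strain
    divergence, a 2% internal vs 50% subtelomeric origin-deletion rate, and
    timing anticorrelated with conservation.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length_bp: int = 200_000
    genome_gc: float = 0.38
    n_ars_per_chrom: int = 10
    ars_length_range: tuple[int, int] = (150, 300)
    ars_at_content: float = 0.70
    acs_consensus: str = "WTTTAYRTTTW"
    n_strains: int = 50
    substitution_rate: float = 0.005
    p_del_internal: float = 0.02
    p_del_subtel: float = 0.5
    subtel_window_bp: int = 20_000
    frac_intersected: float = 0.3
    timing_t0: float = 40.0
    timing_slope_b: float = 20.0
    timing_noise_sd: float = 2.0
    n_duplicated_ars: int = 2
    gene_length_range: tuple[int, int] = (800, 1500)
    frac_essential_genes: float = 0.2
    expression_mean_intergenic: float = 10.0
    expression_mean_intersected: float = 8.0
    expression_sd: float = 2.0
    niches: tuple[str, ...] = ("wine", "beer", "bakery", "wild", "clinical")

    def validate(self) -> None:
        for name in ("genome_gc", "ars_at_content", "substitution_rate",
                     "p_del_internal", "p_del_subtel", "frac_intersected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ars_length_range[1] >= self.chrom_length_bp:
            raise ValueError("origins longer than the chromosome")
        if self.n_strains < 1:
            raise ValueError("need at least one strain")


@dataclass
class PanelTruth:
    """Ground-truth tables for one generated panel."""

    ars: pd.DataFrame  # ars_id, chrom, start, end, subtelomeric, intersected_gene, ...
    presence: pd.DataFrame  # origins x strains, 0/1, truth (not deleted)
    genes: pd.DataFrame  # gene_id, chrom, start, end, relation, essential, expression
    timing: pd.DataFrame  # ars_id, trep_minutes
    strain_metadata: pd.DataFrame  # strain_id, niche
    duplicate_loci: dict[str, list[tuple[str, int, int]]]
    expected_presence: pd.DataFrame  # ars_id, expected_fraction


@dataclass
class Panel:
    config: PanelConfig
    reference: GenomeAssembly
    strains: list[GenomeAssembly]
    dataset: ARSDataset
    genes: list[FeatureRecord]
    truth: PanelTruth
    essential_genes: list[str] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)


def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _at_rich(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _is_subtel(start: int, end: int, length: int, window: int) -> bool:
    return start <= window or end >= length - window + 1


def _find_free_interval(
    occupied: list[tuple[int, int]], lo: int, hi: int, size: int
) -> int | None:
    """1-based start of a free [start, start+size-1] within [lo, hi], or None."""
    cursor = lo
    for s, e in sorted(occupied):
        if e < lo:
            continue
        if s > hi:
            break
        if s - cursor >= size:
            return cursor
        cursor = max(cursor, e + 1)
    if hi - cursor + 1 >= size:
        return cursor
    return None


def generate_panel(config: PanelConfig) -> Panel:
    """Generate a full panel (reference, strains, annotations, truth tables)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length_bp
    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    # --- reference chromosomes ------------------------------------------------
    ref_codes = {c: _random_background(rng, L, config.genome_gc) for c in chrom_ids}

    # --- plant origins, one per slot so spacing is guaranteed -----------------
    ars_rows = []
    margin = 3000  # leaves room for flanking genes inside each slot
    lo_len, hi_len = config.ars_length_range
    for chrom in chrom_ids:
        slot = L // config.n_ars_per_chrom
        for i in range(config.n_ars_per_chrom):
            ars_len = int(rng.integers(lo_len, hi_len + 1))
            start_lo = i * slot + margin
            start_hi = (i + 1) * slot - margin - ars_len
            start = int(rng.integers(start_lo, start_hi + 1)) + 1  # 1-based
            end = start + ars_len - 1
            body = _at_rich(rng, ars_len, config.ars_at_content)
            acs = sample_from_consensus(config.acs_consensus, rng)
            acs_pos = int(rng.integers(10, ars_len - len(acs) - 10 + 1))
            body[acs_pos : acs_pos + len(acs)] = _encode(acs)
            ref_codes[chrom][start - 1 : end] = body
            ars_rows.append(
                {
                    "ars_id": f"ARS_{chrom}_{i + 1:02d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "length": ars_len,
                    "subtelomeric": _is_subtel(start, end, L, config.subtel_window_bp),
                    "acs_word": acs,
                    "acs_offset": acs_pos + 1,
                }
            )
    ars_df = pd.DataFrame(ars_rows)

    # --- tile genes in the gaps; some shifted to overlap their origin ---------
    gene_rows = []
    glo, ghi = config.gene_length_range
    for chrom in chrom_ids:
        sub = ars_df[ars_df.chrom == chrom].sort_values("start")
        bounds = [0] + [int(x) for pair in zip(sub.start, sub.end) for x in pair] + [L + 1]
        gaps = [
            (bounds[2 * i] + 1, bounds[2 * i + 1] - 1)
            for i in range(len(sub) + 1)
        ]
        for gi, (gap_lo, gap_hi) in enumerate(gaps):
            room = gap_hi - gap_lo + 1
            if room < glo + 100:
                continue
            glen = int(rng.integers(glo, min(ghi, room - 100) + 1))
            gstart = gap_lo + (room - glen) // 2
            gene_rows.append(
                {
                    "gene_id": f"gene_{chrom}_{gi + 1:02d}",
                    "chrom": chrom,
                    "start": gstart,
                    "end": gstart + glen - 1,
                    "relation": "flanking",
                    "ars_id": "",
                }
            )
    genes_df = pd.DataFrame(gene_rows)

    # shift a subset of right-flanking genes onto their origin (intersected)
    n_intersected = int(round(config.frac_intersected * len(ars_df)))
    intersect_idx = rng.choice(len(ars_df), size=n_intersected, replace=False)
    intersected_ids = set()
    for idx in sorted(intersect_idx):
        ars = ars_df.iloc[idx]
        right = genes_df[
            (genes_df.chrom == ars.chrom) & (genes_df.start > ars.end)
        ].sort_values("start")
        if right.empty:
            continue
        gidx = right.index[0]
        glen = genes_df.at[gidx, "end"] - genes_df.at[gidx, "start"] + 1
        overlap = max(10, int(round(0.4 * ars.length)))
        new_start = int(ars.end - overlap + 1)
        genes_df.at[gidx, "start"] = new_start
        genes_df.at[gidx, "end"] = new_start + glen - 1
        genes_df.at[gidx, "relation"] = "intersected"
        genes_df.at[gidx, "ars_id"] = ars.ars_id
        intersected_ids.add(ars.ars_id)
    ars_df["intersected"] = ars_df.ars_id.isin(intersected_ids)

    # --- duplicate some origins into subtelomeres of other chromosomes -------
    duplicate_loci: dict[str, list[tuple[str, int, int]]] = {}
    if config.n_duplicated_ars > 0:
        internal = ars_df[~ars_df.subtelomeric]
        pick = internal.iloc[
            rng.choice(len(internal), size=min(config.n_duplicated_ars, len(internal)), replace=False)
        ]
        for _, ars in pick.iterrows():
            targets = [c for c in chrom_ids if c != ars.chrom]
            target = targets[int(rng.integers(len(targets)))]
            occupied = [
                (int(r.start), int(r.end))
                for df in (ars_df, genes_df)
                for _, r in df[df.chrom == target].iterrows()
            ] + [(s, e) for (c, s, e) in
                 (loc for locs in duplicate_loci.values() for loc in locs) if c == target]
            size = int(ars.length)
            start = _find_free_interval(occupied, L - config.subtel_window_bp + 1, L, size + 100)
            if start is None:
                start = _find_free_interval(occupied, 1, config.subtel_window_bp, size + 100)
            if start is None:
                continue
            start += 50
            end = start + size - 1
            src = ref_codes[ars.chrom][int(ars.start) - 1 : int(ars.end)]
            ref_codes[target][start - 1 : end] = src
            duplicate_loci.setdefault(ars.ars_id, []).append((target, start, end))

    reference = GenomeAssembly(
        strain_id="reference",
        chromosomes={c: _decode(codes) for c, codes in ref_codes.items()},
    )
    records = [
        ARSRecord(
            ars_id=r.ars_id,
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            source="synthetic",
            sequence=reference.fetch(r.chrom, int(r.start), int(r.end)),
        )
        for r in ars_df.itertuples()
    ]
    dataset = ARSDataset(records=records, reference_id="reference")
    gene_features = [
        FeatureRecord(
            feature_id=g.gene_id,
            chrom=g.chrom,
            start=int(g.start),
            end=int(g.end),
            strand="+",
            feature_type="gene",
            source="synthetic",
        )
        for g in genes_df.itertuples()
    ]

    # --- per-origin deletion probability (duplicate loci are subtelomeric) ---
    loci_per_ars: dict[str, list[float]] = {}
    for r in ars_df.itertuples():
        p_del = config.p_del_subtel if r.subtelomeric else config.p_del_internal
        loci_per_ars[r.ars_id] = [p_del]
        for _ in duplicate_loci.get(r.ars_id, []):
            loci_per_ars[r.ars_id].append(config.p_del_subtel)

    # --- strains --------------------------------------------------------------
    strain_ids = [f"strain_{i + 1:03d}" for i in range(config.n_strains)]
    strains: list[GenomeAssembly] = []
    presence = np.zeros((len(ars_df), config.n_strains), dtype=np.int8)
    for s_idx in range(config.n_strains):
        codes = {c: arr.copy() for c, arr in ref_codes.items()}
        surviving = np.zeros(len(ars_df), dtype=bool)
        for a_idx, r in enumerate(ars_df.itertuples()):
            p_del = config.p_del_subtel if r.subtelomeric else config.p_del_internal
            alive = rng.random() >= p_del
            if alive:
                surviving[a_idx] = True
            else:
                codes[r.chrom][int(r.start) - 1 : int(r.end)] = _random_background(
                    rng, int(r.length), config.genome_gc
                )
            for chrom, s, e in duplicate_loci.get(r.ars_id, []):
                if rng.random() < config.p_del_subtel:
                    codes[chrom][s - 1 : e] = _random_background(
                        rng, e - s + 1, config.genome_gc
                    )
                else:
                    surviving[a_idx] = True
        for chrom in chrom_ids:
            mask = rng.random(L) < config.substitution_rate
            n_sub = int(mask.sum())
            if n_sub:
                shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
                codes[chrom][mask] = (codes[chrom][mask] + shift) % 4
        presence[:, s_idx] = surviving
        strains.append(
            GenomeAssembly(
                strain_id=strain_ids[s_idx],
                chromosomes={c: _decode(codes[c]) for c in chrom_ids},
            )
        )

    # --- timing, expression, essential genes, metadata ------------------------
    cons_frac = presence.mean(axis=1)
    timing = (
        config.timing_t0
        - config.timing_slope_b * cons_frac
        + rng.normal(0.0, config.timing_noise_sd, size=len(ars_df))
    )
    timing_df = pd.DataFrame({"ars_id": ars_df.ars_id, "trep_minutes": timing})

    expr_mean = np.where(
        genes_df.relation == "intersected",
        config.expression_mean_intersected,
        config.expression_mean_intergenic,
    )
    expression_values = rng.normal(expr_mean, config.expression_sd)
    genes_df["expression"] = expression_values
    n_ess = int(round(config.frac_essential_genes * len(genes_df)))
    ess_idx = set(rng.choice(len(genes_df), size=n_ess, replace=False).tolist())
    genes_df["essential"] = [i in ess_idx for i in range(len(genes_df))]

    metadata = pd.DataFrame(
        {
            "strain_id": strain_ids,
            "niche": [config.niches[int(rng.integers(len(config.niches)))] for _ in strain_ids],
        }
    )

    expected = expected_conservation(config, ars_df, loci_per_ars)
    truth = PanelTruth(
        ars=ars_df,
        presence=pd.DataFrame(presence, index=ars_df.ars_id, columns=strain_ids),
        genes=genes_df,
        timing=timing_df,
        strain_metadata=metadata,
        duplicate_loci=duplicate_loci,
        expected_presence=expected,
    )
    return Panel(
        config=config,
        reference=reference,
        strains=strains,
        dataset=dataset,
        genes=gene_features,
        truth=truth,
        essential_genes=genes_df[genes_df.essential].gene_id.tolist(),
        expression=dict(zip(genes_df.gene_id, genes_df.expression)),
    )


def expected_conservation(
    config: PanelConfig,
    ars_table: pd.DataFrame,
    loci_per_ars: dict[str, list[float]] | None = None,
) -> pd.DataFrame:
    """Analytic expected presence fraction per origin.

    A locus is detectable when it was not deleted and substitutions left its
    identity at or above 90%: the identity term is the binomial probability
    that at most floor(0.1*L) of L bases mutated.  An origin with several
    loci (subtelomeric duplicates) is present when any locus is detectable.
    """
    rows = []
    for r in ars_table.itertuples():
        L = int(r.length)
        p_identity = float(binom.cdf(L // 10, L, config.substitution_rate))
        if loci_per_ars and r.ars_id in loci_per_ars:
            p_dels = loci_per_ars[r.ars_id]
        else:
            p_dels = [config.p_del_subtel if r.subtelomeric else config.p_del_internal]
        p_absent = 1.0
        for p_del in p_dels:
            p_absent *= 1.0 - (1.0 - p_del) * p_identity
        rows.append({"ars_id": r.ars_id, "expected_fraction": 1.0 - p_absent})
    return pd.DataFrame(rows)


def write_panel(panel: Panel, out_dir: str | Path) -> Path:
    """Write the panel to disk: FASTAs, GFF3s, truth TSVs and a config echo."""
    out = Path(out_dir)
    (out / "strains").mkdir(parents=True, exist_ok=True)
    write_fasta(panel.reference, out / "reference.fa")
    for strain in panel.strains:
        write_fasta(strain, out / "strains" / f"{strain.strain_id}.fa")
    write_gff3(panel.genes, out / "genes.gff3")
    write_gff3(panel.dataset.to_features(), out / "ars_truth.gff3")
    write_tsv(panel.truth.ars, out / "ars_truth.tsv")
    write_tsv(panel.truth.presence.reset_index(), out / "presence_truth.tsv")
    write_tsv(panel.truth.genes, out / "genes_truth.tsv")
    write_tsv(panel.truth.timing, out / "timing.tsv")
    write_tsv(panel.truth.strain_metadata, out / "strain_metadata.tsv")
    write_tsv(panel.truth.expected_presence, out / "expected_presence.tsv")
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(panel.config), fh, indent=2, default=list)
    return out
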