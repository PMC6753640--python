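"""Conservation of origins across a strain panel.

Builds the binary origin x strain presence matrix (optionally restricted to
hits on the chromosome corresponding to each origin's reference chromosome,
with duplicate loci of non-unique origins also honoured), classifies origins
as conserved when present in strictly more than 90% of strains, computes
pan/core accumulation curves over random strain orderings, tests the
subtelomeric deficit of homologs, correlates conservation with replication
timing, and summarizes per-strain homolog counts by metadata group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import stats as _stats
from .ars_dataset import ARSDataset
from .context import PositionalContext
from .formats_io import apply_alias
from .homology import HomologyHit


@dataclass
class PresenceMatrix:
    """Binary origin x strain presence table."""

    ars_ids: list[str]
    strain_ids: list[str]
    cells: np.ndarray  # shape (n_ars, n_strains), dtype bool/int

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells).astype(np.int8)
        if self.cells.shape != (len(self.ars_ids), len(self.strain_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def homolog_counts(self) -> dict[str, int]:
        sums = self.cells.sum(axis=1)
        return {a: int(s) for a, s in zip(self.ars_ids, sums)}

    @property
    def strain_totals(self) -> dict[str, int]:
        sums = self.cells.sum(axis=0)
        return {s: int(t) for s, t in zip(self.strain_ids, sums)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.ars_ids, columns=self.strain_ids)


@dataclass
class ConservationCall:
    ars_id: str
    homolog_count: int
    fraction: float
    cls: str  # conserved | non_conserved


@dataclass
class PanCoreCurves:
    n_strains: int
    pan_sizes: np.ndarray  # (n_permutations, n_strains)
    core_sizes: np.ndarray
    n_permutations: int
    seed: int
    fit_params: dict = field(default_factory=dict)

    @property
    def pan_median(self) -> np.ndarray:
        return np.median(self.pan_sizes, axis=0)

    @property
    def core_median(self) -> np.ndarray:
        return np.median(self.core_sizes, axis=0)


def build_presence_matrix(
    hits: Sequence[HomologyHit],
    dataset: ARSDataset,
    strain_ids: Sequence[str],
    chrom_alias: Mapping[str, Mapping[str, str]] | None = None,
    restrict_to_corresponding_chrom: bool = True,
    duplicate_loci: Mapping[str, Iterable[str]] | None = None,
) -> PresenceMatrix:
    """Reduce filtered homology hits to a binary presence matrix.

    With the chromosome-correspondence restriction on, a hit counts only
    when its strain chromosome (through the per-strain alias table, identity
    by default) matches the origin's reference chromosome — or, for known
    multi-locus origins, any chromosome in ``duplicate_loci[ars_id]``.
    """
    allowed: dict[str, set[str]] = {
        rec.ars_id: {rec.chrom} for rec in dataset.records
    }
    if duplicate_loci:
        for ars_id, chroms in duplicate_loci.items():
            if ars_id in allowed:
                allowed[ars_id].update(chroms)
    ars_index = {rec.ars_id: i for i, rec in enumerate(dataset.records)}
    strain_index = {s: j for j, s in enumerate(strain_ids)}
    cells = np.zeros((len(ars_index), len(strain_index)), dtype=np.int8)
    unresolved: set[str] = set()
    for hit in hits:
        if hit.ars_id not in ars_index or hit.strain_id not in strain_index:
            continue
        if restrict_to_corresponding_chrom:
            alias = (chrom_alias or {}).get(hit.strain_id)
            ref_chrom = apply_alias(hit.subject_chrom, alias)
            if chrom_alias is not None and alias is not None and hit.subject_chrom not in alias:
                unresolved.add(f"{hit.strain_id}:{hit.subject_chrom}")
                continue
            if ref_chrom not in allowed[hit.ars_id]:
                continue
        cells[ars_index[hit.ars_id], strain_index[hit.strain_id]] = 1
    if unresolved:
        raise ValueError(
            f"strain chromosomes with no alias under restriction: {sorted(unresolved)}"
        )
    return PresenceMatrix(
        ars_ids=[r.ars_id for r in dataset.records],
        strain_ids=list(strain_ids),
        cells=cells,
    )


def classify_conservation(
    matrix: PresenceMatrix, threshold_fraction: float = 0.90
) -> list[ConservationCall]:
    """Conserved = present in strictly more than ``threshold_fraction`` of strains.

    With 104 strains the strict >90% rule puts the boundary at 94 strains.
    """
    n = matrix.n_strains
    if n < 1:
        raise ValueError("empty strain panel")
    calls = []
    for ars_id, count in matrix.homolog_counts.items():
        calls.append(
            ConservationCall(
                ars_id=ars_id,
                homolog_count=count,
                fraction=count / n,
                cls="conserved" if count > threshold_fraction * n else "non_conserved",
            )
        )
    return calls


def core_ars_set(matrix: PresenceMatrix) -> list[str]:
    """Origins present in every strain of the panel."""
    n = matrix.n_strains
    return [a for a, c in matrix.homolog_counts.items() if c == n]


def accumulate_pan_core(
    matrix: PresenceMatrix, order: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pan/core sizes along one strain ordering.

    pan[k] = |union of origin sets of the first k+1 strains|,
    core[k] = |their intersection|.
    """
    cells = matrix.cells.astype(bool)
    n_ars = cells.shape[0]
    pan = np.zeros(len(order), dtype=np.int64)
    core = np.zeros(len(order), dtype=np.int64)
    union = np.zeros(n_ars, dtype=bool)
    inter = np.ones(n_ars, dtype=bool)
    for i, s in enumerate(order):
        union |= cells[:, s]
        inter &= cells[:, s]
        pan[i] = union.sum()
        core[i] = inter.sum()
    return pan, core


def _heaps(n, kappa, gamma):
    return kappa * n**gamma


def _exp_decay(n, a, b, c):
    return a * np.exp(-b * n) + c


def pan_core_curves(
    matrix: PresenceMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    fit: bool = False,
) -> PanCoreCurves:
    """Pan (union) and core (intersection) origin counts over strain orderings.

    For each random permutation of strains and each prefix size n, pan(n) is
    the union of origin repertoires of the first n strains and core(n) their
    intersection.  Optional diagnostics fit Heaps' law kappa*n^gamma to the
    median pan curve and an exponential decay A*exp(-B*n)+C to the median
    core curve.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    n_strains = matrix.n_strains
    pan = np.zeros((n_permutations, n_strains), dtype=np.int64)
    core = np.zeros((n_permutations, n_strains), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(n_strains)
        pan[p], core[p] = accumulate_pan_core(matrix, order)
    curves = PanCoreCurves(
        n_strains=n_strains,
        pan_sizes=pan,
        core_sizes=core,
        n_permutations=n_permutations,
        seed=seed,
    )
    if fit and n_strains >= 3:
        import warnings

        ns = np.arange(1, n_strains + 1, dtype=float)
        with warnings.catch_warnings():
            # flat curves make the fits degenerate; they are diagnostics only
            warnings.simplefilter("ignore")
            try:
                (kappa, gamma), _ = curve_fit(
                    _heaps, ns, curves.pan_median,
                    p0=(curves.pan_median[0], 0.1), maxfev=5000,
                )
                curves.fit_params["pan"] = {"kappa": float(kappa), "gamma": float(gamma)}
            except RuntimeError:
                pass
            try:
                cm = curves.core_median
                (a, b, c), _ = curve_fit(
                    _exp_decay, ns, cm,
                    p0=(max(cm[0] - cm[-1], 1.0), 0.5, cm[-1]), maxfev=5000,
                )
                curves.fit_params["core"] = {"A": float(a), "B": float(b), "C": float(c)}
            except RuntimeError:
                pass
    return curves


def subtelomere_bias_test(
    calls: Sequence[ConservationCall],
    contexts: Sequence[PositionalContext],
) -> dict:
    """Do subtelomeric origins have fewer homologs than internal ones?

    One-sided Mann-Whitney U (alternative: subtelomeric counts are lower);
    also reports the non-conserved fraction among subtelomeric origins.
    """
    subtel_ids = {c.ars_id for c in contexts if c.subtelomeric}
    known_ids = {c.ars_id for c in contexts}
    missing = [c.ars_id for c in calls if c.ars_id not in known_ids]
    if missing:
        raise ValueError(f"origins without positional context: {missing}")
    subtel = [c.homolog_count for c in calls if c.ars_id in subtel_ids]
    internal = [c.homolog_count for c in calls if c.ars_id not in subtel_ids]
    if not subtel or not internal:
        raise ValueError("need both subtelomeric and internal origins")
    report = _stats.mann_whitney_u(subtel, internal, alternative="less")
    subtel_calls = [c for c in calls if c.ars_id in subtel_ids]
    frac_nc = sum(1 for c in subtel_calls if c.cls == "non_conserved") / len(subtel_calls)
    return {
        "test": report.as_dict(),
        "n_subtelomeric": len(subtel),
        "n_internal": len(internal),
        "subtelomeric_nonconserved_fraction": frac_nc,
    }


def timing_correlation(
    calls: Sequence[ConservationCall],
    timing: Mapping[str, float],
    earlier_is_smaller: bool = True,
) -> dict:
    """Pearson correlation of homolog count with replication timing.

    Timing values (Trep; smaller = earlier unless flipped) are joined on
    origin id.  Also compares timing between conservation classes with a
    two-sided rank-sum test.
    """
    joined = [(c.homolog_count, timing[c.ars_id], c.cls) for c in calls if c.ars_id in timing]
    if len(joined) < 3:
        raise ValueError("fewer than 3 origins with timing values")
    sign = 1.0 if earlier_is_smaller else -1.0
    counts = [j[0] for j in joined]
    times = [sign * j[1] for j in joined]
    r, p = _stats.pearson(counts, times)
    cons = [sign * t for _, t, cls in joined if cls == "conserved"]
    non = [sign * t for _, t, cls in joined if cls == "non_conserved"]
    class_test = None
    if cons and non:
        class_test = _stats.mann_whitney_u(cons, non, alternative="two-sided").as_dict()
    return {
        "pearson_r": r,
        "p_value": p,
        "n": len(joined),
        "class_comparison": class_test,
    }


def summarize_by_group(
    matrix: PresenceMatrix,
    strain_metadata: pd.DataFrame,
    group_key: str,
) -> pd.DataFrame:
    """Per-group distribution of per-strain total homolog counts.

    ``strain_metadata`` needs a ``strain_id`` column plus the grouping
    column; strains missing from the table fall into ``unknown``.
    """
    if group_key not in strain_metadata.columns:
        raise ValueError(f"unknown group key {group_key!r}")
    meta = strain_metadata.set_index("strain_id")[group_key].to_dict()
    totals = matrix.strain_totals
    df = pd.DataFrame(
        {
            "strain_id": list(totals),
            "total_homologs": list(totals.values()),
            "group": [str(meta.get(s, "unknown")) for s in totals],
        }
    )
    out = df.groupby("group")["total_homologs"].agg(
        n="count",
        mean="mean",
        median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
    )
    return out
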