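import numpy as np
import pytest

from ori_panscan.context import (
    adjacent_genes,
    ars_feature_table,
    conserved_adjacent_genes,
    contexts_for_dataset,
    flag_subtelomeric,
    join_annotations,
    overlap_segments,
)
from ori_panscan.formats_io import FeatureRecord, GenomeAssembly


def _feat(fid, start, end, chrom="c", ftype="gene"):
    return FeatureRecord(feature_id=fid, chrom=chrom, start=start, end=end,
                         feature_type=ftype)


class TestFlagSubtelomeric:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (19_999, 20_050, True),    # starts inside the left window
            (20_001, 79_999, False),   # clear of both windows
            (50_000, 80_000, False),   # end == L - w: outside by the rule
            (50_000, 80_001, True),    # end == L - w + 1: inside
            (1, 100, True),
        ],
    )
    def test_window_boundaries(self, start, end, expected):
        assert flag_subtelomeric(start, end, 100_000, 20_000) is expected


class TestAdjacentGenes:
    def test_intergenic_with_gaps(self):
        ctx = adjacent_genes(
            _feat("a", 100, 200, ftype="ARS"),
            [_feat("g1", 10, 50), _feat("g2", 300, 400)],
        )
        assert ctx.cls == "intergenic"
        assert (ctx.left_gene, ctx.left_distance) == ("g1", 49)
        assert (ctx.right_gene, ctx.right_distance) == ("g2", 99)

    def test_intersected_overlap_arithmetic(self):
        ctx = adjacent_genes(_feat("a", 100, 200, ftype="ARS"), [_feat("g", 150, 400)])
        assert ctx.cls == "intersected"
        (gene_id, ov, frac) = ctx.overlap_genes[0]
        assert (gene_id, ov) == ("g", 51)
        assert frac == pytest.approx(51 / 101)

    def test_missing_neighbors_are_none(self):
        ctx = adjacent_genes(_feat("a", 100, 200, ftype="ARS"), [])
        assert ctx.left_gene is None and ctx.right_gene is None
        assert ctx.cls == "intergenic"

    def test_gap_tie_broken_toward_smaller_start(self):
        # two genes ending at the same distance to the left of the origin
        ctx = adjacent_genes(
            _feat("a", 100, 200, ftype="ARS"),
            [_feat("g_far", 5, 50), _feat("g_near", 30, 50)],
        )
        assert ctx.left_gene == "g_far"
        assert ctx.tied_neighbors == ["g_near"]

    def test_matches_brute_force_on_random_layouts(self, rng):
        # oracle: direct scan over all genes with explicit gap/overlap math
        for _ in range(1000):
            a_start = int(rng.integers(1, 5000))
            a_end = a_start + int(rng.integers(0, 400))
            ars = _feat("a", a_start, a_end, ftype="ARS")
            genes = []
            for i in range(int(rng.integers(0, 8))):
                g_start = int(rng.integers(1, 6000))
                genes.append(_feat(f"g{i}", g_start, g_start + int(rng.integers(0, 800))))
            ctx = adjacent_genes(ars, genes)

            ov_expected = set()
            left, right = None, None
            for g in genes:
                ov = min(a_end, g.end) - max(a_start, g.start) + 1
                if ov > 0:
                    ov_expected.add((g.feature_id, ov))
                    assert ov <= min(a_end - a_start + 1, g.end - g.start + 1)
                elif g.end < a_start:
                    gap = a_start - g.end - 1
                    if left is None or (gap, g.start) < left[:2]:
                        left = (gap, g.start, g.feature_id)
                elif g.start > a_end:
                    gap = g.start - a_end - 1
                    if right is None or (gap, g.start) < right[:2]:
                        right = (gap, g.start, g.feature_id)
            assert {(g, o) for g, o, _ in ctx.overlap_genes} == ov_expected
            assert ctx.left_gene == (left[2] if left else None)
            assert ctx.right_gene == (right[2] if right else None)
            if left:
                assert ctx.left_distance == left[0] >= 0
            if right:
                assert ctx.right_distance == right[0] >= 0
            assert (ctx.cls == "intersected") == bool(ov_expected)


class TestOverlapSegments:
    def _setup(self):
        seq = "A" * 149 + "C" * 51 + "G" * 300
        ref = GenomeAssembly("ref", {"c": seq})
        genes = [_feat("g", 150, 400)]
        contexts = contexts_for_dataset(
            [_feat("a", 100, 200, ftype="ARS")], genes, ref.lengths
        )
        return contexts, {g.feature_id: g for g in genes}, ref

    def test_segment_interval_and_sequence(self):
        contexts, genes_by_id, ref = self._setup()
        (seg,) = overlap_segments(contexts, genes_by_id, ref)
        assert (seg["start"], seg["end"], seg["length"]) == (150, 200, 51)
        assert seg["sequence"] == "C" * 51

    def test_intergenic_origin_gives_no_segments(self):
        ref = GenomeAssembly("ref", {"c": "ACGT" * 200})
        contexts = contexts_for_dataset(
            [_feat("a", 100, 200, ftype="ARS")], [_feat("g", 400, 500)], ref.lengths
        )
        assert overlap_segments(contexts, {"g": _feat("g", 400, 500)}, ref) == []

    def test_origin_inside_gene_fraction_one(self):
        ref = GenomeAssembly("ref", {"c": "ACGT" * 200})
        genes = [_feat("g", 50, 700)]
        contexts = contexts_for_dataset(
            [_feat("a", 100, 200, ftype="ARS")], genes, ref.lengths
        )
        assert contexts[0].overlap_genes[0][2] == pytest.approx(1.0)
        (seg,) = overlap_segments(contexts, {"g": genes[0]}, ref)
        assert (seg["start"], seg["end"]) == (100, 200)


class TestConservedAdjacentGenes:
    def _contexts(self, left="g1", right="g2"):
        from ori_panscan.context import PositionalContext

        return [
            PositionalContext(
                ars_id="a1", chrom="c", start=100, end=200, subtelomeric=False,
                left_gene=left, right_gene=right, left_distance=10, right_distance=10,
            )
        ]

    def test_strict_ninety_percent_boundary(self):
        per_strain = {f"s{i}": self._contexts() for i in range(104)}
        # remove adjacency from 10 strains -> 94/104 > 93.6 still conserved
        for i in range(10):
            per_strain[f"s{i}"] = []
        calls = conserved_adjacent_genes(per_strain)
        assert all(c.cls == "conserved" and c.n_strains_adjacent == 94 for c in calls)

    def test_single_strain_adjacency_non_conserved(self):
        per_strain = {f"s{i}": (self._contexts() if i == 0 else []) for i in range(104)}
        calls = conserved_adjacent_genes(per_strain)
        assert all(c.cls == "non_conserved" for c in calls)

    def test_ortholog_map_translates_ids(self):
        per_strain = {"s0": self._contexts(left="strain_gene")}
        calls = conserved_adjacent_genes(
            per_strain, ortholog_map={"s0": {"strain_gene": "ref_gene", "g2": "g2"}}
        )
        assert {c.gene_id for c in calls} == {"ref_gene", "g2"}

    def test_unmapped_gene_counts_as_absent(self):
        per_strain = {"s0": self._contexts(left="mystery")}
        calls = conserved_adjacent_genes(per_strain, ortholog_map={"s0": {"g2": "g2"}})
        assert {c.gene_id for c in calls} == {"g2"}


class TestJoinAnnotations:
    def test_essential_overlap_counted(self):
        from ori_panscan.context import PositionalContext

        contexts = [
            PositionalContext(
                ars_id="a1", chrom="c", start=1, end=100, subtelomeric=False,
                overlap_genes=[("g1", 50, 0.5), ("g2", 20, 0.2)],
            )
        ]
        out = join_annotations(contexts, essential=["g1"])
        assert out["essential_overlap_pairs"] == [("a1", "g1")]
        assert out["n_intersected_with_essential"] == 1

    def test_planted_expression_difference_detected(self, rng):
        from ori_panscan.context import PositionalContext

        contexts, expression = [], {}
        for i in range(30):
            gid = f"gi{i}"
            expression[gid] = float(rng.normal(10, 1))
            contexts.append(PositionalContext(
                ars_id=f"ig{i}", chrom="c", start=1, end=100, subtelomeric=False,
                left_gene=gid, left_distance=5,
            ))
        for i in range(30):
            gid = f"gx{i}"
            expression[gid] = float(rng.normal(7, 1))
            contexts.append(PositionalContext(
                ars_id=f"ix{i}", chrom="c", start=1, end=100, subtelomeric=False,
                overlap_genes=[(gid, 50, 0.5)],
            ))
        out = join_annotations(contexts, expression=expression)
        assert out["expression_comparison"]["p_value"] < 0.05
        assert out["expression_comparison"]["alternative"] == "less"

    def test_missing_expression_skips_comparison(self):
        from ori_panscan.context import PositionalContext

        contexts = [PositionalContext(
            ars_id="a", chrom="c", start=1, end=10, subtelomeric=False
        )]
        out = join_annotations(contexts)
        assert out["expression_comparison"] is None


class TestFeatureTable:
    def test_shape_and_relative_position(self, small_panel):
        from ori_panscan import conservation as cons
        from ori_panscan import context as ctx_mod

        panel = small_panel
        contexts = ctx_mod.contexts_for_dataset(
            panel.dataset.to_features(), panel.genes, panel.reference.lengths
        )
        timing = dict(zip(panel.truth.timing.ars_id, panel.truth.timing.trep_minutes))
        counts = {r.ars_id: 3 for r in panel.dataset.records}
        table = ars_feature_table(
            panel.dataset, contexts, homolog_counts=counts, timing=timing,
            expression=panel.expression, chrom_lengths=panel.reference.lengths,
        )
        assert table.shape[1] == 7
        assert ((table.relative_position >= 0) & (table.relative_position <= 1)).all()

    def test_drop_policy_removes_incomplete_rows(self, small_panel):
        panel = small_panel
        from ori_panscan import context as ctx_mod

        contexts = ctx_mod.contexts_for_dataset(
            panel.dataset.to_features(), panel.genes, panel.reference.lengths
        )
        timing = dict(zip(panel.truth.timing.ars_id, panel.truth.timing.trep_minutes))
        incomplete_timing = dict(list(timing.items())[1:])  # drop one origin
        full = ars_feature_table(
            panel.dataset, contexts, {r.ars_id: 1 for r in panel.dataset.records},
            timing, panel.expression, panel.reference.lengths,
        )
        reduced = ars_feature_table(
            panel.dataset, contexts, {r.ars_id: 1 for r in panel.dataset.records},
            incomplete_timing, panel.expression, panel.reference.lengths,
        )
        assert len(reduced) == len(full) - 1
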