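"""Representative selection, contrasts, diagnostics, chimeras and overlap
trimming."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claderates.sister_contrasts import (
    CladeRecord,
    ContrastRow,
    GeneInterval,
    assemble_representative,
    count_internal_nodes,
    garland_diagnostic,
    make_contrast,
    select_representative,
    trim_overlaps,
)


def tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def caterpillar(n: int) -> dendropy.Tree:
    nwk = "t1"
    for i in range(2, n + 1):
        nwk = f"({nwk},t{i})"
    return tree(nwk + ";")


class TestNodeCounting:
    def test_two_tip_clade_is_zero(self):
        t = tree("(a,b);")
        assert count_internal_nodes(t, "a") == 0
        assert count_internal_nodes(t, "b") == 0

    def test_speciose_clade_candidates(self):
        # a ladder where tip "deep" sits behind 6 intervening nodes and
        # "shallow" behind 3, as in the selection rule's worked example
        nwk = "(((((((deep,x1),x2),x3),x4),x5),x6),(((shallow,y1),y2),y3));"
        t = tree(nwk)
        assert count_internal_nodes(t, "deep") == 6
        assert count_internal_nodes(t, "shallow") == 3

    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_caterpillar_deepest_tip(self, n):
        assert count_internal_nodes(caterpillar(n), "t1") == n - 2

    def test_absent_tip_raises(self):
        with pytest.raises(KeyError):
            count_internal_nodes(tree("(a,b);"), "zzz")


class TestSelectRepresentative:
    def make_clade(self, nwk, with_data):
        t = tree(nwk)
        return CladeRecord("c", 10, t, set(with_data))

    def test_more_speciose_takes_deepest(self):
        nwk = "(((((((deep,x1),x2),x3),x4),x5),x6),(((shallow,y1),y2),y3));"
        clade = self.make_clade(nwk, {"deep", "shallow"})
        assert select_representative(clade, "more_speciose") == "deep"
        assert select_representative(clade, "less_speciose") == "shallow"

    def test_single_candidate_any_role(self):
        clade = self.make_clade("((a,b),c);", {"b"})
        assert select_representative(clade, "more_speciose") == "b"
        assert select_representative(clade, "less_speciose") == "b"

    def test_tie_breaks_lexicographically(self):
        clade = self.make_clade("((b,a),(d,c));", {"a", "b", "c", "d"})
        assert select_representative(clade, "more_speciose") == "a"
        assert select_representative(clade, "less_speciose") == "a"

    def test_no_data_raises(self):
        clade = self.make_clade("(a,b);", set())
        with pytest.raises(ValueError):
            select_representative(clade, "more_speciose")

    def test_unknown_role_rejected(self):
        clade = self.make_clade("(a,b);", {"a"})
        with pytest.raises(ValueError):
            select_representative(clade, "median")


class TestMakeContrast:
    def test_worked_arithmetic(self):
        row = make_contrast(2.0, 1.0, 0.5, 0.5, "T")
        assert row.raw == pytest.approx(math.log(2), abs=1e-4)
        assert row.weight == pytest.approx(1.0)
        assert row.standardized == pytest.approx(math.log(2), abs=1e-4)
        assert row.included

    def test_equal_values_give_zero(self):
        row = make_contrast(0.37, 0.37, 0.2, 0.3, "dN")
        assert row.raw == 0.0 and row.standardized == 0.0

    @pytest.mark.parametrize("va, vb, ta, tb", [(2.0, 0.5, 0.1, 0.3), (5.0, 4.0, 1.0, 0.2)])
    def test_antisymmetric_under_swap(self, va, vb, ta, tb):
        fwd = make_contrast(va, vb, ta, tb, "T")
        rev = make_contrast(vb, va, tb, ta, "T")
        assert fwd.raw == pytest.approx(-rev.raw)
        assert fwd.standardized == pytest.approx(-rev.standardized)

    def test_standardization_preserves_sign(self):
        row = make_contrast(3.0, 1.0, 0.4, 0.1, "dS")
        assert math.copysign(1, row.raw) == math.copysign(1, row.standardized)

    def test_nonpositive_value_excluded_as_missing(self):
        row = make_contrast(0.0, 1.0, 0.1, 0.1, "omega")
        assert not row.included and row.reason == "missing"


def rows_from(std, weights):
    return [
        ContrastRow(f"p{i}", "T", s * w, w, s, True)
        for i, (s, w) in enumerate(zip(std, weights))
    ]


class TestGarlandDiagnostic:
    def test_magnitude_proportional_to_weight_fails(self):
        weights = np.linspace(0.2, 2.0, 12)
        std = 3.0 * weights * np.resize([1, -1], 12)
        res = garland_diagnostic(rows_from(std, weights))
        assert not res.passed and res.p_value < 0.05

    def test_equal_weights_pass_trivially(self):
        res = garland_diagnostic(rows_from(np.r_[1, -2, 0.5, 1.5, -1.0], np.ones(5)))
        assert res.passed and res.slope == 0.0

    def test_well_standardized_contrasts_usually_pass(self):
        rng = np.random.default_rng(7)
        passes = 0
        n_sim = 200
        for _ in range(n_sim):
            w = rng.uniform(0.2, 2.0, 15)
            std = rng.normal(size=15)
            if garland_diagnostic(rows_from(std, w)).passed:
                passes += 1
        assert passes / n_sim > 0.85

    def test_requires_five_rows(self):
        with pytest.raises(ValueError):
            garland_diagnostic(rows_from([1.0, 2.0], [1.0, 1.0]))


class TestAssembleRepresentative:
    def test_single_species_equals_concatenation(self):
        genes = {"g1": ("sp1", "ATGAAA"), "g2": ("sp1", "CCCGGG")}
        chim = assemble_representative(genes, ["g1", "g2"])
        assert chim.sequence == "ATGAAACCCGGG"

    def test_boundary_recorded_at_codon_101(self):
        genes = {"g1": ("sp1", "A" * 300), "g2": ("sp2", "C" * 600)}
        chim = assemble_representative(genes, ["g1", "g2"])
        assert len(chim.sequence) == 900
        assert chim.provenance == [("g1", "sp1", 1, 100), ("g2", "sp2", 101, 300)]

    def test_mapping_order_irrelevant(self):
        g1 = {"a": ("s1", "ATGATG"), "b": ("s2", "CCC")}
        g2 = dict(reversed(list(g1.items())))
        assert (
            assemble_representative(g1, ["a", "b"]).sequence
            == assemble_representative(g2, ["a", "b"]).sequence
        )

    def test_missing_gene_and_frame_errors(self):
        with pytest.raises(ValueError, match="missing gene"):
            assemble_representative({"a": ("s", "ATG")}, ["a", "b"])
        with pytest.raises(ValueError, match="frame"):
            assemble_representative({"a": ("s", "ATGA")}, ["a"])


class TestTrimOverlaps:
    def test_non_overlapping_unchanged(self):
        ivs = [GeneInterval("g1", 1, 99), GeneInterval("g2", 100, 201)]
        out = trim_overlaps(ivs)
        assert [(o.start, o.end) for o in out] == [(1, 99), (100, 201)]

    def test_downstream_trimmed_to_codon_boundary(self):
        ivs = [GeneInterval("up", 1, 100), GeneInterval("down", 91, 201)]
        out = trim_overlaps(ivs, [("up", "down")])
        down = out[1]
        # first codon-complete start past the overlap, in down's own frame
        assert down.start == 103
        assert down.start > 100
        assert (down.start - 91) % 3 == 0

    def test_unresolvable_overlap_flagged(self):
        ivs = [GeneInterval("up", 1, 100), GeneInterval("down", 96, 101)]
        out = trim_overlaps(ivs, [("up", "down")])
        assert out[1].flagged

    @given(st.lists(st.tuples(st.integers(2, 60), st.integers(0, 12)), min_size=2, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_no_output_intervals_intersect(self, layout):
        """Random chains of codon-complete genes with random overlaps come out
        pairwise disjoint (interval-arithmetic oracle)."""
        ivs = []
        pos = 1
        for i, (n_codons, overlap) in enumerate(layout):
            start = max(1, pos - overlap)
            end = start + 3 * n_codons - 1
            ivs.append(GeneInterval(f"g{i}", start, end))
            pos = end + 1
        pairs = [
            (a.gene, b.gene) for a, b in zip(ivs, ivs[1:]) if b.start <= a.end
        ]
        out = {o.gene: o for o in trim_overlaps(ivs, pairs)}
        orig = {iv.gene: iv for iv in ivs}
        for up_name, down_name in pairs:
            up, down = out[up_name], out[down_name]
            if up.flagged or down.flagged:
                continue
            assert up.end < down.start or down.end < up.start
        for o in out.values():
            if not o.flagged:
                assert o.start >= orig[o.gene].start and o.end == orig[o.gene].end
                assert (o.start - orig[o.gene].start) % 3 == 0
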