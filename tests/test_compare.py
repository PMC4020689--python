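"""Renkonen similarity, chord distance, Ward clustering, ranks and IRC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radshift import (
    chord_distance,
    irc,
    pair_merges_first,
    rank_species,
    renkonen,
    turnover,
    ward_cluster,
)
from tests.conftest import make_sample

abundance_maps = st.dictionaries(
    st.sampled_from([f"sp{i}" for i in range(8)]),
    st.floats(min_value=0.01, max_value=50, allow_nan=False),
    min_size=1,
    max_size=8,
)


class TestRenkonen:
    def test_identity(self):
        a = make_sample({"x": 3.0, "y": 1.0})
        assert renkonen(a, a) == pytest.approx(1.0)

    def test_disjoint(self):
        assert renkonen(make_sample({"x": 2.0}), make_sample({"y": 5.0})) == 0.0

    def test_hand_computed(self):
        a = make_sample({"s1": 0.5, "s2": 0.5})
        b = make_sample({"s1": 0.25, "s2": 0.25, "s3": 0.5})
        assert renkonen(a, b) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            renkonen(make_sample({}), make_sample({"x": 1.0}))

    @given(a=abundance_maps, b=abundance_maps)
    @settings(max_examples=60, derandomize=True)
    def test_symmetric_and_bounded(self, a, b):
        sa, sb = make_sample(a), make_sample(b)
        v = renkonen(sa, sb)
        assert v == pytest.approx(renkonen(sb, sa))
        assert -1e-9 <= v <= 1 + 1e-9


class TestChordDistance:
    def test_scale_invariance(self):
        a = make_sample({"x": 1.0, "y": 2.0})
        b = make_sample({"x": 3.0, "y": 6.0})
        assert chord_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_maximum(self):
        assert chord_distance(
            make_sample({"x": 4.0}), make_sample({"y": 1.0})
        ) == pytest.approx(math.sqrt(2))

    def test_hand_computed(self):
        a, b = make_sample({"x": 3.0, "y": 4.0}), make_sample({"x": 4.0, "y": 3.0})
        assert chord_distance(a, b) == pytest.approx(0.28284, abs=1e-5)

    @given(a=abundance_maps, b=abundance_maps, c=abundance_maps)
    @settings(max_examples=60, derandomize=True)
    def test_triangle_inequality(self, a, b, c):
        sa, sb, sc = make_sample(a), make_sample(b), make_sample(c)
        assert chord_distance(sa, sc) <= (
            chord_distance(sa, sb) + chord_distance(sb, sc) + 1e-9
        )


class TestRanks:
    def test_descending_with_name_tie_break(self):
        s = make_sample({"a": 10.0, "b": 5.0, "c": 5.0})
        ranked = rank_species(s)
        assert ranked.ranks == {"a": 1, "b": 2, "c": 3}

    def test_absent_rank_is_s_plus_one(self):
        s = make_sample({"b": 7.0})
        ranked = rank_species(s, universe={"a", "b", "c"})
        assert ranked.ranks == {"b": 1, "a": 2, "c": 2}

    def test_scale_invariance(self):
        s1 = make_sample({"a": 1.0, "b": 3.0})
        s2 = make_sample({"a": 10.0, "b": 30.0})
        assert rank_species(s1).ranks == rank_species(s2).ranks

    def test_union_size_policy(self):
        s = make_sample({"b": 7.0})
        ranked = rank_species(
            s, universe={"a", "b", "c"}, absent_policy="union_size"
        )
        assert ranked.ranks["a"] == 3

    def test_universe_must_cover_sample(self):
        with pytest.raises(ValueError, match="universe"):
            rank_species(make_sample({"a": 1.0}), universe={"b"})


class TestIRC:
    def test_identity(self):
        a = make_sample({"x": 5.0, "y": 2.0})
        assert irc(a, a).value == 0.0

    def test_swap_of_two_ranks(self):
        a = make_sample({"p": 10.0, "q": 5.0, "r": 1.0})
        b = make_sample({"p": 5.0, "q": 10.0, "r": 1.0})
        res = irc(a, b)
        assert res.value == pytest.approx(2 / 3)
        assert res.shifts == {"p": 1, "q": 1, "r": 0}

    def test_absence_rule(self):
        a = make_sample({"sp1": 10.0, "sp2": 5.0})
        b = make_sample({"sp2": 8.0})
        res = irc(a, b)
        assert res.n_union == 2
        assert res.value == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            irc(make_sample({}), make_sample({"x": 1.0}))

    @given(a=abundance_maps, b=abundance_maps, scale=st.floats(0.1, 20))
    @settings(max_examples=80, derandomize=True)
    def test_symmetry_bounds_scale_invariance(self, a, b, scale):
        sa, sb = make_sample(a), make_sample(b)
        res = irc(sa, sb)
        assert res.value == pytest.approx(irc(sb, sa).value)
        assert 0 <= res.value <= res.n_union - 1 + 1e-9
        scaled = make_sample({k: v * scale for k, v in a.items()})
        assert irc(scaled, sb).value == pytest.approx(res.value)

    def test_relabeling_invariance(self):
        a = make_sample({"x": 9.0, "y": 4.0, "z": 1.0})
        b = make_sample({"x": 1.0, "z": 8.0})
        mapping = {"x": "u", "y": "v", "z": "w"}
        a2 = make_sample({mapping[k]: v for k, v in a.abundance.items()})
        b2 = make_sample({mapping[k]: v for k, v in b.abundance.items()})
        assert irc(a, b).value == pytest.approx(irc(a2, b2).value)


class TestTurnover:
    def test_set_arithmetic(self):
        a = make_sample({f"s{i}": 1.0 for i in range(5)})
        b = make_sample({f"s{i}": 1.0 for i in range(3, 9)})
        t = turnover(a, b)
        assert (t.s_before, t.s_now, t.shared) == (5, 6, 2)
        assert (t.only_before, t.only_now, t.union) == (3, 4, 9)
        assert t.union == t.s_before + t.s_now - t.shared

    def test_identity_and_disjoint(self):
        a = make_sample({"x": 1.0, "y": 2.0})
        t = turnover(a, a)
        assert t.shared == t.union == 2 and t.only_before == t.only_now == 0
        d = turnover(a, make_sample({"z": 1.0}))
        assert d.shared == 0 and d.union == 3


class TestWardCluster:
    def test_two_samples_merge_at_chord_distance(self):
        a = make_sample({"x": 3.0, "y": 4.0}, site="s1")
        b = make_sample({"x": 4.0, "y": 3.0}, site="s2")
        dendro = ward_cluster([a, b])
        assert dendro.linkage_matrix[0, 2] == pytest.approx(chord_distance(a, b))

    def test_identical_pairs_merge_first(self):
        s = [
            make_sample({"x": 1.0}, site="a", period="p1"),
            make_sample({"x": 2.0}, site="a", period="p2"),
            make_sample({"y": 1.0}, site="b", period="p1"),
            make_sample({"y": 3.0}, site="b", period="p2"),
        ]
        dendro = ward_cluster(s)
        assert dendro.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert dendro.linkage_matrix[1, 2] == pytest.approx(0.0)
        assert pair_merges_first(dendro, "a_p1", "a_p2")
        assert pair_merges_first(dendro, "b_p1", "b_p2")

    def test_duplicate_labels_rejected(self):
        a = make_sample({"x": 1.0})
        with pytest.raises(ValueError, match="duplicate"):
            ward_cluster([a, a])

    def test_newick_contains_all_leaves_balanced(self):
        s = [
            make_sample(
                {"x": 1.0, "y": 0.5, f"extra{i}_{p}": 0.1 * (i + 1)},
                site=f"s{i}",
                period=p,
            )
            for i in range(3)
            for p in ("1980", "2009")
        ]
        nwk = ward_cluster(s).to_newick()
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")") == len(s) - 1
        for sam in s:
            assert sam.label in nwk
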