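"""Trap pooling, aAD standardization, and delimited-text round trips."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radshift import community, io


def recs_six_traps(record_factory):
    return [
        record_factory(trap=f"t{j}", species="spA", count=2) for j in range(1, 7)
    ]


class TestPooling:
    def test_six_traps_one_interval(self, record_factory):
        pooled = community.pool_traps(recs_six_traps(record_factory))
        assert pooled.counts == {"spA": 12}
        assert pooled.n_traps == 6
        assert pooled.exposure_days == 30

    def test_three_consecutive_intervals(self, record_factory):
        month = date(1980, 7, 1) - date(1980, 6, 1)  # 30 days
        recs = []
        for i in range(3):
            start = date(1980, 6, 1) + month * i
            for sp, c in (("spA", 1), ("spB", 0)):
                recs.append(
                    record_factory(
                        interval_start=start,
                        interval_end=start + month,
                        species=sp,
                        count=c,
                    )
                )
        pooled = community.pool_traps(recs)
        assert pooled.counts["spA"] == 3
        assert pooled.exposure_days == 90

    def test_mixed_sites_rejected(self, record_factory):
        recs = [record_factory(site="s1"), record_factory(site="s2")]
        with pytest.raises(ValueError, match="multiple sites"):
            community.pool_traps(recs)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            community.pool_traps([])

    def test_duplicate_key_rejected(self, record_factory):
        recs = [record_factory(), record_factory()]
        with pytest.raises(ValueError, match="duplicate"):
            community.pool_traps(recs)

    def test_site_period_filter(self, record_factory):
        recs = [record_factory(site="s1"), record_factory(site="s2", count=5)]
        pooled = community.pool_traps(recs, site="s2")
        assert pooled.counts == {"spA": 5}


class TestAAD:
    def test_standard_formula(self):
        s = community.compute_aad({"spA": 120}, n_traps=6, exposure_days=100)
        assert s.abundance["spA"] == pytest.approx(2.0)

    def test_zero_count_dropped(self):
        s = community.compute_aad({"spA": 10, "spB": 0}, 6, 90)
        assert "spB" not in s.abundance
        assert "spB" not in s.raw_counts

    def test_derived_arithmetic(self):
        s = community.compute_aad({"spA": 90}, 6, 90)
        assert s.abundance["spA"] == pytest.approx(15 / 9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            community.compute_aad({"spA": -1}, 6, 90)

    def test_trap_days_override_matches_default_when_full(self):
        full = community.compute_aad({"spA": 60}, 3, 90)
        override = community.compute_aad(
            {"spA": 60}, 3, 90, trap_days={"t1": 90, "t2": 90, "t3": 90}
        )
        assert full.abundance == override.abundance

    def test_lost_trap_increases_aad(self):
        # one trap active only half the season: fewer trap-days, higher aAD
        partial = community.compute_aad(
            {"spA": 60}, 3, 90, trap_days={"t1": 90, "t2": 90, "t3": 45}
        )
        assert partial.abundance["spA"] > community.compute_aad(
            {"spA": 60}, 3, 90
        ).abundance["spA"]

    @given(
        counts=st.dictionaries(
            st.sampled_from(["a", "b", "c", "d"]),
            st.integers(min_value=0, max_value=500),
            min_size=1,
        ),
        n_traps=st.integers(min_value=1, max_value=8),
        days=st.integers(min_value=10, max_value=120),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linearity_and_total(self, counts, n_traps, days):
        s1 = community.compute_aad(counts, n_traps, days)
        s2 = community.compute_aad({k: 2 * v for k, v in counts.items()}, n_traps, days)
        for sp in s1.abundance:
            assert s2.abundance[sp] == pytest.approx(2 * s1.abundance[sp])
        assert s1.total_aad == pytest.approx(
            (sum(counts.values()) / n_traps) / (days / 10)
        )

    def test_split_interval_invariance(self, record_factory):
        whole = [
            record_factory(
                interval_start=date(1980, 6, 1),
                interval_end=date(1980, 8, 1),
                count=10,
            )
        ]
        split = [
            record_factory(
                interval_start=date(1980, 6, 1),
                interval_end=date(1980, 7, 1),
                count=4,
            ),
            record_factory(
                interval_start=date(1980, 7, 1),
                interval_end=date(1980, 8, 1),
                count=6,
            ),
        ]
        a = community.pooled_to_sample(community.pool_traps(whole))
        b = community.pooled_to_sample(community.pool_traps(split))
        assert a.abundance == b.abundance


class TestIO:
    def test_long_table_round_trip(self, tmp_path, record_factory):
        recs = [record_factory(species="spA"), record_factory(species="spB", count=3)]
        path = tmp_path / "catch.csv"
        io.write_long_table(recs, path)
        assert io.read_long_table(path) == recs

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "site,period,trap,interval_start,interval_end,species,cnt\n"
            "s1,1980,t1,1980-06-01,1980-07-01,spA,2\n"
        )
        with pytest.raises(ValueError, match="count"):
            io.read_long_table(path)

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "site,period,trap,interval_start,interval_end,species,count\n"
            "s1,1980,t1,1980-06-01,1980-07-01,spA,2.5\n"
        )
        with pytest.raises(ValueError, match="non-integer"):
            io.read_long_table(path)

    def test_trait_table_round_trip(self, tmp_path):
        traits = community.TraitTable(
            wing_morph={"spA": "macropterous", "spB": "brachypterous"},
            diet={"spA": "zoophytophagous", "spB": "specialized_predator"},
            thermal={"spA": "thermophilic"},
            moisture={"spB": "hygrophilic"},
        )
        path = tmp_path / "traits.csv"
        io.write_trait_table(traits, path)
        back = io.read_trait_table(path)
        assert back == traits

    def test_trait_table_bad_category(self, tmp_path):
        path = tmp_path / "traits.csv"
        path.write_text("species,wing_morph,diet\nspA,winged,generalist_predator\n")
        with pytest.raises(ValueError, match="winged"):
            io.read_trait_table(path)

    def test_community_matrix_round_trip(self, tmp_path, sample_factory):
        samples = [
            sample_factory({"a": 1.25, "b": 0.5}, site="s1", period="1980"),
            sample_factory({"b": 2.0}, site="s1", period="2009"),
            sample_factory({"a": 0.75, "c": 3.5}, site="s2", period="1980"),
        ]
        path = tmp_path / "matrix.csv"
        io.write_community_matrix(samples, path)
        back = io.read_community_matrix(path)
        for orig, rt in zip(samples, back):
            assert rt.label == orig.label
            assert rt.abundance == pytest.approx(orig.abundance)

    def test_missing_traits_reported(self):
        traits = community.TraitTable(
            wing_morph={"spA": "macropterous"}, diet={"spA": "generalist_predator"}
        )
        assert traits.missing_from(["spA", "spB", "spC"]) == ["spB", "spC"]
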