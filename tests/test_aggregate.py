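"""Supporting numbers, the frequency matrix and its orderings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exomir.aggregate import (
    frequency_matrix,
    kingdom_share,
    order_matrix,
    supporting_numbers,
    top_exo_mirnas,
)
from exomir.errors import ValidationError

from conftest import make_profile


class TestSupportingNumbers:
    def test_present_in_all_datasets(self):
        profiles = [
            make_profile(f"d{i}", {"osa-miR156a": 5}, study_id=f"s{i % 3}")
            for i in range(12)
        ]
        table = supporting_numbers(profiles)
        assert table["osa-miR156a"].supporting_number == 12
        assert table["osa-miR156a"].n_datasets_considered == 12
        assert table["osa-miR156a"].study_ids == frozenset({"s0", "s1", "s2"})

    def test_absent_mirna_not_in_table(self):
        table = supporting_numbers([make_profile("d1", {"osa-miR156a": 1})])
        assert "zma-miR168a" not in table

    def test_duplicate_dataset_id_rejected(self):
        p = make_profile("d1", {"osa-miR156a": 1})
        with pytest.raises(ValidationError, match="duplicate"):
            supporting_numbers([p, p])

    def test_min_count_threshold(self):
        profiles = [
            make_profile("d1", {"osa-miR156a": 1}),
            make_profile("d2", {"osa-miR156a": 10}),
        ]
        assert supporting_numbers(profiles)["osa-miR156a"].supporting_number == 2
        assert supporting_numbers(profiles, min_count=5)["osa-miR156a"].supporting_number == 1

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        presence=st.lists(
            st.sets(st.sampled_from(["osa-miR156a", "zma-miR168a", "ebv-miR-BART1-5p"])),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_brute_force_recount(self, presence):
        profiles = [
            make_profile(f"d{i}", {mid: 1 for mid in ids})
            for i, ids in enumerate(presence)
        ]
        table = supporting_numbers(profiles)
        for mid in {m for ids in presence for m in ids}:
            assert table[mid].supporting_number == sum(mid in ids for ids in presence)

    def test_monotone_under_appending(self):
        profiles = [
            make_profile("d1", {"osa-miR156a": 1}),
            make_profile("d2", {"osa-miR156a": 2, "zma-miR168a": 1}),
            make_profile("d3", {"zma-miR168a": 4}),
        ]
        prev = 0
        for i in range(1, 4):
            table = supporting_numbers(profiles[:i])
            cur = table["osa-miR156a"].supporting_number if "osa-miR156a" in table else 0
            assert cur >= prev
            prev = cur


class TestFrequencyMatrix:
    def test_single_dataset_reduces_to_rpm_times_1000(self):
        prof = make_profile("d1", {"osa-miR156a": 50}, total_reads=1_000_000)
        fm = frequency_matrix([prof])
        rpm = prof.hits[0].rpm
        assert fm.values.loc["osa", "miR156"] == pytest.approx(rpm * 1000, rel=1e-12)

    def test_additive_over_duplicated_dataset(self):
        p1 = make_profile("d1", {"osa-miR156a": 50}, total_reads=1_000_000)
        p2 = make_profile("d2", {"osa-miR156a": 50}, total_reads=1_000_000)
        one = frequency_matrix([p1])
        two = frequency_matrix([p1, p2])
        assert two.values.loc["osa", "miR156"] == pytest.approx(
            2 * one.values.loc["osa", "miR156"], rel=1e-12
        )

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(42)
        profiles = []
        mirnas = ["osa-miR156a", "osa-miR168a", "zma-miR168a", "ebv-miR-BART1-5p"]
        for i in range(5):
            counts = {m: int(rng.integers(1, 200)) for m in mirnas if rng.random() < 0.7}
            total = int(rng.integers(10_000, 1_000_000))
            if counts:
                profiles.append(make_profile(f"d{i}", counts, total_reads=total))
        fm = frequency_matrix(profiles)
        # brute-force recomputation straight from the formula
        expected: dict[tuple, float] = {}
        for p in profiles:
            for h in p.hits:
                key = (h.species_code, h.family_key)
                expected[key] = expected.get(key, 0.0) + h.count / p.total_reads * 1e9
        for (sp, fam), val in expected.items():
            assert fm.values.loc[sp, fam] == pytest.approx(val, rel=1e-9)
        assert float(fm.values.to_numpy().sum()) == pytest.approx(
            sum(expected.values()), rel=1e-9
        )

    def test_zero_cells_mean_no_hits(self):
        p = make_profile("d1", {"osa-miR156a": 5, "ebv-miR-BART1-5p": 2})
        fm = frequency_matrix([p])
        assert fm.values.loc["ebv", "miR156"] == 0.0
        assert (fm.values.to_numpy() >= 0).all()

    def test_profile_order_invariance(self):
        p1 = make_profile("d1", {"osa-miR156a": 50}, total_reads=100_000)
        p2 = make_profile("d2", {"zma-miR168a": 9}, total_reads=200_000)
        a = frequency_matrix([p1, p2]).values
        b = frequency_matrix([p2, p1]).values
        assert a.equals(b)

    def test_dedup_shared_splits_credit(self):
        p = make_profile("d1", {"osa-miR168a": 10, "zma-miR168a": 10}, total_reads=1_000_000)
        # mark the hits as shared between the two species
        from dataclasses import replace

        p.hits = [
            replace(h, shared_with=("zma",) if h.species_code == "osa" else ("osa",))
            for h in p.hits
        ]
        full = frequency_matrix([p])
        frac = frequency_matrix([p], dedup_shared=True)
        assert frac.values.loc["osa", "miR168"] == pytest.approx(
            full.values.loc["osa", "miR168"] / 2
        )

    def test_empty_selection_rejected(self):
        with pytest.raises(ValidationError):
            frequency_matrix([make_profile("d1", {"osa-miR156a": 1})], source_label="liver")


class TestOrderMatrix:
    @pytest.fixture()
    def matrix(self):
        p1 = make_profile("d1", {"zma-miR168a": 100, "osa-miR156a": 1})
        p2 = make_profile("d2", {"osa-miR156a": 2, "ebv-miR-BART1-5p": 500})
        return frequency_matrix([p1, p2])

    def test_by_species_lexicographic(self, matrix):
        out = order_matrix(matrix, "by_species")
        assert out.species == sorted(matrix.species)

    def test_by_mirna_lexicographic(self, matrix):
        out = order_matrix(matrix, "by_mirna")
        assert out.families == sorted(matrix.families)

    def test_by_frequency_dominant_first(self, matrix):
        out = order_matrix(matrix, "by_frequency")
        sums = out.values.sum(axis=1)
        assert list(sums) == sorted(sums, reverse=True)

    def test_values_permuted_not_changed(self, matrix):
        for mode in ("by_mirna", "by_species", "by_frequency"):
            out = order_matrix(matrix, mode)
            assert sorted(out.values.to_numpy().ravel()) == pytest.approx(
                sorted(matrix.values.to_numpy().ravel())
            )
            for sp in matrix.species:
                for fam in matrix.families:
                    assert out.values.loc[sp, fam] == matrix.values.loc[sp, fam]

    def test_unknown_mode(self, matrix):
        with pytest.raises(ValueError):
            order_matrix(matrix, "by_color")


class TestTopExoMirnas:
    def test_ranking_and_clamping(self):
        profiles = [
            make_profile(
                f"d{i}",
                {m: 1 for m in ["osa-miR156a", "zma-miR168a"][: 1 + i % 2]},
            )
            for i in range(6)
        ]
        table = supporting_numbers(profiles)
        top = top_exo_mirnas(table, 30)
        assert len(top) == 2  # clamped to table size
        numbers = [n for _, n in top]
        assert numbers == sorted(numbers, reverse=True)

    def test_ties_broken_lexicographically(self):
        profiles = [make_profile("d1", {"zma-miR168a": 1, "osa-miR156a": 1})]
        table = supporting_numbers(profiles)
        assert [m for m, _ in top_exo_mirnas(table, 2)] == ["osa-miR156a", "zma-miR168a"]
        # deterministic across repeated invocation
        assert top_exo_mirnas(table, 2) == top_exo_mirnas(table, 2)


def test_kingdom_share_virus_breakdown(taxonomy):
    counts = {f"ebv-miR-BART1-5p": 3, "ebv-miR-BHRF1-1": 1, "kshv-miR-K12-1": 2}
    prof = make_profile("d1", counts)
    share = kingdom_share([prof], taxonomy, "virus")
    assert share["ebv"] == pytest.approx(100 * 2 / 3)
    assert share["kshv"] == pytest.approx(100 * 1 / 3)
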