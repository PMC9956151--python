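"""Congener pruning and gap-based clade GC bounds."""

from __future__ import annotations

import pytest

from gclandscape.curation import (SpeciesRecord, assemble_minmax_table,
                                  curate_congeners, detect_gc_gap)


def rec(species, gc, level="scaffold", group="reptiles"):
    return SpeciesRecord(species=species, group=group, assembly_level=level,
                         gc_dna=gc)


CONGENERS = [
    rec("Mus caroli", 41.0, "scaffold"),
    rec("Mus musculus", 41.8, "chromosome"),
    rec("Mus pahari", 41.2, "contig"),
    rec("Mus spicilegus", 41.1, "scaffold"),
    rec("Mus spretus", 41.4, "chromosome"),
]


class TestCurateCongeners:
    def test_chromosome_level_preferred_then_alphabetical(self):
        result = curate_congeners(CONGENERS, max_per_genus=1)
        assert [r.species for r in result.retained] == ["Mus musculus"]
        assert len(result.removed) == 4
        assert all("redundant congener" in reason for _, reason in result.removed)

    def test_max_two_keeps_both_chromosome_assemblies(self):
        result = curate_congeners(CONGENERS, max_per_genus=2)
        assert sorted(r.species for r in result.retained) == [
            "Mus musculus", "Mus spretus"]

    def test_alphabetical_tiebreak_between_equal_levels(self):
        records = [rec("Danio rerio", 36.5, "chromosome"),
                   rec("Danio aesculapii", 36.0, "chromosome"),
                   rec("Danio kyathit", 36.2, "chromosome")]
        result = curate_congeners(records, max_per_genus=1)
        assert [r.species for r in result.retained] == ["Danio aesculapii"]

    def test_distinct_genera_unchanged(self):
        records = [rec("Mus musculus", 41.8), rec("Danio rerio", 36.5),
                   rec("Gallus gallus", 42.0)]
        result = curate_congeners(records)
        assert result.retained == records
        assert result.removed == []

    def test_idempotent(self):
        once = curate_congeners(CONGENERS).retained
        twice = curate_congeners(once).retained
        assert twice == once

    def test_genus_parsed_from_binomial(self):
        assert rec("Notechis scutatus", 37.2).genus == "Notechis"
        assert SpeciesRecord(species="Danio_rerio", group="fish",
                             assembly_level="chromosome", gc_dna=36.5
                             ).genus == "Danio"

    def test_invalid_max_rejected(self):
        with pytest.raises(ValueError):
            curate_congeners(CONGENERS, max_per_genus=0)


# A value list mirroring the snake/lizard lower-bound scan: suspect
# scaffold-level extremes below a 2-point gap, first chromosome-level
# assembly just beyond it.
REPTILE_LIKE = [
    rec("Suspectus unus", 33.0, "scaffold"),
    rec("Suspectus duo", 34.5, "scaffold"),
    rec("Suspectus tres", 35.0, "scaffold"),
    rec("Notechis scutatus", 37.2, "chromosome"),
    rec("Ordinarius unus", 38.0, "scaffold"),
    rec("Ordinarius duo", 39.5, "chromosome"),
]


class TestDetectGcGap:
    def test_lower_bound_at_first_value_beyond_gap(self):
        p = detect_gc_gap(REPTILE_LIKE, min_gap=2.0, side="lower")
        assert p.gap_interval == (35.0, 37.2)
        assert p.bound_gc == 37.2
        assert p.supporting_species == "Notechis scutatus"
        assert len(p.excluded) == 3

    def test_chromosome_level_preferred_beyond_gap(self):
        records = [r for r in REPTILE_LIKE]
        # make the first value beyond the gap scaffold-level: the bound
        # advances to the first chromosome assembly at or beyond it
        records[3] = rec("Notechis scutatus", 37.2, "scaffold")
        p = detect_gc_gap(records, min_gap=2.0, side="lower")
        assert p.gap_interval == (35.0, 37.2)
        assert p.supporting_species == "Ordinarius duo"
        assert p.bound_gc == 39.5

    def test_no_gap_falls_back_to_extreme(self):
        records = [rec(f"s{i}", 40.0 + i * 0.5) for i in range(5)]
        lower = detect_gc_gap(records, min_gap=2.0, side="lower")
        assert lower.gap_interval is None and lower.bound_gc == 40.0
        upper = detect_gc_gap(records, min_gap=2.0, side="upper")
        assert upper.gap_interval is None and upper.bound_gc == 42.0

    def test_all_equal_values(self):
        records = [rec(f"s{i}", 41.0) for i in range(4)]
        p = detect_gc_gap(records, min_gap=1.0, side="lower")
        assert p.bound_gc == 41.0 and p.gap_interval is None

    def test_upper_side_scan(self):
        records = [rec("a", 40.0), rec("b", 41.0), rec("c", 42.0),
                   rec("inflated", 47.0, "contig")]
        p = detect_gc_gap(records, min_gap=2.0, side="upper")
        assert p.gap_interval == (42.0, 47.0)
        assert p.bound_gc == 42.0
        assert [r.species for r, _ in p.excluded] == ["inflated"]

    def test_permutation_invariance(self):
        import itertools

        base = detect_gc_gap(REPTILE_LIKE, min_gap=2.0, side="lower")
        for perm in itertools.islice(itertools.permutations(REPTILE_LIKE), 0, 120, 7):
            p = detect_gc_gap(list(perm), min_gap=2.0, side="lower")
            assert (p.bound_gc, p.supporting_species, p.gap_interval) == (
                base.bound_gc, base.supporting_species, base.gap_interval)

    def test_bound_never_inside_gap(self):
        for side in ("lower", "upper"):
            p = detect_gc_gap(REPTILE_LIKE, min_gap=1.0, side=side)
            if p.gap_interval is not None:
                lo, hi = p.gap_interval
                assert not (lo < p.bound_gc < hi)

    @pytest.mark.parametrize("bad", [[], [rec("a", 40)], [rec("a", 40), rec("b", 41)]])
    def test_too_few_values_rejected(self, bad):
        with pytest.raises(ValueError, match="at least 3"):
            detect_gc_gap(bad, min_gap=2.0, side="lower")

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            detect_gc_gap(REPTILE_LIKE, min_gap=0, side="lower")
        with pytest.raises(ValueError):
            detect_gc_gap(REPTILE_LIKE, min_gap=1.0, side="sideways")


class TestMinMaxTable:
    def test_two_groups_sorted_rows(self):
        reptiles_low = detect_gc_gap(REPTILE_LIKE, min_gap=2.0, side="lower")
        fish = [rec("Danio rerio", 36.5, "chromosome", group="fish"),
                rec("Alosa alosa", 48.0, "chromosome", group="fish"),
                rec("Thaleichthys pacificus", 46.0, "scaffold", group="fish")]
        fish_high = detect_gc_gap(fish, min_gap=2.0, side="upper")
        table = assemble_minmax_table([reptiles_low, fish_high])
        assert list(table["group"]) == ["fish", "reptiles"]
        reptile_row = table[table["group"] == "reptiles"].iloc[0]
        assert reptile_row["min_species"] == "Notechis scutatus"
        assert reptile_row["min_gc"] == 37.2

    def test_empty_input_gives_empty_table(self):
        table = assemble_minmax_table([])
        assert len(table) == 0
        assert list(table.columns) == ["group", "min_species", "min_gc",
                                       "max_species", "max_gc"]

    def test_duplicate_proposal_rejected(self):
        p = detect_gc_gap(REPTILE_LIKE, min_gap=2.0, side="lower")
        with pytest.raises(ValueError, match="duplicate"):
            assemble_minmax_table([p, p])
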