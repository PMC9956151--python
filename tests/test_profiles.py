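"""Species triples, Delta statistics, group summaries, histograms."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gclandscape.composition import batch_stats, compose_sequence
from gclandscape.profiles import (SpeciesProfile, build_species_profile,
                                  compute_deltas, gc_histogram, group_table,
                                  summarize_group, summarize_groups)

pct = st.floats(min_value=0, max_value=100, allow_nan=False)


def _batch(species, fraction, seq="ACGT"):
    return batch_stats(species, fraction, [compose_sequence("s", seq)])


def _profiles(dna_values, group="g"):
    return [
        SpeciesProfile(species=f"sp{i}", group=group, gc_dna=v,
                       gc_cdna=v + 5, gc_cds=v + 7)
        for i, v in enumerate(dna_values)
    ]


class TestComputeDeltas:
    def test_identical_fractions_give_zero(self):
        d = compute_deltas(44.0, 44.0, 44.0)
        assert (d.delta1, d.delta2, d.delta3) == (0.0, 0.0, 0.0)

    def test_signs_and_values(self):
        d = compute_deltas(40.0, 48.5, 51.0)
        assert d.delta1 == pytest.approx(8.5)
        assert d.delta2 == pytest.approx(2.5)
        assert d.delta3 == pytest.approx(11.0)

    @pytest.mark.parametrize("triple", [(-1, 50, 50), (50, 101, 50), (50, 50, 200)])
    def test_out_of_range_rejected(self, triple):
        with pytest.raises(ValueError):
            compute_deltas(*triple)

    @settings(deadline=None, max_examples=300)
    @given(pct, pct, pct)
    def test_additivity_exact(self, dna, cdna, cds):
        d = compute_deltas(dna, cdna, cds)
        assert d.delta1 + d.delta2 == d.delta3  # exact, not approx

    def test_rounded_presentation_preserves_additivity(self):
        d = compute_deltas(41.13, 50.87, 51.94)
        r1, r2, r3 = d.rounded()
        assert r3 == round(r1 + r2, 1)


class TestBuildSpeciesProfile:
    def test_triple_from_batches(self):
        profile = build_species_profile(
            _batch("sp", "DNA", "AATTACGT"),   # 25%
            _batch("sp", "cDNA", "ACGT"),      # 50%
            _batch("sp", "cds", "GGGCCCAT"),   # 75%
            group="fish",
        )
        assert profile.triple == (25.0, 50.0, 75.0)
        assert profile.deltas.delta3 == 50.0

    def test_identical_batches_give_equal_triple(self):
        b = lambda f: _batch("sp", f, "GATTACA")
        p = build_species_profile(b("DNA"), b("cDNA"), b("cds"), group="g")
        assert p.gc_dna == p.gc_cdna == p.gc_cds

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_species_profile(_batch("a", "DNA"), _batch("b", "cDNA"),
                                  _batch("a", "cds"), group="g")

    def test_wrong_fraction_slot_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            build_species_profile(_batch("a", "cds"), _batch("a", "cDNA"),
                                  _batch("a", "DNA"), group="g")

    def test_undefined_gc_propagates_as_error(self):
        with pytest.raises(ValueError, match="undefined"):
            build_species_profile(_batch("a", "DNA", "NNNN"),
                                  _batch("a", "cDNA"), _batch("a", "cds"),
                                  group="g")


class TestSummarizeGroup:
    def test_single_species_degenerate(self):
        s = summarize_group(_profiles([42.0]), "g")
        assert s.dna.mean == s.dna.median == s.dna.q1 == s.dna.q3 == 42.0
        assert s.dna.iqr == 0.0
        assert s.n_species == 1

    def test_quantiles_match_order_statistic_oracle(self):
        """Linear interpolation on {40,42,44,46}: position (n-1)p gives
        q1 at 0.75 -> 41.5, median 43.0, q3 at 2.25 -> 44.5, IQR 3.0."""
        s = summarize_group(_profiles([40.0, 42.0, 44.0, 46.0]), "g")
        assert s.dna.q1 == 41.5
        assert s.dna.median == 43.0
        assert s.dna.q3 == 44.5
        assert s.dna.iqr == 3.0
        assert s.dna.q1 <= s.dna.median <= s.dna.q3

    def test_means_are_unweighted(self):
        s = summarize_group(_profiles([40.0, 50.0]), "g")
        assert s.dna.mean == 45.0

    def test_deltas_come_from_group_means(self):
        profiles = [
            SpeciesProfile(species="a", group="g", gc_dna=40, gc_cdna=50, gc_cds=52),
            SpeciesProfile(species="b", group="g", gc_dna=42, gc_cdna=48, gc_cds=56),
        ]
        s = summarize_group(profiles, "g")
        assert s.deltas.delta1 == pytest.approx(49.0 - 41.0)
        assert s.deltas.delta3 == pytest.approx(54.0 - 41.0)

    def test_tukey_whiskers_and_outliers(self):
        values = [40.0, 41.0, 42.0, 43.0, 44.0, 60.0]  # 60 is an outlier
        s = summarize_group(_profiles(values), "g")
        assert s.dna.outliers == (60.0,)
        assert s.dna.whisker_high == 44.0
        assert s.dna.whisker_low == 40.0
        assert s.dna.min <= s.dna.whisker_low <= s.dna.whisker_high <= s.dna.max

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="no profiles"):
            summarize_group(_profiles([40.0], group="other"), "g")

    def test_group_table_shape_and_order(self):
        profiles = _profiles([40.0, 44.0], group="fish") + _profiles(
            [41.0], group="mammals")
        table = group_table(summarize_groups(profiles))
        assert list(table["group"]) == ["fish", "mammals"]  # appearance order
        assert list(table.columns) == [
            "group", "n_species", "gc_dna", "gc_cdna", "gc_cds",
            "delta1_cdna_dna", "delta2_cds_cdna", "delta3_cds_dna",
        ]
        row = table.iloc[0]
        assert row["delta1_cdna_dna"] + row["delta2_cds_cdna"] == pytest.approx(
            row["delta3_cds_dna"])


class TestGCHistogram:
    def _batch_at(self, gc_values):
        seqs = []
        for i, v in enumerate(gc_values):
            gc_count = int(round(v))  # 100-base sequences: GC% == count
            seqs.append(compose_sequence(f"s{i}", "G" * gc_count +
                                         "A" * (100 - gc_count)))
        return batch_stats("sp", "cds", seqs)

    def test_point_mass_single_bin(self):
        h = gc_histogram(self._batch_at([50] * 10), bin_width=1.0)
        assert sum(h.counts) == 10
        idx = h.bin_edges.index(50.0)
        assert h.counts[idx] == 10

    def test_boundary_bins_and_closed_last_bin(self):
        h = gc_histogram(self._batch_at([0, 100]), bin_width=1.0)
        assert h.counts[0] == 1
        assert h.counts[-1] == 1  # GC 100 lands in the final, closed bin

    def test_counts_conserved_and_undefined_tracked(self):
        rng = np.random.default_rng(0)
        batch = self._batch_at(rng.integers(0, 101, size=50))
        batch.sequences.append(compose_sequence("undef", "NNN"))
        h = gc_histogram(batch, bin_width=5.0)
        assert h.n_defined == 50
        assert h.n_undefined == 1

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gc_histogram(self._batch_at([50]), bin_width=0)
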