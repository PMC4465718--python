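"""RACE tallies, candidate-window enumeration, candidate selection, and
reconstruction of the cleavage-site segment from the published table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpsirna.cleavage import (
    enumerate_candidate_windows,
    expected_race_product_sizes,
    load_published_candidates,
    reconstruct_target_from_candidates,
    select_candidate_sirnas,
    tally_cleavage,
)
from hpsirna.mapping import MappedSirna
from hpsirna.sequences import revcomp, to_rna
from hpsirna.simulate import RaceModel, simulate_race_clones


def brute_force_windows(cut_sites, k, excl, max_pos=1000):
    """Oracle: filter every window start against the definition directly."""
    out = set()
    for s in range(1, max_pos):
        e = s + k - 1
        for i, j in cut_sites:
            if s <= i and j <= e:
                off = i - s + 1
                if excl + 1 <= off <= k - excl - 1:
                    out.add((s, e))
    return sorted(out)


class TestTally:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["sample", "transcript", "cut_i", "cut_j"])

    def test_major_site_fraction_over_half(self):
        # 13 of 23 clones at the two major sites
        rows = (
            [("L1", "t", 297, 298)] * 8
            + [("L1", "t", 301, 302)] * 5
            + [("L1", "t", 274, 275)] * 6
            + [("L1", "t", 120, 121)] * 4
        )
        tallies = tally_cleavage(self._table(rows), region=(1, 318))
        t = tallies["L1"]
        combined = t.fractions[(297, 298)] + t.fractions[(301, 302)]
        assert combined == pytest.approx(13 / 23)
        assert combined > 0.5

    def test_outside_region_counted(self):
        rows = [("WT", "t", 400, 401)] * 8 + [("WT", "t", 200, 201)] * 20
        t = tally_cleavage(self._table(rows), region=(1, 318))["WT"]
        assert t.outside_region_count == 8
        assert t.inside_region_count == 20
        assert t.total == 28

    def test_single_clone_fraction_one(self):
        t = tally_cleavage(self._table([("a", "t", 10, 11)]), region=(1, 318))["a"]
        assert t.fractions[(10, 11)] == 1.0

    def test_fractions_sum_to_one_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        rows = [("x", "t", int(i), int(i) + 1) for i in rng.integers(1, 300, size=40)]
        a = tally_cleavage(self._table(rows), region=(1, 318))["x"]
        rng.shuffle(rows)
        b = tally_cleavage(self._table(rows), region=(1, 318))["x"]
        assert sum(a.fractions.values()) == pytest.approx(1.0)
        assert a.fractions == b.fractions

    def test_conserved_set_shrinks_with_more_samples(self):
        rows = [
            ("A", "t", 100, 101), ("A", "t", 200, 201),
            ("B", "t", 100, 101), ("B", "t", 200, 201),
            ("C", "t", 100, 101),
        ]
        two = tally_cleavage(self._table(rows), region=(1, 318), sample_set=["A", "B"])
        three = tally_cleavage(self._table(rows), region=(1, 318), sample_set=["A", "B", "C"])
        assert two["A"].conserved_sites == {(100, 101), (200, 201)}
        assert three["A"].conserved_sites == {(100, 101)}
        assert three["A"].conserved_sites <= two["A"].conserved_sites

    def test_out_of_bounds_rows_rejected(self):
        rows = [("a", "t", 10, 11), ("a", "t", 900, 901)]
        t = tally_cleavage(self._table(rows), region=(1, 318), transcript_length=600)["a"]
        assert t.rejected_rows == 1
        assert t.total == 1

    def test_directed_sites_recovered_under_degradation(self):
        from hpsirna.construct import TargetTranscript

        rng = np.random.default_rng(3)
        t = TargetTranscript(
            "t", "".join(rng.choice(list("ACGT"), size=700)), target_region=(101, 418)
        )
        sites = {(397, 398): 0.5, (401, 402): 0.3, (374, 375): 0.2}
        model = RaceModel(
            directed_sites=sites, degradation_fraction=0.3, n_clones=1000, seed=5
        )
        clones = simulate_race_clones(t, model, sample_id="L")
        tally = tally_cleavage(clones, region=(101, 418))["L"]
        top3 = sorted(tally.fractions, key=tally.fractions.get, reverse=True)[:3]
        assert set(top3) == set(sites)


class TestCandidateWindows:
    def test_published_pair_yields_20_windows(self):
        windows = enumerate_candidate_windows([(297, 298), (301, 302)], k=21, terminal_exclusion=2)
        assert len(windows) == 20
        assert [s for s, _ in windows] == list(range(280, 300))

    def test_single_site_yields_16_windows(self):
        windows = enumerate_candidate_windows([(297, 298)], k=21, terminal_exclusion=2)
        assert len(windows) == 16
        assert [s for s, _ in windows] == list(range(280, 296))
        assert windows == brute_force_windows([(297, 298)], 21, 2)

    def test_no_exclusion_yields_every_covering_window(self):
        windows = enumerate_candidate_windows([(297, 298)], k=21, terminal_exclusion=0)
        assert len(windows) == 20
        assert windows == brute_force_windows([(297, 298)], 21, 0)

    def test_empty_sites_error(self):
        with pytest.raises(ValueError):
            enumerate_candidate_windows([])

    @given(
        st.lists(st.integers(50, 400), min_size=1, max_size=4, unique=True),
        st.integers(19, 25),
        st.integers(0, 4),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_brute_force_on_random_instances(self, cuts, k, excl):
        if k <= 2 * excl:
            return
        sites = [(i, i + 1) for i in cuts]
        assert enumerate_candidate_windows(sites, k=k, terminal_exclusion=excl) == (
            brute_force_windows(sites, k, excl)
        )

    @given(st.integers(1, 12), st.integers(21, 24), st.integers(1, 3))
    @settings(max_examples=60, derandomize=True)
    def test_union_size_identity_for_close_pairs(self, d, k, excl):
        m = k - 2 * excl - 1  # windows admitted per site
        if d >= m:
            return
        sites = [(100, 101), (100 + d, 101 + d)]
        windows = enumerate_candidate_windows(sites, k=k, terminal_exclusion=excl)
        assert len(windows) == m + d


class TestCandidateSelection:
    def _mapped_from_segment(self, segment, seg_start, cpms, sample="S-24-4D"):
        out = []
        for off, cpm in cpms.items():
            window = segment[off - 1 : off + 20]
            out.append(
                MappedSirna(
                    sequence=revcomp(window),
                    length=21,
                    reference_id="IR",
                    start=seg_start + off - 1,
                    end=seg_start + off + 19,
                    strand="antisense",
                    raw_count=1,
                    cpm=cpm,
                )
            )
        return {sample: out}

    def test_ranks_by_reference_cpm_descending(self):
        rng = np.random.default_rng(9)
        segment = "".join(rng.choice(list("ACGT"), size=40))
        cpms = {off: float(100 - off) for off in range(1, 21)}
        mapped = self._mapped_from_segment(segment, 280, cpms)
        df = select_candidate_sirnas(mapped, [(297, 298), (301, 302)], "S-24-4D")
        assert len(df) == 20
        assert df["cpm_S-24-4D"].tolist() == sorted(df["cpm_S-24-4D"], reverse=True)
        assert df.window_start.tolist()[0] == 280

    def test_cut_at_offset_two_excluded(self):
        rng = np.random.default_rng(10)
        segment = "".join(rng.choice(list("ACGT"), size=60))
        # window starting at 296 places cut 297-298 at offset 2: discarded
        mapped = self._mapped_from_segment(segment, 296, {1: 5.0})
        df = select_candidate_sirnas(mapped, [(297, 298)], "S-24-4D")
        assert df.empty

    def test_empty_antisense_library(self):
        df = select_candidate_sirnas({"S-24-4D": []}, [(297, 298)], "S-24-4D")
        assert df.empty

    def test_missing_reference_sample_errors(self):
        with pytest.raises(ValueError):
            select_candidate_sirnas({"a": []}, [(297, 298)], "S-24-4D")

    def test_published_cpms_reproduce_published_rank_order(self):
        """Feeding the published per-line CPM column through selection must
        reproduce the published table's own rank order."""
        pub = load_published_candidates()
        segment, offsets = reconstruct_target_from_candidates(pub.sequence.tolist())
        mapped = {"S-24-4D": []}
        for seq, cpm in zip(pub.sequence, pub["cpm_S-24-4D"]):
            off = offsets[seq]
            mapped["S-24-4D"].append(
                MappedSirna(
                    sequence=seq.replace("U", "T"),
                    length=21,
                    reference_id="IR",
                    start=280 + off - 1,
                    end=280 + off + 19,
                    strand="antisense",
                    raw_count=1,
                    cpm=float(cpm),
                )
            )
        df = select_candidate_sirnas(mapped, [(297, 298), (301, 302)], "S-24-4D")
        assert len(df) == 20
        assert df.sequence.tolist() == pub.sequence.tolist()
        assert df.sequence.iloc[0] == "AAUGGUGCAGAUCUUUCUGGC"


class TestReconstruction:
    def test_published_sequences_tile_40nt_segment(self):
        pub = load_published_candidates()
        segment, offsets = reconstruct_target_from_candidates(pub.sequence.tolist())
        assert len(segment) == 40
        assert sorted(offsets.values()) == list(range(1, 21))
        # round trip: every candidate is the reverse complement of its window
        for seq, off in offsets.items():
            assert to_rna(revcomp(segment[off - 1 : off + 20])) == seq

    def test_non_overlapping_fragments_error(self):
        with pytest.raises(ValueError, match="tile"):
            reconstruct_target_from_candidates(["A" * 21, "C" * 21])

    def test_single_sequence_returns_its_revcomp(self):
        seq = "AAUGGUGCAGAUCUUUCUGGC"
        segment, offsets = reconstruct_target_from_candidates([seq])
        assert segment == revcomp(seq.replace("U", "T"))
        assert offsets == {seq: 1}


class TestProductSizes:
    @pytest.mark.parametrize("lo,hi", [(281, 599), (143, 461)])
    def test_published_ranges(self, lo, hi):
        assert expected_race_product_sizes(318, lo - 100, 100) == (lo, hi)
        assert hi - lo == 318

    def test_zero_region_min_equals_max(self):
        lo, hi = expected_race_product_sizes(0, 50, 30)
        assert lo == hi == 80

    def test_negative_offsets_error(self):
        with pytest.raises(ValueError):
            expected_race_product_sizes(318, -1, 10)
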