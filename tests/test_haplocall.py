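"""Haplogroup caller: SNP tallies, path search, reports, damage
triage."""

import numpy as np
import pytest

from nrykit import simulate as sim
from nrykit.haplocall import (SampleCallTable, SnpCall, call_haplogroup,
                              export_reports, flag_damage_suspects,
                              tally_snp_calls)
from nrykit.haplogroups import HaplogroupTree
from nrykit.io import PileupTable, SitePileup, SnpRecord


def snp(pos, hg, anc="A", der="G"):
    return SnpRecord(f"M{pos}", hg, pos, anc, der)


def pileup(sites):
    return PileupTable.from_sites(
        [SitePileup(p, counts) for p, counts in sites.items()])


class TestTally:
    def test_all_derived_damage_pair(self):
        table = tally_snp_calls(pileup({100: {"T": 3}}),
                                [snp(100, "H", "C", "T")])
        (call,) = table.calls
        assert (call.derived_count, call.ancestral_count,
                call.difference) == (3, 0, 3)
        assert call.damage_candidate

    def test_mixed_counts_and_transversion(self):
        table = tally_snp_calls(pileup({50: {"A": 1, "G": 2}}),
                                [snp(50, "H", "A", "G")])
        (call,) = table.calls
        assert call.difference == 1
        assert not call.damage_candidate

    def test_uncovered_snp_emits_no_call(self):
        table = tally_snp_calls(pileup({50: {"A": 1}}),
                                [snp(50, "H"), snp(60, "H")])
        assert len(table.calls) == 1
        assert table.covered_fraction == pytest.approx(0.5)

    def test_other_bases_counted_separately(self):
        table = tally_snp_calls(pileup({50: {"A": 2, "G": 3, "C": 1}}),
                                [snp(50, "H", "A", "G")])
        assert table.calls[0].other_count == 1

    def test_min_end_offset_tracks_derived_reads(self):
        site = SitePileup(50, {"A": 1, "G": 2},
                          {"A": [30], "G": [2, 17]})
        table = tally_snp_calls(PileupTable.from_sites([site]),
                                [snp(50, "H", "A", "G")])
        assert table.calls[0].min_end_offset == 2

    def test_difference_antisymmetric_under_polarity_swap(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, g = int(rng.integers(0, 10)), int(rng.integers(0, 10))
            if a + g == 0:
                continue
            fwd = tally_snp_calls(pileup({10: {"A": a, "G": g}}),
                                  [snp(10, "H", "A", "G")])
            rev = tally_snp_calls(pileup({10: {"A": a, "G": g}}),
                                  [snp(10, "H", "G", "A")])
            assert fwd.calls[0].difference == -rev.calls[0].difference

    def test_vectorised_path_agrees_with_mapping_fallback(self):
        rng = np.random.default_rng(7)
        sites = {}
        for p in rng.choice(1000, size=50, replace=False):
            counts = {"A": int(rng.integers(0, 4)),
                      "G": int(rng.integers(0, 4))}
            counts = {b: c for b, c in counts.items() if c}
            if counts:
                sites[int(p)] = counts
        catalogue = [snp(p, "H", "A", "G") for p in sorted(sites)]
        fast = tally_snp_calls(pileup(sites), catalogue)
        slow = tally_snp_calls(
            {p: SitePileup(p, cts) for p, cts in sites.items()}, catalogue)
        key = lambda c: (c.snp.position, c.derived_count,
                         c.ancestral_count, c.other_count)
        assert [key(c) for c in fast.calls] == [key(c) for c in slow.calls]


CHAIN = HaplogroupTree({"R": None, "A": "R", "B": "A", "C": "B", "X": "R"})


class TestCallHaplogroup:
    def test_single_supported_branch_below_root(self):
        table = SampleCallTable("s", [SnpCall(snp(1, "A"), 2, 0)], 1)
        assignment = call_haplogroup(table, CHAIN)
        assert assignment.haplogroup == "A"
        assert assignment.path == ["R", "A"]

    def test_deepest_fully_supported_node_wins(self):
        calls = [SnpCall(snp(1, "A"), 2, 0), SnpCall(snp(2, "B"), 1, 0),
                 SnpCall(snp(3, "C"), 3, 0), SnpCall(snp(4, "X"), 1, 0)]
        assignment = call_haplogroup(SampleCallTable("s", calls, 4), CHAIN)
        assert assignment.haplogroup == "C"

    def test_negative_intermediate_branch_blocks_descent(self):
        calls = [SnpCall(snp(1, "A"), 2, 0), SnpCall(snp(2, "B"), 0, 3),
                 SnpCall(snp(3, "C"), 3, 0)]
        assignment = call_haplogroup(SampleCallTable("s", calls, 3), CHAIN)
        assert assignment.haplogroup == "A"

    def test_conflicting_branch_reported_not_blocking(self):
        calls = [SnpCall(snp(1, "A"), 2, 0), SnpCall(snp(2, "A"), 0, 2),
                 SnpCall(snp(3, "A"), 3, 0)]
        assignment = call_haplogroup(SampleCallTable("s", calls, 3), CHAIN)
        assert assignment.haplogroup == "A"
        assert assignment.conflicts == ["A"]

    def test_empty_table_unassigned_with_reason(self):
        assignment = call_haplogroup(SampleCallTable("s", [], 10), CHAIN)
        assert assignment.haplogroup is None
        assert "no catalogue SNPs covered" in assignment.reason

    def test_no_positive_branch_unassigned(self):
        calls = [SnpCall(snp(1, "A"), 0, 2)]
        assignment = call_haplogroup(SampleCallTable("s", calls, 1), CHAIN)
        assert assignment.haplogroup is None

    def test_unknown_labels_warn_and_are_ignored(self):
        calls = [SnpCall(snp(1, "A"), 2, 0),
                 SnpCall(snp(2, "ZZZ"), 5, 0)]
        with pytest.warns(UserWarning, match="absent from the tree"):
            assignment = call_haplogroup(SampleCallTable("s", calls, 2),
                                         CHAIN)
        assert assignment.haplogroup == "A"

    def test_recovers_truth_on_clean_simulation(self, small_truth,
                                                clean_pileups):
        catalogue = sim.emit_snp_table(small_truth)
        tree = small_truth.haplogroup_tree()
        for leaf in small_truth.tree.leaves():
            table = tally_snp_calls(clean_pileups.pileups[leaf.leaf_label],
                                    catalogue, sample=leaf.leaf_label)
            assignment = call_haplogroup(table, tree)
            expected = _attainable_call(small_truth, clean_pileups,
                                        leaf.leaf_label)
            assert assignment.haplogroup == expected
            # and the call always lies on the true root path
            assert small_truth.leaf_haplogroup(
                leaf.leaf_label).startswith(assignment.haplogroup)


def _attainable_call(truth, data, label):
    """Independent path-tracing oracle: the deepest node on the leaf's
    true root path all of whose branches carry >= 1 covered defining
    SNP, computed from simulation truth and raw coverage only."""
    pileup_table = data.pileups[label]
    by_branch = {}
    for m in truth.mutations:
        by_branch.setdefault(m.branch, []).append(m.position)
    path = truth.tree.root_path(truth.tree.leaf_ids[label])
    best = truth.tree.nodes[path[0]].haplogroup  # root
    for node in path[1:]:
        positions = by_branch.get(node, [])
        covered = [p for p in positions if p in pileup_table]
        if not covered:
            break
        best = truth.tree.nodes[node].haplogroup
    return best


class TestReports:
    def _table(self):
        calls = [SnpCall(snp(1, "A"), 3, 0), SnpCall(snp(2, "B"), 0, 1),
                 SnpCall(snp(3, "C"), 1, 0)]
        return SampleCallTable("s", calls, 3)

    def test_positive_file_subset_of_all(self, tmp_path):
        pos, full = export_reports(self._table(), tmp_path / "p.csv",
                                   tmp_path / "a.csv")
        assert len(pos) == 2 and len(full) == 3
        merged = pos.merge(full, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()
        assert (full[full["difference"] > 0].reset_index(drop=True)
                .equals(pos))

    def test_empty_table_writes_headers_only(self, tmp_path):
        pos, full = export_reports(SampleCallTable("s", [], 0),
                                   tmp_path / "p.csv", tmp_path / "a.csv")
        assert len(pos) == 0 and len(full) == 0
        header = (tmp_path / "p.csv").read_text().splitlines()[0]
        assert "difference" in header

    def test_rows_sorted_by_haplogroup_then_position(self, tmp_path):
        calls = [SnpCall(snp(9, "B"), 1, 0), SnpCall(snp(4, "A"), 1, 0),
                 SnpCall(snp(2, "B"), 1, 0)]
        _, full = export_reports(SampleCallTable("s", calls, 3),
                                 tmp_path / "p.csv", tmp_path / "a.csv")
        assert full["haplogroup"].tolist() == ["A", "B", "B"]
        assert full["position"].tolist() == [4, 2, 9]


class TestDamageSuspects:
    def test_single_read_transition_near_read_end_flagged(self):
        call = SnpCall(snp(1, "H", "C", "T"), 1, 0, min_end_offset=2)
        assert flag_damage_suspects(SampleCallTable("s", [call], 1),
                                    min_reads=2, min_offset=3) == [call]

    def test_well_supported_transition_not_flagged(self):
        call = SnpCall(snp(1, "H", "C", "T"), 5, 0, min_end_offset=1)
        assert flag_damage_suspects(SampleCallTable("s", [call], 1),
                                    min_reads=2, min_offset=3) == []

    def test_transversion_never_flagged(self):
        call = SnpCall(snp(1, "H", "A", "G"), 1, 0, min_end_offset=1)
        assert flag_damage_suspects(SampleCallTable("s", [call], 1),
                                    min_reads=2, min_offset=3) == []

    def test_interior_read_position_not_flagged(self):
        call = SnpCall(snp(1, "H", "C", "T"), 1, 0, min_end_offset=25)
        assert flag_damage_suspects(SampleCallTable("s", [call], 1),
                                    min_reads=2, min_offset=3) == []
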