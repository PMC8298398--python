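"""Synthetic-lineage generator: tree geometry, Poisson mutation
placement, infinite sites, and the pileup noise model."""

import numpy as np
import pytest

from nrykit import simulate as sim
from nrykit.simulate import (LineageTree, Mutation, SimulationTruth,
                             TreeNode, emit_pileups, emit_snp_table,
                             place_mutations, simulate_tree)


class TestSimulateTree:
    def test_two_leaf_tmrca_equals_depth(self):
        tree = simulate_tree(2, 161_300, seed=1)
        assert tree.tmrca("S000", "S001") == pytest.approx(161_300)

    def test_deterministic_given_seed(self):
        a = simulate_tree(8, 50_000, seed=7)
        b = simulate_tree(8, 50_000, seed=7)
        assert {i: (n.parent, n.time) for i, n in a.nodes.items()} == \
            {i: (n.parent, n.time) for i, n in b.nodes.items()}

    def test_different_seeds_differ(self):
        a = simulate_tree(8, 50_000, seed=7)
        b = simulate_tree(8, 50_000, seed=8)
        assert {i: (n.parent, n.time) for i, n in a.nodes.items()} != \
            {i: (n.parent, n.time) for i, n in b.nodes.items()}

    def test_rejects_single_leaf(self):
        with pytest.raises(ValueError):
            simulate_tree(1, 1000, seed=0)

    def test_times_decrease_toward_present(self):
        tree = simulate_tree(10, 80_000, seed=3)
        for node in tree.nodes.values():
            if node.parent is not None:
                assert node.time < tree.nodes[node.parent].time
        assert tree.nodes[tree.root].time == pytest.approx(80_000)

    def test_haplogroup_labels_form_a_tree(self):
        tree = simulate_tree(6, 10_000, seed=5)
        hgtree = tree.haplogroup_tree()
        assert hgtree.root == "HG"
        for leaf in tree.leaves():
            assert leaf.haplogroup in hgtree


def _two_branch_tree(duration):
    """Two leaves splitting `duration` years ago."""
    nodes = {
        0: TreeNode(0, 2, 0.0, leaf_label="S000", haplogroup="HG0"),
        1: TreeNode(1, 2, 0.0, leaf_label="S001", haplogroup="HG1"),
        2: TreeNode(2, None, duration, haplogroup="HG"),
    }
    return LineageTree(nodes, 2)


class TestPlaceMutations:
    def test_poisson_mean_matches_closed_form(self):
        # one branch of 123,000 years at the NRY rate over the mappable
        # length has mean mu*L*t ~ 998.4 mutations
        mu, L, t = 7.77e-10, 10_445_000, 123_000.0
        expected = mu * L * t
        tree = _two_branch_tree(t)
        counts = []
        for seed in range(200):
            truth = place_mutations(tree, mu, L, seed=seed)
            counts.append(sum(1 for m in truth.mutations if m.branch == 0))
        observed = np.mean(counts)
        se = np.sqrt(expected / 200)
        assert abs(observed - expected) < 3 * se

    def test_zero_length_branch_gets_no_mutations(self):
        nodes = {
            0: TreeNode(0, 2, 0.0, leaf_label="S000", haplogroup="HG0"),
            1: TreeNode(1, 2, 0.0, leaf_label="S001", haplogroup="HG1"),
            2: TreeNode(2, 3, 40_000.0, haplogroup="HG2"),
            3: TreeNode(3, None, 40_000.0001, haplogroup="HG"),
        }
        tree = LineageTree(nodes, 3)
        for seed in range(20):
            truth = place_mutations(tree, 8e-10, 1_000_000, seed=seed)
            assert not any(m.branch == 2 for m in truth.mutations)

    def test_pairwise_differences_match_2muLT(self):
        mu, L, t = 8e-10, 1_000_000, 100_000.0
        tree = _two_branch_tree(t)
        expected = 2 * mu * L * t  # 160
        totals = [len(place_mutations(tree, mu, L, seed=s).mutations)
                  for s in range(200)]
        se = np.sqrt(expected / 200)
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_infinite_sites_no_duplicate_positions(self, small_truth):
        positions = [m.position for m in small_truth.mutations]
        assert len(set(positions)) == len(positions)

    def test_rejects_saturating_rate(self):
        tree = _two_branch_tree(1e6)
        with pytest.raises(ValueError, match="mutations"):
            place_mutations(tree, 1e-3, 1000, seed=0)


class TestSnpTable:
    def test_record_count_equals_mutation_count(self, small_truth):
        assert len(emit_snp_table(small_truth)) == len(small_truth.mutations)

    def test_leaf_is_derived_for_exactly_its_root_path_snps(self,
                                                            small_truth):
        snps = emit_snp_table(small_truth)
        by_branch_label = {}
        for m in small_truth.mutations:
            label = small_truth.tree.nodes[m.branch].haplogroup
            by_branch_label.setdefault(label, set()).add(m.position)
        for leaf in small_truth.tree.leaves():
            # independent path-tracing oracle over haplogroup labels
            path_labels = set()
            hg = small_truth.leaf_haplogroup(leaf.leaf_label)
            while hg:
                path_labels.add(hg)
                hg = hg[:-1] if hg != "HG" else ""
            expected = set()
            for label in path_labels:
                expected |= by_branch_label.get(label, set())
            derived = set(
                small_truth.leaf_derived_positions(leaf.leaf_label).tolist())
            assert derived == expected
            # every derived SNP is labelled with a clade on the path
            for s in snps:
                if s.position in derived:
                    assert s.haplogroup in path_labels

    def test_two_leaf_mutation_labelled_with_subtended_clade(self):
        tree = _two_branch_tree(10_000)
        truth = SimulationTruth(
            tree, [Mutation(5, 0, "A", "G")], mu=8e-10, length=100)
        (rec,) = emit_snp_table(truth)
        assert rec.haplogroup == "HG0"

    def test_requires_at_least_one_mutation(self):
        truth = SimulationTruth(_two_branch_tree(10_000), [], 8e-10, 100)
        with pytest.raises(ValueError):
            emit_snp_table(truth)


class TestEmitPileups:
    def test_clean_pileups_are_homozygous_everywhere(self, clean_pileups):
        for table in clean_pileups.pileups.values():
            assert ((table.counts > 0).sum(axis=1) == 1).all()

    def test_full_missingness_gives_empty_pileups(self, small_truth):
        data = emit_pileups(small_truth, 10.0, missing_frac=1.0, seed=1,
                            positions=small_truth.variant_positions)
        assert all(len(t) == 0 for t in data.pileups.values())

    def test_contamination_requires_source(self, small_truth):
        with pytest.raises(ValueError, match="contam_source"):
            emit_pileups(small_truth, 5.0, contam_frac=0.5, seed=1)

    def test_offsets_match_counts(self, clean_pileups):
        table = next(iter(clean_pileups.pileups.values()))
        site = table.site_at(0)
        for base, count in site.counts.items():
            assert len(site.end_offsets[base]) == count

    def test_damage_only_converts_c_to_t_and_g_to_a(self, small_truth):
        clean = emit_pileups(small_truth, 30.0, seed=7,
                             positions=small_truth.variant_positions,
                             with_offsets=False)
        damaged = emit_pileups(small_truth, 30.0, damage_rate=0.3, seed=7,
                               positions=small_truth.variant_positions,
                               with_offsets=False)
        for label in clean.pileups:
            c, d = clean.pileups[label], damaged.pileups[label]
            # depth fields drawn identically (same seed stream ordering
            # differs), so compare allele identities instead: damaged
            # pileups may only show T where clean showed C, A where G
            pos = np.intersect1d(c.positions, d.positions)
            ic, _ = c.lookup(pos)
            idx, _ = d.lookup(pos)
            A, C, G, T = 0, 1, 2, 3
            extra = (d.counts[idx] > 0) & ~(c.counts[ic] > 0)
            rows = extra.any(axis=1)
            for r in np.flatnonzero(rows):
                new_bases = set(np.flatnonzero(extra[r]))
                old_bases = set(np.flatnonzero(c.counts[ic[r]] > 0))
                assert new_bases <= {T, A}
                if T in new_bases:
                    assert C in old_bases
                if A in new_bases:
                    assert G in old_bases

    def test_expected_heterozygosity_under_half_contamination(self):
        # deep two-leaf split; closed-form expectation for the fraction
        # of discordant sites showing both alleles at depth k ~ Poisson
        mu, L, t = 8e-10, 1_000_000, 2_000_000.0
        tree = _two_branch_tree(t)
        truth = place_mutations(tree, mu, L, seed=42)
        n_disc = len(truth.mutations)  # every mutation separates the pair
        data = emit_pileups(truth, 10.0, contam_frac=0.5,
                            contam_source="S001", seed=43,
                            with_offsets=False)
        table = data.pileups["S000"]
        depths = table.depths
        het_sites = ((table.counts > 0).sum(axis=1) >= 2).sum()
        # P(het | discordant, depth k) = 1 - 2*(1/2)^k ; average over k
        from math import factorial
        k = np.arange(1, 60)
        pk = np.exp(-10.0) * 10.0 ** k / np.array(
            [factorial(int(x)) for x in k], dtype=float)
        p_het = float(np.sum(pk * (1 - 2 * 0.5 ** k)) / np.sum(pk))
        expected = n_disc * p_het
        assert abs(het_sites - expected) < 4 * np.sqrt(expected)
        # and far above the 0.1% screen
        assert het_sites / len(depths) > 0.001
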