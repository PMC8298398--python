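"""Synthetic Y-lineage data with known truth.

The generator emulates the data regime this package analyses: a
non-recombining haploid locus whose history is a single tree, mutations
placed on branches as a Poisson process under an infinite-sites model,
per-sample pileups with Poisson depth, site drop-out, post-mortem
deamination (C→T / G→A per read) and optional male contamination drawn
from another leaf's haplotype.

Defaults follow the NRY regime: substitution rate μ = 8.0e-10
substitutions/site/year (within the published 7.77e-10–8.93e-10 range)
and a mappable length of up to ~10.4 Mb, configurable down to 1e5 bp so
the full pipeline can be exercised quickly. Every stochastic operation
takes a mandatory seed.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from functools import cached_property
from typing import NamedTuple

import numpy as np
import pandas as pd

from .haplogroups import HaplogroupTree
from .io import BASES, BASE_INDEX, PileupTable, SnpRecord

DEFAULT_MU = 8.0e-10         # substitutions / site / year
DEFAULT_LENGTH = 10_445_000  # bp of mappable NRY

__all__ = [
    "DEFAULT_MU",
    "DEFAULT_LENGTH",
    "TreeNode",
    "LineageTree",
    "Mutation",
    "SimulationTruth",
    "SimulatedPileups",
    "simulate_tree",
    "place_mutations",
    "emit_pileups",
    "emit_snp_table",
    "emit_target_bed",
]


@dataclass
class TreeNode:
    id: int
    parent: int | None
    time: float                # years before present (0 = present)
    leaf_label: str | None = None
    haplogroup: str = ""


@dataclass
class LineageTree:
    """Binary genealogy of sampled male lineages.

    Node times are in years before present and strictly decrease from
    parent to child; leaves sit at time 0. Each node carries a
    haplogroup label encoding its position in the tree (root ``HG``,
    children appending ``0``/``1``), so the label set is itself a valid
    haplogroup hierarchy.
    """

    nodes: dict[int, TreeNode]
    root: int

    def __post_init__(self) -> None:
        roots = [n.id for n in self.nodes.values() if n.parent is None]
        if roots != [self.root] and set(roots) != {self.root}:
            raise ValueError("exactly one root required")
        for node in self.nodes.values():
            if node.parent is not None:
                if node.time >= self.nodes[node.parent].time:
                    raise ValueError(
                        f"node {node.id} not younger than its parent")
            if node.leaf_label is not None and node.time != 0:
                raise ValueError("leaves must sit at time 0")

    @cached_property
    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {i: [] for i in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                out[node.parent].append(node.id)
        return out

    def leaves(self) -> list[TreeNode]:
        return sorted((n for n in self.nodes.values()
                       if n.leaf_label is not None),
                      key=lambda n: n.leaf_label)

    @cached_property
    def leaf_ids(self) -> dict[str, int]:
        return {n.leaf_label: n.id for n in self.leaves()}

    def branch_duration(self, node_id: int) -> float:
        node = self.nodes[node_id]
        if node.parent is None:
            return 0.0
        return self.nodes[node.parent].time - node.time

    def total_branch_length(self) -> float:
        return sum(self.branch_duration(i) for i in self.nodes)

    def root_path(self, node_id: int) -> list[int]:
        """Node ids from the root down to ``node_id`` inclusive."""
        path = [node_id]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path[::-1]

    def tmrca(self, label_a: str, label_b: str) -> float:
        """Time of the most recent common ancestor of two leaves."""
        pa = self.root_path(self.leaf_ids[label_a])
        pb = self.root_path(self.leaf_ids[label_b])
        mrca = self.root
        for x, y in zip(pa, pb):
            if x != y:
                break
            mrca = x
        return self.nodes[mrca].time

    def haplogroup_tree(self) -> HaplogroupTree:
        parent: dict[str, str | None] = {}
        for node in self.nodes.values():
            par = node.parent
            parent[node.haplogroup] = (
                self.nodes[par].haplogroup if par is not None else None)
        return HaplogroupTree(parent)


def simulate_tree(n_leaves: int, depth_years: float, seed: int) -> LineageTree:
    """Random binary genealogy with the root at ``depth_years``.

    Topology and relative node times come from a Kingman-style
    coalescent (random pair merges, exponential waiting times), then
    all times are rescaled so the root sits exactly at ``depth_years``.
    Deterministic given ``seed``; leaf labels are ``S000``, ``S001``, …
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    if depth_years <= 0:
        raise ValueError("depth_years must be > 0")
    rng = np.random.default_rng(seed)
    nodes: dict[int, TreeNode] = {}
    width = max(3, len(str(n_leaves - 1)))
    active: list[int] = []
    for i in range(n_leaves):
        nodes[i] = TreeNode(i, None, 0.0, leaf_label=f"S{i:0{width}d}")
        active.append(i)
    next_id = n_leaves
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        nodes[next_id] = TreeNode(next_id, None, t)
        nodes[a].parent = next_id
        nodes[b].parent = next_id
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    root = active[0]
    scale = depth_years / nodes[root].time
    for node in nodes.values():
        node.time *= scale
    # haplogroup labels: binary path strings below the root
    nodes[root].haplogroup = "HG"
    stack = [root]
    while stack:
        cur = stack.pop()
        kids = sorted(i for i in nodes if nodes[i].parent == cur)
        for rank, kid in enumerate(kids):
            nodes[kid].haplogroup = nodes[cur].haplogroup + str(rank)
            stack.append(kid)
    return LineageTree(nodes, root)


class Mutation(NamedTuple):
    position: int    # 1-based, unique across the simulation
    branch: int      # node id below the mutated branch
    ancestral: str
    derived: str


@dataclass
class SimulationTruth:
    """A tree plus the mutations placed on it (infinite-sites)."""

    tree: LineageTree
    mutations: list[Mutation]
    mu: float
    length: int

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.length <= 0:
            raise ValueError("mu and length must be positive")
        positions = [m.position for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise ValueError("infinite-sites violated: duplicate position")
        for m in self.mutations:
            if m.branch not in self.tree.nodes:
                raise ValueError(f"mutation on unknown branch {m.branch}")

    @cached_property
    def variant_positions(self) -> np.ndarray:
        return np.sort(np.array([m.position for m in self.mutations],
                                dtype=np.int64))

    @cached_property
    def _by_position(self) -> dict[int, Mutation]:
        return {m.position: m for m in self.mutations}

    @cached_property
    def _branch_mutations(self) -> dict[int, list[Mutation]]:
        out: dict[int, list[Mutation]] = {}
        for m in self.mutations:
            out.setdefault(m.branch, []).append(m)
        return out

    def leaf_haplogroup(self, label: str) -> str:
        return self.tree.nodes[self.tree.leaf_ids[label]].haplogroup

    def leaf_derived_positions(self, label: str) -> np.ndarray:
        """Positions at which this leaf carries the derived allele
        (mutations on its root path)."""
        path = self.tree.root_path(self.tree.leaf_ids[label])
        positions = [m.position for node in path
                     for m in self._branch_mutations.get(node, [])]
        return np.sort(np.array(positions, dtype=np.int64))

    def haplotype(self, label: str,
                  positions: np.ndarray | None = None) -> np.ndarray:
        """Base (as '<U1') carried by the leaf at each requested
        position; defaults to the variant positions."""
        if positions is None:
            positions = self.variant_positions
        positions = np.asarray(positions, dtype=np.int64)
        derived = set(int(p) for p in self.leaf_derived_positions(label))
        out = np.empty(len(positions), dtype="<U1")
        for i, p in enumerate(positions):
            m = self._by_position.get(int(p))
            if m is None:
                out[i] = "A"   # invariant sites share an arbitrary base
            else:
                out[i] = m.derived if int(p) in derived else m.ancestral
        return out

    def haplogroup_tree(self) -> HaplogroupTree:
        return self.tree.haplogroup_tree()


def place_mutations(tree: LineageTree, mu: float, length: int,
                    seed: int) -> SimulationTruth:
    """Drop mutations on branches as Poisson(μ·L·duration), positions
    uniform without replacement over 1..L (infinite sites).

    Raises when the expected mutation count exceeds L — the
    infinite-sites approximation is then untenable and a smaller μ·L
    should be used.
    """
    if mu <= 0 or length <= 0:
        raise ValueError("mu and length must be positive")
    rng = np.random.default_rng(seed)
    branch_ids = [i for i in tree.nodes if tree.nodes[i].parent is not None]
    durations = np.array([tree.branch_duration(i) for i in branch_ids])
    means = mu * length * durations
    if means.sum() > length:
        raise ValueError(
            f"expected {means.sum():.0f} mutations exceeds sequence length "
            f"{length}; reduce mu*length or branch lengths")
    counts = rng.poisson(means)
    total = int(counts.sum())
    if total > length:
        raise ValueError("drew more mutations than sites; reduce mu*length")
    positions = rng.choice(length, size=total, replace=False) + 1
    anc_idx = rng.integers(0, 4, size=total)
    der_idx = (anc_idx + rng.integers(1, 4, size=total)) % 4
    mutations: list[Mutation] = []
    k = 0
    for branch, c in zip(branch_ids, counts):
        for _ in range(int(c)):
            mutations.append(Mutation(int(positions[k]), branch,
                                      BASES[anc_idx[k]], BASES[der_idx[k]]))
            k += 1
    mutations.sort(key=lambda m: m.position)
    return SimulationTruth(tree, mutations, mu, length)


@dataclass
class SimulatedPileups:
    """Per-leaf pileups plus the truth tables needed to check them.

    ``haplotypes`` is a variant-positions × leaves frame of each leaf's
    true base; ``ancestral`` the ancestral base per variant position.
    """

    pileups: dict[str, PileupTable]
    haplotypes: pd.DataFrame
    ancestral: pd.Series
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def emit_pileups(
    truth: SimulationTruth,
    mean_depth: float,
    missing_frac: float = 0.0,
    damage_rate: float = 0.0,
    contam_frac: float = 0.0,
    contam_source: str | None = None,
    seed: int = 0,
    read_length: int = 60,
    positions: Sequence[int] | np.ndarray | None = None,
    with_offsets: bool = True,
) -> SimulatedPileups:
    """Emit one pileup per leaf under the stated noise model.

    Per covered site the read depth is Poisson(``mean_depth``); a site
    is dropped entirely with probability ``missing_frac``; each read
    whose base is C flips to T (and G to A) with probability
    ``damage_rate``; with ``contam_frac`` > 0 each read is instead drawn
    from ``contam_source``'s haplotype with that probability. Read-end
    offsets are uniform over 0..read_length//2 (distance to the nearer
    terminus). ``positions`` restricts emission to a subset of sites
    (e.g. a SNP catalogue) — the default is every site 1..L.
    """
    for name, v in (("missing_frac", missing_frac),
                    ("damage_rate", damage_rate),
                    ("contam_frac", contam_frac)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if contam_frac > 0 and contam_source is None:
        raise ValueError("contam_frac > 0 requires a contam_source leaf")
    rng = np.random.default_rng(seed)
    if positions is None:
        pos = np.arange(1, truth.length + 1, dtype=np.int64)
    else:
        pos = np.unique(np.asarray(positions, dtype=np.int64))
        if len(pos) and (pos[0] < 1 or pos[-1] > truth.length):
            raise ValueError("positions outside 1..L")
    n_pos = len(pos)

    # true base codes per leaf over the emitted positions
    mut_pos = truth.variant_positions
    anc_code = np.zeros(n_pos, dtype=np.int8)  # 'A' background
    hit_idx, hit = _match(pos, mut_pos)
    for i in np.flatnonzero(hit):
        m = truth._by_position[int(pos[i])]
        anc_code[i] = BASE_INDEX[m.ancestral]

    leaves = [n.leaf_label for n in truth.tree.leaves()]

    def leaf_codes(label: str) -> np.ndarray:
        codes = anc_code.copy()
        dpos = truth.leaf_derived_positions(label)
        _, is_der = _match(pos, dpos)
        for i in np.flatnonzero(is_der):
            codes[i] = BASE_INDEX[truth._by_position[int(pos[i])].derived]
        return codes

    contam_codes = leaf_codes(contam_source) if contam_source else None
    C, T, G, A = (BASE_INDEX["C"], BASE_INDEX["T"],
                  BASE_INDEX["G"], BASE_INDEX["A"])
    pileups: dict[str, PileupTable] = {}
    for label in leaves:
        codes = leaf_codes(label)
        depth = rng.poisson(mean_depth, size=n_pos)
        if missing_frac > 0:
            depth[rng.random(n_pos) < missing_frac] = 0
        counts = np.zeros((n_pos, 4), dtype=np.int64)
        rows = np.arange(n_pos)
        if contam_codes is not None and contam_frac > 0:
            k = rng.binomial(depth, contam_frac)
            np.add.at(counts, (rows, codes), depth - k)
            np.add.at(counts, (rows, contam_codes), k)
        else:
            counts[rows, codes] = depth
        if damage_rate > 0:
            flip_ct = rng.binomial(counts[:, C], damage_rate)
            flip_ga = rng.binomial(counts[:, G], damage_rate)
            counts[:, C] -= flip_ct
            counts[:, T] += flip_ct
            counts[:, G] -= flip_ga
            counts[:, A] += flip_ga
        if with_offsets:
            flat = counts.ravel()
            off_ptr = np.concatenate([[0], np.cumsum(flat)]).astype(np.int64)
            off_values = rng.integers(0, read_length // 2 + 1,
                                      size=int(off_ptr[-1]))
            pileups[label] = PileupTable(pos, counts, off_values, off_ptr)
        else:
            pileups[label] = PileupTable(pos, counts)

    hap = pd.DataFrame(
        {label: truth.haplotype(label) for label in leaves},
        index=pd.Index(mut_pos, name="position"))
    ancestral = pd.Series(
        [truth._by_position[int(p)].ancestral for p in mut_pos],
        index=pd.Index(mut_pos, name="position"), name="ancestral")
    return SimulatedPileups(pileups, hap, ancestral, positions=pos)


def _match(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each element of sorted-or-not ``a``: its index into sorted
    ``b`` and whether it is present."""
    b = np.sort(np.asarray(b, dtype=np.int64))
    idx = np.searchsorted(b, a)
    idxc = np.clip(idx, 0, max(len(b) - 1, 0))
    found = (b[idxc] == a) if len(b) else np.zeros(len(a), dtype=bool)
    return idxc, found


def emit_snp_table(truth: SimulationTruth) -> list[SnpRecord]:
    """Synthetic haplogroup-SNP catalogue: one record per mutation,
    labelled with the clade subtended by the mutated branch."""
    if not truth.mutations:
        raise ValueError("truth has no mutations")
    records = [
        SnpRecord(
            name=f"M{m.position}",
            haplogroup=truth.tree.nodes[m.branch].haplogroup,
            position=m.position,
            ancestral=m.ancestral,
            derived=m.derived,
        )
        for m in truth.mutations
    ]
    records.sort(key=lambda r: r.position)
    return records


def emit_target_bed(truth: SimulationTruth):
    """Target-region description of the simulated locus (one interval
    spanning the full simulated sequence)."""
    from .io import TargetRegions

    return TargetRegions.from_intervals("Y", [(0, truth.length)],
                                        label="simulated")
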