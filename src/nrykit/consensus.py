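"""Per-sample consensus haplotypes and the segregating-site alignment.

Consensus calling is deliberately conservative for ancient DNA: a base
is called only from at least two reads whose minor-allele fraction is
strictly below 10%, taking the majority allele; everything else is
missing. The multi-sample alignment keeps segregating sites (columns
with >= 2 distinct called bases) covered in >= 2 samples, and drops
samples covering fewer than a minimum number of segregating sites
(default 1100); the two filters are applied iteratively to a fixed
point because each can invalidate the other.

Maximum-likelihood tree search on the exported FASTA is delegated to
external phylogenetics software; a neighbour-joining tree on pairwise
mismatch proportions is provided as an internal sanity surrogate.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .io import (BASES, MISSING, PileupTable, SitePileup, read_alignment,
                 write_alignment)

DEFAULT_MIN_DEPTH = 2
DEFAULT_MAX_MINOR_FRAC = 0.10
DEFAULT_MIN_SEG_SITES = 1100

__all__ = [
    "DEFAULT_MIN_DEPTH",
    "DEFAULT_MAX_MINOR_FRAC",
    "DEFAULT_MIN_SEG_SITES",
    "ConsensusSequence",
    "AlignmentMatrix",
    "consensus_call",
    "consensus_from_pileup",
    "build_alignment",
    "pairwise_distance_tree",
]


@dataclass
class ConsensusSequence:
    """Called bases of one sample; positions absent from ``positions``
    are missing."""

    sample: str
    positions: np.ndarray      # sorted 1-based positions with a call
    bases: np.ndarray          # '<U1', aligned with positions

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.bases = np.asarray(self.bases, dtype="<U1")
        if len(self.positions) != len(self.bases):
            raise ValueError("positions and bases differ in length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.bases, list(BASES))
        if bad.any():
            raise ValueError("called bases must be A/C/G/T")

    def __len__(self) -> int:
        return len(self.positions)

    def call_at(self, position: int) -> str:
        i = np.searchsorted(self.positions, position)
        if i < len(self.positions) and self.positions[i] == position:
            return str(self.bases[i])
        return MISSING


def consensus_call(site: SitePileup,
                   min_depth: int = DEFAULT_MIN_DEPTH,
                   max_minor_frac: float = DEFAULT_MAX_MINOR_FRAC) -> str:
    """Majority-allele call for one site, or ``N``.

    Missing when depth < ``min_depth``, when the minor-allele fraction
    (1 − majority/depth) is not strictly below ``max_minor_frac``
    (so a 9:1 site is masked at the default), or on a tie for the
    majority base.
    """
    depth = site.depth
    if depth < min_depth:
        return MISSING
    counts = [(site.counts.get(b, 0), b) for b in BASES]
    top = max(c for c, _ in counts)
    winners = [b for c, b in counts if c == top]
    if len(winners) != 1:
        return MISSING
    # integer minor count vs frac*depth avoids 1 - 9/10 != 0.1 rounding
    if depth - top >= max_minor_frac * depth:
        return MISSING
    return winners[0]


def consensus_from_pileup(
    pileup: Mapping[int, SitePileup] | PileupTable,
    sample: str = "",
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_minor_frac: float = DEFAULT_MAX_MINOR_FRAC,
) -> ConsensusSequence:
    """Apply :func:`consensus_call` across a whole pileup (vectorised
    for :class:`PileupTable`)."""
    if isinstance(pileup, PileupTable):
        counts = pileup.counts
        depth = counts.sum(axis=1)
        top = counts.max(axis=1)
        tie = (counts == top[:, None]).sum(axis=1) > 1
        ok = (depth >= min_depth) & ~tie & \
            (depth - top < max_minor_frac * depth)
        base_arr = np.array(list(BASES), dtype="<U1")
        calls = base_arr[np.argmax(counts, axis=1)]
        return ConsensusSequence(sample, pileup.positions[ok], calls[ok])
    positions, bases = [], []
    for pos in sorted(pileup):
        b = consensus_call(pileup[pos], min_depth, max_minor_frac)
        if b != MISSING:
            positions.append(pos)
            bases.append(b)
    return ConsensusSequence(sample, np.array(positions, dtype=np.int64),
                             np.array(bases, dtype="<U1"))


@dataclass
class AlignmentMatrix:
    """Samples × segregating-site matrix of called bases (``N`` missing)."""

    samples: list[str]
    positions: np.ndarray
    cells: np.ndarray          # (n_samples, n_sites), '<U1'
    seg_sites_covered: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cells = np.asarray(self.cells, dtype="<U1").reshape(
            len(self.samples), len(self.positions))

    @cached_property
    def covered(self) -> np.ndarray:
        return self.cells != MISSING

    def row(self, sample: str) -> ConsensusSequence:
        i = self.samples.index(sample)
        mask = self.covered[i]
        return ConsensusSequence(sample, self.positions[mask],
                                 self.cells[i][mask])

    def rows(self) -> list[ConsensusSequence]:
        return [self.row(s) for s in self.samples]

    def write(self, path: str | Path,
              sites_path: str | Path | None = None) -> None:
        write_alignment(self, path, sites_path)

    @classmethod
    def read(cls, path: str | Path,
             sites_path: str | Path | None = None) -> "AlignmentMatrix":
        samples, positions, cells = read_alignment(path, sites_path)
        return cls(samples, positions, cells)


def _segregating(cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column: covered-in->=2-samples flag and >=2-distinct flag."""
    covered = cells != MISSING
    cov2 = covered.sum(axis=0) >= 2
    distinct = np.zeros(cells.shape[1], dtype=np.int64)
    for b in BASES:
        distinct += (cells == b).any(axis=0)
    return cov2, distinct >= 2


def build_alignment(
    consensuses: Sequence[ConsensusSequence],
    min_seg_sites: int = DEFAULT_MIN_SEG_SITES,
) -> AlignmentMatrix:
    """Assemble the segregating-site alignment under the sample/site
    filters, iterated to a fixed point.

    Raises when fewer than two samples survive (naming the filter) or
    when no segregating sites exist at all.
    """
    if len(consensuses) < 2:
        raise ValueError("need >= 2 consensus sequences")
    names = [c.sample for c in consensuses]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names")
    all_pos = np.unique(np.concatenate(
        [c.positions for c in consensuses]
        or [np.empty(0, dtype=np.int64)]))
    cells = np.full((len(consensuses), len(all_pos)), MISSING, dtype="<U1")
    for i, c in enumerate(consensuses):
        idx = np.searchsorted(all_pos, c.positions)
        cells[i, idx] = c.bases

    samples = list(names)
    positions = all_pos
    while True:
        cov2, poly = _segregating(cells)
        seg = cov2 & poly
        if not seg.any():
            raise ValueError(
                "no segregating sites among the surviving samples "
                "(nothing to align)")
        per_sample = (cells[:, seg] != MISSING).sum(axis=1)
        keep_samples = per_sample >= min_seg_sites
        if keep_samples.sum() < 2:
            raise ValueError(
                f"fewer than two samples cover >= {min_seg_sites} "
                "segregating sites (minimum-segregating-sites filter)")
        stable = bool(keep_samples.all() and seg.all())
        cells = cells[keep_samples][:, seg]
        samples = [s for s, k in zip(samples, keep_samples) if k]
        positions = positions[seg]
        if stable:
            break
    covered = cells != MISSING
    seg_counts = {s: int(covered[i].sum()) for i, s in enumerate(samples)}
    return AlignmentMatrix(samples, positions, cells,
                           seg_sites_covered=seg_counts)


def pairwise_distance_tree(matrix: AlignmentMatrix) -> str:
    """Neighbour-joining Newick tree on pairwise mismatch proportions
    over jointly covered sites. Deterministic given the matrix; raises
    if any sample pair shares no covered site."""
    n = len(matrix.samples)
    if n < 3:
        raise ValueError("need >= 3 samples for a tree")
    covered = matrix.covered
    dist = np.zeros((n, n))
    empty_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            joint = covered[i] & covered[j]
            m = int(joint.sum())
            if m == 0:
                empty_pairs.append((matrix.samples[i], matrix.samples[j]))
                continue
            mism = int((matrix.cells[i][joint] != matrix.cells[j][joint]).sum())
            dist[i, j] = dist[j, i] = mism / m
    if empty_pairs:
        raise ValueError(
            f"sample pairs with no jointly covered sites: {empty_pairs}")
    dm = DistanceMatrix(dist, ids=matrix.samples)
    tree = nj(dm)
    return str(tree).strip()
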