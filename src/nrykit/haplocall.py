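"""Pileup-based Y-haplogroup assignment.

For every catalogue SNP covered in a sample's pileup we tally reads
supporting the derived and ancestral alleles and record the signed
difference (derived − ancestral). Per-clade support is the sum of
differences over that clade's defining SNPs; the sample is assigned the
deepest haplogroup reachable from the root along branches whose
aggregate support is positive. Positive difference means evidence for
the derived allele. Branches carrying both positive- and
negative-difference SNPs are reported as conflicts (a transitional
form, or artefacts worth manual review) but do not block the call.

Deamination artefacts (C→T / G→A allele pairs) are annotated on every
call together with the smallest read-end offset among derived-allele
reads, so single-read transitions near a read terminus can be triaged.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .haplogroups import HaplogroupTree
from .io import BASE_INDEX, PileupTable, SitePileup, SnpRecord

__all__ = [
    "SnpCall",
    "SampleCallTable",
    "HaplogroupAssignment",
    "tally_snp_calls",
    "call_haplogroup",
    "export_reports",
    "flag_damage_suspects",
]


@dataclass(frozen=True)
class SnpCall:
    """Read tally for one catalogue SNP in one sample."""

    snp: SnpRecord
    derived_count: int
    ancestral_count: int
    other_count: int = 0
    min_end_offset: int | None = None   # among derived-supporting reads

    def __post_init__(self) -> None:
        if min(self.derived_count, self.ancestral_count, self.other_count) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def difference(self) -> int:
        """derived − ancestral; positive = evidence for the derived
        allele."""
        return self.derived_count - self.ancestral_count

    @property
    def damage_candidate(self) -> bool:
        """Determined solely by the allele pair (C→T or G→A)."""
        return self.snp.is_damage_pair


@dataclass
class SampleCallTable:
    sample: str
    calls: list[SnpCall] = field(default_factory=list)
    catalogue_size: int = 0

    @property
    def covered_fraction(self) -> float:
        if self.catalogue_size == 0:
            return 0.0
        return len(self.calls) / self.catalogue_size

    def support_by_haplogroup(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for call in self.calls:
            hg = call.snp.haplogroup
            out[hg] = out.get(hg, 0) + call.difference
        return out


def tally_snp_calls(
    pileup: Mapping[int, SitePileup] | PileupTable,
    snps: Sequence[SnpRecord],
    sample: str = "",
) -> SampleCallTable:
    """One :class:`SnpCall` per catalogue SNP with depth >= 1.

    Reads matching neither allele are counted as ``other``;
    ``min_end_offset`` is the smallest distance-to-read-end among
    derived-supporting reads (None when offsets are unavailable or no
    derived reads exist).
    """
    calls: list[SnpCall] = []
    if isinstance(pileup, PileupTable) and len(pileup):
        positions = np.array([s.position for s in snps], dtype=np.int64)
        idx, found = pileup.lookup(positions)
        minoff = pileup.min_offsets()
        for k in np.flatnonzero(found):
            snp = snps[k]
            row = pileup.counts[idx[k]]
            di, ai = BASE_INDEX[snp.derived], BASE_INDEX[snp.ancestral]
            der, anc = int(row[di]), int(row[ai])
            other = int(row.sum()) - der - anc
            moff = None
            if minoff is not None and der > 0 and minoff[idx[k], di] >= 0:
                moff = int(minoff[idx[k], di])
            calls.append(SnpCall(snp, der, anc, other, moff))
    else:
        for snp in snps:
            site = pileup.get(snp.position) if hasattr(pileup, "get") else None
            if site is None or site.depth == 0:
                continue
            der = site.counts.get(snp.derived, 0)
            anc = site.counts.get(snp.ancestral, 0)
            other = site.depth - der - anc
            offs = site.end_offsets.get(snp.derived, [])
            moff = min(offs) if (der > 0 and offs) else None
            calls.append(SnpCall(snp, der, anc, other, moff))
    return SampleCallTable(sample, calls, catalogue_size=len(snps))


@dataclass
class HaplogroupAssignment:
    sample: str
    haplogroup: str | None
    path: list[str] = field(default_factory=list)
    support: dict[str, int] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)
    reason: str | None = None

    @property
    def assigned(self) -> bool:
        return self.haplogroup is not None


def call_haplogroup(
    table: SampleCallTable,
    tree: HaplogroupTree,
    min_support: int = 1,
) -> HaplogroupAssignment:
    """Assign the deepest haplogroup on a fully-supported root path.

    Every branch on the path from the root to the call must have
    aggregate support (sum of SNP differences for that clade's SNPs)
    of at least ``min_support``. Among equally deep candidates the
    path with the larger cumulative support wins, then the
    lexicographically smaller label. SNP labels absent from the tree
    are ignored with a warning; clades whose SNPs mix positive and
    negative differences are listed as conflicts.
    """
    if not table.calls:
        return HaplogroupAssignment(table.sample, None,
                                    reason="no catalogue SNPs covered")
    support = table.support_by_haplogroup()
    unknown = sorted(hg for hg in support if hg not in tree)
    if unknown:
        warnings.warn(
            f"{table.sample}: ignoring {len(unknown)} haplogroup labels "
            f"absent from the tree (e.g. {unknown[:3]})", stacklevel=2)
        support = {hg: s for hg, s in support.items() if hg in tree}

    signs: dict[str, set[int]] = {}
    for call in table.calls:
        if call.difference and call.snp.haplogroup in tree:
            signs.setdefault(call.snp.haplogroup, set()).add(
                1 if call.difference > 0 else -1)
    conflicts = sorted(hg for hg, s in signs.items() if s == {1, -1})

    # DFS from the root through positively supported branches
    best: tuple[int, int, list[str]] | None = None  # (depth, cum, path)
    stack: list[tuple[str, int, int, list[str]]] = [(tree.root, 0, 0, [tree.root])]
    while stack:
        label, depth, cum, path = stack.pop()
        cand = (depth, cum, path)
        if best is None or (cand[0], cand[1], [-ord(c) for c in "".join(cand[2])]) > \
                (best[0], best[1], [-ord(c) for c in "".join(best[2])]):
            best = cand
        for child in tree.children[label]:
            s = support.get(child, 0)
            if s >= min_support:
                stack.append((child, depth + 1, cum + s, path + [child]))

    assert best is not None
    depth, _, path = best
    if depth == 0:
        # no branch below the root is positively supported
        return HaplogroupAssignment(
            table.sample, None, support=support, conflicts=conflicts,
            reason="no positively supported branch below the root")
    return HaplogroupAssignment(table.sample, path[-1], path=path,
                                support=support, conflicts=conflicts)


def _report_frame(table: SampleCallTable) -> pd.DataFrame:
    rows = [
        {
            "name": c.snp.name,
            "haplogroup": c.snp.haplogroup,
            "position": c.snp.position,
            "ancestral": c.snp.ancestral,
            "derived": c.snp.derived,
            "derived_count": c.derived_count,
            "ancestral_count": c.ancestral_count,
            "other_count": c.other_count,
            "difference": c.difference,
            "damage_candidate": c.damage_candidate,
            "min_end_offset": c.min_end_offset,
        }
        for c in table.calls
    ]
    df = pd.DataFrame(rows, columns=[
        "name", "haplogroup", "position", "ancestral", "derived",
        "derived_count", "ancestral_count", "other_count", "difference",
        "damage_candidate", "min_end_offset"])
    return df.sort_values(["haplogroup", "position"],
                          kind="stable").reset_index(drop=True)


def export_reports(table: SampleCallTable,
                   positive_path: str | Path,
                   all_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write the two per-sample CSVs.

    The first lists only SNPs with positive differences (the easy read
    of the root-to-terminal path); the second lists every covered SNP,
    positive or negative, for double-checking basal branches and
    spotting transitional forms. Returns both frames.
    """
    df_all = _report_frame(table)
    df_pos = df_all[df_all["difference"] > 0].reset_index(drop=True)
    df_pos.to_csv(positive_path, index=False)
    df_all.to_csv(all_path, index=False)
    return df_pos, df_all


def flag_damage_suspects(table: SampleCallTable,
                         min_reads: int = 2,
                         min_offset: int = 3) -> list[SnpCall]:
    """Calls a human would manually inspect: deamination-mimicking
    allele pair, supported by fewer than ``min_reads`` derived reads,
    with the closest derived read within ``min_offset`` bp of a read
    terminus."""
    if min_reads < 1 or min_offset < 0:
        raise ValueError("min_reads >= 1 and min_offset >= 0 required")
    out = []
    for c in table.calls:
        if not (c.damage_candidate and 0 < c.derived_count < min_reads):
            continue
        if c.min_end_offset is not None and c.min_end_offset < min_offset:
            out.append(c)
    return out
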