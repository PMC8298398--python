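"""Readers and writers for the external file formats of the pipeline.

Coordinate conventions are fixed here and nowhere else:

* BED intervals are 0-based, half-open (the BED standard).
* SNP catalogue positions are 1-based (ISOGG / VCF convention).
* The single crossing point is :meth:`TargetRegions.contains`: a SNP at
  1-based position ``p`` lies in an interval ``(start, end)`` iff
  ``start <= p - 1 < end``.

Pileup base strings are strand-folded (upper/lower case merged) because
haplogroup SNP catalogues are strandless; deamination orientation is
handled downstream from the allele pair itself.
"""

from __future__ import annotations

import logging
import re
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING = "N"

__all__ = [
    "BASES",
    "BASE_INDEX",
    "MISSING",
    "TargetRegions",
    "SnpRecord",
    "SnpTable",
    "SitePileup",
    "PileupTable",
    "BedParseError",
    "SnpTableSchemaError",
    "PileupParseError",
    "read_bed",
    "read_snp_table",
    "write_snp_table",
    "read_pileup",
    "write_pileup",
    "write_alignment",
    "read_alignment",
]


class BedParseError(ValueError):
    """Malformed BED input."""


class SnpTableSchemaError(ValueError):
    """SNP catalogue is missing a required column."""


class PileupParseError(ValueError):
    """Malformed pileup text."""


# ---------------------------------------------------------------------------
# Target regions (BED)
# ---------------------------------------------------------------------------


def _merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge half-open intervals into a disjoint set."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [list(iv[0])]
    for start, end in iv[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.asarray(merged, dtype=np.int64)


@dataclass(frozen=True)
class TargetRegions:
    """Sorted, merged half-open intervals on one chromosome.

    Parameters
    ----------
    chrom :
        Chromosome name (``"Y"`` for the assays this package models).
    intervals :
        ``(n, 2)`` int array of 0-based half-open ``(start, end)`` pairs,
        already sorted and non-overlapping. Use :meth:`from_intervals`
        to build from arbitrary input.
    label :
        Free-text assay name.
    """

    chrom: str
    intervals: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "intervals", iv)
        if len(iv):
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError("every interval must satisfy end > start")
            if np.any(np.diff(iv[:, 0]) < 0) or np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("intervals must be sorted and disjoint; "
                                 "use TargetRegions.from_intervals")

    @classmethod
    def from_intervals(
        cls,
        chrom: str,
        intervals: Iterable[tuple[int, int]],
        label: str = "",
    ) -> "TargetRegions":
        iv = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
        if len(iv) and np.any(iv[:, 1] <= iv[:, 0]):
            raise ValueError("every interval must satisfy end > start")
        if len(iv) and np.any(iv < 0):
            raise ValueError("interval coordinates must be non-negative")
        return cls(chrom, _merge_intervals(iv), label)

    @property
    def total_length(self) -> int:
        if len(self.intervals) == 0:
            return 0
        return int(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, positions_1based) -> np.ndarray:
        """Membership test for 1-based positions; the only 1-based/0-based
        crossing point in the package."""
        p0 = np.atleast_1d(np.asarray(positions_1based, dtype=np.int64)) - 1
        if len(self.intervals) == 0:
            return np.zeros(p0.shape, dtype=bool)
        idx = np.searchsorted(self.intervals[:, 0], p0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(p0.shape, dtype=bool)
        out[ok] = p0[ok] < self.intervals[idx[ok], 1]
        return out

    def union(self, other: "TargetRegions") -> "TargetRegions":
        if other.chrom != self.chrom:
            raise ValueError("cannot union regions on different chromosomes")
        iv = np.vstack([self.intervals, other.intervals])
        return TargetRegions(self.chrom, _merge_intervals(iv),
                             label=self.label or other.label)


def read_bed(path: str | Path, chrom: str | None = None,
             label: str = "") -> TargetRegions:
    """Read a 3-column BED file into merged :class:`TargetRegions`.

    All records must lie on a single chromosome (pass ``chrom`` to
    enforce a particular one). Malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    path = Path(path)
    intervals: list[tuple[int, int]] = []
    seen_chrom = chrom
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 whitespace-delimited "
                    f"columns, got {len(fields)}")
            c = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < 0:
                raise BedParseError(
                    f"{path}:{lineno}: negative coordinate")
            if end <= start:
                raise BedParseError(
                    f"{path}:{lineno}: end <= start ({start}, {end})")
            if seen_chrom is None:
                seen_chrom = c
            elif c != seen_chrom:
                raise BedParseError(
                    f"{path}:{lineno}: multiple chromosomes in one file "
                    f"({seen_chrom!r} and {c!r})")
            intervals.append((start, end))
    return TargetRegions.from_intervals(seen_chrom or "", intervals,
                                        label=label or path.stem)


def write_bed(regions: TargetRegions, path: str | Path) -> None:
    with open(path, "w") as fh:
        for start, end in regions.intervals:
            fh.write(f"{regions.chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Haplogroup-defining SNP catalogues
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpRecord:
    """One haplogroup-defining SNP (ISOGG-style record)."""

    name: str
    haplogroup: str
    position: int  # 1-based
    ancestral: str
    derived: str

    def __post_init__(self) -> None:
        if self.ancestral not in BASE_INDEX or self.derived not in BASE_INDEX:
            raise ValueError(
                f"{self.name}: alleles must be A/C/G/T, got "
                f"{self.ancestral!r}->{self.derived!r}")
        if self.ancestral == self.derived:
            raise ValueError(f"{self.name}: ancestral == derived")
        if self.position < 1:
            raise ValueError(f"{self.name}: position must be >= 1")

    @property
    def is_damage_pair(self) -> bool:
        """True when the ancestral→derived change can be mimicked by
        post-mortem deamination (C→T, or G→A on the other strand)."""
        return (self.ancestral, self.derived) in (("C", "T"), ("G", "A"))


class SnpTable(list):
    """A list of :class:`SnpRecord` that remembers how many input rows
    were skipped as malformed."""

    def __init__(self, records: Iterable[SnpRecord] = (), n_skipped: int = 0):
        super().__init__(records)
        self.n_skipped = n_skipped


_DEFAULT_COLUMNS = {
    "name": "name",
    "haplogroup": "haplogroup",
    "position": "position",
    "ancestral": "ancestral",
    "derived": "derived",
}


def read_snp_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> SnpTable:
    """Read a delimited haplogroup-SNP catalogue.

    ``column_map`` maps the logical fields (``name``, ``haplogroup``,
    ``position`` and either ``ancestral``/``derived`` or a combined
    ``mutation`` column of the form ``"C->T"``) to the file's column
    headers; the ISOGG export column names vary between snapshots so
    the map is configurable. Rows with non-ACGT alleles, non-positive
    or non-numeric positions are skipped and counted on the returned
    :class:`SnpTable`.
    """
    cmap = dict(_DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                     skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]

    for key in ("name", "haplogroup", "position"):
        if cmap[key] not in df.columns:
            raise SnpTableSchemaError(
                f"missing required column {cmap[key]!r} "
                f"(have {list(df.columns)})")
    has_pair = cmap["ancestral"] in df.columns and cmap["derived"] in df.columns
    mutation_col = cmap.get("mutation", "mutation")
    if not has_pair and mutation_col not in df.columns:
        raise SnpTableSchemaError(
            f"need either {cmap['ancestral']!r}/{cmap['derived']!r} columns "
            f"or a {mutation_col!r} column")

    records: list[SnpRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        try:
            if has_pair:
                anc = str(row[cmap["ancestral"]]).strip().upper()
                der = str(row[cmap["derived"]]).strip().upper()
            else:
                mut = str(row[mutation_col]).replace(" ", "")
                anc, _, der = mut.upper().partition("->")
            rec = SnpRecord(
                name=str(row[cmap["name"]]).strip(),
                haplogroup=str(row[cmap["haplogroup"]]).strip(),
                position=int(str(row[cmap["position"]]).strip()),
                ancestral=anc,
                derived=der,
            )
        except (ValueError, TypeError):
            n_skipped += 1
            continue
        records.append(rec)
    return SnpTable(records, n_skipped=n_skipped)


def write_snp_table(snps: Iterable[SnpRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.name, s.haplogroup, s.position, s.ancestral, s.derived)
         for s in snps],
        columns=["name", "haplogroup", "position", "ancestral", "derived"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------


@dataclass
class SitePileup:
    """Per-position base counts with optional read-end offsets.

    ``end_offsets[b]`` lists, for each read supporting base ``b``, the
    distance in bp from the nearer read terminus — the quantity used to
    decide how much to trust a putative deamination artefact.
    """

    position: int
    counts: dict[str, int]
    end_offsets: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for b, c in self.counts.items():
            if b not in BASE_INDEX:
                raise ValueError(f"unexpected base {b!r}")
            if c < 0:
                raise ValueError("counts must be >= 0")
        for b, offs in self.end_offsets.items():
            if any(o < 0 for o in offs):
                raise ValueError("end offsets must be >= 0")
            if len(offs) != self.counts.get(b, 0):
                raise ValueError(
                    f"offsets for base {b!r} do not match its count")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)


class PileupTable(Mapping):
    """Column-oriented pileup over one chromosome.

    Behaves as a ``Mapping[int, SitePileup]`` (1-based position →
    per-site view) while storing base counts as an ``(n_sites, 4)``
    matrix plus a CSR layout of read-end offsets, so whole-chromosome
    operations (consensus calling, heterozygosity, SNP tallies) stay
    vectorised. Zero-depth sites are never stored.
    """

    def __init__(
        self,
        positions: np.ndarray,
        counts: np.ndarray,
        off_values: np.ndarray | None = None,
        off_ptr: np.ndarray | None = None,
    ):
        positions = np.asarray(positions, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64).reshape(len(positions), 4)
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        presorted = len(positions) < 2 or bool(
            np.all(positions[1:] > positions[:-1]))
        if presorted:
            order = np.flatnonzero(counts.sum(axis=1) > 0)
        else:
            order = np.argsort(positions, kind="stable")
            order = order[counts[order].sum(axis=1) > 0]
        self.positions = positions[order]
        if not presorted and len(np.unique(self.positions)) != \
                len(self.positions):
            raise ValueError("duplicate positions in pileup")
        self.counts = counts[order]
        if off_values is not None:
            if off_ptr is None:
                raise ValueError("off_ptr required with off_values")
            # re-index the CSR offsets to the sorted/filtered row order
            off_ptr = np.asarray(off_ptr, dtype=np.int64)
            off_values = np.asarray(off_values, dtype=np.int64)
            if len(order) == len(positions) and \
                    np.array_equal(order, np.arange(len(positions))):
                self.off_values = off_values
            else:
                seg = (4 * order[:, None] + np.arange(4)).ravel()
                lens = (off_ptr[1:] - off_ptr[:-1])[seg]
                starts = off_ptr[:-1][seg]
                total = int(lens.sum())
                gather = (np.repeat(starts, lens) + np.arange(total)
                          - np.repeat(np.cumsum(lens) - lens, lens))
                self.off_values = off_values[gather]
            flat = self.counts.ravel()
            self.off_ptr = np.concatenate(
                [[0], np.cumsum(flat)]).astype(np.int64)
            if len(self.off_values) != self.off_ptr[-1]:
                raise ValueError("offset values do not match counts")
        else:
            self.off_values = None
            self.off_ptr = None

    def _row_of(self, position: int) -> int:
        i = int(np.searchsorted(self.positions, int(position)))
        if i >= len(self.positions) or self.positions[i] != int(position):
            raise KeyError(position)
        return i

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_sites(cls, sites: Iterable[SitePileup]) -> "PileupTable":
        sites = sorted(sites, key=lambda s: s.position)
        n = len(sites)
        positions = np.fromiter((s.position for s in sites), np.int64, n)
        counts = np.zeros((n, 4), dtype=np.int64)
        offs: list[np.ndarray] = []
        have_offsets = any(s.end_offsets for s in sites)
        for i, s in enumerate(sites):
            for b, c in s.counts.items():
                counts[i, BASE_INDEX[b]] = c
            if have_offsets:
                for b in BASES:
                    want = s.counts.get(b, 0)
                    got = s.end_offsets.get(b, [])
                    if want and len(got) != want:
                        raise ValueError(
                            f"position {s.position}: offsets for {b} "
                            "do not match count")
                    offs.append(np.asarray(got, dtype=np.int64))
        if have_offsets:
            off_values = (np.concatenate(offs) if offs
                          else np.empty(0, dtype=np.int64))
            off_ptr = np.concatenate(
                [[0], np.cumsum(counts.ravel())]).astype(np.int64)
            return cls(positions, counts, off_values, off_ptr)
        return cls(positions, counts)

    # -- Mapping protocol ----------------------------------------------------

    def __getitem__(self, position: int) -> SitePileup:
        return self.site_at(self._row_of(position))

    def __iter__(self):
        return iter(int(p) for p in self.positions)

    def __len__(self) -> int:
        return len(self.positions)

    def __contains__(self, position) -> bool:
        try:
            self._row_of(position)
        except KeyError:
            return False
        return True

    # -- views ---------------------------------------------------------------

    def site_at(self, i: int) -> SitePileup:
        counts = {b: int(self.counts[i, j])
                  for j, b in enumerate(BASES) if self.counts[i, j] > 0}
        offsets: dict[str, list[int]] = {}
        if self.off_values is not None:
            for j, b in enumerate(BASES):
                lo, hi = self.off_ptr[4 * i + j], self.off_ptr[4 * i + j + 1]
                if hi > lo:
                    offsets[b] = [int(x) for x in self.off_values[lo:hi]]
        return SitePileup(int(self.positions[i]), counts, offsets)

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def lookup(self, positions) -> tuple[np.ndarray, np.ndarray]:
        """Row indices for 1-based ``positions``; second array flags hits."""
        pos = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(self.positions, pos)
        idx_clip = np.clip(idx, 0, max(len(self.positions) - 1, 0))
        found = (len(self.positions) > 0) & (
            self.positions[idx_clip] == pos) if len(self.positions) else \
            np.zeros(pos.shape, dtype=bool)
        return idx_clip, found

    def min_offsets(self) -> np.ndarray | None:
        """Minimum read-end offset per (site, base); -1 where no reads
        or offsets were not recorded."""
        if self.off_values is None:
            return None
        flat = self.counts.ravel()
        out = np.full(flat.shape, -1, dtype=np.int64)
        nz = flat > 0
        if nz.any():
            mins = np.minimum.reduceat(self.off_values, self.off_ptr[:-1][nz])
            out[nz] = mins
        return out.reshape(self.counts.shape)


_PLAIN_BASES = re.compile(r"[ACGTacgt]+\Z")


def _parse_base_string(bases: str, ref: str, path, lineno: int) -> list[str | None]:
    """Expand an mpileup base column into one entry per read.

    Returns the called base (strand-folded) per read, or ``None`` for
    reads excluded from counts (deletions ``*`` and ambiguous ``N``).
    """
    calls: list[str | None] = []
    i, n = 0, len(bases)
    ref = ref.upper()
    while i < n:
        c = bases[i]
        if c == "^":          # read start: skip mapping-quality char
            i += 2
            continue
        if c == "$":          # read end marker
            i += 1
            continue
        if c in "+-":         # indel: skip the inserted/deleted sequence
            j = i + 1
            num = ""
            while j < n and bases[j].isdigit():
                num += bases[j]
                j += 1
            if not num:
                raise PileupParseError(f"{path}:{lineno}: bad indel syntax")
            i = j + int(num)
            continue
        if c in ".,":
            if ref not in BASE_INDEX:
                calls.append(None)
            else:
                calls.append(ref)
            i += 1
            continue
        cu = c.upper()
        if cu in BASE_INDEX:
            calls.append(cu)
            i += 1
            continue
        if cu in "*N<>":
            calls.append(None)
            i += 1
            continue
        raise PileupParseError(
            f"{path}:{lineno}: unexpected character {c!r} in base column")
    return calls


def read_pileup(path: str | Path) -> PileupTable:
    """Read samtools-mpileup-style text for a single chromosome.

    Columns: chrom, 1-based position, reference base, depth, read
    bases, [base qualities], [comma-separated read-end offsets, one per
    read]. Deletions and Ns are excluded from counts; zero-depth
    positions are absent from the result.
    """
    path = Path(path)
    positions: list[int] = []
    count_rows: list[list[int]] = []
    off_rows: list[list[list[int]]] = []
    any_offsets = False
    chrom = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 5:
                raise PileupParseError(
                    f"{path}:{lineno}: expected >=5 columns")
            c, pos_s, ref, depth_s, bases = fields[:5]
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise PileupParseError(
                    f"{path}:{lineno}: multiple chromosomes in one pileup")
            try:
                position, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise PileupParseError(
                    f"{path}:{lineno}: non-integer position/depth") from exc
            if _PLAIN_BASES.match(bases):
                calls = list(bases.upper())
            else:
                calls = _parse_base_string(bases, ref, path, lineno)
            if len(calls) != depth:
                raise PileupParseError(
                    f"{path}:{lineno}: depth column says {depth} but base "
                    f"string holds {len(calls)} reads")
            offsets_per_read: list[int] | None = None
            if len(fields) >= 7 and fields[6].strip():
                try:
                    offsets_per_read = [int(x) for x in
                                        fields[6].split(",") if x != ""]
                except ValueError as exc:
                    raise PileupParseError(
                        f"{path}:{lineno}: bad offsets column") from exc
                if len(offsets_per_read) != depth:
                    raise PileupParseError(
                        f"{path}:{lineno}: {len(offsets_per_read)} offsets "
                        f"for depth {depth}")
            row = [0, 0, 0, 0]
            offs: list[list[int]] = [[], [], [], []]
            for k, b in enumerate(calls):
                if b is None:
                    continue
                j = BASE_INDEX[b]
                row[j] += 1
                if offsets_per_read is not None:
                    offs[j].append(offsets_per_read[k])
            if sum(row):
                positions.append(position)
                count_rows.append(row)
                off_rows.append(offs)
                any_offsets = any_offsets or offsets_per_read is not None
    counts = (np.array(count_rows, dtype=np.int64).reshape(-1, 4))
    pos_arr = np.array(positions, dtype=np.int64)
    if not any_offsets:
        return PileupTable(pos_arr, counts)
    off_values = np.array(
        [o for offs in off_rows for per_base in offs for o in per_base],
        dtype=np.int64)
    off_ptr = np.concatenate([[0], np.cumsum(counts.ravel())]).astype(
        np.int64)
    if len(off_values) != off_ptr[-1]:
        raise PileupParseError(
            f"{path}: offsets present for only part of the file")
    return PileupTable(pos_arr, counts, off_values, off_ptr)


def write_pileup(table: PileupTable, path: str | Path,
                 chrom: str = "Y") -> None:
    """Write a :class:`PileupTable` in the mpileup dialect read back by
    :func:`read_pileup` (reference column written as ``N``; offsets as a
    seventh comma-separated column when present)."""
    counts = table.counts
    depths = counts.sum(axis=1)
    have_offsets = table.off_values is not None
    if have_offsets:
        off_str = table.off_values.astype("U")
        ptr = table.off_ptr
    with open(path, "w") as fh:
        for i in range(len(table)):
            row = counts[i]
            base_str = "".join(b * int(c) for b, c in zip(BASES, row))
            depth = int(depths[i])
            line = (f"{chrom}\t{int(table.positions[i])}\tN\t{depth}\t"
                    f"{base_str}\t{'I' * depth}")
            if have_offsets and depth:
                line += "\t" + ",".join(off_str[ptr[4 * i]:ptr[4 * i + 4]])
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Alignments (FASTA + sidecar site table)
# ---------------------------------------------------------------------------


def write_alignment(matrix, path: str | Path,
                    sites_path: str | Path | None = None) -> None:
    """Export an alignment matrix as FASTA plus a sidecar table mapping
    alignment columns to chromosome positions.

    ``matrix`` needs ``samples``, ``positions`` and ``cells`` (an
    ``(n_samples, n_sites)`` array of single characters, ``N`` for
    missing). Duplicate sample names are rejected; an all-missing row is
    written but logged as a warning.
    """
    samples = list(matrix.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample names in alignment")
    cells = np.asarray(matrix.cells, dtype="<U1")
    if cells.shape != (len(samples), len(matrix.positions)):
        raise ValueError("alignment matrix is not rectangular")
    path = Path(path)
    records = []
    for i, sample in enumerate(samples):
        seq = "".join(cells[i])
        if seq and set(seq) == {MISSING}:
            warnings.warn(f"sample {sample!r} is entirely missing",
                          stacklevel=2)
        records.append(SeqRecord(Seq(seq), id=sample, description=""))
    SeqIO.write(records, str(path), "fasta")
    if sites_path is None:
        sites_path = path.with_suffix(path.suffix + ".sites.tsv")
    pd.DataFrame({
        "column": np.arange(len(matrix.positions)),
        "position": np.asarray(matrix.positions, dtype=np.int64),
    }).to_csv(sites_path, sep="\t", index=False)


def read_alignment(path: str | Path,
                   sites_path: str | Path | None = None):
    """Read back a FASTA alignment written by :func:`write_alignment`.

    Returns ``(samples, positions, cells)``; positions come from the
    sidecar table, or default to 1..n_sites when it is absent.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    samples = [r.id for r in records]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample names in alignment")
    if records:
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValueError("alignment records differ in length")
        n_sites = lengths.pop()
    else:
        n_sites = 0
    cells = np.array([list(str(r.seq).upper()) for r in records],
                     dtype="<U1").reshape(len(records), n_sites)
    if sites_path is None:
        candidate = path.with_suffix(path.suffix + ".sites.tsv")
        sites_path = candidate if candidate.exists() else None
    if sites_path is not None:
        sites = pd.read_csv(sites_path, sep="\t")
        positions = sites["position"].to_numpy(dtype=np.int64)
    else:
        positions = np.arange(1, n_sites + 1, dtype=np.int64)
    if len(positions) != n_sites:
        raise ValueError("sidecar site table does not match alignment width")
    return samples, positions, cells
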