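"""Ingroup/outgroup diagnostic-SNP discovery.

A site is diagnostic for a candidate clade when, against the reference
polarity, (1) no ingroup individual is ancestral, (2) more than one
ingroup individual is covered, (3) no outgroup individual is derived,
and (4) more than one outgroup individual is covered. Novel variants
whose allele pair can be mimicked by deamination (C→T or G→A) are
excluded unless they are previously catalogued SNPs. Because ancient
coverage is sparse, "x/N derived" always means the remaining N−x are
missing, never ancestral — rule (1) guarantees it.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BASES, SnpRecord

ANCESTRAL, DERIVED, MISSING_STATE = 0, 1, -1
INGROUP, OUTGROUP = "ingroup", "outgroup"
NOVEL = "novel"

__all__ = [
    "ANCESTRAL",
    "DERIVED",
    "MISSING_STATE",
    "INGROUP",
    "OUTGROUP",
    "NOVEL",
    "GenotypeMatrix",
    "DiagnosticSnp",
    "find_diagnostic_sites",
    "annotate_known",
    "missingness_report",
    "read_genotype_matrix",
    "write_genotype_matrix",
]


@dataclass
class GenotypeMatrix:
    """Samples × positions 3-state matrix (ancestral / derived /
    missing) polarised against the reference allele at each position.

    ``ref``/``alt`` give the per-position allele pair: ``ref`` is the
    reference (ancestral-polarity) base, ``alt`` the alternate
    (derived-polarity) base. ``groups`` labels each sample ingroup or
    outgroup.
    """

    samples: list[str]
    groups: np.ndarray          # '<U8', "ingroup" | "outgroup"
    positions: np.ndarray       # 1-based, strictly increasing
    ref: np.ndarray             # '<U1'
    alt: np.ndarray             # '<U1'
    cells: np.ndarray           # (n_samples, n_positions) int8

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype="<U8")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="<U1")
        self.alt = np.asarray(self.alt, dtype="<U1")
        self.cells = np.asarray(self.cells, dtype=np.int8).reshape(
            len(self.samples), len(self.positions))
        if len(self.groups) != len(self.samples):
            raise ValueError("groups and samples differ in length")
        bad = set(self.groups) - {INGROUP, OUTGROUP}
        if bad:
            raise ValueError(f"unknown group labels {bad}")
        if not (len(self.positions) == len(self.ref) == len(self.alt)):
            raise ValueError("positions/ref/alt differ in length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        for arr, name in ((self.ref, "ref"), (self.alt, "alt")):
            if len(arr) and not np.isin(arr, list(BASES)).all():
                raise ValueError(f"{name} alleles must be A/C/G/T")
        if len(self.positions) and np.any(self.ref == self.alt):
            raise ValueError("ref == alt at some position")
        ok = np.isin(self.cells, [ANCESTRAL, DERIVED, MISSING_STATE])
        if not ok.all():
            raise ValueError("cells must be -1/0/1")

    @property
    def ingroup_mask(self) -> np.ndarray:
        return self.groups == INGROUP

    @property
    def outgroup_mask(self) -> np.ndarray:
        return self.groups == OUTGROUP


@dataclass
class DiagnosticSnp:
    """One site satisfying the four diagnostic rules."""

    position: int
    ref: str
    alt: str
    ingroup_derived: int
    ingroup_covered: int
    outgroup_covered: int
    damage_pair: bool
    known_annotation: str = NOVEL
    polarity_flipped: bool = False

    @property
    def is_known(self) -> bool:
        return self.known_annotation != NOVEL


def _damage_pair(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    return ((ref == "C") & (alt == "T")) | ((ref == "G") & (alt == "A"))


def _catalogue_lookup(cat: Sequence[SnpRecord]):
    """position → list of records at that position."""
    out: dict[int, list[SnpRecord]] = {}
    for rec in cat:
        out.setdefault(rec.position, []).append(rec)
    return out


def find_diagnostic_sites(
    matrix: GenotypeMatrix,
    known: Sequence[SnpRecord] = (),
) -> list[DiagnosticSnp]:
    """All positions satisfying the four ingroup/outgroup rules, with
    deamination-mimicking allele pairs retained only when previously
    catalogued. Each result is annotated with the catalogue haplogroup
    or marked novel."""
    n_in = int(matrix.ingroup_mask.sum())
    n_out = int(matrix.outgroup_mask.sum())
    if n_in < 2 or n_out < 2:
        raise ValueError(
            "need >= 2 ingroup and >= 2 outgroup samples (coverage rules "
            "2 and 4 are unsatisfiable otherwise)")
    cin = matrix.cells[matrix.ingroup_mask]
    cout = matrix.cells[matrix.outgroup_mask]
    rule1 = (cin == ANCESTRAL).sum(axis=0) == 0
    rule2 = (cin != MISSING_STATE).sum(axis=0) >= 2
    rule3 = (cout == DERIVED).sum(axis=0) == 0
    rule4 = (cout != MISSING_STATE).sum(axis=0) >= 2
    passing = rule1 & rule2 & rule3 & rule4
    damage = _damage_pair(matrix.ref, matrix.alt)

    lookup = _catalogue_lookup(known)
    out: list[DiagnosticSnp] = []
    for j in np.flatnonzero(passing):
        pos = int(matrix.positions[j])
        ref, alt = str(matrix.ref[j]), str(matrix.alt[j])
        annotation, flipped = NOVEL, False
        for rec in lookup.get(pos, []):
            if rec.ancestral == ref and rec.derived == alt:
                annotation, flipped = rec.haplogroup, False
                break
            if rec.ancestral == alt and rec.derived == ref:
                annotation, flipped = rec.haplogroup, True
        if damage[j] and annotation == NOVEL:
            continue
        out.append(DiagnosticSnp(
            position=pos, ref=ref, alt=alt,
            ingroup_derived=int((cin[:, j] == DERIVED).sum()),
            ingroup_covered=int((cin[:, j] != MISSING_STATE).sum()),
            outgroup_covered=int((cout[:, j] != MISSING_STATE).sum()),
            damage_pair=bool(damage[j]),
            known_annotation=annotation,
            polarity_flipped=flipped,
        ))
    return out


def annotate_known(
    snps: Sequence[DiagnosticSnp],
    catalogues: Sequence[Sequence[SnpRecord]],
    clade: str | None = None,
) -> tuple[list[DiagnosticSnp], dict[str, int]]:
    """Re-annotate against additional catalogues (exact position +
    allele-pair match; polarity flips annotated, never corrected).

    Returns the annotated list and summary counts: when ``clade`` is
    given, known hits are split into in-clade (haplogroup label starts
    with ``clade``) and out-of-clade; otherwise just known vs novel.
    """
    lookups = [_catalogue_lookup(cat) for cat in catalogues]
    annotated: list[DiagnosticSnp] = []
    for s in snps:
        annotation, flipped = s.known_annotation, s.polarity_flipped
        if annotation == NOVEL:
            for lookup in lookups:
                for rec in lookup.get(s.position, []):
                    if rec.ancestral == s.ref and rec.derived == s.alt:
                        annotation, flipped = rec.haplogroup, False
                        break
                    if rec.ancestral == s.alt and rec.derived == s.ref:
                        annotation, flipped = rec.haplogroup, True
                if annotation != NOVEL:
                    break
        annotated.append(DiagnosticSnp(
            s.position, s.ref, s.alt, s.ingroup_derived, s.ingroup_covered,
            s.outgroup_covered, s.damage_pair, annotation, flipped))
    summary: dict[str, int] = {
        "total": len(annotated),
        "novel": sum(1 for s in annotated if not s.is_known),
    }
    if clade is None:
        summary["known"] = summary["total"] - summary["novel"]
    else:
        summary["known_in_clade"] = sum(
            1 for s in annotated
            if s.is_known and s.known_annotation.startswith(clade))
        summary["known_out_of_clade"] = (
            summary["total"] - summary["novel"] - summary["known_in_clade"])
    return annotated, summary


def missingness_report(
    matrix: GenotypeMatrix,
    positions: Sequence[int],
    group: str = INGROUP,
) -> pd.DataFrame:
    """Per-position "x/N derived, rest missing" table for one group.

    Positions must exist in the matrix; the report includes the
    ancestral count so the rule-(1) guarantee (none of the N−x covered
    samples are ancestral) is checkable, not assumed.
    """
    if group not in (INGROUP, OUTGROUP):
        raise ValueError("group must be 'ingroup' or 'outgroup'")
    mask = matrix.groups == group
    n_group = int(mask.sum())
    rows = []
    for pos in positions:
        j = np.searchsorted(matrix.positions, pos)
        if j >= len(matrix.positions) or matrix.positions[j] != pos:
            raise KeyError(f"position {pos} not in matrix")
        col = matrix.cells[mask, j]
        derived = int((col == DERIVED).sum())
        ancestral = int((col == ANCESTRAL).sum())
        rows.append({
            "position": int(pos),
            "derived": derived,
            "ancestral": ancestral,
            "missing": n_group - derived - ancestral,
            "group_size": n_group,
            "summary": f"{derived}/{n_group}",
        })
    return pd.DataFrame(rows, columns=["position", "derived", "ancestral",
                                       "missing", "group_size", "summary"])


# ---------------------------------------------------------------------------
# Delimited 3-state matrix I/O (for the CLI)
# ---------------------------------------------------------------------------

_STATE_TO_TEXT = {ANCESTRAL: "ancestral", DERIVED: "derived",
                  MISSING_STATE: "missing"}
_TEXT_TO_STATE = {v: k for k, v in _STATE_TO_TEXT.items()}
_TEXT_TO_STATE.update({"0": ANCESTRAL, "1": DERIVED, ".": MISSING_STATE})


def write_genotype_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Wide TSV: position, ref, alt, then one 3-state column per sample;
    a ``group:`` prefix row carries the ingroup/outgroup labels."""
    df = pd.DataFrame({
        "position": matrix.positions,
        "ref": matrix.ref,
        "alt": matrix.alt,
    })
    for i, s in enumerate(matrix.samples):
        df[s] = [_STATE_TO_TEXT[int(v)] for v in matrix.cells[i]]
    with open(path, "w") as fh:
        fh.write("#group\t-\t-\t" +
                 "\t".join(matrix.groups.tolist()) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#group"):
            raise ValueError("matrix file must start with a '#group' row")
        group_fields = header.rstrip("\n").split("\t")[3:]
        df = pd.read_csv(fh, sep="\t", dtype=str)
    samples = list(df.columns[3:])
    if len(group_fields) != len(samples):
        raise ValueError("group row does not match the sample columns")
    cells = np.array(
        [[_TEXT_TO_STATE[str(v)] for v in df[s]] for s in samples],
        dtype=np.int8).reshape(len(samples), len(df))
    return GenotypeMatrix(
        samples=samples,
        groups=np.array(group_fields, dtype="<U8"),
        positions=df["position"].astype(np.int64).to_numpy(),
        ref=df["ref"].to_numpy(dtype="<U1"),
        alt=df["alt"].to_numpy(dtype="<U1"),
        cells=cells,
    )
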