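"""The haplogroup hierarchy: a rooted tree of clade labels.

Y haplogroups form a nested nomenclature (each clade defined by one or
more derived SNP alleles). This module holds the minimal tree container
shared by the assay-coverage statistics (``SNPs within k branches
downstream of a clade``) and the haplogroup caller (root-to-terminal
path search).
"""

from __future__ import annotations

from collections import deque
from collections.abc import Iterable, Mapping
from pathlib import Path


class HaplogroupTree:
    """Rooted tree of haplogroup labels.

    Parameters
    ----------
    parent :
        Mapping ``child label -> parent label``; exactly one label must
        have parent ``None`` (or be absent as a key while appearing as
        a parent) — that label is the root.
    """

    def __init__(self, parent: Mapping[str, str | None]):
        self.parent: dict[str, str | None] = {}
        labels = set(parent)
        for child, par in parent.items():
            self.parent[child] = par
            if par is not None:
                labels.add(par)
        for label in labels:
            self.parent.setdefault(label, None)
        roots = [lab for lab, par in self.parent.items() if par is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {roots}")
        self.root = roots[0]
        self.children: dict[str, list[str]] = {lab: [] for lab in self.parent}
        for child, par in self.parent.items():
            if par is not None:
                if par not in self.parent:
                    raise ValueError(f"unknown parent label {par!r}")
                self.children[par].append(child)
        for kids in self.children.values():
            kids.sort()
        # cycle check: every label must reach the root
        for label in self.parent:
            seen = set()
            cur: str | None = label
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle involving {label!r}")
                seen.add(cur)
                cur = self.parent[cur]
            if self.root not in seen:
                raise ValueError(f"label {label!r} does not reach the root")

    def __contains__(self, label: str) -> bool:
        return label in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def path_from_root(self, label: str) -> list[str]:
        """Labels from the root down to ``label`` inclusive."""
        if label not in self.parent:
            raise KeyError(label)
        path = [label]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])  # type: ignore[arg-type]
        return path[::-1]

    def descendants_within(self, label: str, depth: int) -> set[str]:
        """``label`` plus all descendants at most ``depth`` edges below it."""
        if label not in self.parent:
            raise KeyError(label)
        if depth < 0:
            raise ValueError("depth must be >= 0")
        out = {label}
        frontier = deque([(label, 0)])
        while frontier:
            lab, d = frontier.popleft()
            if d == depth:
                continue
            for child in self.children[lab]:
                out.add(child)
                frontier.append((child, d + 1))
        return out

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "HaplogroupTree":
        """Build from ``(child, parent)`` pairs."""
        return cls({child: parent for child, parent in edges})

    @classmethod
    def read(cls, path: str | Path) -> "HaplogroupTree":
        """Read a two-column (child, parent) TSV; parent '-' or empty
        means root."""
        parent: dict[str, str | None] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) == 1:
                    fields = line.split()
                child = fields[0]
                par = fields[1] if len(fields) > 1 else ""
                parent[child] = None if par in ("", "-", "NA") else par
        return cls(parent)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for child in sorted(self.parent):
                par = self.parent[child]
                fh.write(f"{child}\t{par if par is not None else '-'}\n")
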