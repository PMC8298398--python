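"""Contamination screening via NRY heterozygosity.

A male sample carries a single Y chromosome, so every NRY site should
show one base among its reads. The fraction of covered sites with more
than one distinct base read ("heterozygosity" in the haploid QC sense)
rises with contamination from another male; samples above a small
threshold (default 0.1%) are flagged.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np

from .io import PileupTable, SitePileup

DEFAULT_THRESHOLD = 0.001

__all__ = ["DEFAULT_THRESHOLD", "HetResult", "heterozygosity"]


@dataclass(frozen=True)
class HetResult:
    sample: str
    sites_assessed: int
    het_sites: int
    heterozygosity: float      # NaN when no sites were assessed
    passed: bool
    threshold: float = DEFAULT_THRESHOLD
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.het_sites > self.sites_assessed:
            raise ValueError("het_sites cannot exceed sites_assessed")


def heterozygosity(
    pileup: Mapping[int, SitePileup] | PileupTable,
    min_depth: int = 1,
    threshold: float = DEFAULT_THRESHOLD,
    min_minor_reads: int = 1,
    sample: str = "",
) -> HetResult:
    """Proportion of sites with more than one type of base read.

    Sites with depth >= ``min_depth`` are assessed; a site is
    heterozygous when at least two distinct bases each have
    >= ``min_minor_reads`` reads. The default (1) is the literal
    criterion — any second base makes a site heterozygous; a stricter
    setting damps single-read deamination artefacts. ``passed`` is
    heterozygosity < ``threshold``; with zero assessable sites the
    result fails with a recorded reason.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if min_minor_reads < 1:
        raise ValueError("min_minor_reads must be >= 1")
    if isinstance(pileup, PileupTable):
        depths = pileup.depths
        assessed = depths >= min_depth
        distinct = (pileup.counts >= min_minor_reads).sum(axis=1)
        het = assessed & (distinct >= 2)
        n_assessed = int(assessed.sum())
        n_het = int(het.sum())
    else:
        n_assessed = n_het = 0
        for pos in pileup:
            site = pileup[pos]
            if site.depth < min_depth:
                continue
            n_assessed += 1
            big = sum(1 for c in site.counts.values()
                      if c >= min_minor_reads)
            if big >= 2:
                n_het += 1
    if n_assessed == 0:
        return HetResult(sample, 0, 0, float("nan"), False, threshold,
                         reason="no sites met the depth requirement")
    h = n_het / n_assessed
    return HetResult(sample, n_assessed, n_het, h, h < threshold, threshold)
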