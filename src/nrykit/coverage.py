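"""Capture-assay coverage comparisons and enrichment statistics.

Compares capture assays (a whole-NRY tiling capture, a SNP-panel
capture, plain shotgun) against a haplogroup-SNP catalogue: probe
window expansion, catalogue coverage fractions, per-clade diagnostic
coverage, per-5-million-read normalisation, fold increases with a
location test, endogenous-DNA correlation checks, and the waiting-time
arithmetic that motivates sequencing the NRY at all (one substitution
per lineage roughly every 1/(μ·L) years).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .haplogroups import HaplogroupTree
from .io import SnpRecord, TargetRegions

READS_PER_UNIT = 5_000_000

__all__ = [
    "READS_PER_UNIT",
    "LibraryStats",
    "EnrichmentResult",
    "expand_windows",
    "coverage_fraction",
    "haplogroup_snp_set",
    "normalize_per_unit",
    "fold_increase",
    "enrichment_tests",
    "endogenous_correlation",
    "expected_waiting_years",
    "filter_by_endogenous",
]


@dataclass(frozen=True)
class LibraryStats:
    """Per-library sequencing summary used in assay comparisons."""

    library: str
    mode: str                 # "shotgun" | "snp-panel" | "nry-capture"
    mapped_reads: int
    sites_covered: int = 0
    isogg_snps_covered: int = 0
    endogenous_pct: float = 0.0

    _MODES = ("shotgun", "snp-panel", "nry-capture")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}")
        if min(self.mapped_reads, self.sites_covered,
               self.isogg_snps_covered) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.endogenous_pct <= 100.0:
            raise ValueError("endogenous_pct must be in [0, 100]")


def expand_windows(snps: Sequence[SnpRecord], window_bp: int = 120,
                   chrom: str = "Y", label: str = "") -> TargetRegions:
    """Symmetric probe windows around each SNP, merged.

    A SNP at 1-based ``p`` with window ``w`` contributes the inclusive
    range ``[p - w/2, p + w/2]`` — ``w + 1`` positions before merging
    (the SNP base itself plus ``w/2`` bp flanking on either side,
    mirroring tiled capture probes). ``window_bp`` must be even;
    intervals are clipped at coordinate 0.
    """
    if window_bp < 0 or window_bp % 2:
        raise ValueError("window_bp must be even and >= 0")
    half = window_bp // 2
    pos0 = np.array([s.position - 1 for s in snps], dtype=np.int64)
    starts = np.maximum(pos0 - half, 0)
    ends = pos0 + half + 1
    return TargetRegions.from_intervals(
        chrom, np.column_stack([starts, ends]), label=label)


def coverage_fraction(snps: Sequence[SnpRecord],
                      regions: TargetRegions) -> float:
    """Fraction of catalogue SNPs whose position falls in ``regions``."""
    if len(snps) == 0:
        raise ValueError("coverage fraction undefined for an empty catalogue")
    positions = np.array([s.position for s in snps], dtype=np.int64)
    return float(np.mean(regions.contains(positions)))


def haplogroup_snp_set(tree: HaplogroupTree, snps: Sequence[SnpRecord],
                       root_label: str, depth: int = 3) -> list[SnpRecord]:
    """Catalogue SNPs defining ``root_label`` or clades up to ``depth``
    branches downstream of it (the per-haplogroup diagnostic set)."""
    if root_label not in tree:
        raise KeyError(f"unknown haplogroup {root_label!r}")
    wanted = tree.descendants_within(root_label, depth)
    return [s for s in snps if s.haplogroup in wanted]


def normalize_per_unit(count: float, mapped_reads: int,
                       unit: int = READS_PER_UNIT) -> float:
    """Sites/SNPs covered rescaled to a fixed sequencing effort
    (default: per five million mapped endogenous reads)."""
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be > 0")
    return count * unit / mapped_reads


def fold_increase(normalized_a: float, normalized_b: float) -> float:
    if normalized_b <= 0:
        raise ValueError("denominator must be > 0")
    return normalized_a / normalized_b


@dataclass(frozen=True)
class EnrichmentResult:
    mean_fold: float
    p_value: float
    folds: np.ndarray


def enrichment_tests(
    pairs: Sequence[tuple[float, float]],
    ids: Sequence[str] | None = None,
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Mean fold increase between two sequencing modes plus a one-sample
    t-test of the log fold increases against zero.

    ``pairs`` holds per-library normalised counts ``(mode_a, mode_b)``;
    the fold per library is a/b. Log transformation makes the folds
    symmetric about 0 under the null of no enrichment.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 libraries for the location test")
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    bad = (a <= 0) | (b <= 0)
    if bad.any():
        names = ([ids[i] for i in np.flatnonzero(bad)] if ids is not None
                 else list(np.flatnonzero(bad)))
        raise ValueError(f"non-positive counts for libraries {names}")
    folds = a / b
    logf = np.log(folds)
    if np.allclose(logf, logf[0]):
        # degenerate: identical folds; t statistic undefined
        p = 1.0 if np.isclose(logf[0], 0.0) else 0.0
    else:
        p = float(stats.ttest_1samp(logf, 0.0,
                                    alternative=alternative).pvalue)
    return EnrichmentResult(float(folds.mean()), p, folds)


def endogenous_correlation(endogenous_pct, response,
                           method: str = "pearson") -> tuple[float, float]:
    """Correlation between per-library endogenous-DNA percentage and a
    response (fold increase, SNPs covered, ...), with a two-sided p.

    The product-moment correlation is the default; ``method="spearman"``
    gives the rank alternative. Requires >= 4 libraries and non-constant
    inputs.
    """
    x = np.asarray(endogenous_pct, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(x) != len(y):
        raise ValueError("input lengths differ")
    if len(x) < 4:
        raise ValueError("need >= 4 libraries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r.statistic), float(r.pvalue)


def expected_waiting_years(mu: float, length: int) -> float:
    """Expected years between substitutions on one lineage: 1/(μ·L)."""
    if mu <= 0 or length <= 0:
        raise ValueError("mu and length must be positive")
    return 1.0 / (mu * length)


def filter_by_endogenous(stats_list: Sequence[LibraryStats],
                         min_endogenous_pct: float = 0.1
                         ) -> list[LibraryStats]:
    """Empirical comparisons only use libraries whose shotgun endogenous
    DNA exceeds a floor (default 0.1%)."""
    return [s for s in stats_list if s.endogenous_pct > min_endogenous_pct]
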