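"""Calibrated pairwise TMRCA estimation.

Two haploid lineages that split T years ago accumulate differences
independently, so over n jointly called sites the expected difference
count is d ≈ 2·μ·n·T. The estimator is the standard pairwise-divergence
form

    TMRCA = c · d / (2·n_overlap),

with every rate assumption absorbed into the calibration constant c
(years per unit relative divergence), fitted so that the mean TMRCA of
an outgroup anchor (haplogroup A0 against everything else, split
~161.3 kya) is reproduced exactly. Confidence intervals come from the
exact (Garwood) Poisson interval on the difference count, mapped
through the same linear transform — pairs with fewer overlapping sites
naturally get wider intervals.

Consensus sequences derived from SNP-panel capture are refused by
default: a panel that targets known segregating sites enriches d but
not n, biasing the implied rate upward. Shotgun and whole-NRY capture
data do not share this problem.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .consensus import ConsensusSequence

DEFAULT_ANCHOR_YEARS = 161_300.0
TRANSITION_PAIRS = frozenset({("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")})

__all__ = [
    "DEFAULT_ANCHOR_YEARS",
    "PairwiseTmrca",
    "CalibrationAnchor",
    "CladeSummary",
    "pairwise_differences",
    "make_pair",
    "all_pairs",
    "calibrate",
    "estimate_tmrca",
    "clade_summary",
    "poisson_interval",
]


def pairwise_differences(
    a: ConsensusSequence,
    b: ConsensusSequence,
    exclude_transitions: bool = False,
) -> tuple[int, int]:
    """(n_overlap, d): jointly called sites and differing ones.

    With ``exclude_transitions`` both counts are restricted to
    transversion-comparable mismatch classes: C↔T and G↔A mismatches are
    dropped from d, a damage-robust sensitivity mode.
    """
    # both position arrays are sorted and unique: a searchsorted join
    # beats intersect1d's re-sorting
    if len(a.positions) == 0 or len(b.positions) == 0:
        return 0, 0
    idx = np.searchsorted(b.positions, a.positions)
    idx_c = np.clip(idx, 0, len(b.positions) - 1)
    hit = b.positions[idx_c] == a.positions
    n = int(hit.sum())
    if n == 0:
        return 0, 0
    ba, bb = a.bases[hit], b.bases[idx_c[hit]]
    mismatch = ba != bb
    if exclude_transitions:
        ts = np.zeros(n, dtype=bool)
        for x, y in TRANSITION_PAIRS:
            ts |= (ba == x) & (bb == y)
        mismatch &= ~ts
        n -= int(ts.sum())
    return n, int(mismatch.sum())


@dataclass(frozen=True)
class PairwiseTmrca:
    """Divergence record for one sample pair.

    ``same_site`` marks pairs of individuals from the same sampling
    site (excluded from clade summaries by default, since close kin or
    shared local ancestry would bias split times downward).
    """

    sample_a: str
    sample_b: str
    n_overlap: int
    d: int
    tmrca: float | None = None
    ci: tuple[float, float] | None = None
    same_site: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.d <= max(self.n_overlap, 0):
            raise ValueError("need 0 <= d <= n_overlap")
        if self.ci is not None and self.tmrca is not None:
            lo, hi = self.ci
            if not lo <= self.tmrca <= hi:
                raise ValueError("CI must bracket the estimate")

    @property
    def usable(self) -> bool:
        return self.n_overlap > 0

    @property
    def relative_divergence(self) -> float:
        if self.n_overlap == 0:
            raise ValueError("undefined with no overlapping sites")
        return self.d / (2.0 * self.n_overlap)


def make_pair(a: ConsensusSequence, b: ConsensusSequence,
              same_site: bool = False,
              exclude_transitions: bool = False) -> PairwiseTmrca:
    n, d = pairwise_differences(a, b, exclude_transitions)
    return PairwiseTmrca(a.sample, b.sample, n, d, same_site=same_site)


def all_pairs(
    consensuses: Sequence[ConsensusSequence],
    sources: Mapping[str, str] | None = None,
    sites: Mapping[str, str] | None = None,
    allow_targeted: bool = False,
    exclude_transitions: bool = False,
) -> list[PairwiseTmrca]:
    """All unordered sample pairs.

    ``sources`` maps sample → sequencing mode; samples whose consensus
    came from SNP-panel capture are refused unless ``allow_targeted``
    (targeting known segregating sites upwardly biases the implied
    substitution rate). ``sites`` maps sample → sampling-site label for
    the same-site flag.
    """
    if sources is not None and not allow_targeted:
        panel = sorted(s.sample for s in consensuses
                       if sources.get(s.sample) == "snp-panel")
        if panel:
            raise ValueError(
                f"SNP-panel-derived consensuses refused for TMRCA "
                f"(upwardly biased rate): {panel}; pass "
                f"allow_targeted=True to override")
    out = []
    for i in range(len(consensuses)):
        for j in range(i + 1, len(consensuses)):
            a, b = consensuses[i], consensuses[j]
            same = (sites is not None
                    and sites.get(a.sample) is not None
                    and sites.get(a.sample) == sites.get(b.sample))
            out.append(make_pair(a, b, same_site=same,
                                 exclude_transitions=exclude_transitions))
    return out


@dataclass(frozen=True)
class CalibrationAnchor:
    """Outgroup anchor: label, assumed split time, fitted constant c
    (years per unit relative divergence)."""

    label: str
    anchor_years: float
    c: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("calibration constant must be > 0")


def calibrate(anchor_pairs: Sequence[PairwiseTmrca],
              anchor_years: float = DEFAULT_ANCHOR_YEARS,
              label: str = "A0") -> CalibrationAnchor:
    """Fit c so the mean calibrated TMRCA over the anchor pairs equals
    ``anchor_years`` exactly."""
    usable = [p for p in anchor_pairs if p.usable]
    if not usable:
        raise ValueError("no usable anchor pairs (all have n_overlap == 0)")
    mean_rd = float(np.mean([p.relative_divergence for p in usable]))
    if mean_rd <= 0:
        raise ValueError("anchor pairs show zero divergence; cannot calibrate")
    return CalibrationAnchor(label, float(anchor_years),
                             anchor_years / mean_rd)


def poisson_interval(count: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) two-sided interval for a Poisson mean given one
    observed count."""
    if count < 0:
        raise ValueError("count must be >= 0")
    alpha = 1.0 - level
    lo = 0.0 if count == 0 else chi2.ppf(alpha / 2.0, 2 * count) / 2.0
    hi = chi2.ppf(1.0 - alpha / 2.0, 2 * count + 2) / 2.0
    return float(lo), float(hi)


def estimate_tmrca(pair: PairwiseTmrca,
                   calibration: CalibrationAnchor,
                   ci_level: float = 0.95) -> PairwiseTmrca:
    """Attach the calibrated TMRCA and its CI to a pair."""
    if pair.n_overlap == 0:
        raise ValueError(
            f"pair ({pair.sample_a}, {pair.sample_b}) has no overlapping "
            "sites")
    scale = calibration.c / (2.0 * pair.n_overlap)
    d_lo, d_hi = poisson_interval(pair.d, ci_level)
    return replace(pair, tmrca=scale * pair.d,
                   ci=(scale * d_lo, scale * d_hi))


@dataclass(frozen=True)
class CladeSummary:
    group_a: str
    group_b: str
    mean_tmrca: float
    n_pairs: int
    pairs: tuple[PairwiseTmrca, ...]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"sample_a": p.sample_a, "sample_b": p.sample_b,
             "n_overlap": p.n_overlap, "d": p.d, "tmrca": p.tmrca,
             "ci_low": p.ci[0] if p.ci else None,
             "ci_high": p.ci[1] if p.ci else None}
            for p in self.pairs])


def clade_summary(
    pairs: Sequence[PairwiseTmrca],
    group_of: Mapping[str, str],
    group_a: str,
    group_b: str,
    exclude_same_site: bool = True,
) -> CladeSummary:
    """Mean TMRCA over cross-group pairs (one sample in each clade),
    optionally dropping pairs of individuals from the same sampling
    site. Pairs must already carry estimates."""
    cross = [
        p for p in pairs
        if {group_of.get(p.sample_a), group_of.get(p.sample_b)}
        == {group_a, group_b}
    ]
    retained = [p for p in cross
                if not (exclude_same_site and p.same_site)]
    if not retained:
        if cross:
            raise ValueError(
                f"all {len(cross)} {group_a}–{group_b} pairs were excluded "
                "by the same-sampling-site filter")
        raise ValueError(f"no {group_a}–{group_b} pairs available")
    missing = [p for p in retained if p.tmrca is None]
    if missing:
        raise ValueError("pairs lack TMRCA estimates; run estimate_tmrca")
    return CladeSummary(group_a, group_b,
                        float(np.mean([p.tmrca for p in retained])),
                        len(retained), tuple(retained))
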