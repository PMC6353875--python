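"""Trimmed-threshold significance classification of endpoint CSPs.

A residue's endpoint Δδ is called significant when it exceeds the mean
plus 1.00 sample standard deviations of the assigned, non-broadened
population computed *after* removing the ceil(10%) largest values — the
trimming keeps genuinely shifted binding-site residues from inflating
their own threshold. Two tiers are reported: > mean + 1.0·SD and
> mean + 1.5·SD. Trimmed residues are still classified against the
thresholds (trimming affects only the statistics, not eligibility).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .csp import ASSIGNED, ResidueCSP
from .errors import InputError

__all__ = [
    "SignificanceResult",
    "classify_significance",
    "write_significance_table",
    "NOT_SIGNIFICANT",
    "GE_1SD",
    "GE_1P5SD",
    "TIER_ORDER",
]

NOT_SIGNIFICANT = "not_significant"
GE_1SD = "ge_1sd"
GE_1P5SD = "ge_1p5sd"
TIER_ORDER = (NOT_SIGNIFICANT, GE_1SD, GE_1P5SD)

#: minimum population of assigned, non-broadened residues
MIN_POPULATION = 5

TRIM_FRACTION = 0.10


@dataclass(frozen=True)
class SignificanceResult:
    threshold_1sd: float  # ppm, mean + 1.0 SD of the trimmed population
    threshold_1p5sd: float  # ppm, mean + 1.5 SD
    population_mean: float
    population_sd: float
    trimmed_residues: frozenset[int]
    tier: Mapping[int, str]  # residue -> tier, over assigned residues only
    endpoint_csp: Mapping[int, float]

    @property
    def significant(self) -> frozenset[int]:
        """Residues above the 1.0-SD threshold (includes the 1.5-SD tier)."""
        return frozenset(r for r, t in self.tier.items() if t != NOT_SIGNIFICANT)

    def at_tier(self, tier: str) -> frozenset[int]:
        """Residues at or above ``tier`` (ge_1sd or ge_1p5sd)."""
        if tier not in (GE_1SD, GE_1P5SD):
            raise InputError(f"unknown tier {tier!r}")
        if tier == GE_1SD:
            return self.significant
        return frozenset(r for r, t in self.tier.items() if t == GE_1P5SD)


def classify_significance(csps: Iterable[ResidueCSP]) -> SignificanceResult:
    """Apply the trimmed mean + k·SD rule to endpoint CSPs.

    Population: endpoint Δδ of assigned residues only (prolines,
    unassigned and broadened residues are excluded from the statistics
    and receive no tier). Trim count is ceil(0.10·n), ties at the trim
    boundary broken toward the lower residue number. SD is the sample
    (n−1) standard deviation. Comparisons are strict (>), so a
    zero-variance population yields no significant residues.
    """
    pop = sorted(
        (r for r in csps if r.status == ASSIGNED),
        key=lambda r: r.residue_number,
    )
    n = len(pop)
    if n < MIN_POPULATION:
        raise InputError(
            f"need at least {MIN_POPULATION} assigned, non-broadened residues, got {n}"
        )

    # largest first; ties by residue number for a deterministic trim set
    by_size = sorted(pop, key=lambda r: (-r.endpoint_csp, r.residue_number))
    k = math.ceil(TRIM_FRACTION * n)
    trimmed = frozenset(r.residue_number for r in by_size[:k])
    kept = np.array([r.endpoint_csp for r in by_size[k:]])

    mean = float(np.mean(kept))
    sd = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
    thr1 = mean + 1.0 * sd
    thr15 = mean + 1.5 * sd

    tier: dict[int, str] = {}
    endpoint: dict[int, float] = {}
    for r in pop:
        v = r.endpoint_csp
        endpoint[r.residue_number] = v
        if v > thr15:
            tier[r.residue_number] = GE_1P5SD
        elif v > thr1:
            tier[r.residue_number] = GE_1SD
        else:
            tier[r.residue_number] = NOT_SIGNIFICANT

    return SignificanceResult(
        threshold_1sd=thr1,
        threshold_1p5sd=thr15,
        population_mean=mean,
        population_sd=sd,
        trimmed_residues=trimmed,
        tier=tier,
        endpoint_csp=endpoint,
    )


def write_significance_table(result: SignificanceResult, path: str | Path) -> None:
    lines = [
        f"# population_mean\t{result.population_mean:.6f}",
        f"# population_sd\t{result.population_sd:.6f}",
        f"# threshold_1sd\t{result.threshold_1sd:.6f}",
        f"# threshold_1p5sd\t{result.threshold_1p5sd:.6f}",
        "residue_number\tendpoint_csp\ttier\ttrimmed",
    ]
    for resnum in sorted(result.tier):
        lines.append(
            f"{resnum}\t{result.endpoint_csp[resnum]:.6f}\t{result.tier[resnum]}\t"
            f"{int(resnum in result.trimmed_residues)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
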