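"""Map significance tiers onto a residue-range annotation of the construct.

The default annotation describes the EZH2 SRM-SANT1 construct (residues
141-251): the SRM helix, the SRM-SANT1 linker, the three SANT1 helices
(α1 168-178, α2 221-230, α3 237-247) and the intervening loops. The
helix boundaries come from the construct's secondary structure; the SRM
C-terminal boundary is approximate and overridable via an annotation
file (3 columns: name, start, end, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import InputError
from .significance import SignificanceResult, TIER_ORDER

__all__ = [
    "Region",
    "RegionAnnotation",
    "DEFAULT_SRM_SANT1",
    "read_annotation",
    "classify_regions",
    "write_region_table",
    "UNANNOTATED",
]

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class Region:
    name: str
    start: int  # inclusive
    end: int  # inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"region {self.name}: start {self.start} > end {self.end}")

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass(frozen=True)
class RegionAnnotation:
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.regions, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise InputError(f"regions {a.name} and {b.name} overlap")

    @property
    def bounds(self) -> tuple[int, int]:
        return min(r.start for r in self.regions), max(r.end for r in self.regions)

    def region_of(self, residue: int) -> str:
        lo, hi = self.bounds
        if not lo <= residue <= hi:
            raise InputError(
                f"residue {residue} outside construct bounds {lo}-{hi}"
            )
        for r in self.regions:
            if residue in r:
                return r.name
        return UNANNOTATED


DEFAULT_SRM_SANT1 = RegionAnnotation(
    regions=(
        Region("SRM", 141, 158),
        Region("linker", 159, 167),
        Region("alpha1", 168, 178),
        Region("alpha1-alpha2_loop", 179, 220),
        Region("alpha2", 221, 230),
        Region("alpha2-alpha3_loop", 231, 236),
        Region("alpha3", 237, 247),
        Region("C-term", 248, 251),
    )
)


def read_annotation(path: str | Path) -> RegionAnnotation:
    """Read a 3-column (name, start, end) annotation; '#' comments allowed."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    regions: list[Region] = []
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise InputError(f"{path}:{line_no}: expected 'name start end'")
        try:
            regions.append(Region(fields[0], int(fields[1]), int(fields[2])))
        except ValueError:
            raise InputError(f"{path}:{line_no}: non-integer boundary") from None
    if not regions:
        raise InputError(f"{path}: no regions found")
    return RegionAnnotation(tuple(regions))


def classify_regions(
    result: SignificanceResult,
    ann: RegionAnnotation = DEFAULT_SRM_SANT1,
) -> pd.DataFrame:
    """Count classified residues per (region, tier).

    Every classified residue lands in exactly one region (or the
    implicit ``unannotated`` bin); residues outside the construct bounds
    raise. Rows are regions in annotation order, columns the tiers plus
    a total; the counts partition the classified residues.
    """
    names = [r.name for r in ann.regions] + [UNANNOTATED]
    counts = pd.DataFrame(0, index=names, columns=list(TIER_ORDER), dtype=int)
    for resnum, tier in result.tier.items():
        counts.loc[ann.region_of(resnum), tier] += 1
    counts["total"] = counts.sum(axis=1)
    counts.index.name = "region"
    return counts


def write_region_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")
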