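"""Strand-aware proximity overlap of ChIP-seq peak sets.

Two peaks co-occur when they sit on the same chromosome, their strands
are compatible, and the gap between them is at most ``max_gap`` base
pairs (default 150). Coordinates follow the BED convention: 0-based,
half-open, so touching intervals have gap 0 and

    gap = max(0, max(start_a, start_b) - min(end_a, end_b)).

Strand compatibility: by default "." (unstranded, the usual case for
ChIP-seq peaks) matches anything and explicit strands must agree;
``strict=True`` requires exact strand equality instead. Setting
``same_strand=False`` ignores strand entirely.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import InputError

__all__ = [
    "GenomicPeak",
    "OverlapSummary",
    "read_bed",
    "write_bed",
    "overlap_peaks",
    "gap_between",
    "write_pairs",
    "write_overlap_summary",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicPeak:
    """A BED interval: 0-based half-open [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InputError("peak chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise InputError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise InputError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    a_with_b: int  # A peaks with >= 1 qualifying partner in B
    b_with_a: int
    pairs: int  # qualifying (a, b) pairs

    @property
    def a_only(self) -> int:
        return self.n_a - self.a_with_b

    @property
    def b_only(self) -> int:
        return self.n_b - self.b_with_a


def read_bed(path: str | Path) -> tuple[GenomicPeak, ...]:
    """Read BED3+; strand from column 6 when present, else '.'."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"BED file not found: {path}")
    peaks: list[GenomicPeak] = []
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise InputError(f"{path}:{line_no}: BED needs >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise InputError(f"{path}:{line_no}: non-integer coordinates") from None
        strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
        try:
            peaks.append(GenomicPeak(fields[0], start, end, strand))
        except InputError as exc:
            raise InputError(f"{path}:{line_no}: {exc}") from None
    return tuple(peaks)


def write_bed(peaks: Iterable[GenomicPeak], path: str | Path) -> None:
    lines = [f"{p.chrom}\t{p.start}\t{p.end}\t.\t0\t{p.strand}" for p in peaks]
    Path(path).write_text("\n".join(lines) + "\n")


def gap_between(a: GenomicPeak, b: GenomicPeak) -> int | None:
    """Base-pair gap between two peaks; None for different chromosomes."""
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _strand_ok(sa: str, sb: str, strict: bool) -> bool:
    if strict:
        return sa == sb
    return sa == "." or sb == "." or sa == sb


def overlap_peaks(
    a: Sequence[GenomicPeak],
    b: Sequence[GenomicPeak],
    max_gap: int = 150,
    same_strand: bool = True,
    strict: bool = False,
    return_pairs: bool = False,
):
    """Count qualifying pairs under the distance + strand rule.

    A pair qualifies iff same chromosome, compatible strands and
    gap <= ``max_gap``. Returns an :class:`OverlapSummary`, or
    ``(summary, pairs)`` with the qualifying index pairs when
    ``return_pairs`` is true. Per-chromosome sweep over B sorted by
    start; candidate partners are located by binary search on
    start_b <= end_a + max_gap and filtered on the symmetric condition.
    """
    if not a or not b:
        raise InputError("both peak sets must be non-empty")
    if max_gap < 0:
        raise InputError(f"max_gap must be >= 0, got {max_gap}")

    by_chrom: dict[str, list[int]] = defaultdict(list)
    for j, pb in enumerate(b):
        by_chrom[pb.chrom].append(j)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda j: b[j].start)

    a_hit = [False] * len(a)
    b_hit = [False] * len(b)
    pairs: list[tuple[int, int]] = []
    for i, pa in enumerate(a):
        idx = by_chrom.get(pa.chrom)
        if not idx:
            continue
        starts = [b[j].start for j in idx]
        hi = bisect_right(starts, pa.end + max_gap)
        for j in idx[:hi]:
            pb = b[j]
            if pb.end < pa.start - max_gap:
                continue
            if same_strand and not _strand_ok(pa.strand, pb.strand, strict):
                continue
            a_hit[i] = True
            b_hit[j] = True
            pairs.append((i, j))

    summary = OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        a_with_b=sum(a_hit),
        b_with_a=sum(b_hit),
        pairs=len(pairs),
    )
    return (summary, pairs) if return_pairs else summary


def write_pairs(
    a: Sequence[GenomicPeak],
    b: Sequence[GenomicPeak],
    pairs: Iterable[tuple[int, int]],
    path: str | Path,
) -> None:
    """BEDPE-like pair list: both intervals plus their gap."""
    lines = []
    for i, j in pairs:
        pa, pb = a[i], b[j]
        lines.append(
            f"{pa.chrom}\t{pa.start}\t{pa.end}\t{pb.chrom}\t{pb.start}\t{pb.end}\t"
            f"{pa.strand}\t{pb.strand}\t{gap_between(pa, pb)}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_overlap_summary(summary: OverlapSummary, path: str | Path) -> None:
    lines = [
        "metric\tcount",
        f"n_a\t{summary.n_a}",
        f"n_b\t{summary.n_b}",
        f"a_with_b\t{summary.a_with_b}",
        f"b_with_a\t{summary.b_with_a}",
        f"a_only\t{summary.a_only}",
        f"b_only\t{summary.b_only}",
        f"pairs\t{summary.pairs}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
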