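"""Docking-restraint export from CSP significance.

Significantly perturbed residues become *active* residues of the
protein (chain A); the peptide residues offered by the user become the
active set of chain B. Each chain-A residue is paired with the
disjunction of all chain-B residues in an ambiguous interaction
restraint (AIR): the restraint is satisfied when the residue is close
to *any* partner residue. Restraints are written as CNS-style assign
statements, one line per chain-A residue::

    assign (segid A and resid 172) ((segid B and resid 15) or ...) 2.0 2.0 0.0

with the three trailing numbers the target distance d, the minus bound
(d − dist_lower) and the plus bound (dist_upper − d = 0), i.e. an
effective-distance window [dist_lower, dist_upper]. An active-residue
JSON sidecar accompanies the table.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import InputError
from .significance import GE_1SD, SignificanceResult

__all__ = [
    "RestraintSpec",
    "build_restraints",
    "write_air_table",
    "read_air_table",
    "write_active_sidecar",
]


@dataclass(frozen=True)
class RestraintSpec:
    active_a: tuple[int, ...]  # protein (chain A) residues
    active_b: tuple[int, ...]  # peptide (chain B) residues
    dist_lower: float = 0.0  # Angstrom
    dist_upper: float = 2.0  # Angstrom, effective-distance upper bound

    def __post_init__(self) -> None:
        if not self.active_a:
            raise InputError("active_a must be non-empty")
        if not self.active_b:
            raise InputError("active_b must be non-empty")
        if self.dist_lower > self.dist_upper:
            raise InputError(
                f"dist_lower {self.dist_lower} > dist_upper {self.dist_upper}"
            )


def build_restraints(
    result: SignificanceResult,
    partner_residues: Iterable[int],
    tier: str = GE_1SD,
    active_override: Iterable[int] | None = None,
    dist_lower: float = 0.0,
    dist_upper: float = 2.0,
) -> RestraintSpec:
    """Derive the active sets: CSP tier on chain A, user list on chain B.

    ``tier`` selects which significance tier (and above) defines the
    chain-A actives; ``active_override`` replaces the CSP-derived list
    entirely (e.g. to reproduce a manually curated active set). An empty
    significant set is an error pointing at the override.
    """
    partner = tuple(sorted(set(int(r) for r in partner_residues)))
    if active_override is not None:
        active_a = tuple(sorted(set(int(r) for r in active_override)))
    else:
        active_a = tuple(sorted(result.at_tier(tier)))
        if not active_a:
            raise InputError(
                "no residues at the requested significance tier; "
                "supply active_override to set the active residues manually"
            )
    return RestraintSpec(active_a, partner, dist_lower, dist_upper)


def write_air_table(spec: RestraintSpec, path: str | Path) -> None:
    """One ambiguous restraint line per chain-A active residue."""
    lines = []
    partner = " or ".join(f"(segid B and resid {r})" for r in spec.active_b)
    d = spec.dist_upper
    dminus = spec.dist_upper - spec.dist_lower
    for r in spec.active_a:
        lines.append(
            f"assign (segid A and resid {r}) ({partner}) {d:.1f} {dminus:.1f} 0.0"
        )
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write restraint table to {path}: {exc}") from exc


_ASSIGN = re.compile(
    r"^assign \(segid A and resid (\d+)\) \((.*)\) "
    r"([0-9.]+) ([0-9.]+) ([0-9.]+)$"
)
_PARTNER = re.compile(r"\(segid B and resid (\d+)\)")


def read_air_table(path: str | Path) -> RestraintSpec:
    """Parse back a written AIR table (round-trips :func:`write_air_table`)."""
    active_a: list[int] = []
    active_b: tuple[int, ...] | None = None
    d = dminus = None
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _ASSIGN.match(line)
        if m is None:
            raise InputError(f"{path}:{line_no}: unparseable restraint line")
        active_a.append(int(m.group(1)))
        partners = tuple(int(x) for x in _PARTNER.findall(m.group(2)))
        if active_b is None:
            active_b = partners
        elif partners != active_b:
            raise InputError(f"{path}:{line_no}: inconsistent partner set")
        d, dminus = float(m.group(3)), float(m.group(4))
    if not active_a or active_b is None:
        raise InputError(f"{path}: no restraints found")
    return RestraintSpec(
        tuple(active_a), active_b, dist_lower=d - dminus, dist_upper=d
    )


def write_active_sidecar(spec: RestraintSpec, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "active_a": list(spec.active_a),
                "active_b": list(spec.active_b),
                "passive_a": [],
                "passive_b": [],
                "dist_lower_A": spec.dist_lower,
                "dist_upper_A": spec.dist_upper,
            },
            indent=2,
        )
        + "\n"
    )
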