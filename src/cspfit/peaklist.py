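"""Assigned amide peak lists and titration designs.

A titration is a sequence of 2-D ¹H-¹⁵N HSQC peak lists collected on a
fixed protein while a ligand is added stepwise. Each peak list assigns
one amide cross-peak (δH, δN) to a residue of the construct; peaks that
broaden beyond detection at a given point are recorded with the ``NA``
sentinel and carry ``present=False``.

Two text dialects are read:

* ``tsv`` — four whitespace/tab-separated columns:
  ``residue_number  residue_type  delta_H_ppm  delta_N_ppm``
  (an optional header line and ``#`` comments are skipped);
* ``sparky`` — Sparky-style ¹⁵N-HSQC lists, ``V172N-H  w1  w2`` with
  w1 = δN and w2 = δH (the native axis order of an ¹⁵N-HSQC list).

The titration design is a YAML file::

    protein_name: SRM-SANT1
    ligand_name: H4(1-21)
    protein_conc: 0.1          # mM
    dialect: tsv               # optional, default tsv
    points:
      - peaklist: point00.tsv
        molar_ratio: 0         # or ligand_conc: 0.0 (mM)
      - peaklist: point01.tsv
        molar_ratio: 1
        protein_conc: 0.095    # optional per-point dilution override

Peak-list paths are resolved relative to the config file. Concentrations
are millimolar throughout. The first point must be the apo reference
(zero ligand) and ligand concentrations must increase strictly.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import InputError

__all__ = [
    "Peak",
    "TitrationPoint",
    "TitrationSeries",
    "read_peaklist",
    "write_peaklist",
    "read_titration",
]

#: plausible amide shift windows (ppm); outside -> warning, not error
H_RANGE = (5.0, 12.0)
N_RANGE = (100.0, 135.0)

MIN_POINTS = 3

_SENTINEL = "NA"


@dataclass(frozen=True)
class Peak:
    """One assigned amide cross-peak.

    ``delta_H``/``delta_N`` are ppm; both are ``None`` when the peak is
    broadened beyond detection at this titration point (``present=False``).
    """

    residue_number: int
    residue_type: str
    delta_H: float | None
    delta_N: float | None
    present: bool = True

    def __post_init__(self) -> None:
        if self.present:
            if self.delta_H is None or self.delta_N is None:
                raise InputError(
                    f"residue {self.residue_number}: present peak lacks shift values"
                )
            if not (math.isfinite(self.delta_H) and math.isfinite(self.delta_N)):
                raise InputError(
                    f"residue {self.residue_number}: non-finite chemical shift"
                )
            if not (H_RANGE[0] <= self.delta_H <= H_RANGE[1]):
                warnings.warn(
                    f"residue {self.residue_number}: delta_H={self.delta_H} ppm "
                    f"outside the usual amide window {H_RANGE}",
                    stacklevel=2,
                )
            if not (N_RANGE[0] <= self.delta_N <= N_RANGE[1]):
                warnings.warn(
                    f"residue {self.residue_number}: delta_N={self.delta_N} ppm "
                    f"outside the usual amide window {N_RANGE}",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class TitrationPoint:
    """One HSQC spectrum: ligand/protein concentrations plus its peak list."""

    ligand_conc: float  # mM, [L]
    protein_conc: float  # mM, [P]
    peaks: tuple[Peak, ...]
    molar_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.protein_conc <= 0:
            raise InputError(f"protein_conc must be > 0, got {self.protein_conc}")
        if self.ligand_conc < 0:
            raise InputError(f"ligand_conc must be >= 0, got {self.ligand_conc}")
        if self.molar_ratio is not None:
            implied = self.ligand_conc / self.protein_conc
            if not math.isclose(self.molar_ratio, implied, rel_tol=1e-6, abs_tol=1e-6):
                raise InputError(
                    f"molar_ratio {self.molar_ratio} inconsistent with "
                    f"ligand_conc/protein_conc = {implied:g}"
                )
        seen: set[int] = set()
        for p in self.peaks:
            if p.residue_number in seen:
                raise InputError(f"duplicate residue {p.residue_number} in peak list")
            seen.add(p.residue_number)

    def peak_for(self, residue_number: int) -> Peak | None:
        for p in self.peaks:
            if p.residue_number == residue_number:
                return p
        return None


@dataclass(frozen=True)
class TitrationSeries:
    """Ordered titration points, apo (zero ligand) first."""

    points: tuple[TitrationPoint, ...]
    protein_name: str = ""
    ligand_name: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < MIN_POINTS:
            raise InputError(
                f"titration needs at least {MIN_POINTS} points, got {len(self.points)}"
            )
        if self.points[0].ligand_conc != 0:
            raise InputError("first titration point must be the apo reference ([L]=0)")
        concs = [p.ligand_conc for p in self.points]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise InputError(
                f"ligand concentrations must increase strictly, got {concs}"
            )

    @property
    def apo(self) -> TitrationPoint:
        return self.points[0]

    @property
    def ligand_concs(self) -> tuple[float, ...]:
        return tuple(p.ligand_conc for p in self.points)

    @property
    def protein_concs(self) -> tuple[float, ...]:
        return tuple(p.protein_conc for p in self.points)


# ---------------------------------------------------------------------------
# peak-list I/O

_SPARKY_ASSIGN = re.compile(r"^([A-Za-z])(\d+)N-?H$")


def _parse_shift(token: str, line_no: int, path: Path) -> float | None:
    if token.upper() == _SENTINEL:
        return None
    try:
        return float(token)
    except ValueError:
        raise InputError(
            f"{path}:{line_no}: cannot parse chemical shift {token!r}"
        ) from None


def read_peaklist(path: str | Path, dialect: str = "tsv") -> tuple[Peak, ...]:
    """Read an assigned peak list; row order is preserved.

    ``NA`` in both shift columns marks a peak broadened beyond detection
    (``present=False``). Duplicate residue numbers, missing columns and
    unparseable rows raise :class:`InputError` naming the offender.
    """
    path = Path(path)
    if dialect not in ("tsv", "sparky"):
        raise InputError(f"unknown peak-list dialect {dialect!r}")
    if not path.exists():
        raise InputError(f"peak list not found: {path}")

    peaks: list[Peak] = []
    seen: set[int] = set()
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if dialect == "tsv":
            if line_no == 1 and not _is_int(fields[0]):
                continue  # header row
            if len(fields) < 4:
                raise InputError(
                    f"{path}:{line_no}: expected 4 columns "
                    "(residue_number residue_type delta_H delta_N), "
                    f"got {len(fields)}"
                )
            if not _is_int(fields[0]):
                raise InputError(
                    f"{path}:{line_no}: residue_number {fields[0]!r} is not an integer"
                )
            resnum = int(fields[0])
            restype = fields[1]
            dh = _parse_shift(fields[2], line_no, path)
            dn = _parse_shift(fields[3], line_no, path)
        else:  # sparky
            if fields[0].lower() == "assignment":
                continue  # header row
            m = _SPARKY_ASSIGN.match(fields[0])
            if m is None:
                raise InputError(
                    f"{path}:{line_no}: cannot parse assignment {fields[0]!r} "
                    "(expected e.g. V172N-H)"
                )
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{line_no}: expected 'assignment w1 w2', got {len(fields)} fields"
                )
            restype = m.group(1).upper()
            resnum = int(m.group(2))
            dn = _parse_shift(fields[1], line_no, path)  # w1 = 15N
            dh = _parse_shift(fields[2], line_no, path)  # w2 = 1H

        if resnum in seen:
            raise InputError(f"{path}:{line_no}: duplicate residue {resnum}")
        seen.add(resnum)
        present = dh is not None and dn is not None
        peaks.append(
            Peak(resnum, restype, dh if present else None, dn if present else None,
                 present=present)
        )
    return tuple(peaks)


def write_peaklist(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks in the canonical 4-column TSV dialect (round-trips exactly)."""
    lines = ["# residue_number\tresidue_type\tdelta_H\tdelta_N"]
    for p in peaks:
        if p.present:
            lines.append(f"{p.residue_number}\t{p.residue_type}\t{p.delta_H!r}\t{p.delta_N!r}")
        else:
            lines.append(f"{p.residue_number}\t{p.residue_type}\t{_SENTINEL}\t{_SENTINEL}")
    Path(path).write_text("\n".join(lines) + "\n")


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# titration design

def read_titration(config_path: str | Path) -> TitrationSeries:
    """Load a titration design (YAML, schema in the module docstring)."""
    config_path = Path(config_path)
    if not config_path.exists():
        raise InputError(f"titration config not found: {config_path}")
    try:
        cfg = yaml.safe_load(config_path.read_text())
    except yaml.YAMLError as exc:
        raise InputError(f"{config_path}: invalid YAML: {exc}") from exc
    if not isinstance(cfg, dict):
        raise InputError(f"{config_path}: config must be a mapping")

    try:
        protein_conc = float(cfg["protein_conc"])
    except KeyError:
        raise InputError(f"{config_path}: missing required key 'protein_conc'") from None
    dialect = cfg.get("dialect", "tsv")
    entries = cfg.get("points")
    if not isinstance(entries, list) or not entries:
        raise InputError(f"{config_path}: 'points' must be a non-empty list")

    base = config_path.parent
    points: list[TitrationPoint] = []
    for i, entry in enumerate(entries):
        if "peaklist" not in entry:
            raise InputError(f"{config_path}: point {i} lacks 'peaklist'")
        peaks = read_peaklist(base / entry["peaklist"], dialect=dialect)
        p_conc = float(entry.get("protein_conc", protein_conc))
        if "ligand_conc" in entry:
            l_conc = float(entry["ligand_conc"])
            ratio = float(entry["molar_ratio"]) if "molar_ratio" in entry else l_conc / p_conc
        elif "molar_ratio" in entry:
            ratio = float(entry["molar_ratio"])
            l_conc = ratio * p_conc
        else:
            raise InputError(
                f"{config_path}: point {i} needs 'ligand_conc' or 'molar_ratio'"
            )
        points.append(TitrationPoint(l_conc, p_conc, peaks, molar_ratio=ratio))

    return TitrationSeries(
        points=tuple(points),
        protein_name=str(cfg.get("protein_name", "")),
        ligand_name=str(cfg.get("ligand_name", "")),
    )
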