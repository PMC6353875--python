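"""Normalized chemical shift perturbations.

The combined amide CSP collapses the 2-D peak displacement into a single
non-negative ppm value,

    Δδ = sqrt(ΔδH² + (w · ΔδN)²),      w = 0.20 by default,

where ΔδH and ΔδN are the ¹H and ¹⁵N shift changes relative to the apo
spectrum and the weight w compensates for the ~5× wider dispersion of
the nitrogen dimension. Every titration point is differenced against the
apo reference; the endpoint Δδ (apo vs final point) is the quantity used
downstream for significance classification, while the full per-point
trajectory feeds the binding-isotherm fits.

Residue status:

* ``assigned``  — usable apo peak, observed at every point;
* ``broadened`` — observed in apo but absent from some later point
  (intermediate-exchange broadening); the trajectory is undefined from
  the first absent point onward;
* ``proline``   — no backbone amide, never observed;
* ``unassigned`` — no usable apo reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError
from .peaklist import TitrationSeries

__all__ = [
    "CSPConfig",
    "ResidueCSP",
    "normalized_csp",
    "compute_csps",
    "write_csp_table",
    "ASSIGNED",
    "BROADENED",
    "PROLINE",
    "UNASSIGNED",
]

ASSIGNED = "assigned"
BROADENED = "broadened"
PROLINE = "proline"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CSPConfig:
    """Normalization settings. ``nitrogen_weight`` scales ΔδN (default 0.20)."""

    nitrogen_weight: float = 0.20

    def __post_init__(self) -> None:
        if not self.nitrogen_weight > 0:
            raise InputError(f"nitrogen_weight must be > 0, got {self.nitrogen_weight}")


def normalized_csp(dH, dN, cfg: CSPConfig = CSPConfig()):
    """Combined CSP sqrt(dH² + (w·dN)²) in ppm; accepts scalars or arrays.

    Even in both arguments and non-negative. Non-finite input raises.
    """
    dH = np.asarray(dH, dtype=float)
    dN = np.asarray(dN, dtype=float)
    if not (np.all(np.isfinite(dH)) and np.all(np.isfinite(dN))):
        raise InputError("normalized_csp requires finite shift differences")
    out = np.hypot(dH, cfg.nitrogen_weight * dN)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ResidueCSP:
    """Per-residue CSP trajectory across titration points.

    Trajectories are arrays of length n_points with NaN where undefined
    (broadened points). ``endpoint_csp`` is the last defined Δδ.
    """

    residue_number: int
    residue_type: str
    status: str
    delta_H_traj: np.ndarray = field(default_factory=lambda: np.empty(0))
    delta_N_traj: np.ndarray = field(default_factory=lambda: np.empty(0))
    csp_traj: np.ndarray = field(default_factory=lambda: np.empty(0))
    endpoint_csp: float = float("nan")
    first_absent: int | None = None  # point index of first broadened point

    @property
    def n_defined(self) -> int:
        return int(np.sum(~np.isnan(self.csp_traj)))


def compute_csps(
    series: TitrationSeries,
    cfg: CSPConfig = CSPConfig(),
    construct: tuple[int, int] | None = None,
) -> list[ResidueCSP]:
    """Difference every titration point against the apo reference.

    One :class:`ResidueCSP` per residue in the apo peak list, ordered by
    residue number. A residue observed at a later point but not in apo is
    an error (there is nothing to reference it to). When ``construct``
    (first, last residue) is given, residues of the construct with no apo
    peak are emitted with status ``unassigned`` so that plots and tables
    can show the full sequence.
    """
    apo = series.apo
    n_pts = len(series.points)
    apo_residues = {p.residue_number for p in apo.peaks}
    for pt in series.points[1:]:
        for p in pt.peaks:
            if p.residue_number not in apo_residues:
                raise InputError(
                    f"residue {p.residue_number} appears at [L]={pt.ligand_conc} mM "
                    "but has no apo reference peak"
                )

    out: list[ResidueCSP] = []
    for ref in sorted(apo.peaks, key=lambda p: p.residue_number):
        resnum, restype = ref.residue_number, ref.residue_type
        if restype.upper() == "P":
            out.append(ResidueCSP(resnum, restype, PROLINE))
            continue
        if not ref.present:
            out.append(ResidueCSP(resnum, restype, UNASSIGNED))
            continue

        dH = np.full(n_pts, np.nan)
        dN = np.full(n_pts, np.nan)
        first_absent: int | None = None
        for i, pt in enumerate(series.points):
            peak = ref if i == 0 else pt.peak_for(resnum)
            if peak is None or not peak.present:
                first_absent = i
                break
            dH[i] = peak.delta_H - ref.delta_H
            dN[i] = peak.delta_N - ref.delta_N
        defined = slice(0, first_absent) if first_absent is not None else slice(None)
        csp = np.full(n_pts, np.nan)
        csp[defined] = normalized_csp(dH[defined], dN[defined], cfg)
        endpoint = csp[first_absent - 1] if first_absent is not None else csp[-1]
        status = BROADENED if first_absent is not None else ASSIGNED
        out.append(
            ResidueCSP(resnum, restype, status, dH, dN, csp,
                       float(endpoint), first_absent)
        )

    if construct is not None:
        lo, hi = construct
        present = {r.residue_number for r in out}
        for resnum in range(lo, hi + 1):
            if resnum not in present:
                out.append(ResidueCSP(resnum, "X", UNASSIGNED))
        out.sort(key=lambda r: r.residue_number)
    return out


def write_csp_table(csps: Sequence[ResidueCSP], path: str | Path) -> None:
    """Per-residue TSV: status, per-point ΔδH/ΔδN/Δδ and endpoint Δδ."""
    n_pts = max((len(r.csp_traj) for r in csps), default=0)
    header = ["residue_number", "residue_type", "status"]
    header += [f"dH_{i}" for i in range(n_pts)]
    header += [f"dN_{i}" for i in range(n_pts)]
    header += [f"csp_{i}" for i in range(n_pts)]
    header += ["endpoint_csp"]
    lines = ["\t".join(header)]

    def fmt(x: float) -> str:
        return "NA" if math.isnan(x) else f"{x:.6f}"

    for r in csps:
        row = [str(r.residue_number), r.residue_type, r.status]
        for traj in (r.delta_H_traj, r.delta_N_traj, r.csp_traj):
            vals = list(traj) + [float("nan")] * (n_pts - len(traj))
            row += [fmt(v) for v in vals]
        row.append(fmt(r.endpoint_csp))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
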