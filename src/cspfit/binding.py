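"""One-site binding with ligand depletion: per-residue Kd fits and the
global-Kd aggregation rules.

At the millimolar protein concentrations of an HSQC titration the bound
ligand is a non-negligible fraction of the total, so the observed CSP
follows the quadratic (ligand-depletion) isotherm rather than the simple
hyperbola:

    Δδ = Δδmax · ( (L + P + Kd) − sqrt((L + P + Kd)² − 4·P·L) ) / (2·P)

with L, P, Kd in the same concentration units (mM here) and Δδmax the
normalized CSP at saturation. Each residue's trajectory is fitted for
(Kd, Δδmax) by bounded trust-region least squares.

The global affinity is the mean over the per-residue Kd values of the
significantly perturbed residues, after a one-pass exclusion of
residues ≥ 2 sample SD from the mean. When half or more of the residues
are excluded, or when more than half of the fits never approach
saturation (fraction bound at the final point below the cutoff), the
affinity is underdetermined and is reported as a lower limit
"> min(Kd)" instead of a mean ± SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import lmfit
import numpy as np

from .csp import ResidueCSP
from .errors import FitError, InputError
from .peaklist import TitrationSeries

__all__ = [
    "FitConfig",
    "BindingFit",
    "GlobalKd",
    "isotherm",
    "fraction_bound",
    "fit_residue",
    "aggregate_global_kd",
    "write_fit_table",
]


def isotherm(L, P, kd, ddmax):
    """Ligand-depletion isotherm; vectorized over ``L`` (and ``P``).

    Returns Δδ in the units of ``ddmax``; lies in [0, ddmax] for valid
    inputs, is strictly increasing in L and strictly decreasing in Kd.
    """
    L = np.asarray(L, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0):
        raise InputError("protein concentration must be > 0")
    if np.any(L < 0):
        raise InputError("ligand concentration must be >= 0")
    s = L + P + kd
    disc = s * s - 4.0 * P * L
    if np.any(disc < 0):  # impossible for kd >= 0; guards fitter excursions
        raise FitError("negative discriminant in binding isotherm")
    # (s - sqrt(disc)) / (2P) rationalized to avoid cancellation at small P
    out = ddmax * 2.0 * L / (s + np.sqrt(disc))
    return float(out) if out.ndim == 0 else out


def fraction_bound(L, P, kd):
    """Fraction of protein bound, [PL]/[P]_total, under ligand depletion."""
    return isotherm(L, P, kd, 1.0)


@dataclass(frozen=True)
class FitConfig:
    """Fit and aggregation settings.

    saturation_cutoff: minimum fraction bound at the final point for a
        fit to count as saturated (underdetermined-Kd guard).
    kd_min/ddmax_min: positivity bounds passed to the optimizer.
    """

    saturation_cutoff: float = 0.8
    kd_min: float = 1e-6
    ddmax_min: float = 1e-6
    kd_max: float = 1e3
    ddmax_max: float = 1e2
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12


@dataclass(frozen=True)
class BindingFit:
    residue_number: int
    kd: float  # mM
    ddmax: float  # ppm
    kd_stderr: float  # mM, NaN when unavailable
    converged: bool
    saturated: bool
    frac_bound_end: float
    n_points: int  # non-apo points used
    rmse: float  # ppm


def fit_residue(
    csp: ResidueCSP,
    series: TitrationSeries,
    cfg: FitConfig = FitConfig(),
) -> BindingFit:
    """Least-squares (Kd, Δδmax) estimate for one residue's trajectory.

    Uses the defined (non-broadened) points only; at least 3 non-apo
    points are required. Initialization is scale-aware: Kd starts at the
    median non-zero ligand concentration, Δδmax at 1.2× the largest
    observed Δδ. Optimizer failure returns ``converged=False`` with the
    last parameter values rather than raising.
    """
    L_all = np.asarray(series.ligand_concs)
    P_all = np.asarray(series.protein_concs)
    traj = np.asarray(csp.csp_traj, dtype=float)
    if traj.size != L_all.size:
        raise InputError(
            f"residue {csp.residue_number}: trajectory length {traj.size} "
            f"does not match {L_all.size} titration points"
        )
    ok = ~np.isnan(traj)
    n_nonapo = int(np.sum(ok[1:]))
    if n_nonapo < 3:
        raise InputError(
            f"residue {csp.residue_number}: need >= 3 defined non-apo points, "
            f"got {n_nonapo}"
        )
    L, P, y = L_all[ok], P_all[ok], traj[ok]

    params = lmfit.Parameters()
    params.add("kd", value=float(np.median(L[L > 0])), min=cfg.kd_min, max=cfg.kd_max)
    params.add("ddmax", value=1.2 * float(np.max(y)) if np.max(y) > 0 else 0.01,
               min=cfg.ddmax_min, max=cfg.ddmax_max)

    def residuals(p: lmfit.Parameters) -> np.ndarray:
        return isotherm(L, P, p["kd"].value, p["ddmax"].value) - y

    result = lmfit.minimize(
        residuals, params, method="least_squares",
        ftol=cfg.ftol, xtol=cfg.xtol, gtol=cfg.gtol,
    )
    kd = float(result.params["kd"].value)
    ddmax = float(result.params["ddmax"].value)
    stderr = result.params["kd"].stderr
    L_end, P_end = float(L[-1]), float(P[-1])
    fb_end = fraction_bound(L_end, P_end, kd)
    rmse = float(np.sqrt(np.mean(np.asarray(result.residual) ** 2)))
    return BindingFit(
        residue_number=csp.residue_number,
        kd=kd,
        ddmax=ddmax,
        kd_stderr=float(stderr) if stderr is not None else float("nan"),
        converged=bool(result.success),
        saturated=fb_end >= cfg.saturation_cutoff,
        frac_bound_end=fb_end,
        n_points=n_nonapo,
        rmse=rmse,
    )


@dataclass(frozen=True)
class GlobalKd:
    """Aggregated affinity: mean ± SD over retained residues, or a lower limit.

    In the lower-limit form ``mean_kd``/``sd_kd`` are NaN and
    ``limit_value`` is the smallest (tightest) per-residue Kd.
    """

    mean_kd: float  # mM; NaN when is_lower_limit
    sd_kd: float  # mM; NaN when is_lower_limit
    residues_used: frozenset[int]
    residues_excluded: frozenset[int]
    is_lower_limit: bool
    limit_value: float  # mM; NaN unless is_lower_limit

    def describe(self) -> str:
        if self.is_lower_limit:
            return f"Kd > {self.limit_value:.3g} mM (underdetermined, lower limit)"
        return f"Kd = {self.mean_kd:.3g} +/- {self.sd_kd:.3g} mM (n={len(self.residues_used)})"


def aggregate_global_kd(
    fits: Iterable[BindingFit],
    significant: Iterable[int],
    cfg: FitConfig = FitConfig(),
) -> GlobalKd:
    """One-pass aggregation of per-residue Kd values.

    Candidates are the converged fits of significant residues (>= 2
    required). Mean and sample SD are taken over all candidates;
    residues with |Kd − mean| >= 2·SD are excluded (skipped when SD = 0,
    where the criterion is vacuous) and the mean/SD are recomputed over
    the retained set. The lower-limit form is returned when the excluded
    fraction reaches 50% or when more than half of the candidate fits
    are unsaturated.
    """
    significant = set(significant)
    cand = sorted(
        (f for f in fits if f.residue_number in significant and f.converged),
        key=lambda f: f.residue_number,
    )
    if len(cand) < 2:
        raise InputError(
            f"global Kd needs >= 2 converged fits of significant residues, got {len(cand)}"
        )
    kds = np.array([f.kd for f in cand])
    mean = float(np.mean(kds))
    sd = float(np.std(kds, ddof=1))

    if sd > 0:
        excluded_mask = np.abs(kds - mean) >= 2.0 * sd
    else:
        excluded_mask = np.zeros(len(kds), dtype=bool)
    excluded = frozenset(f.residue_number for f, m in zip(cand, excluded_mask) if m)
    used = frozenset(f.residue_number for f, m in zip(cand, excluded_mask) if not m)

    frac_excluded = len(excluded) / len(cand)
    frac_unsaturated = sum(not f.saturated for f in cand) / len(cand)
    if frac_excluded >= 0.5 or frac_unsaturated > 0.5:
        return GlobalKd(
            mean_kd=float("nan"),
            sd_kd=float("nan"),
            residues_used=frozenset(),
            residues_excluded=excluded,
            is_lower_limit=True,
            limit_value=float(np.min(kds)),
        )

    kept = kds[~excluded_mask]
    return GlobalKd(
        mean_kd=float(np.mean(kept)),
        sd_kd=float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0,
        residues_used=used,
        residues_excluded=excluded,
        is_lower_limit=False,
        limit_value=float("nan"),
    )


def write_fit_table(fits: Sequence[BindingFit], path: str | Path) -> None:
    lines = [
        "residue_number\tkd_mM\tkd_stderr_mM\tddmax_ppm\tconverged\tsaturated\t"
        "frac_bound_end\tn_points\trmse_ppm"
    ]
    for f in sorted(fits, key=lambda f: f.residue_number):
        stderr = "NA" if math.isnan(f.kd_stderr) else f"{f.kd_stderr:.6g}"
        lines.append(
            f"{f.residue_number}\t{f.kd:.6g}\t{stderr}\t{f.ddmax:.6g}\t"
            f"{int(f.converged)}\t{int(f.saturated)}\t{f.frac_bound_end:.4f}\t"
            f"{f.n_points}\t{f.rmse:.3g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
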