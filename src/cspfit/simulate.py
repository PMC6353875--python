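"""Synthetic titration series and genomic peak sets with ground truth.

The titration generator is the forward model the analysis assumes:
binder residues share a single true Kd and drift linearly in the 2-D
(δH, δN) plane — fast exchange — with a per-residue random direction and
saturation amplitude Δδmax, the displacement magnitude at each point
given by the ligand-depletion isotherm so that the *normalized* CSP of
the noiseless displacement equals the isotherm value exactly. Non-binder
residues stay at their apo position. Independent Gaussian ppm noise is
added per dimension to every non-apo point (the apo spectrum is the
reference and is generated noise-free). Optional exchange broadening
removes binder peaks on points whose fraction bound falls inside a
configurable window, mimicking intermediate-exchange disappearance at
half-saturation.

Defaults mirror a realistic HSQC titration of a ~110-residue construct
at 0.1 mM with ligand added to 32:1: see :class:`TitrationSimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .binding import fraction_bound, isotherm
from .csp import CSPConfig
from .errors import InputError
from .overlap import GenomicPeak, write_bed
from .peaklist import Peak, TitrationPoint, TitrationSeries, write_peaklist

__all__ = [
    "TitrationSimConfig",
    "simulate_titration",
    "write_titration_dir",
    "simulate_peaksets",
]

_AMINO_ACIDS = tuple("ACDEFGHIKLMNQRSTVWY")  # no proline: prolines have no amide


@dataclass(frozen=True)
class TitrationSimConfig:
    """Forward-model settings (concentrations in mM, shifts/noise in ppm).

    ``direction_seed`` fixes the structural randomness (binder identity,
    shift directions, amplitudes, apo positions); ``noise_seed`` fixes
    the measurement noise, so noise replicates share one "protein".
    """

    true_kd: float = 0.3
    protein_conc: float = 0.1
    molar_ratios: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    n_residues: int = 60
    binder_fraction: float = 0.25
    ddmax_range: tuple[float, float] = (0.05, 0.25)
    noise_sd: float = 0.005
    broadening: tuple[float, float] | None = None  # fraction-bound window
    direction_seed: int = 0
    noise_seed: int = 1
    residue_start: int = 141
    nitrogen_weight: float = 0.20

    def __post_init__(self) -> None:
        if self.true_kd <= 0 or self.protein_conc <= 0:
            raise InputError("true_kd and protein_conc must be > 0")
        r = self.molar_ratios
        if len(r) < 3 or r[0] != 0 or any(y <= x for x, y in zip(r, r[1:])):
            raise InputError(
                "molar_ratios must start at 0 and increase strictly (>= 3 points)"
            )
        if not 0 <= self.binder_fraction <= 1:
            raise InputError("binder_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if not 0 < self.ddmax_range[0] <= self.ddmax_range[1]:
            raise InputError("ddmax_range must be a positive interval")
        if self.broadening is not None:
            lo, hi = self.broadening
            if not 0 <= lo < hi <= 1:
                raise InputError("broadening window must satisfy 0 <= lo < hi <= 1")


def simulate_titration(
    cfg: TitrationSimConfig = TitrationSimConfig(),
) -> tuple[TitrationSeries, pd.DataFrame]:
    """Generate a titration series plus its ground-truth table.

    Identical seeds give bit-identical output. The truth table has one
    row per residue: ``residue_number, residue_type, is_binder, kd_mM,
    ddmax_ppm, direction_rad``.
    """
    rng_dir = np.random.default_rng(cfg.direction_seed)
    rng_noise = np.random.default_rng(cfg.noise_seed)

    n = cfg.n_residues
    resnums = np.arange(cfg.residue_start, cfg.residue_start + n)
    restypes = rng_dir.choice(_AMINO_ACIDS, size=n)
    n_binders = int(round(cfg.binder_fraction * n))
    binder_idx = rng_dir.choice(n, size=n_binders, replace=False)
    is_binder = np.zeros(n, dtype=bool)
    is_binder[binder_idx] = True

    # apo peak positions: plausible amide windows
    apo_H = rng_dir.uniform(7.5, 9.5, size=n)
    apo_N = rng_dir.uniform(108.0, 130.0, size=n)

    theta = rng_dir.uniform(0.0, 2.0 * np.pi, size=n)
    ddmax = rng_dir.uniform(*cfg.ddmax_range, size=n)
    theta[~is_binder] = np.nan
    ddmax[~is_binder] = np.nan

    P = cfg.protein_conc
    ligand = np.asarray(cfg.molar_ratios) * P
    points: list[TitrationPoint] = []
    for i, L in enumerate(ligand):
        dH = np.zeros(n)
        dN = np.zeros(n)
        if i > 0:
            m = np.zeros(n)
            m[is_binder] = isotherm(L, P, cfg.true_kd, 1.0) * ddmax[is_binder]
            # direction resolved so the weighted norm of the noiseless
            # displacement equals the isotherm value exactly
            dH = m * np.cos(np.nan_to_num(theta))
            dN = m * np.sin(np.nan_to_num(theta)) / cfg.nitrogen_weight
            if cfg.noise_sd > 0:
                dH = dH + rng_noise.normal(0.0, cfg.noise_sd, size=n)
                dN = dN + rng_noise.normal(0.0, cfg.noise_sd, size=n)
        absent = np.zeros(n, dtype=bool)
        if cfg.broadening is not None and i > 0:
            lo, hi = cfg.broadening
            fb = fraction_bound(L, P, cfg.true_kd)
            if lo <= fb <= hi:
                absent = is_binder.copy()
        peaks = tuple(
            Peak(int(resnums[k]), str(restypes[k]), None, None, present=False)
            if absent[k]
            else Peak(
                int(resnums[k]),
                str(restypes[k]),
                float(apo_H[k] + dH[k]),
                float(apo_N[k] + dN[k]),
            )
            for k in range(n)
        )
        points.append(
            TitrationPoint(float(L), P, peaks, molar_ratio=float(cfg.molar_ratios[i]))
        )

    truth = pd.DataFrame(
        {
            "residue_number": resnums,
            "residue_type": restypes,
            "is_binder": is_binder,
            "kd_mM": np.where(is_binder, cfg.true_kd, np.nan),
            "ddmax_ppm": ddmax,
            "direction_rad": theta,
        }
    )
    series = TitrationSeries(
        points=tuple(points),
        protein_name="synthetic-protein",
        ligand_name=f"synthetic-ligand(kd={cfg.true_kd}mM)",
    )
    return series, truth


def write_titration_dir(
    series: TitrationSeries, truth: pd.DataFrame, outdir: str | Path
) -> Path:
    """Write peak lists, the design YAML and the truth table to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, pt in enumerate(series.points):
        name = f"point{i:02d}.tsv"
        write_peaklist(pt.peaks, outdir / name)
        entries.append(
            {
                "peaklist": name,
                "ligand_conc": pt.ligand_conc,
                "protein_conc": pt.protein_conc,
            }
        )
    design = {
        "protein_name": series.protein_name,
        "ligand_name": series.ligand_name,
        "protein_conc": series.points[0].protein_conc,
        "dialect": "tsv",
        "points": entries,
    }
    (outdir / "design.yaml").write_text(yaml.safe_dump(design, sort_keys=False))
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir / "design.yaml"


def simulate_peaksets(
    n_a: int,
    n_b: int,
    genome_size: int = 10_000_000,
    shared_fraction: float = 0.5,
    jitter_bp: int = 150,
    seed: int = 0,
    peak_width: tuple[int, int] = (150, 500),
    chrom: str = "chr1",
) -> tuple[tuple[GenomicPeak, ...], tuple[GenomicPeak, ...], pd.DataFrame]:
    """Two peak sets where a known fraction of B is planted near A.

    Planted B peaks start within ``jitter_bp`` of the partner's end (gap
    <= jitter_bp by construction) on the same strand; background B peaks
    are rejection-sampled to lie farther than ``jitter_bp`` from every A
    peak, so with a sparse genome the planted pairs are exactly the
    qualifying ones. Returns (A, B, truth) where truth labels each B
    peak with ``planted`` and its partner index (-1 for background).
    """
    if n_a < 1 or n_b < 1:
        raise InputError("n_a and n_b must be >= 1")
    if not 0 <= shared_fraction <= 1:
        raise InputError("shared_fraction must be in [0, 1]")
    if jitter_bp < 0 or genome_size <= 2 * (peak_width[1] + jitter_bp):
        raise InputError("invalid jitter_bp / genome_size")
    rng = np.random.default_rng(seed)

    def rand_width() -> int:
        return int(rng.integers(peak_width[0], peak_width[1] + 1))

    a_peaks: list[GenomicPeak] = []
    for _ in range(n_a):
        w = rand_width()
        s = int(rng.integers(0, genome_size - w))
        a_peaks.append(GenomicPeak(chrom, s, s + w, str(rng.choice(["+", "-"]))))

    n_planted = int(round(shared_fraction * n_b))
    b_peaks: list[GenomicPeak] = []
    partner: list[int] = []
    for _ in range(n_planted):
        i = int(rng.integers(0, n_a))
        pa = a_peaks[i]
        g = int(rng.integers(0, jitter_bp + 1))
        w = rand_width()
        s = min(pa.end + g, genome_size - w - 1)
        b_peaks.append(GenomicPeak(chrom, s, s + w, pa.strand))
        partner.append(i)
    margin = jitter_bp + 1
    for _ in range(n_b - n_planted):
        w = rand_width()
        for _attempt in range(1000):
            s = int(rng.integers(0, genome_size - w))
            if all(
                max(0, max(pa.start, s) - min(pa.end, s + w)) > jitter_bp + margin
                for pa in a_peaks
            ):
                break
        else:
            raise InputError(
                "could not place background peaks away from A; genome too dense"
            )
        b_peaks.append(GenomicPeak(chrom, s, s + w, str(rng.choice(["+", "-"]))))
        partner.append(-1)

    truth = pd.DataFrame(
        {
            "b_index": np.arange(n_b),
            "planted": [p >= 0 for p in partner],
            "partner_a": partner,
        }
    )
    return tuple(a_peaks), tuple(b_peaks), truth
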