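"""End-to-end titration analysis: ingest → CSP → significance → fits →
global Kd → region mapping → optional restraint export.

The binding call combines the relative significance rule with an
absolute floor: a run reports binding only if at least one residue both
clears the trimmed mean + 1 SD tier *and* shows an endpoint CSP of at
least ``min_csp`` ppm (default 0.02 ppm, a conventional minimum
detectable amide shift). The relative rule alone would flag the upper
tail of any noise-only spectrum; the floor is what lets a genuinely
inert ligand come out as "NB" (no binding). Residues failing the floor
keep their tier in the significance table — the floor gates only the
binding decision and the fit set.

Outputs written to the run directory (all deterministic given the
inputs; no timestamps):

* ``csp_table.tsv``        per-residue trajectories
* ``significance.tsv``     tiers and thresholds
* ``fits.tsv``             per-residue (Kd, Δδmax) fits
* ``regions.tsv``          tier counts per construct region
* ``restraints.tbl`` / ``active.json``   when restraint export is enabled
* ``summary.json``         machine-readable result
* ``report.txt``           human-readable report
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import binding, csp as csp_mod, regions as regions_mod, restraints as restr_mod
from .binding import FitConfig, aggregate_global_kd, fit_residue
from .csp import ASSIGNED, CSPConfig, compute_csps
from .errors import CSPFitError, InputError
from .peaklist import TitrationSeries, read_titration
from .regions import DEFAULT_SRM_SANT1, RegionAnnotation, classify_regions, read_annotation
from .significance import GE_1SD, SignificanceResult, classify_significance

logger = logging.getLogger("cspfit.pipeline")

__all__ = ["RunConfig", "load_run_config", "run_titration_pipeline", "analyze_series"]

#: result labels in summary.json
RESULT_KD = "kd"
RESULT_LOWER_LIMIT = "lower_limit"
RESULT_NB = "NB"
RESULT_INSUFFICIENT = "insufficient_fits"


@dataclass(frozen=True)
class RunConfig:
    design: Path
    outdir: Path
    nitrogen_weight: float = 0.20
    min_csp: float = 0.02  # ppm, absolute binding floor
    saturation_cutoff: float = 0.8
    annotation: Path | None = None  # default: built-in SRM-SANT1 annotation
    restraint_partner: tuple[int, ...] = ()  # enable restraint export when non-empty
    restraint_tier: str = GE_1SD
    dist_lower: float = 0.0
    dist_upper: float = 2.0


def load_run_config(path: str | Path) -> RunConfig:
    """Load a declarative run config (YAML); paths resolve against it."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"run config not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "design" not in raw:
        raise InputError(f"{path}: run config must be a mapping with a 'design' key")
    base = path.parent
    ann = raw.get("annotation")
    return RunConfig(
        design=base / raw["design"],
        outdir=base / raw.get("outdir", "cspfit_out"),
        nitrogen_weight=float(raw.get("nitrogen_weight", 0.20)),
        min_csp=float(raw.get("min_csp", 0.02)),
        saturation_cutoff=float(raw.get("saturation_cutoff", 0.8)),
        annotation=(base / ann) if ann else None,
        restraint_partner=tuple(raw.get("restraint_partner", [])),
        restraint_tier=str(raw.get("restraint_tier", GE_1SD)),
        dist_lower=float(raw.get("dist_lower", 0.0)),
        dist_upper=float(raw.get("dist_upper", 2.0)),
    )


def analyze_series(
    series: TitrationSeries,
    csp_cfg: CSPConfig = CSPConfig(),
    fit_cfg: FitConfig = FitConfig(),
    min_csp: float = 0.02,
    annotation: RegionAnnotation | None = None,
) -> dict[str, Any]:
    """Run the in-memory analysis and return a result bundle.

    Keys: ``csps``, ``significance``, ``binding_residues``, ``fits``,
    ``global_kd`` (None unless result == "kd"/"lower_limit"), ``result``,
    ``regions`` (None without an annotation covering the construct).
    """
    csps = compute_csps(series, csp_cfg)
    sig = classify_significance(csps)
    logger.info(
        "significance: n=%d, trimmed=%d, threshold_1sd=%.4f ppm",
        len(sig.tier), len(sig.trimmed_residues), sig.threshold_1sd,
    )

    # binding call: relative tier AND absolute floor
    binding_residues = sorted(
        r for r in sig.significant if sig.endpoint_csp[r] >= min_csp
    )
    by_resnum = {r.residue_number: r for r in csps}

    fits: list[binding.BindingFit] = []
    global_kd = None
    if not binding_residues:
        result = RESULT_NB
        logger.info("no residue passes tier + %.3f ppm floor: NB", min_csp)
    else:
        for resnum in binding_residues:
            try:
                fits.append(fit_residue(by_resnum[resnum], series, fit_cfg))
            except InputError as exc:
                logger.warning("skipping residue %d: %s", resnum, exc)
        try:
            global_kd = aggregate_global_kd(fits, binding_residues, fit_cfg)
            result = RESULT_LOWER_LIMIT if global_kd.is_lower_limit else RESULT_KD
            logger.info("global Kd: %s (excluded: %s)",
                        global_kd.describe(), sorted(global_kd.residues_excluded))
        except InputError as exc:
            result = RESULT_INSUFFICIENT
            logger.warning("global Kd not aggregated: %s", exc)

    region_counts = None
    if annotation is not None:
        try:
            region_counts = classify_regions(sig, annotation)
        except InputError as exc:
            logger.warning("region mapping skipped: %s", exc)

    return {
        "csps": csps,
        "significance": sig,
        "binding_residues": binding_residues,
        "fits": fits,
        "global_kd": global_kd,
        "result": result,
        "regions": region_counts,
    }


def run_titration_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline from a run config, writing all outputs."""
    try:
        series = read_titration(cfg.design)
    except InputError as exc:
        raise InputError(f"ingest stage: {exc}") from exc
    logger.info(
        "loaded %s vs %s: %d points, [P]=%g mM",
        series.protein_name, series.ligand_name,
        len(series.points), series.points[0].protein_conc,
    )

    annotation = (
        read_annotation(cfg.annotation) if cfg.annotation else DEFAULT_SRM_SANT1
    )
    res = analyze_series(
        series,
        csp_cfg=CSPConfig(nitrogen_weight=cfg.nitrogen_weight),
        fit_cfg=FitConfig(saturation_cutoff=cfg.saturation_cutoff),
        min_csp=cfg.min_csp,
        annotation=annotation,
    )

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csp_mod.write_csp_table(res["csps"], outdir / "csp_table.tsv")
    sig: SignificanceResult = res["significance"]
    from .significance import write_significance_table

    write_significance_table(sig, outdir / "significance.tsv")
    binding.write_fit_table(res["fits"], outdir / "fits.tsv")
    if res["regions"] is not None:
        regions_mod.write_region_table(res["regions"], outdir / "regions.tsv")

    if cfg.restraint_partner and res["result"] in (RESULT_KD, RESULT_LOWER_LIMIT):
        spec = restr_mod.build_restraints(
            sig, cfg.restraint_partner, tier=cfg.restraint_tier,
            dist_lower=cfg.dist_lower, dist_upper=cfg.dist_upper,
        )
        restr_mod.write_air_table(spec, outdir / "restraints.tbl")
        restr_mod.write_active_sidecar(spec, outdir / "active.json")

    summary = _summarize(series, res, cfg)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (outdir / "report.txt").write_text(_report_text(series, res, summary))
    return {**res, "summary": summary, "outdir": outdir}


def _summarize(series: TitrationSeries, res: dict, cfg: RunConfig) -> dict:
    sig: SignificanceResult = res["significance"]
    gk = res["global_kd"]
    summary: dict[str, Any] = {
        "protein": series.protein_name,
        "ligand": series.ligand_name,
        "n_points": len(series.points),
        "n_classified": len(sig.tier),
        "threshold_1sd_ppm": sig.threshold_1sd,
        "threshold_1p5sd_ppm": sig.threshold_1p5sd,
        "n_trimmed": len(sig.trimmed_residues),
        "n_significant": len(sig.significant),
        "min_csp_ppm": cfg.min_csp,
        "binding_residues": list(res["binding_residues"]),
        "result": res["result"],
    }
    if gk is not None:
        if gk.is_lower_limit:
            summary["kd_lower_limit_mM"] = gk.limit_value
        else:
            summary["global_kd_mM"] = gk.mean_kd
            summary["global_kd_sd_mM"] = gk.sd_kd
            summary["n_residues_used"] = len(gk.residues_used)
        summary["residues_excluded"] = sorted(gk.residues_excluded)
    return summary


def _report_text(series: TitrationSeries, res: dict, summary: dict) -> str:
    gk = res["global_kd"]
    lines = [
        f"Titration analysis: {series.protein_name} + {series.ligand_name}",
        f"  points: {len(series.points)}  "
        f"ligand 0-{series.ligand_concs[-1]:g} mM  [P]={series.protein_concs[0]:g} mM",
        f"  classified residues: {summary['n_classified']}"
        f" (trimmed {summary['n_trimmed']} for thresholds)",
        f"  significance thresholds: {summary['threshold_1sd_ppm']:.4f} /"
        f" {summary['threshold_1p5sd_ppm']:.4f} ppm (1.0 / 1.5 SD)",
        f"  significant residues passing the {summary['min_csp_ppm']:g} ppm floor: "
        f"{len(res['binding_residues'])}",
    ]
    if res["result"] == RESULT_NB:
        lines.append("  result: NB (no binding detected)")
    elif res["result"] == RESULT_INSUFFICIENT:
        lines.append("  result: binding detected but too few fits for a global Kd")
    elif gk is not None:
        lines.append(f"  result: {gk.describe()}")
    return "\n".join(lines) + "\n"
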