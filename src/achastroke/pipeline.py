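"""End-to-end study orchestration: simulate -> classify -> volumetry -> stats.

``run_study`` reproduces the analysis chain on a synthetic cohort: it builds
the atlas, draws the cohort, synthesizes CBV maps, calls AChA occlusion
blinded (the classifier sees only maps and atlas, never ground truth),
quantifies edema-corrected infarct volumes from the generated histology
traces, builds infarct probability maps for the permanent-occlusion group,
and runs the inference chain on the measured quantities. Re-running with the
same config and seed reproduces every CSV bit-identically (floats are
written at 6 significant figures).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classification import classify_achao
from .geometry import AtlasShape, GridSpec, TerritoryAtlas, build_atlas, save_atlas
from .stats import (
    cohort_table,
    multiple_linear_regression,
    run_group_comparisons,
    screen_predictors,
    StatsInputError,
)
from .synthetic import (
    CohortConfig,
    GROUP_ORDER,
    generate_cbv_maps,
    generate_cohort,
    generate_infarct_traces,
)
from .volumetry import probability_map, render_probability_map, volume_report

__all__ = ["StudyConfig", "StudyReport", "ReportError", "run_study", "make_report"]

FLOAT_FORMAT = "%.6g"


class ReportError(RuntimeError):
    """A report was requested from incomplete stage outputs."""


@dataclass
class StudyConfig:
    """Resolved configuration of one full study run."""

    grid: GridSpec = field(default_factory=GridSpec)
    atlas_shape: AtlasShape = field(default_factory=AtlasShape)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    vessel_threshold: float = 10.0
    tolerance_voxels: int = 0
    duration_coding: str = "hours24"
    screen_alpha: float = 0.10
    t_variant: str = "pooled"
    probability_map_levels: tuple[float, ...] = (-0.3, -2.3)
    seed: int = 0
    write_images: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if isinstance(d.get("grid"), dict):
            g = dict(d["grid"])
            g["bregma_levels"] = tuple(g.get("bregma_levels", (0.0, -2.4)))
            d["grid"] = GridSpec(**g)
        if isinstance(d.get("atlas_shape"), dict):
            d["atlas_shape"] = AtlasShape(**d["atlas_shape"])
        if isinstance(d.get("cohort"), dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "probability_map_levels" in d:
            d["probability_map_levels"] = tuple(d["probability_map_levels"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert to YAML/JSON-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class StudyReport:
    """Paths and summary object produced by one study run."""

    outdir: Path
    paths: dict[str, Path]
    summary: dict


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_study(config: StudyConfig, outdir: str | Path) -> StudyReport:
    """Run the full pipeline and write all study artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    warnings: list[str] = []

    config.to_yaml(outdir / "config_resolved.yaml")
    paths["config"] = outdir / "config_resolved.yaml"

    atlas = build_atlas(config.grid, config.atlas_shape)
    paths["atlas"] = save_atlas(atlas, outdir / "atlas.tif")

    # --- simulate ---------------------------------------------------------
    records = generate_cohort(config.cohort, config.seed)
    cohort_df = pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "group": r.occlusion_group,
                "acha_occluded_true": int(r.acha_occluded),
                "weight_g": r.weight_g,
                "infarct_volume_total_mm3": r.infarct_volume_total,
                "infarct_volume_cortical_mm3": r.infarct_volume_cortical,
                "infarct_volume_subcortical_mm3": r.infarct_volume_subcortical,
                "contralateral_hemisphere_mm3": r.contralateral_hemisphere_volume,
                "ipsilateral_hemisphere_mm3": r.ipsilateral_hemisphere_volume,
            }
            for r in records
        ]
    )
    _write_csv(cohort_df, outdir / "cohort.csv")
    paths["cohort"] = outdir / "cohort.csv"

    # --- classify (blinded: maps + atlas only) ----------------------------
    class_rows = []
    acha_calls: dict[str, bool] = {}
    if config.write_images:
        from .io import save_cbv_maps

        (outdir / "maps").mkdir(exist_ok=True)
    for rec in records:
        maps = generate_cbv_maps(rec, atlas, config.cohort, config.seed)
        if config.write_images:
            save_cbv_maps(maps, outdir / "maps" / f"{rec.animal_id}.tif")
        res = classify_achao(
            maps,
            atlas,
            vessel_threshold=config.vessel_threshold,
            tolerance_voxels=config.tolerance_voxels,
        )
        acha_calls[res.animal_id] = res.acha_occluded
        class_rows.append(
            {
                "animal_id": res.animal_id,
                "slice_used_bregma_mm": res.slice_used,
                "mean_contralateral_cbv": res.mean_contralateral_cbv,
                "excluded_vessel_voxels": res.excluded_vessel_voxels,
                "supra_threshold_voxels_in_acha": res.supra_threshold_voxels_in_acha,
                "acha_occluded": int(res.acha_occluded),
            }
        )
    class_df = pd.DataFrame(class_rows)
    _write_csv(class_df, outdir / "classification.csv")
    paths["classification"] = outdir / "classification.csv"

    # --- volumetry --------------------------------------------------------
    vol_rows = []
    corrected: dict[str, float] = {}
    traces_by_id = {}
    for rec in records:
        traces = generate_infarct_traces(rec, atlas, config.cohort, config.seed)
        traces_by_id[rec.animal_id] = traces
        rep = volume_report(traces, atlas)
        corrected[rec.animal_id] = rep.corrected_infarct
        vol_rows.append(
            {
                "animal_id": rep.animal_id,
                "raw_infarct_mm3": rep.raw_infarct,
                "contralateral_hemisphere_mm3": rep.contralateral_hemisphere,
                "ipsilateral_hemisphere_mm3": rep.ipsilateral_hemisphere,
                "corrected_infarct_mm3": rep.corrected_infarct,
                "cortical_corrected_mm3": rep.cortical_corrected,
                "subcortical_corrected_mm3": rep.subcortical_corrected,
            }
        )
    vol_df = pd.DataFrame(vol_rows)
    _write_csv(vol_df, outdir / "volumes.csv")
    paths["volumes"] = outdir / "volumes.csv"

    # --- probability maps (permanent-occlusion group) ---------------------
    pmcao_ids = [r.animal_id for r in records if r.occlusion_group == "permanent"]
    prob_maps = {}
    for level in config.probability_map_levels:
        stacks = []
        for aid in pmcao_ids:
            tr = traces_by_id[aid]
            s = int(np.argmin([abs(p - level) for p in tr.positions]))
            stacks.append(tr.infarct[s])
        if not stacks:
            warnings.append("no permanent-occlusion animals: probability maps skipped")
            break
        frac = probability_map(np.stack(stacks))
        tif = outdir / f"probability_map_{level:+.1f}mm.tif"
        tifffile.imwrite(tif, frac.astype(np.float32))
        png = render_probability_map(
            frac,
            n=len(stacks),
            path=outdir / f"probability_map_{level:+.1f}mm.png",
            title=f"infarct probability, {level:+.1f} mm bregma (n={len(stacks)})",
        )
        prob_maps[f"{level:+.1f}"] = {
            "n": len(stacks),
            "max_fraction": float(frac.max()),
            "tif": str(tif),
            "png": str(png),
        }
        paths[f"probability_map_{level:+.1f}"] = tif

    # --- statistics on measured quantities --------------------------------
    table = cohort_table(
        records,
        acha_calls=acha_calls,
        volumes=corrected,
        duration_coding=config.duration_coding,
    )
    _write_csv(table, outdir / "analysis_table.csv")
    paths["analysis_table"] = outdir / "analysis_table.csv"

    comparisons = run_group_comparisons(table, variant=config.t_variant)
    screening = screen_predictors(table, alpha=config.screen_alpha)
    included = tuple(e.name for e in screening if e.included)
    regression = None
    if included:
        try:
            regression = multiple_linear_regression(table, predictors=included)
        except StatsInputError as exc:
            warnings.append(f"regression skipped: {exc}")
    else:
        warnings.append("no predictor passed screening: regression skipped")
    for e in screening:
        if e.note:
            warnings.append(f"screening: {e.name}: {e.note}")

    strata = []
    for group in [g for g in GROUP_ORDER if g in set(table["group"])]:
        sub = table[table["group"] == group]["infarct_volume_mm3"]
        strata.append(
            {
                "stratum": group,
                "n": int(len(sub)),
                "mean_mm3": float(sub.mean()),
                "sd_mm3": float(sub.std(ddof=1)),
            }
        )
    strata.append(
        {
            "stratum": "pooled",
            "n": int(len(table)),
            "mean_mm3": float(table["infarct_volume_mm3"].mean()),
            "sd_mm3": float(table["infarct_volume_mm3"].std(ddof=1)),
        }
    )

    summary = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_animals": len(records),
        "n_acha_occluded_calls": int(sum(acha_calls.values())),
        "group_summary": strata,
        "comparisons": [_plain(asdict(c)) for c in comparisons],
        "screening": [_plain(asdict(e)) for e in screening],
        "regression": _plain(asdict(regression)) if regression else None,
        "probability_maps": prob_maps,
        "warnings": warnings,
        "config": _plain(config.to_dict()),
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2))
    paths["report_json"] = outdir / "report.json"

    (outdir / "report.md").write_text(make_report(summary))
    paths["report_md"] = outdir / "report.md"

    return StudyReport(outdir=outdir, paths=paths, summary=summary)


def _f(x, nd=3):
    return "n/a" if x is None else f"{x:.{nd}f}"


def make_report(summary: dict) -> str:
    """Render the human-readable study report (markdown) from a summary.

    Raises :class:`ReportError` naming any missing stage outputs.
    """
    required = ("config_hash", "seed", "group_summary", "comparisons", "screening")
    missing = [k for k in required if k not in summary]
    if missing:
        raise ReportError(f"missing stage outputs: {', '.join(missing)}")

    lines = [
        "# Synthetic MCAo / AChAo study report",
        "",
        f"config hash: `{summary['config_hash']}`; seed: {summary['seed']}",
        "",
        f"Animals: {summary.get('n_animals', '?')}; "
        f"AChA occlusion calls (blinded CBV read): "
        f"{summary.get('n_acha_occluded_calls', '?')}",
        "",
        "## Corrected infarct volume by stratum (mean +/- SD, mm^3)",
        "",
        "| stratum | n | mean | SD |",
        "|---|---|---|---|",
    ]
    for s in summary["group_summary"]:
        lines.append(
            f"| {s['stratum']} | {s['n']} | {_f(s['mean_mm3'], 1)} | {_f(s['sd_mm3'], 1)} |"
        )
    lines += [
        "",
        "## MCAo vs MCAo + AChAo comparisons",
        "",
        "| stratum | n (no/yes) | mean no | mean yes | t | df | p | status |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for c in summary["comparisons"]:
        status = "analyzed" if c["analyzed"] else c["reason"]
        if c.get("warnings"):
            status += "; " + "; ".join(c["warnings"])
        lines.append(
            f"| {c['name']} | {c['n_no_achao']}/{c['n_achao']} "
            f"| {_f(c['mean_no_achao'], 1)} | {_f(c['mean_achao'], 1)} "
            f"| {_f(c['t'])} | {_f(c['df'], 1)} | {_f(c['p'], 4)} | {status} |"
        )
    lines += [
        "",
        "No multiple-testing correction is applied.",
        "",
        "## Predictor screening (marginal Pearson, include at p < 0.10)",
        "",
        "| predictor | r | p | included |",
        "|---|---|---|---|",
    ]
    for e in summary["screening"]:
        inc = "yes" if e["included"] else ("no" + (f" ({e['note']})" if e["note"] else ""))
        lines.append(f"| {e['name']} | {_f(e['r'])} | {_f(e['p'], 4)} | {inc} |")
    reg = summary.get("regression")
    lines += ["", "## Multiple linear regression (standardized coefficients)", ""]
    if reg is None:
        lines.append("regression not run (see warnings)")
    else:
        lines += [
            f"n = {reg['n']}; r^2 = {reg['r_squared']:.3f}; "
            f"adjusted r^2 = {reg['adjusted_r_squared']:.3f}",
            "",
            "| predictor | beta (standardized) | coefficient | p |",
            "|---|---|---|---|",
        ]
        for name in reg["predictors"]:
            lines.append(
                f"| {name} | {reg['beta'][name]:.3f} | {reg['coef'][name]:.4g} "
                f"| {reg['pvalues'][name]:.4g} |"
            )
    if summary.get("warnings"):
        lines += ["", "## Warnings", ""]
        lines += [f"- {w}" for w in summary["warnings"]]
    lines.append("")
    return "\n".join(lines)
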