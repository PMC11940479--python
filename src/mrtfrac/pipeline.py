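"""Pipeline stages: simulate -> reduce -> fit -> EUD -> compare.

Each stage is a pure function of (config, seed) writing CSV artifacts plus
a JSON manifest (config hash, seed, package version), so a run can be
reproduced bit-for-bit from its manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cfa import bio_pooled_survival, fit_lq, read_records, summarize_replicates, survival_table
from .config import RunConfig, config_hash
from .lqm import eud_single_fraction, plan_sf, sf_uniform
from .stats_compare import ancova_pairwise, significance_table
from .synthetic_data import plan_for, simulate_study

__all__ = ["cmd_simulate", "cmd_analyze", "cmd_plan", "run_all"]

log = logging.getLogger("mrtfrac")


def _write_manifest(cfg: RunConfig, out_dir: Path, stage: str, artifacts: list[str]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "artifacts": artifacts,
    }
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _prepare(out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
        log.addHandler(handler)
    log.setLevel(logging.INFO)
    return out


def cmd_simulate(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Simulate the configured study; write the CFA record CSV."""
    out = _prepare(out_dir)
    records = simulate_study(cfg.design())
    path = out / "cfa_records.csv"
    records.to_csv(path, index=False)
    log.info("simulated %d CFA records -> %s", len(records), path)
    _write_manifest(cfg, out, "simulate", [path.name])
    return path


def cmd_analyze(cfg: RunConfig, records_csv: str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Reduce records, fit LQ on the broad-beam arm, attach EUDs, compare arms."""
    out = _prepare(out_dir)
    records = read_records(records_csv)
    design = cfg.design()
    params_by_line = {c.label: c.params for c in design.cell_lines}

    def lookup(cell_line: str, modality: str, dose: float):
        return plan_for(design, cell_line, modality, dose)

    points = summarize_replicates(records, params_by_line, lookup, design.domain)
    points_path = out / "survival_points.csv"
    points.to_csv(points_path, index=False)

    # LQ fit per cell line from the broad-beam arm, one point per
    # biological replicate and dose, against single-fraction-equivalent dose
    bb_label = next(m.label for m in design.modalities if m.kind == "broad_beam")
    pooled = bio_pooled_survival(records)
    fits = []
    for cl in design.cell_lines:
        sub = pooled[(pooled["cell_line"] == cl.label) & (pooled["modality"] == bb_label)]
        euds = np.array(
            [
                eud_single_fraction(
                    cl.params, plan_sf(cl.params, lookup(cl.label, bb_label, d), design.domain)
                )
                for d in sub["dose_level_gy"]
            ]
        )
        fit = fit_lq(euds, sub["sf"].clip(upper=1.0).to_numpy())
        fits.append(
            {"cell_line": cl.label, "alpha": fit.alpha, "beta": fit.beta,
             "se_alpha": fit.se_alpha, "se_beta": fit.se_beta, "clamped": fit.clamped}
        )
    fit_path = out / "lq_fit.csv"
    pd.DataFrame(fits).to_csv(fit_path, index=False)

    # replicate-level observations with EUD covariate for the ANCOVA
    wells = survival_table(records)
    eud_map = {
        (r.cell_line, r.modality, r.dose_level_gy): r.eud_gy for r in points.itertuples()
    }
    wells["eud_gy"] = [
        eud_map[(r.cell_line, r.modality, r.dose_level_gy)] for r in wells.itertuples()
    ]
    ana = cfg.analysis
    dose_range = ana.get("dose_range_gy")
    if dose_range is not None:
        dose_range = tuple(dose_range)
    sig_paths = []
    for cl in design.cell_lines:
        sub = wells[(wells["cell_line"] == cl.label) & (wells["sf"] > 0)]
        result = ancova_pairwise(
            sub,
            cell_line=cl.label,
            response_scale=ana.get("response_scale", "log"),
            dose_range_gy=dose_range,
            alpha_level=ana.get("alpha_level", 0.05),
            holm=ana.get("holm", False),
        )
        sig_path = out / f"significance_{cl.label.replace('/', '_')}.csv"
        significance_table(result).to_csv(sig_path)
        sig_paths.append(sig_path)

    plot_path = out / "survival_curves.png"
    _plot_survival(points, plot_path)

    artifacts = [points_path, fit_path, *sig_paths, plot_path]
    log.info("analysis artifacts: %s", [p.name for p in artifacts])
    _write_manifest(cfg, out, "analyze", [p.name for p in artifacts])
    return {"points": points_path, "fit": fit_path,
            "significance": sig_paths, "plot": plot_path}


def _plot_survival(points: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lines = points["cell_line"].unique()
    fig, axes = plt.subplots(1, len(lines), figsize=(5.5 * len(lines), 4.2), squeeze=False)
    for ax, cl in zip(axes[0], lines):
        sub = points[points["cell_line"] == cl]
        for mod, grp in sub.groupby("modality"):
            grp = grp.sort_values("eud_gy")
            ax.errorbar(grp["eud_gy"], grp["sf_mean"], yerr=grp["sf_sem"],
                        marker="o", capsize=3, label=mod)
        ax.set_yscale("log")
        ax.set_xlabel("equivalent uniform dose, single fraction (Gy)")
        ax.set_ylabel("surviving fraction")
        ax.set_title(cl)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cmd_plan(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Per-fraction doses matching every arm to equal survival per level.

    For each cell line, dose level and arm, reports the per-fraction
    (peak) dose whose plan reproduces the survival of a uniform single
    fraction at that level, plus the round-trip EUD of the matched plan.
    """
    out = _prepare(out_dir)
    design = cfg.design()
    rows = []
    for cl in design.cell_lines:
        for level in design.dose_levels_gy:
            if level == 0:
                continue
            for mod in design.modalities:
                plan = plan_for(design, cl.label, mod.label, level)
                sf = plan_sf(cl.params, plan, design.domain)
                rows.append(
                    {
                        "cell_line": cl.label,
                        "modality": mod.label,
                        "target_eud_gy": level,
                        "peak_dose_per_fraction_gy": plan.fractions[0].peak_dose_gy,
                        "sf": sf,
                        "eud_roundtrip_gy": eud_single_fraction(cl.params, sf),
                    }
                )
    path = out / "matched_peak_doses.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    log.info("matched plan doses -> %s", path)
    _write_manifest(cfg, out, "plan", [path.name])
    return path


def run_all(cfg: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """simulate + plan + analyze in one reproducible run."""
    records = cmd_simulate(cfg, out_dir)
    plan_csv = cmd_plan(cfg, out_dir)
    artifacts = cmd_analyze(cfg, records, out_dir)
    artifacts["records"] = records
    artifacts["plan"] = plan_csv
    return artifacts
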