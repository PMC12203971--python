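"""End-to-end pipeline orchestration.

Runs generate -> repeated selection -> secondary pool -> final selection
-> structural analysis, from a single configuration, and writes the
selected ensemble, score report, secondary-structure profile, interaction
matrices and a provenance manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import (
    AnalysisThresholds,
    ensemble_ss,
    export_ss_logo,
    interaction_matrix,
    pca_conformers,
)
from .forward import ensemble_metrics
from .io import (
    read_pdb_ensemble,
    read_saxs_dat,
    read_shift_table,
    write_pdb_ensemble,
    write_saxs_dat,
    write_shift_table,
)
from .selection import (
    PrecomputedObservables,
    SelectionObjective,
    build_secondary_pool,
    final_select,
    repeated_subset_protocol,
)
from .synthetic import SyntheticScenario, make_truth, observe

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; synthetic mode needs no input files."""

    output_dir: str = "results/pipeline"
    mode: str = "synthetic"               # synthetic | real
    # real-data inputs
    shifts_path: str | None = None
    saxs_path: str | None = None
    pool_pdb_path: str | None = None
    # stage parameters
    pool_size: int = 2000
    draw_size: int = 500
    repeats: int = 5
    per_repeat_size: int = 60
    final_size: int = 60
    snapshots_per_member: int = 10
    weight_shift: float = 1.0
    weight_saxs: float = 1.0
    numbering_offset: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full selection-and-analysis workflow.

    Returns the manifest (also written as JSON to the output directory).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"config": asdict(config), "stages": {}}

    if config.mode == "synthetic":
        scenario = SyntheticScenario(
            pool_size=config.pool_size, draw_size=config.draw_size,
            repeats=config.repeats, per_repeat_size=config.per_repeat_size,
            final_size=config.final_size,
            snapshots_per_member=config.snapshots_per_member,
            seed=config.seed,
        )
        truth, pool = make_truth(scenario)
        obs_shifts, obs_saxs = observe(truth, scenario)
        write_pdb_ensemble(truth, out / "truth_ensemble.pdb")
        write_shift_table(obs_shifts, out / "observed_shifts.tsv")
        write_saxs_dat(obs_saxs, out / "observed_saxs.dat")
        manifest["stages"]["truth"] = {"n": len(truth)}
    elif config.mode == "real":
        if not (config.shifts_path and config.saxs_path and config.pool_pdb_path):
            raise ValueError("real mode needs shifts, SAXS and pool PDB paths")
        obs_shifts = read_shift_table(config.shifts_path)
        obs_saxs = read_saxs_dat(config.saxs_path)
        pool = read_pdb_ensemble(config.pool_pdb_path, stage="initial_pool")
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    manifest["stages"]["pool"] = {"n": len(pool)}

    objective = SelectionObjective(weight_shift=config.weight_shift,
                                   weight_saxs=config.weight_saxs)
    pre = PrecomputedObservables(pool, obs_shifts, obs_saxs)
    union = repeated_subset_protocol(
        pool, obs_shifts, obs_saxs, objective,
        draw_size=min(config.draw_size, len(pool)), repeats=config.repeats,
        per_repeat_size=config.per_repeat_size, seed=rng, precomputed=pre)
    manifest["stages"]["union"] = {"n": len(union)}

    secondary = build_secondary_pool(union, config.snapshots_per_member, seed=rng)
    manifest["stages"]["secondary_pool"] = {
        "n": len(secondary),
        "snapshots_per_member": config.snapshots_per_member,
    }

    pre2 = PrecomputedObservables(secondary, obs_shifts, obs_saxs)
    result = final_select(secondary, obs_shifts, obs_saxs, objective,
                          final_size=min(config.final_size, len(secondary)),
                          precomputed=pre2)
    selected = secondary.subset(result.indices, stage="selected")
    manifest["stages"]["final"] = {
        "n": len(selected),
        "shift_rmsd_ppm": result.rmsd,
        "secondary_shift_correlation": result.secondary_correlation,
        "saxs_chi2": result.chi2,
        "objective": result.objective,
    }

    write_pdb_ensemble(selected, out / "selected_ensemble.pdb",
                       numbering_offset=config.numbering_offset)

    # per-stage score report
    report_rows = []
    for label, ens in (("pool", pool), ("secondary_pool", secondary),
                       ("selected", selected)):
        pre_l = pre if ens is pool else (pre2 if ens is secondary else None)
        if pre_l is None:
            pre_l = PrecomputedObservables(ens, obs_shifts, obs_saxs)
        # stage scores are those of the whole stage ensemble
        from .selection import _secondary_correlation, _subset_scores
        rmsd, chi2 = _subset_scores(pre_l, list(range(len(ens))))
        corr = _secondary_correlation(pre_l, list(range(len(ens))))
        metrics = ensemble_metrics(ens)
        report_rows.append({
            "stage": label, "n": len(ens),
            "shift_rmsd_ppm": round(rmsd, 6),
            "secondary_shift_correlation": round(corr, 6),
            "saxs_chi2": round(chi2, 6),
            "mean_rg_nm": round(float(metrics["rg"].mean()), 6),
            "mean_end_to_end_nm": round(float(metrics["end_to_end"].mean()), 6),
        })
    report = pd.DataFrame(report_rows)
    report.to_csv(out / "score_report.tsv", sep="\t", index=False)

    # structural analysis of the selected ensemble
    profile = ensemble_ss(selected)
    profile.probabilities.to_csv(out / "ss_profile.tsv", sep="\t")
    percents, rows = export_ss_logo(profile)
    percents.to_csv(out / "ss_logo_matrix.tsv", sep="\t")
    (out / "ss_pseudo_alignment.txt").write_text("\n".join(rows) + "\n")

    thresholds = AnalysisThresholds()
    for kind in ("salt_bridge", "cation_pi", "edge_to_face"):
        mat = interaction_matrix(selected, thresholds, kind=kind)
        mat.to_frame().to_csv(out / f"interactions_{kind}.tsv",
                              sep="\t", index=False)
        manifest["stages"].setdefault("interactions", {})[kind] = {
            "pairs": len(mat.counts),
            "total": int(sum(mat.counts.values())),
        }

    _, sel_proj, evr = pca_conformers(pool, selected)
    np.savetxt(out / "pca_selected_projections.tsv", sel_proj, delimiter="\t")
    manifest["stages"]["pca"] = {"explained_variance_ratio": [float(v) for v in evr]}

    manifest["outputs"] = sorted({p.name for p in out.iterdir()} | {"manifest.json"})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return manifest
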