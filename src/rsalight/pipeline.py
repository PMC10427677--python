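"""End-to-end orchestration on a synthetic cohort.

Stage order: simulate runs -> LSS betas -> searchlight similarity maps ->
anxiety-minus-neutral difference maps -> ROI ANCOVA (with leave-one-region-
out) + voxelwise permutation inference -> clinical correlations.  Every
output is written under the configured directory and recorded, with a
SHA-256 hash, in a JSON manifest; rerunning the same configuration
reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .clinical import correlate_roi_clinical, fisher_z_compare
from .glm import DEFAULT_DRIFT_CUTOFF_S, fit_trial_betas
from .inference import TFCEParams, permute_correlation, permute_one_sample, permute_two_sample
from .roi import build_roi, leave_one_region_out, subject_roi_scores
from .searchlight import DEFAULT_MIN_VOXELS, DEFAULT_RADIUS, difference_map, searchlight_map
from .simulate import (
    CONDITIONS,
    SimulationConfig,
    default_region_specs,
    default_region_thresholds,
    generate_atlas_fixture,
    generate_cohort,
)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    searchlight_radius: int = DEFAULT_RADIUS
    min_voxels: int = DEFAULT_MIN_VOXELS
    drift_cutoff_s: float = DEFAULT_DRIFT_CUTOFF_S
    tfce: TFCEParams = field(default_factory=TFCEParams)
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "rsalight_out"
    run_voxelwise: bool = True
    covariates: tuple[str, ...] = ("age", "pds")
    clinical_covariate: str = "ham_a"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        self.simulation.validate(self.searchlight_radius)


def demo_config(out_dir: str = "rsalight_out", seed: int = 0) -> PipelineConfig:
    """Desk-scale configuration: full cohort, reduced grid/run, few permutations."""
    sim = SimulationConfig(
        grid_shape=(12, 12, 12), n_volumes=250, n_words=10, n_reps=2,
        n_subjects_per_group=(6, 5), seed=seed,
    )
    sim.consistency_map = {
        "mpfc": {"anxiety": {"AN": 0.7, "control": 0.0},
                 "neutral": {"AN": 0.0, "control": 0.0}}
    }
    return PipelineConfig(simulation=sim, n_permutations=200, seed=seed,
                          out_dir=out_dir)


def subject_similarity_maps(cohort, subject_id, config: PipelineConfig):
    """betas -> searchlight maps for both conditions plus the difference map."""
    maps = {}
    for cond in CONDITIONS:
        run, events = cohort.subject_run(subject_id, cond)
        betas = fit_trial_betas(
            run, events, None, cohort.config.tr,
            hrf_model=cohort.config.hrf_model,
            drift_cutoff_s=config.drift_cutoff_s,
            subject_id=subject_id, condition=cond,
        )
        maps[cond] = searchlight_map(
            betas, None, config.searchlight_radius, config.min_voxels
        )
    maps["anxiety_minus_neutral"] = difference_map(maps["anxiety"], maps["neutral"])
    return maps


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the output manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation)
    voxel = sim.voxel_size
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "searchlight_radius": config.searchlight_radius,
            "min_voxels": config.min_voxels,
            "n_permutations": config.n_permutations,
            "alpha": config.alpha,
            "tfce": dataclasses.asdict(config.tfce),
            "simulation": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(sim).items()
            },
        },
        "files": {},
        "warnings": [],
    }

    def record(key, path):
        manifest["files"][key] = {
            "path": str(Path(path).relative_to(out)),
            "sha256": rio.sha256_of(path),
        }

    cohort = generate_cohort(sim, config.seed)
    record_warnings: list[str] = []

    rio.write_participants(out / "participants.tsv", cohort.participants)
    record("participants", out / "participants.tsv")
    (out / "ground_truth.json").write_text(json.dumps(cohort.ground_truth, indent=1))
    record("ground_truth", out / "ground_truth.json")

    maps_dir = out / "simmaps"
    maps_dir.mkdir(exist_ok=True)
    all_maps: dict[str, dict] = {c: {} for c in (*CONDITIONS, "anxiety_minus_neutral")}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for sid in cohort.participants["subject_id"]:
            try:
                maps = subject_similarity_maps(cohort, sid, config)
            except Exception as exc:
                raise RuntimeError(f"similarity stage failed for {sid}: {exc}") from exc
            for name, sm in maps.items():
                p = maps_dir / f"{sid}_{name}.nii"
                rio.write_similarity_map(p, sm, voxel_size=voxel)
                record(f"simmap/{sid}/{name}", p)
                all_maps[name][sid] = sm
        record_warnings.extend(str(w.message) for w in caught)

    # ROI stage: fixture atlas, per-subject z scores, ANCOVA + leave-one-out
    specs = default_region_specs(sim.grid_shape)
    atlas = generate_atlas_fixture(sim.grid_shape, specs)
    thresholds = default_region_thresholds(specs)
    roiset = build_roi(atlas, thresholds)
    records = cohort.participants
    diff_maps = all_maps["anxiety_minus_neutral"]
    scores = {
        cond: subject_roi_scores(all_maps[cond], roiset.merged_mask)
        for cond in (*CONDITIONS, "anxiety_minus_neutral")
    }
    score_table = pd.DataFrame(scores).rename_axis("subject_id").reset_index()
    rio.write_participants(out / "roi_scores.tsv", score_table)
    record("roi_scores", out / "roi_scores.tsv")

    loro = leave_one_region_out(atlas, thresholds, diff_maps, records,
                                covariates=config.covariates)
    roi_rows = [
        {
            "omitted_region": "none" if omit is None else omit,
            "f_stat": res.f_stat, "df_num": res.df_num, "df_den": res.df_den,
            "p_value": res.p_value, "n_used": res.n_used,
        }
        for omit, res in loro
    ]
    pd.DataFrame(roi_rows).to_csv(out / "roi_ancova.tsv", sep="\t", index=False)
    record("roi_ancova", out / "roi_ancova.tsv")

    # Voxelwise permutation inference
    if config.run_voxelwise:
        ids = list(records["subject_id"])
        stack = np.array([np.nan_to_num(diff_maps[s].data, nan=0.0) for s in ids])
        cov = records[list(config.covariates)].to_numpy(dtype=float)
        group = (records["group"] == "AN").to_numpy()
        res2 = permute_two_sample(
            stack, group, cov, config.n_permutations, config.tfce,
            seed=config.seed + 1,
        )
        anx = np.array(
            [np.nan_to_num(all_maps["anxiety"][s].data, nan=0.0) for s in ids]
        )
        ham = records[config.clinical_covariate].to_numpy(dtype=float)
        resc = permute_correlation(
            anx, ham, nuisance=None, n_perm=config.n_permutations,
            params=config.tfce, seed=config.seed + 2,
        )
        res1 = permute_one_sample(
            stack[group], cov[group], config.n_permutations, config.tfce,
            seed=config.seed + 3,
        )
        for name, res in (("two_sample", res2), ("correlation", resc),
                          ("one_sample_AN", res1)):
            for part, arr in (("tstat", res.stat_map), ("tfce", res.tfce_map),
                              ("fwe_1mp", 1.0 - res.fwe_p_map)):
                p = out / f"{name}_{part}.nii"
                rio.write_nifti(p, arr, voxel_size=voxel)
                record(f"{name}/{part}", p)
            from .inference import cluster_table

            tab = cluster_table(res, config.alpha)
            tab.to_csv(out / f"{name}_clusters.tsv", sep="\t", index=False)
            record(f"{name}/clusters", out / f"{name}_clusters.tsv")

    # Clinical correlations (sqrt-transformed anxiety-condition ROI scores)
    corr = correlate_roi_clinical(
        scores["anxiety"], records, config.clinical_covariate,
        exclusion_rule=None, transform_policy="signed",
    )
    corr.to_csv(out / "roi_clinical_correlations.tsv", sep="\t", index=False)
    record("clinical_correlations", out / "roi_clinical_correlations.tsv")
    per_group = corr.set_index("cohort")
    if {"AN", "control"} <= set(per_group.index) and (
        per_group.loc[["AN", "control"], "n"] > 3
    ).all():
        z, p = fisher_z_compare(
            per_group.loc["AN", "r"], int(per_group.loc["AN", "n"]),
            per_group.loc["control", "r"], int(per_group.loc["control", "n"]),
        )
        manifest["fisher_comparison"] = {"z": z, "p_one_sided": p}

    manifest["warnings"] = record_warnings
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
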