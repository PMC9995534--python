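"""End-to-end orchestration: simulate → gait → adapt → associate → report.

A :class:`PipelineConfig` (one YAML file with per-stage blocks) drives the
run; per-stage seeds are split deterministically from a master seed, every
stage writes its artifacts plus a provenance sidecar, and a markdown run
report mirrors the usual study tables: group-stratified mean±SD of each
symmetry score and one cluster table per tested contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gaitbrain import io
from gaitbrain.adaptation import SplitBeltAdaptation
from gaitbrain.cohort import (
    BrainSimSpec,
    CohortSpec,
    make_atlas,
    simulate_brain_maps,
    simulate_step_series,
)
from gaitbrain.tfce import TFCEParams
from gaitbrain.voxelwise import VoxelwiseLinearModel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "make_report", "run_pipeline"]

STAGES = ("simulate", "adapt", "brain", "associate", "report")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-study run."""

    outdir: str = "gaitbrain_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    brain: dict = field(default_factory=dict)  # BrainSimSpec overrides
    plateau: dict = field(default_factory=lambda: {"n_last": 50, "n_consec": 9, "k_sd": 2.0})
    association: dict = field(
        default_factory=lambda: {
            "question": "q1",
            "score_parameter": "StepCoM",
            "score_cols": None,
            "include_tiv": True,
            "n_perm": 500,
            "alpha": 0.05,
            "tfce": {},
        }
    )
    stages: tuple[str, ...] = STAGES
    steps_csv: str | None = None  # use existing inputs instead of simulating
    covariates_tsv: str | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = io.load_config(path)
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def as_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "cohort": self.cohort,
            "brain": self.brain,
            "plateau": self.plateau,
            "association": self.association,
            "stages": list(self.stages),
            "steps_csv": self.steps_csv,
            "covariates_tsv": self.covariates_tsv,
        }


@dataclass
class RunReport:
    """Per-stage record counts and headline tables of one run."""

    counts: dict
    score_summary: pd.DataFrame | None
    cluster_tables: dict
    outdir: Path
    report_path: Path | None = None


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from a master seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(master).spawn(n)]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages in order; idempotent for a fixed
    config + seed.  Raises on the first failing stage, naming it."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    counts: dict = {}
    cfg_dict = config.as_dict()
    scores_wide = None
    results = {}

    try:
        if "simulate" in config.stages:
            spec = CohortSpec.from_dict({**config.cohort, "seed": seeds[0]})
            cohort = simulate_step_series(spec)
            io.write_steps_csv(cohort.steps, outdir / "steps.csv")
            io.write_covariates_tsv(cohort.covariates, outdir / "covariates.tsv")
            cohort.truth.to_csv(outdir / "truth_gait.tsv", sep="\t", index=False)
            io.write_provenance(outdir / "simulate.prov.json", cfg_dict, seeds[0])
            counts["simulate"] = {"subjects": len(cohort.covariates), "step_rows": len(cohort.steps)}
            logger.info("simulate: %s", counts["simulate"])
            steps_path, cov_path = outdir / "steps.csv", outdir / "covariates.tsv"
        else:
            if config.steps_csv is None:
                raise FileNotFoundError("no steps_csv configured and simulate stage disabled")
            steps_path = Path(config.steps_csv)
            cov_path = Path(config.covariates_tsv) if config.covariates_tsv else None
            if not steps_path.exists():
                raise FileNotFoundError(f"steps file not found: {steps_path}")

        if "adapt" in config.stages:
            if cov_path is not None and not Path(cov_path).exists():
                raise FileNotFoundError(f"covariates file not found: {cov_path}")
            model = SplitBeltAdaptation.from_csv(steps_path, cov_path, **config.plateau)
            adapt = model.fit()
            adapt.scores.to_csv(outdir / "behavioral_scores.tsv", sep="\t", index=False)
            scores_wide = adapt.scores_wide()
            scores_wide.to_csv(outdir / "behavioral_scores_wide.tsv", sep="\t", index=False)
            io.write_provenance(outdir / "adapt.prov.json", cfg_dict, config.seed)
            counts["adapt"] = {"score_rows": len(adapt.scores)}
            results["adapt"] = adapt
            logger.info("adapt: %s", counts["adapt"])

        if "brain" in config.stages:
            if scores_wide is None:
                raise RuntimeError("brain stage requires the adapt stage's scores")
            bspec = BrainSimSpec.from_dict({**config.brain, "seed": seeds[2]})
            score_col = f"sym_{config.association.get('score_parameter', 'StepCoM')}"
            stack, truth = simulate_brain_maps(
                bspec, scores_wide[score_col].to_numpy(), scores_wide
            )
            for i, subject in enumerate(scores_wide["subject"]):
                io.save_nifti(stack.data[i], stack.affine, outdir / f"map_{subject}.nii")
            io.save_mask_nifti(stack.mask, stack.affine, outdir / "mask.nii")
            atlas, lookup = make_atlas(bspec.shape, stack.mask)
            io.save_nifti(atlas, stack.affine, outdir / "atlas.nii")
            lookup.to_csv(outdir / "atlas_lookup.tsv", sep="\t", index=False)
            io.save_mask_nifti(truth["roi"], stack.affine, outdir / "truth_roi.nii")
            io.write_provenance(outdir / "brain.prov.json", cfg_dict, seeds[2])
            counts["brain"] = {"maps": stack.n_subjects, "voxels": stack.n_voxels}
            results["stack"], results["atlas"] = stack, (atlas, lookup)
            logger.info("brain: %s", counts["brain"])

        cluster_tables = {}
        if "associate" in config.stages:
            if "stack" not in results or scores_wide is None:
                raise RuntimeError("associate stage requires the brain and adapt stages")
            assoc = config.association
            tfce_params = TFCEParams(**assoc.get("tfce", {}))
            model = VoxelwiseLinearModel.from_dataframe(
                results["stack"],
                scores_wide,
                score_cols=assoc.get("score_cols"),
                question=assoc.get("question", "q1"),
                include_tiv=assoc.get("include_tiv", True),
            )
            for contrast in model.design.contrasts:
                res = model.fit(
                    contrast,
                    n_perm=assoc.get("n_perm", 500),
                    seed=seeds[3],
                    tfce_params=tfce_params,
                    alpha=assoc.get("alpha", 0.05),
                )
                atlas, lookup = results["atlas"]
                ct = res.label_clusters(atlas, lookup)
                ct.to_tsv(outdir / f"clusters_{contrast}.tsv")
                res.save(outdir / "maps")
                cluster_tables[contrast] = ct
                (outdir / f"summary_{contrast}.txt").write_text(res.summary() + "\n")
            io.write_provenance(outdir / "associate.prov.json", cfg_dict, seeds[3])
            counts["associate"] = {
                "contrasts": len(cluster_tables),
                "clusters": {k: len(v) for k, v in cluster_tables.items()},
            }
            logger.info("associate: %s", counts["associate"])

        score_summary = None
        if "adapt" in results:
            s = results["adapt"].scores
            if "group" in s.columns:
                score_summary = (
                    s.groupby(["parameter", "group"])["magnitude_at_plateau"]
                    .agg(["mean", "std", "count"])
                    .reset_index()
                )
        report = RunReport(counts, score_summary, cluster_tables, outdir)
        if "report" in config.stages:
            report.report_path = make_report(report, cfg_dict, config.seed)
        return report
    except Exception as exc:
        stage = _failing_stage(counts, config.stages)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _failing_stage(counts: dict, stages) -> str:
    for stage in stages:
        if stage not in counts and stage != "report":
            return stage
    return "report"


def make_report(report: RunReport, config: dict, seed: int) -> Path:
    """Write the markdown run report; absent artifacts are listed, not fatal."""
    from gaitbrain import __version__

    lines = [
        "# gaitbrain run report",
        "",
        f"- seed: {seed}",
        f"- config hash: {io.config_hash(config)}",
        f"- version: {__version__}",
        "",
        "## Stage record counts",
        "",
    ]
    for stage, info in report.counts.items():
        lines.append(f"- {stage}: {info}")
    lines += ["", "## Gait asymmetry scores by group (mean ± SD)", ""]
    if report.score_summary is not None:
        lines.append("| parameter | group | n | magnitude-at-plateau (%) |")
        lines.append("|---|---|---|---|")
        for _, row in report.score_summary.iterrows():
            lines.append(
                f"| {row['parameter']} | {row['group']} | {int(row['count'])} | "
                f"{row['mean']:.1f} ± {row['std']:.1f} |"
            )
    else:
        lines.append("*absent: behavioral scores*")
    lines += ["", "## Voxelwise clusters", ""]
    if report.cluster_tables:
        for contrast, ct in report.cluster_tables.items():
            lines.append(f"### Contrast {contrast}")
            lines.append("")
            if len(ct):
                lines.append("| cluster | K_E | p_FWE | x | y | z | labels |")
                lines.append("|---|---|---|---|---|---|---|")
                label_map: dict[int, str] = {}
                if ct.labels is not None:
                    for _, r in ct.labels.iterrows():
                        label_map.setdefault(int(r["cluster"]), "")
                        label_map[int(r["cluster"])] += f"{r['label_name']} ({r['overlap_pct']:.0f}%); "
                for _, row in ct.table.iterrows():
                    lines.append(
                        f"| {int(row['cluster'])} | {int(row['k_e'])} | {row['p_fwe']:.4f} | "
                        f"{row['x']:.0f} | {row['y']:.0f} | {row['z']:.0f} | "
                        f"{label_map.get(int(row['cluster']), '')} |"
                    )
            else:
                lines.append("no significant clusters")
            lines.append("")
    else:
        lines.append("*absent: cluster tables*")
    path = report.outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
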