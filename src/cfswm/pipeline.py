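"""End-to-end pipeline runner on synthetic data.

Ties the stages together at desk scale: printed design -> seeded schedules
-> simulated observers -> events tables and behavioral statistics; and
synthetic beta volumes -> gapped folds -> balanced ROI decoding -> group
permutation inference.  Every stage's randomness flows from one master seed
through named substreams, so a config run twice writes byte-identical
tables; a JSON manifest records seeds, parameters, and outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior_stats, design, events_io, mvpa, observers, synthetic_fmri


@dataclass
class RunConfig:
    experiment_id: int = 3
    n_subjects: int = 10
    master_seed: int = 0
    observer: str = "tagged"  # {"tagged", "untagged", "guess"}
    include_pas2: bool = False
    # decoding settings
    n_folds: int = 10
    min_gap_s: float = 30.0
    radius_voxels: float = 4.2
    max_roi_voxels: int = 5000
    n_iter: int = 50
    n_perm: int = 200
    decode_phase: str = "delay"
    grid_shape: tuple[int, int, int] = (24, 24, 16)
    run_decoding: bool = True
    out_dir: str = "cfswm_run"

    def validate(self) -> None:
        if self.experiment_id not in (1, 2, 3):
            raise ValueError("experiment_id must be 1, 2, or 3")
        if self.observer not in ("tagged", "untagged", "guess"):
            raise ValueError("observer must be tagged, untagged, or guess")
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if self.n_iter < 1 or self.n_folds < 2 or self.n_subjects < 2:
            raise ValueError("n_iter, n_folds, and n_subjects are out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "grid_shape" in data:
            data["grid_shape"] = tuple(data["grid_shape"])
        return cls(**data)


def _observer_params(name: str) -> observers.ObserverParams:
    return {
        "tagged": observers.tagged_observer,
        "untagged": observers.untagged_observer,
        "guess": observers.guessing_observer,
    }[name]()


@dataclass
class SubjectSeeds:
    session: int
    betas: int
    folds: int
    decode: int


def _subject_seeds(master_seed: int, subject: int) -> SubjectSeeds:
    ss = np.random.SeedSequence([master_seed, subject])
    vals = ss.generate_state(4) % (2**31 - 1)
    return SubjectSeeds(*(int(v) for v in vals))


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": [], "outputs": []}
    try:
        exp = design.build_design(config.experiment_id)
        params = _observer_params(config.observer)
        manifest["stages"].append("design")

        # --- behavior ---------------------------------------------------
        per_subject_rows = []
        performances = []
        hits_minus_guess = []
        for s in range(config.n_subjects):
            seeds = _subject_seeds(config.master_seed, s)
            schedule = design.build_schedule(exp, seeds.session)
            staircase = design.StaircaseState(current_rgb=exp.staircase.start)
            records = observers.run_session(
                schedule, params, staircase, seeds.session, exp.staircase
            )
            table = events_io.schedule_to_table(schedule, exp, records)
            for block, block_table in table.groupby("block"):
                path = out / f"sub-{s:02d}_block-{int(block)}_events.tsv"
                events_io.write_events(block_table, path)
                manifest["outputs"].append(str(path))
            retained, log = behavior_stats.apply_exclusions(
                records, include_pas2=config.include_pas2
            )
            rates = behavior_stats.compute_rates(retained, n_excluded=len(log))
            key = (design.NONCONSCIOUS, True)
            if key in rates.conditions:
                cell = rates.cell(*key)
                if cell.performance is not None:
                    performances.append(cell.performance)
                if cell.hits_minus_guess is not None:
                    hits_minus_guess.append(cell.hits_minus_guess)
                per_subject_rows.append(
                    {
                        "subject": s,
                        "hit_rate": cell.hit_rate,
                        "fa_distractor_rate": cell.fa_distractor_rate,
                        "performance": cell.performance,
                        "yes_absent_rate": rates.yes_absent_rate,
                        "n_retained": rates.n_retained,
                        "n_excluded": rates.n_excluded,
                    }
                )
        manifest["stages"].append("behavior")
        import pandas as pd

        summary = pd.DataFrame(per_subject_rows)
        summary_path = out / "behavior_summary.tsv"
        summary.to_csv(summary_path, sep="\t", index=False, float_format="%.4f")
        manifest["outputs"].append(str(summary_path))
        group_stats: dict = {}
        if len(performances) >= 2 and float(np.std(performances, ddof=1)) > 0:
            t_res = behavior_stats.one_sample_t(performances)
            bf = behavior_stats.bayes_factor_null(t_res.statistic, t_res.n)
            group_stats["nonconscious_performance"] = {
                "mean": float(np.mean(performances)),
                "t": t_res.statistic,
                "df": t_res.df,
                "p": t_res.p_two_tailed,
                "bf01": bf.bf01,
                "bf_band": bf.bf_band,
            }
        manifest["behavior_group_stats"] = group_stats
        manifest["stages"].append("behavior-stats")

        # --- decoding ---------------------------------------------------
        if config.run_decoding:
            grid = synthetic_fmri.default_grid(config.grid_shape)
            effects = synthetic_fmri.default_effects(grid)
            subjects = []
            for s in range(config.n_subjects):
                seeds = _subject_seeds(config.master_seed, s)
                schedule = design.build_schedule(exp, seeds.session)
                images = synthetic_fmri.generate_betas(
                    schedule, effects, grid, seeds.betas, phases=(config.decode_phase,)
                )
                data, labels = mvpa.stack_images(
                    images, phase=config.decode_phase, where={"condition": "conscious"}
                )
                y = labels["target_side"].to_numpy()
                folds = mvpa.build_folds(
                    labels["onset_s"].to_numpy(),
                    n_folds=config.n_folds,
                    min_gap_s=config.min_gap_s,
                    seed=seeds.folds,
                    labels=y,
                )
                X = mvpa.mask_features(data, grid.visuospatial_mask)
                subjects.append(mvpa.SubjectDecodeData(X=X, labels=y, folds=folds))
            result = mvpa.group_permutation_test(
                subjects, n_perm=config.n_perm, seed=config.master_seed
            )
            manifest["decoding"] = {
                "contrast": f"conscious-target-side-{config.decode_phase}",
                "group_accuracy": result.observed_group_accuracy,
                "p_value": result.p_value,
                "n_perm": result.n_perm,
                "per_subject": result.per_subject_observed.tolist(),
            }
            manifest["stages"].append("decoding")
    except Exception as err:  # record the failing stage, then re-raise
        manifest["failed_after"] = manifest["stages"][-1] if manifest["stages"] else None
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
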