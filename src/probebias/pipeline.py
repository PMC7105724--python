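"""End-to-end pipeline: simulate -> preprocess -> score -> infer -> regress.

A :class:`RunConfig` (YAML-serializable) pins every analysis choice — seed,
cohort size, injected effects, filter thresholds, outlier policy, ANCOVA and
ladder options — and :func:`run_pipeline` executes the stages in order,
writing tidy CSV artifacts, per-stage logs and a provenance JSON (seed,
config, row counts, content hashes). Identical config and seed yield
byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort, design, inference, ladder, preprocess, scoring

DEFAULT_LADDER_PREDICTORS = (
    "stai_t",
    "panas_pos",
    "panas_neg",
    "prss_cat",
    "prss_cope",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending context."""


@dataclass
class RunConfig:
    seed: int = 0
    n_per_sex: int = 32
    effects: list[dict] = field(default_factory=list)
    noise: dict = field(default_factory=dict)
    premature_cutoff_ms: float = 100.0
    max_rt_ms: float = 2000.0
    iqr_multiplier: float = 1.5
    outlier_scope: str = "cellwise"
    cell_mean_method: str = "side_cell"
    collapse_durations: bool = True
    alpha: float = 0.05
    ladder_predictors: list[str] = field(default_factory=lambda: list(DEFAULT_LADDER_PREDICTORS))
    ladder_outcomes: list[str] = field(
        default_factory=lambda: ["delta_avoidance", "delta_engagement", "delta_disengagement"]
    )
    out_dir: str = "probebias_run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.6g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"seed": config.seed, "config": dataclasses.asdict(config),
                        "stages": {}, "files": {}}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage context is the contract
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    schedule = stage("design", design.build_dotprobe_schedule, seed=config.seed)
    subjects = stage("cohort", cohort.sample_cohort, config.n_per_sex, seed=config.seed)
    effects = cohort.BiasEffectMap.from_dicts(config.effects)
    noise = cohort.RTNoiseParams(**config.noise)
    trials = stage(
        "simulate", cohort.simulate_experiment, subjects, schedule, effects, noise,
        seed=config.seed,
    )
    required = {"subject_id", "phase", "condition", "probe_side", "response_side", "rt_ms"}
    missing_cols = required - set(trials.columns)
    if missing_cols:
        raise PipelineError(f"stage 'preprocess' failed: missing columns {sorted(missing_cols)}")
    retained, excl_log = stage(
        "preprocess", preprocess.filter_trials, trials,
        config.premature_cutoff_ms, config.max_rt_ms,
    )
    cells = stage("aggregate", preprocess.aggregate_cell_means, retained,
                  method=config.cell_mean_method)
    cells, bounds = stage(
        "outliers", preprocess.apply_outlier_policy, cells,
        multiplier=config.iqr_multiplier, scope=config.outlier_scope,
    )
    indices = stage("score", scoring.score_indices, cells)
    deltas = stage("change_scores", scoring.change_scores, indices,
                   collapse_durations=config.collapse_durations)

    # phase x duration x sex ANCOVA (BMI covariate) per index and condition
    idx_full = indices.merge(subjects[["subject_id", "sex", "bmi"]], on="subject_id")
    anova_rows = []
    for label, grp in idx_full.groupby("target_label", observed=True):
        for index_name in scoring.INDEX_NAMES:
            grp_ok = grp.dropna(subset=[index_name])
            try:
                table = inference.rm_ancova(
                    grp_ok, dv=index_name, within=["phase", "duration_ms"],
                    between="sex", covariate="bmi",
                )
            except ValueError as exc:
                raise PipelineError(f"stage 'infer' failed for {label}/{index_name}: {exc}")
            table.insert(0, "index", index_name)
            table.insert(0, "condition", label)
            anova_rows.append(table)
    anova = pd.concat(anova_rows, ignore_index=True)

    ladder_data = deltas.merge(subjects, on="subject_id")
    ladder_rows = []
    for label, grp in ladder_data.groupby("target_label", observed=True):
        for outcome in config.ladder_outcomes:
            for predictor in config.ladder_predictors:
                try:
                    res = ladder.run_ladder(grp, outcome, predictor, alpha=config.alpha)
                except (ValueError, ladder.SingularModelError) as exc:
                    raise PipelineError(
                        f"stage 'ladder' failed for {label}/{outcome}/{predictor}: {exc}"
                    )
                ladder_rows.append(
                    {
                        "condition": label,
                        "outcome": outcome,
                        "predictor": predictor,
                        "stage": res.stage,
                        "f": res.f,
                        "p": res.p_model,
                        "adj_r2": res.adj_r2,
                        "interaction_significant": bool(
                            (res.coefficients["term"].str.startswith("sex*"))
                            .where(res.coefficients["p"] < config.alpha, False)
                            .any()
                        ),
                    }
                )
    ladder_table = pd.DataFrame(ladder_rows)

    summary = scoring.index_summary_table(indices, subjects)
    outputs = {
        "schedule.csv": schedule,
        "subjects.csv": subjects,
        "trials.csv": trials,
        "exclusion_log.csv": excl_log,
        "cell_means.csv": cells,
        "outlier_bounds.csv": bounds,
        "indices.csv": indices,
        "change_scores.csv": deltas,
        "anova_tables.csv": anova,
        "ladder_results.csv": ladder_table,
        "index_summary.csv": summary,
    }
    for name, frame in outputs.items():
        _write_csv(frame, out / name)
        provenance["stages"][name] = int(len(frame))
        provenance["files"][name] = _sha256(out / name)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return out
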