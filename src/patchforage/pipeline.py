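"""End-to-end reproducible pipeline: simulate -> score -> fit window -> regress.

Mirrors the study flow: each synthetic participant plays a pre run, a
mood shift is planted, they play a post run; LTD is scored per run at the
(fitted or overridden) CRR window; mood deltas conditioned on the realized
LTD deltas are emitted as grid ratings; three hierarchical regressions
(pre levels, post levels, deltas) close the loop.  A manifest records the
config hash, the seed-splitting rule, and every output path; re-running
with the same config reproduces every numeric output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import AgentPolicy, simulate_cohort
from .analysis import compute_ltd
from .environment import EnvironmentConfig
from .mood_stats import (
    hierarchical_compare,
    iqr_outlier_filter,
    mean_mood,
)
from .mood_synth import MoodEffectSpec, generate_mood_deltas, solve_predictor_correlation
from .records import write_event_log
from .window import WindowSelector

__all__ = ["PipelineConfig", "run_full_pipeline"]

log = logging.getLogger("patchforage.pipeline")


def _default_mood_spec(n_participants: int) -> MoodEffectSpec:
    ba, bv, r2 = 0.24, -0.33, 0.09
    return MoodEffectSpec(
        beta_arousal=ba,
        beta_valence=bv,
        predictor_correlation=solve_predictor_correlation(ba, bv, r2),
        r_squared=r2,
        n_participants=n_participants,
    )


@dataclass
class PipelineConfig:
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    policy: AgentPolicy = field(default_factory=lambda: AgentPolicy(kind="give_up_time"))
    mood_effects: MoodEffectSpec | None = None
    n_participants: int = 20
    master_seed: int = 0
    output_dir: str = "pipeline_out"
    window: float | str = "fit"  # seconds, or "fit" for the two-stage search

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if isinstance(self.window, str) and self.window != "fit":
            raise ValueError("window must be a positive number or 'fit'")
        if not isinstance(self.window, str) and self.window <= 0:
            raise ValueError("window must be a positive number or 'fit'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        env = EnvironmentConfig(**doc.get("environment", {}))
        policy = AgentPolicy(**doc.get("policy", {}))
        mood = None
        if "mood_effects" in doc:
            m = dict(doc["mood_effects"])
            if "predictor_correlation" not in m:
                m["predictor_correlation"] = solve_predictor_correlation(
                    m["beta_arousal"], m["beta_valence"], m["r_squared"]
                )
            m.setdefault("n_participants", doc.get("n_participants", 20))
            mood = MoodEffectSpec(**m)
        return cls(
            environment=env,
            policy=policy,
            mood_effects=mood,
            n_participants=doc.get("n_participants", 20),
            master_seed=doc.get("master_seed", 0),
            output_dir=doc.get("output_dir", "pipeline_out"),
            window=doc.get("window", "fit"),
        )


def _config_hash(config: PipelineConfig) -> str:
    doc = {
        "environment": dataclasses.asdict(config.environment),
        "policy": dataclasses.asdict(config.policy),
        "mood_effects": dataclasses.asdict(config.mood_effects) if config.mood_effects else None,
        "n_participants": config.n_participants,
        "master_seed": config.master_seed,
        "window": config.window,
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


# stage seeds are the first 32-bit words of SeedSequence(master_seed).spawn(k)
_STAGES = ("cohort", "layouts", "mood")


def _stage_seeds(master_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the run manifest."""
    t0 = time.monotonic()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "master_seed": config.master_seed,
        "seed_rule": "SeedSequence(master_seed).spawn per stage: " + ", ".join(_STAGES),
        "stage_seeds": seeds,
        "outputs": {},
    }

    stage = "simulate_cohort"
    try:
        log.info("stage=%s seed=%d", stage, seeds["cohort"])
        cohort = simulate_cohort(
            layout_seed_base=seeds["layouts"],
            policy=config.policy,
            n=config.n_participants,
            runs_per_participant=2,
            seed=seeds["cohort"],
            config=config.environment,
        )
        log_dir = out / "logs"
        log_dir.mkdir(exist_ok=True)
        log_paths = []
        for pid, run_index, eventlog in cohort:
            p = log_dir / f"{pid}_{run_index}.csv"
            write_event_log(eventlog, p)
            log_paths.append(str(p))
        manifest["outputs"]["event_logs"] = log_paths

        stage = "fit_window"
        pre_logs = [lg for _, run, lg in cohort if run == "pre"]
        if config.window == "fit":
            selector = WindowSelector().fit(pre_logs)
            window_s = selector.best_window_s_
            manifest["window"] = {
                "mode": "fit",
                "stage1_grid": [
                    selector.stage1_result_.grid.start_s,
                    selector.stage1_result_.grid.stop_s,
                    selector.stage1_result_.grid.step_s,
                ],
                "stage2_grid": [
                    selector.stage2_result_.grid.start_s,
                    selector.stage2_result_.grid.stop_s,
                    selector.stage2_result_.grid.step_s,
                ],
                "best_window_s": window_s,
                "best_mean_ltd": selector.best_mean_ltd_,
            }
        else:
            window_s = float(config.window)
            manifest["window"] = {"mode": "override", "best_window_s": window_s}
        log.info("stage=fit_window window_s=%.3f", window_s)

        stage = "compute_ltd"
        ltd_rows = []
        for pid, run_index, eventlog in cohort:
            res = compute_ltd(eventlog, window_s)
            ltd_rows.append(
                {
                    "participant_id": pid,
                    "run_index": run_index,
                    "participant_ltd": res.participant_ltd,
                    "n_visits": len(res.per_visit),
                    "n_excluded": res.n_excluded,
                }
            )
        ltd_df = pd.DataFrame(ltd_rows)
        ltd_path = out / "ltd_summary.csv"
        ltd_df.to_csv(ltd_path, index=False)
        manifest["outputs"]["ltd_summary"] = str(ltd_path)

        wide = ltd_df.pivot(index="participant_id", columns="run_index", values="participant_ltd")
        wide = wide.dropna()
        if len(wide) < 4:
            raise RuntimeError("fewer than 4 participants with defined LTD on both runs")

        stage = "generate_mood_deltas"
        mood_spec = config.mood_effects or _default_mood_spec(len(wide))
        ltd_delta = (wide["post"] - wide["pre"]).to_numpy()
        deltas, ratings = generate_mood_deltas(mood_spec, seed=seeds["mood"], ltd_deltas=ltd_delta)
        deltas["participant_id"] = list(wide.index)
        ratings["participant_id"] = np.repeat(list(wide.index), 6)
        mood_path = out / "mood_ratings.csv"
        ratings.to_csv(mood_path, index=False)
        manifest["outputs"]["mood_ratings"] = str(mood_path)

        stage = "regress"
        keep = iqr_outlier_filter(wide["pre"].to_numpy()) & iqr_outlier_filter(
            wide["post"].to_numpy()
        )
        kept_ids = [pid for pid, k in zip(wide.index, keep) if k]
        manifest["n_outliers_removed"] = int((~keep).sum())

        rows = []
        frames = {
            "pre": pd.DataFrame(
                {
                    "participant_id": kept_ids,
                    "delta_arousal": [
                        mean_mood(ratings, (1, 2), pid)[0] for pid in kept_ids
                    ],
                    "delta_valence": [
                        mean_mood(ratings, (1, 2), pid)[1] for pid in kept_ids
                    ],
                    "delta_ltd": wide.loc[kept_ids, "pre"].to_numpy(),
                }
            ),
            "post": pd.DataFrame(
                {
                    "participant_id": kept_ids,
                    "delta_arousal": [
                        mean_mood(ratings, (5, 6), pid)[0] for pid in kept_ids
                    ],
                    "delta_valence": [
                        mean_mood(ratings, (5, 6), pid)[1] for pid in kept_ids
                    ],
                    "delta_ltd": wide.loc[kept_ids, "post"].to_numpy(),
                }
            ),
            "delta": deltas[deltas["participant_id"].isin(kept_ids)],
        }
        for model_name, frame in frames.items():
            chosen, comparison = hierarchical_compare(frame)
            for term in chosen.terms:
                rows.append(
                    {
                        "model": model_name,
                        "term": term,
                        "beta": chosen.beta[term],
                        "ci_low": chosen.conf_int[term][0],
                        "ci_high": chosen.conf_int[term][1],
                        "p_raw": chosen.p_values[term],
                        "p_corr": chosen.p_corrected[term],
                        "r_squared": chosen.r_squared,
                        "bic": chosen.bic,
                        "n": chosen.n,
                        "chosen_model": comparison["chosen"],
                    }
                )
        reg_df = pd.DataFrame(rows)
        reg_path = out / "regressions.tsv"
        reg_df.to_csv(reg_path, sep="\t", index=False)
        manifest["outputs"]["regressions"] = str(reg_path)
    except Exception as exc:  # annotate the failing stage and re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["elapsed_s"] = round(time.monotonic() - t0, 3)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
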