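"""Orchestration of seeded experiment batches and per-trial measures.

An :class:`ExperimentPlan` lists design cells — combinations of sensing
radius (fog ~10 m vs clear ~150 m), global information (HUD vs compass),
target count (9 vs 18), and scripted strategy — and a number of seeded
replicate trials per cell.  :func:`run_experiment` simulates every
cell x replicate with a deterministic per-trial seed derived from the
root seed, computes the per-trial measures (duration and outcome, search
overlap proportion, and both DFA channels for every player), and returns
a tidy metrics table.  Stage failures (e.g. a series too short for DFA)
are recorded per trial and the run continues.

:func:`summarize` reduces the metrics table to per-cell means with
percentile-bootstrap confidence intervals, and
:func:`direction_checks` compares matched cells on the qualitative
directions expected of the manipulations (global information and clear
visibility speed completion; more targets slow it; partitioned search
overlaps less than shared search).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .dfa import DFAConfig, dfa_alpha
from .overlap import trial_overlap
from .simulate import PolicyConfig, TrialLog, WorldConfig, run_trial
from .timeseries import (
    displacement_angle_series,
    head_orientation_change_series,
    prepared_player_tracks,
    write_trial_log,
)

__all__ = [
    "ExperimentCell",
    "ExperimentPlan",
    "default_cells",
    "trial_seed",
    "trial_metrics",
    "run_experiment",
    "summarize",
    "direction_checks",
]

FOG_SENSE_RADIUS = 10.0
CLEAR_SENSE_RADIUS = 150.0


@dataclass(frozen=True)
class ExperimentCell:
    """One design cell of the emulated experiment."""

    name: str
    sense_radius: float = CLEAR_SENSE_RADIUS
    global_info: bool = True
    n_targets: int = 9
    strategy: str = "partitioned_sweep"

    def policy_config(self, **overrides: Any) -> PolicyConfig:
        return PolicyConfig(
            strategy=self.strategy,
            sense_radius=self.sense_radius,
            global_info=self.global_info,
            **overrides,
        )

    def world_config(self, base: WorldConfig | None = None) -> WorldConfig:
        base = base or WorldConfig()
        return dataclasses.replace(base, n_targets=self.n_targets)

    def labels(self) -> dict[str, Any]:
        return {
            "cell": self.name,
            "sense_radius": self.sense_radius,
            "global_info": self.global_info,
            "n_targets": self.n_targets,
            "strategy": self.strategy,
            "visibility": "clear" if self.sense_radius >= CLEAR_SENSE_RADIUS else "fog",
            "hud": "global" if self.global_info else "compass",
        }


@dataclass(frozen=True)
class ExperimentPlan:
    """Cells, replicate count, root seed, and optional on-disk output."""

    cells: tuple[ExperimentCell, ...]
    trials_per_cell: int
    root_seed: int
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        names = [c.name for c in self.cells]
        if len(set(names)) != len(names):
            raise ValueError("cell names must be unique")


def default_cells(strategy: str = "partitioned_sweep") -> tuple[ExperimentCell, ...]:
    """The 2 x 2 x 2 design (Visibility x HUD x Target Number) for one strategy."""
    cells = []
    for sense, vis in ((FOG_SENSE_RADIUS, "fog"), (CLEAR_SENSE_RADIUS, "clear")):
        for global_info, hud in ((True, "hud"), (False, "compass")):
            for n_targets in (9, 18):
                cells.append(
                    ExperimentCell(
                        name=f"{vis}-{hud}-{n_targets}ta",
                        sense_radius=sense,
                        global_info=global_info,
                        n_targets=n_targets,
                        strategy=strategy,
                    )
                )
    return tuple(cells)


def trial_seed(root_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-trial seed below 2**31."""
    ss = np.random.SeedSequence(root_seed, spawn_key=(cell_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def trial_metrics(
    log: TrialLog, dfa_config: DFAConfig | None = None
) -> dict[str, Any]:
    """Per-trial measures from one log: duration, overlap, DFA channels."""
    row: dict[str, Any] = {
        "duration": log.duration,
        "outcome": log.outcome,
        "event": log.outcome == "success",
    }
    try:
        result = trial_overlap(log)
        row["proportion_overlap"] = result.proportion
        row["total_search_area"] = result.total_area
    except Exception as exc:  # noqa: BLE001 - recorded, run continues
        row["proportion_overlap"] = np.nan
        row["overlap_error"] = str(exc)

    disp, head = [], []
    for i in range(log.n_players):
        try:
            positions, headings = prepared_player_tracks(log, i)
            d = dfa_alpha(displacement_angle_series(positions).values, dfa_config)
            h = dfa_alpha(head_orientation_change_series(headings).values, dfa_config)
            row[f"dfa_disp_p{i}"] = d.alpha
            row[f"dfa_head_p{i}"] = h.alpha
            disp.append(d.alpha)
            head.append(h.alpha)
        except Exception as exc:  # noqa: BLE001
            row[f"dfa_disp_p{i}"] = np.nan
            row[f"dfa_head_p{i}"] = np.nan
            row[f"dfa_error_p{i}"] = str(exc)
    row["dfa_disp_mean"] = float(np.mean(disp)) if disp else np.nan
    row["dfa_head_mean"] = float(np.mean(head)) if head else np.nan
    return row


def run_experiment(
    plan: ExperimentPlan,
    world_base: WorldConfig | None = None,
    dfa_config: DFAConfig | None = None,
    policy_overrides: dict[str, Any] | None = None,
) -> pd.DataFrame:
    """Simulate and measure every cell x replicate of a plan.

    Fully reproducible from the plan: per-trial seeds derive from
    ``root_seed`` and the (cell, replicate) indices.  With
    ``plan.output_dir`` set, each trial log and manifest is written there
    so every metrics row is traceable to an on-disk record.
    """
    out_dir = Path(plan.output_dir) if plan.output_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, cell in enumerate(plan.cells):
        world = cell.world_config(world_base)
        policy = cell.policy_config(**(policy_overrides or {}))
        policies = [policy] * 3
        for rep in range(plan.trials_per_cell):
            seed = trial_seed(plan.root_seed, ci, rep)
            labels = cell.labels() | {"replicate": rep, "seed": seed}
            try:
                log, _ = run_trial(world, policies, seed, condition=labels)
            except Exception as exc:  # noqa: BLE001 - per-trial failure recorded
                rows.append(labels | {"trial_error": str(exc)})
                continue
            if out_dir is not None:
                log_path = out_dir / f"{cell.name}_rep{rep}.csv"
                write_trial_log(log, log_path)
                labels["log_path"] = str(log_path)
            rows.append(labels | trial_metrics(log, dfa_config))
    return pd.DataFrame(rows)


_SUMMARY_MEASURES = ("duration", "proportion_overlap", "dfa_disp_mean", "dfa_head_mean")


def summarize(
    metrics: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    measures: tuple[str, ...] = _SUMMARY_MEASURES,
) -> pd.DataFrame:
    """Per-cell means with 95% percentile-bootstrap confidence intervals."""
    if "cell" not in metrics.columns or metrics.empty:
        raise ValueError("metrics table must contain a non-empty 'cell' column")
    rng = np.random.default_rng(seed)
    out = []
    for cell, group in metrics.groupby("cell", sort=False):
        row: dict[str, Any] = {"cell": cell, "n_trials": len(group)}
        for col in ("visibility", "hud", "n_targets", "strategy"):
            if col in group.columns:
                row[col] = group[col].iloc[0]
        for m in measures:
            values = group[m].to_numpy(float) if m in group.columns else np.array([])
            values = values[np.isfinite(values)]
            row[f"n_{m}"] = values.size
            if values.size == 0:
                row[f"{m}_mean"] = np.nan
                row[f"{m}_ci_low"] = np.nan
                row[f"{m}_ci_high"] = np.nan
                continue
            row[f"{m}_mean"] = float(values.mean())
            idx = rng.integers(0, values.size, size=(n_boot, values.size))
            boot = values[idx].mean(axis=1)
            row[f"{m}_ci_low"] = float(np.percentile(boot, 2.5))
            row[f"{m}_ci_high"] = float(np.percentile(boot, 97.5))
        out.append(row)
    return pd.DataFrame(out)


def direction_checks(metrics: pd.DataFrame) -> dict[str, bool]:
    """Qualitative direction flags comparing matched condition cells.

    Means are taken across all trials on each side of a factor.  Flags:

    * ``hud_faster``   — global-information trials complete no slower
    * ``clear_faster`` — clear-visibility trials complete no slower
    * ``more_targets_slower`` — 18-target trials take at least as long
    * ``partitioned_less_overlap`` — partitioned sweep overlaps strictly
      less than shared sweep (when both strategies are present)
    * ``overlap_duration_positive`` — trials overlapping more take longer
      (Spearman correlation > 0), i.e. division of labor helps
    """
    flags: dict[str, bool] = {}

    def mean_of(mask: pd.Series, col: str) -> float:
        vals = metrics.loc[mask, col].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else np.nan

    if "hud" in metrics.columns and metrics["hud"].nunique() > 1:
        flags["hud_faster"] = mean_of(metrics["hud"] == "global", "duration") <= mean_of(
            metrics["hud"] == "compass", "duration"
        )
    if "visibility" in metrics.columns and metrics["visibility"].nunique() > 1:
        flags["clear_faster"] = mean_of(
            metrics["visibility"] == "clear", "duration"
        ) <= mean_of(metrics["visibility"] == "fog", "duration")
    if "n_targets" in metrics.columns and metrics["n_targets"].nunique() > 1:
        flags["more_targets_slower"] = mean_of(
            metrics["n_targets"] == 18, "duration"
        ) >= mean_of(metrics["n_targets"] == 9, "duration")
    if "strategy" in metrics.columns and {
        "partitioned_sweep",
        "shared_sweep",
    } <= set(metrics["strategy"].unique()):
        flags["partitioned_less_overlap"] = mean_of(
            metrics["strategy"] == "partitioned_sweep", "proportion_overlap"
        ) < mean_of(metrics["strategy"] == "shared_sweep", "proportion_overlap")
    ok = metrics[["proportion_overlap", "duration"]].dropna()
    if len(ok) >= 3 and ok["proportion_overlap"].nunique() > 1 and ok["duration"].nunique() > 1:
        rho = ok["proportion_overlap"].corr(ok["duration"], method="spearman")
        flags["overlap_duration_positive"] = bool(rho > 0)
    return flags
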