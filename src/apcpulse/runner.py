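"""Scenario-suite experiment runner: model -> traces -> analytics.

Chains the three computational layers for every named scenario in a
:class:`~apcpulse.config.RunConfig`, writes all intermediate and final
tables as delimited text into the run directory, and finishes with an
atomically written JSON manifest that echoes the effective configuration
— enough to re-execute the run bit-identically (timestamps excepted).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analytics import (
    classify_trace,
    divergence_time,
    fraction_transient,
    median_trace,
    normalize_to_control,
    percent_inactivation,
)
from .config import RunConfig, config_to_dict
from .io import write_traces, write_trajectory
from .model import simulate
from .synth import PopulationConfig, TraceTable, generate_population

logger = logging.getLogger("apcpulse")

__all__ = ["RunManifest", "run_experiment", "summarize", "analyze_table"]


@dataclass
class RunManifest:
    """Record of one completed run: config echo, outputs, wall-clock stamps."""

    config: dict
    version: str
    seed: int
    outputs: dict[str, list[str]] = field(default_factory=dict)
    started_at: float = 0.0
    finished_at: float = 0.0
    failed_stage: str | None = None

    def write(self, path: Path) -> Path:
        """Atomic write: the manifest appears complete or not at all."""
        payload = dataclasses.asdict(self)
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
            os.replace(tmp, path)
        finally:
            if os.path.exists(tmp):
                os.unlink(tmp)
        return path


def analyze_table(table: TraceTable, cfg: RunConfig) -> pd.DataFrame:
    """Per-cell analytics for one scenario's trace table.

    Always classifies each reporter trace; additionally reports pre/post
    MG132 slopes and percent inactivation when the run used the reporter
    mechanics with an MG132 time.
    """
    a = cfg.analysis
    mg = cfg.reporter.mg132_time
    with_slopes = (
        cfg.population.generator_mode == "reporter_mechanics" and mg is not None
    )
    rows = []
    for cell_id, cell in table.data[table.data["channel"] == "apc_reporter"].groupby(
        "cell_id", sort=False
    ):
        tc = classify_trace(
            cell,
            min_prominence=a.min_prominence,
            terminal_fraction=a.terminal_fraction,
            smooth_window=a.smooth_window,
        )
        row = {
            "cell_id": cell_id,
            "scenario": cell["scenario"].iloc[0],
            "label": tc.label,
            "peak_value": tc.peak_value,
            "peak_time": tc.peak_time,
            "baseline": tc.baseline,
            "terminal_value": tc.terminal_value,
            "prominence": tc.prominence,
            "slope_pre": np.nan,
            "slope_post": np.nan,
            "percent_inactivation": np.nan,
        }
        if with_slopes:
            est = percent_inactivation(
                cell, mg, pre_window=a.pre_window, post_window=a.post_window
            )
            row.update(
                slope_pre=est.slope_pre,
                slope_post=est.slope_post,
                percent_inactivation=est.percent_inactivation,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    analytics: dict[str, pd.DataFrame],
    medians: dict[str, tuple[np.ndarray, np.ndarray]],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Run-level summary: one row per scenario.

    Reports the transient fraction, its ratio to the control scenario,
    the median percent inactivation (where slopes were computed) and the
    divergence time of the scenario median from the control median.
    """
    if not analytics:
        raise ValueError("no analyzed scenarios to summarize")
    control = cfg.control_scenario
    if control not in analytics:
        raise ValueError(f"control scenario {control!r} missing from analytics")
    a = cfg.analysis
    t_ctrl, m_ctrl = medians[control]
    eps = a.epsilon_fraction * float(np.ptp(m_ctrl))

    f_control = fraction_transient(analytics[control]["label"])
    rows = []
    for name, df in analytics.items():
        f = fraction_transient(df["label"])
        pct = df["percent_inactivation"].dropna()
        if name == control:
            div = None
        else:
            res = divergence_time(
                (t_ctrl, m_ctrl), medians[name], epsilon=eps,
                sustain_points=a.sustain_points,
            )
            div = res.divergence_time
        rows.append(
            {
                "scenario": name,
                "n_cells": df["cell_id"].nunique(),
                "fraction_transient": f,
                "fraction_transient_vs_control": (
                    normalize_to_control(f, f_control) if f_control > 0 else np.nan
                ),
                "median_percent_inactivation": (
                    float(pct.median()) if len(pct) else np.nan
                ),
                "divergence_time_vs_control": np.nan if div is None else div,
            }
        )
    return pd.DataFrame(rows)


def run_experiment(cfg: RunConfig, scenarios: list[str] | None = None) -> RunManifest:
    """Execute the full suite: simulate, generate, analyze, summarize.

    Every output is a delimited text file under ``cfg.output_dir``; the
    manifest is written last.  A failure in any stage aborts the run with
    the stage name; the manifest then records the failed stage and the
    outputs produced so far.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config_to_dict(cfg),
        version=__version__,
        seed=cfg.seed,
        started_at=time.time(),
    )
    names = scenarios if scenarios is not None else list(cfg.protocols)
    unknown = sorted(set(names) - set(cfg.protocols))
    if unknown:
        raise ValueError(f"unknown scenario(s): {', '.join(unknown)}")

    analytics: dict[str, pd.DataFrame] = {}
    medians: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    stage = "setup"
    try:
        for name in names:
            protocol = cfg.protocols[name]
            stage = f"simulate[{name}]"
            logger.info("simulating scenario %s", name)
            traj = simulate(
                cfg.model,
                protocol,
                t_end=cfg.population.duration,
                output_dt=cfg.population.sampling_interval,
            )
            traj_file = write_trajectory(traj, outdir / f"trajectory_{name}.csv")
            manifest.outputs.setdefault("trajectories", []).append(str(traj_file))

            stage = f"generate[{name}]"
            pop_cfg = dataclasses.replace(
                cfg.population, scenario=name, seed=cfg.seed
            )
            table = generate_population(
                cfg.model, protocol, cfg.reporter, pop_cfg, base_trajectory=traj
            )
            trace_file = write_traces(table, outdir / f"traces_{name}.csv")
            manifest.outputs.setdefault("traces", []).append(str(trace_file))

            stage = f"analyze[{name}]"
            analytics[name] = analyze_table(table, cfg)
            medians[name] = median_trace(table, scenario=name)
            an_file = outdir / f"analytics_{name}.csv"
            analytics[name].to_csv(an_file, index=False)
            manifest.outputs.setdefault("analytics", []).append(str(an_file))

        stage = "summarize"
        summary = summarize(analytics, medians, cfg)
        summary_file = outdir / "summary.csv"
        summary.to_csv(summary_file, index=False)
        manifest.outputs["summary"] = [str(summary_file)]
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.finished_at = time.time()
        manifest.write(outdir / "manifest.json")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest.finished_at = time.time()
    manifest.write(outdir / "manifest.json")
    logger.info("run complete: %s", outdir)
    return manifest
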