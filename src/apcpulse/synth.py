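"""Synthetic single-cell biosensor traces.

This layer stands in for live-cell imaging of quiescent epithelial cells
(e.g. MCF-10A) re-entering the cell cycle: fluorescence is sampled every
12 min (0.2 h), cells differ in expression scale, and measurements carry
multiplicative noise.  Two kinds of traces are produced:

* APC/C degron-reporter traces.  Two generator modes exist because the
  model's GEMININ variable and the physical biosensor are different
  objects:

  - ``model_direct`` emits the model GEMININ series, scaled per cell.  It
    cannot represent MG132, which acts on the degradation machinery, not
    on the modelled drive.
  - ``reporter_mechanics`` integrates the reporter ODE
    dG/dt = synthesis - d_max * APC(t) * G, i.e. a constitutively
    expressed degron fusion degraded in proportion to APC/C activity.
    Adding the proteasome inhibitor MG132 at ``mg132_time`` zeroes the
    degradation term, so the post-MG132 accumulation slope equals the
    synthesis rate exactly — the 100 %-inhibition reference exploited by
    the slope-ratio analytics.

* CDK2 activity traces: a phenomenological saturating ramp from a
  quiescent level towards a cycling plateau for cells that enter the
  cycle, and a flat quiescent trace otherwise, with per-cell truth labels.

Randomness policy: one root seed; each cell draws from an independent
substream keyed by (root seed, cell index), so enlarging ``n_cells``
never reshuffles earlier cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .model import (
    KineticParameters,
    StimulusProtocol,
    Trajectory,
    simulate,
)

__all__ = [
    "ReporterParameters",
    "PopulationConfig",
    "Cdk2GeneratorParams",
    "TraceTable",
    "reporter_from_apc",
    "generate_population",
    "generate_cdk2_population",
    "add_noise",
]

TRACE_COLUMNS = ["cell_id", "scenario", "time_h", "channel", "value"]


@dataclass(frozen=True)
class ReporterParameters:
    """Degron-reporter mechanics.

    synthesis_rate:
        Constitutive production, arbitrary fluorescence units per hour.
    max_degradation_rate:
        First-order degradation rate (1/h) at full APC/C activity.
    mg132_time:
        Proteasome-inhibitor addition time (h); degradation is zero from
        then on.  None means no MG132.
    initial_level:
        Starting fluorescence; defaults to synthesis/degradation, the
        quasi-steady level of a quiescent cell with fully active APC/C.
    """

    synthesis_rate: float = 1.0
    max_degradation_rate: float = 1.0
    mg132_time: float | None = None
    initial_level: float | None = None

    def __post_init__(self) -> None:
        if self.synthesis_rate <= 0:
            raise ValueError("synthesis_rate must be > 0")
        if self.max_degradation_rate < 0:
            raise ValueError("max_degradation_rate must be >= 0")
        if self.mg132_time is not None and self.mg132_time < 0:
            raise ValueError("mg132_time must be >= 0")
        if self.initial_level is not None and self.initial_level < 0:
            raise ValueError("initial_level must be >= 0")

    def resolved_initial(self) -> float:
        if self.initial_level is not None:
            return self.initial_level
        if self.max_degradation_rate == 0:
            return 0.0
        return self.synthesis_rate / self.max_degradation_rate


@dataclass(frozen=True)
class PopulationConfig:
    """Population size, heterogeneity, noise and sampling of a synthetic run."""

    n_cells: int = 200
    parameter_cv: float = 0.15
    noise_sd: float = 0.05
    sampling_interval: float = 0.2
    duration: float = 24.0
    seed: int = 0
    scenario: str = "control"
    generator_mode: Literal["model_direct", "reporter_mechanics"] = "model_direct"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.parameter_cv < 0:
            raise ValueError("parameter_cv must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.duration < self.sampling_interval:
            raise ValueError("duration must cover at least one interval")
        if self.generator_mode not in ("model_direct", "reporter_mechanics"):
            raise ValueError(f"unknown generator_mode {self.generator_mode!r}")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.sampling_interval))
        return np.linspace(0.0, n * self.sampling_interval, n + 1)


@dataclass(frozen=True)
class Cdk2GeneratorParams:
    """Phenomenological CDK2-activity trace shape.

    Cycling cells ramp from ``quiescent_level`` to ``cycling_plateau`` as
    1 - exp(-rise_rate * (t - onset)) after an onset drawn from a normal
    distribution truncated to [0, onset_clip]; quiescent cells stay flat.
    """

    quiescent_level: float = 0.5
    cycling_plateau: float = 1.5
    rise_onset_mean: float = 6.0
    rise_onset_sd: float = 2.0
    rise_rate: float = 1.0
    fraction_cycling_true: float = 0.7
    onset_clip: float = 16.0

    def __post_init__(self) -> None:
        if self.cycling_plateau <= self.quiescent_level:
            raise ValueError("cycling_plateau must exceed quiescent_level")
        if not 0.0 <= self.fraction_cycling_true <= 1.0:
            raise ValueError("fraction_cycling_true must be in [0, 1]")
        if self.rise_rate <= 0 or self.rise_onset_sd < 0:
            raise ValueError("rise_rate must be > 0 and rise_onset_sd >= 0")


@dataclass
class TraceTable:
    """Tidy long-format collection of single-cell traces with ground truth.

    ``data`` holds one row per (cell, sample):
    cell_id, scenario, time_h, channel, value.  ``cell_meta`` holds one row
    per cell with the generator's truth: per-cell parameter scales and, for
    CDK2 traces, the cycling label.
    """

    data: pd.DataFrame
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trace table missing columns: {missing}")
        self.data = self.data[TRACE_COLUMNS].reset_index(drop=True)

    def cells(self) -> list[str]:
        return list(dict.fromkeys(self.data["cell_id"]))

    def trace(self, cell_id: str, channel: str | None = None) -> pd.DataFrame:
        sel = self.data[self.data["cell_id"] == cell_id]
        if channel is not None:
            sel = sel[sel["channel"] == channel]
        if sel.empty:
            raise KeyError(f"no trace for cell {cell_id!r} channel {channel!r}")
        return sel.reset_index(drop=True)

    def pivot(self, channel: str) -> pd.DataFrame:
        """Wide matrix: index time_h, one column per cell (single channel)."""
        sel = self.data[self.data["channel"] == channel]
        if sel.empty:
            raise KeyError(f"no rows for channel {channel!r}")
        return sel.pivot(index="time_h", columns="cell_id", values="value")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraceTable):
            return NotImplemented
        return self.data.equals(other.data) and self.cell_meta.equals(
            other.cell_meta
        )


def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    # substream keyed by (root seed, cell index): stable under n_cells changes
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(cell_index,)))


def _lognormal_scale(rng: np.random.Generator, cv: float) -> float:
    """Draw a positive scale with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return float(rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2)))


def add_noise(
    series: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Multiplicative Gaussian measurement noise, truncated at zero.

    Each value becomes value * (1 + eps) with eps ~ N(0, noise_sd);
    negative results are clipped to 0.  Deterministic given the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    series = np.asarray(series, dtype=float)
    if noise_sd == 0:
        return series.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=series.shape)
    return np.maximum(series * (1.0 + eps), 0.0)


def reporter_from_apc(
    times: np.ndarray,
    apc: np.ndarray,
    rp: ReporterParameters,
    synthesis_scale: float = 1.0,
    degradation_scale: float = 1.0,
) -> np.ndarray:
    """Integrate the reporter ODE driven by an APC/C activity series.

    dG/dt = s - d_eff(t) * apc(t) * G, with d_eff = max_degradation_rate
    before ``mg132_time`` and 0 after.  APC/C activity is held
    piecewise-constant at its left-grid value on each sampling interval,
    for which the linear ODE is solved exactly per interval.  If
    ``mg132_time`` falls inside an interval the interval is split there.
    """
    times = np.asarray(times, dtype=float)
    apc = np.asarray(apc, dtype=float)
    if times.shape != apc.shape:
        raise ValueError("times and apc must be aligned")
    if np.any(apc < -1e-9) or np.any(apc > 1 + 1e-9):
        raise ValueError("apc values must lie in [0, 1]")

    s = rp.synthesis_rate * synthesis_scale
    d_max = rp.max_degradation_rate * degradation_scale
    init = rp.resolved_initial()
    if rp.initial_level is None and d_max > 0:
        init = s / d_max  # quiescent quasi-steady level of this cell
    mg = rp.mg132_time

    out = np.empty_like(times)
    g = float(init)
    out[0] = g
    for i in range(len(times) - 1):
        t0, t1 = times[i], times[i + 1]
        a = apc[i]
        # split the interval at the MG132 switch if it lands inside
        if mg is not None and t0 < mg < t1:
            g = _advance(g, s, d_max * a, mg - t0)
            g = _advance(g, s, 0.0, t1 - mg)
        else:
            rate = 0.0 if (mg is not None and t0 >= mg) else d_max * a
            g = _advance(g, s, rate, t1 - t0)
        if g < 0:
            raise RuntimeError("reporter level went negative (internal error)")
        out[i + 1] = g
    return out


def _advance(g: float, s: float, r: float, h: float) -> float:
    """Exact step of dG/dt = s - r*G over duration h (r constant)."""
    if r == 0.0:
        return g + s * h
    e = math.exp(-r * h)
    return g * e + (s / r) * (1.0 - e)


def generate_population(
    params: KineticParameters | None = None,
    protocol: StimulusProtocol | None = None,
    rp: ReporterParameters | None = None,
    cfg: PopulationConfig | None = None,
    base_trajectory: Trajectory | None = None,
) -> TraceTable:
    """Generate a heterogeneous, noisy population of APC/C-reporter traces.

    The deterministic model is solved once on the sampling grid; each cell
    then applies its own lognormal parameter scales (CV = ``parameter_cv``)
    and multiplicative measurement noise (sd = ``noise_sd``).  In
    ``model_direct`` mode the emitted signal is the per-cell-scaled model
    GEMININ series; in ``reporter_mechanics`` mode the reporter ODE is
    driven by the model APC series with per-cell synthesis and degradation
    scales.  Pass ``base_trajectory`` to reuse an existing model solution
    (it must be on the sampling grid).
    """
    params = params or KineticParameters()
    protocol = protocol or StimulusProtocol()
    rp = rp or ReporterParameters()
    cfg = cfg or PopulationConfig()

    if cfg.generator_mode == "model_direct" and rp.mg132_time is not None:
        raise ValueError(
            "MG132 has no representation in model_direct mode; "
            "use generator_mode='reporter_mechanics'"
        )

    grid = cfg.time_grid()
    if base_trajectory is None:
        base_trajectory = simulate(
            params, protocol, t_end=float(grid[-1]), output_dt=cfg.sampling_interval
        )
    if not np.allclose(base_trajectory.times, grid):
        raise ValueError("base_trajectory grid does not match the sampling grid")

    geminin = base_trajectory["geminin"]
    apc = np.clip(base_trajectory["apc"], 0.0, 1.0)

    frames = []
    meta_rows = []
    for ci in range(cfg.n_cells):
        rng = _cell_rng(cfg.seed, ci)
        syn_scale = _lognormal_scale(rng, cfg.parameter_cv)
        deg_scale = _lognormal_scale(rng, cfg.parameter_cv)
        cell_id = f"{cfg.scenario}_c{ci:04d}"

        if cfg.generator_mode == "model_direct":
            clean = syn_scale * geminin
        else:
            clean = reporter_from_apc(
                grid, apc, rp, synthesis_scale=syn_scale, degradation_scale=deg_scale
            )
        noisy = add_noise(clean, cfg.noise_sd, rng)

        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "scenario": cfg.scenario,
                    "time_h": grid,
                    "channel": "apc_reporter",
                    "value": noisy,
                }
            )
        )
        meta_rows.append(
            {
                "cell_id": cell_id,
                "scenario": cfg.scenario,
                "channel": "apc_reporter",
                "synthesis_scale": syn_scale,
                "degradation_scale": deg_scale,
                "generator_mode": cfg.generator_mode,
            }
        )

    data = pd.concat(frames, ignore_index=True)
    return TraceTable(data=data, cell_meta=pd.DataFrame(meta_rows))


def generate_cdk2_population(
    cp: Cdk2GeneratorParams | None = None,
    cfg: PopulationConfig | None = None,
) -> TraceTable:
    """Generate CDK2-activity traces for a cycling/quiescent cell mixture.

    Each cell is cycling with probability ``fraction_cycling_true``
    (recorded as the truth label).  Cycling cells follow the saturating
    ramp of :class:`Cdk2GeneratorParams`; quiescent cells stay at the
    quiescent level.  Noise as in :func:`generate_population`.
    """
    cp = cp or Cdk2GeneratorParams()
    cfg = cfg or PopulationConfig()
    grid = cfg.time_grid()

    frames = []
    meta_rows = []
    for ci in range(cfg.n_cells):
        rng = _cell_rng(cfg.seed, ci)
        cycling = bool(rng.random() < cp.fraction_cycling_true)
        onset = float(
            np.clip(rng.normal(cp.rise_onset_mean, cp.rise_onset_sd), 0.0, cp.onset_clip)
        )
        cell_id = f"{cfg.scenario}_c{ci:04d}"

        if cycling:
            dt_on = np.maximum(grid - onset, 0.0)
            clean = cp.quiescent_level + (cp.cycling_plateau - cp.quiescent_level) * (
                1.0 - np.exp(-cp.rise_rate * dt_on)
            )
        else:
            clean = np.full_like(grid, cp.quiescent_level)
        noisy = add_noise(clean, cfg.noise_sd, rng)

        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "scenario": cfg.scenario,
                    "time_h": grid,
                    "channel": "cdk2_activity",
                    "value": noisy,
                }
            )
        )
        meta_rows.append(
            {
                "cell_id": cell_id,
                "scenario": cfg.scenario,
                "channel": "cdk2_activity",
                "cycling_true": cycling,
                "rise_onset": onset if cycling else float("nan"),
            }
        )

    data = pd.concat(frames, ignore_index=True)
    return TraceTable(data=data, cell_meta=pd.DataFrame(meta_rows))
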