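"""Incoherent-feedforward-loop (IFFL) model of APC/C activity during cell-cycle entry.

The model describes how mitogen stimulation of quiescent cells produces a
*transient, partial* inactivation of the ubiquitin ligase APC/C-CDH1.
Mitogens activate mTOR quickly; mTOR phosphorylates the APC/C coactivator
CDH1 (pCDH1), which dissociates it from the APC/C and lowers APC/C activity.
With a delay, the same mitogen input activates a protein phosphatase (PP)
that removes the CDH1 phosphorylation and restores APC/C activity.  The
fast-activating and slow-repressing arms form an incoherent feedforward
loop, so APC/C activity dips and recovers, and an APC/C substrate (geminin,
standing in for the degron biosensor) shows a transient pulse.

Five ordinary differential equations with Hill-function drives:

    d mTOR/dt    = ( H+(S, k1, n1)                      - mTOR    ) / tau_mtor
    d PP/dt      = ( H+(S, k2, n2) * [t >= t_pp]        - PP      ) / tau_pp
    d pCDH1/dt   = ( H+(mTOR, k3, n3) * H-(PP, k4, n4)  - pCDH1   ) / tau_pcdh1
    d APC/dt     = ( H-(pCDH1, k5, n5)                  - APC     ) / tau_apc
    d GEMININ/dt = ( H-(APC, k6, n6)                    - GEMININ ) / tau_geminin

where H+(x,k,n) = x^n/(k^n+x^n) and H-(x,k,n) = k^n/(k^n+x^n).  All state
variables are dimensionless activities/levels in [0, 1]; time is in hours.
The delayed phosphatase arm is a hard step: its drive is zero before
``pp_onset_time`` (default 4 h).

Perturbation scenarios map to drive modifications:

* rapamycin (mTOR inhibitor): mTOR drive zeroed from ``rapamycin_time``
  onward (existing activity relaxes with ``tau_mtor``); an instantaneous
  clamp variant is available via ``rapamycin_clamp``.
* pan-phosphatase inhibitor: PP drive zeroed from
  ``phosphatase_inhibitor_time`` onward, so APC/C never reactivates.
* CDH1(T129A) dominant negative: pCDH1 drive forced to zero for all time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParameters",
    "SystemState",
    "StimulusProtocol",
    "Trajectory",
    "PulseMetrics",
    "STATE_NAMES",
    "hill_up",
    "hill_down",
    "derivatives",
    "simulate",
    "reference_simulate",
    "steady_state",
    "pulse_metrics",
]

STATE_NAMES = ("mtor", "pp", "pcdh1", "apc", "geminin")


def hill_up(x: float, k: float, n: float) -> float:
    """Activating Hill fraction x^n / (k^n + x^n).

    Monotone non-decreasing in ``x``; exactly 0 at ``x == 0`` (avoids 0**n
    edge cases for non-integer n) and 0.5 at ``x == k``.
    """
    _check_hill_args(x, k, n)
    if x == 0.0:
        return 0.0
    # Work with the ratio (k/x)^n for numerical symmetry at large x.
    try:
        r = (k / x) ** n
    except OverflowError:
        return 0.0
    return 1.0 / (1.0 + r)


def hill_down(x: float, k: float, n: float) -> float:
    """Inhibitory Hill fraction k^n / (k^n + x^n) = 1 - hill_up(x, k, n)."""
    _check_hill_args(x, k, n)
    if x == 0.0:
        return 1.0
    try:
        r = (x / k) ** n
    except OverflowError:
        return 0.0
    return 1.0 / (1.0 + r)


def _check_hill_args(x: float, k: float, n: float) -> None:
    if not math.isfinite(x) or x < 0:
        raise ValueError(f"Hill input must be finite and >= 0, got {x!r}")
    if not math.isfinite(k) or k <= 0:
        raise ValueError(f"Hill half-max k must be finite and > 0, got {k!r}")
    if not math.isfinite(n) or n < 1:
        raise ValueError(f"Hill coefficient n must be finite and >= 1, got {n!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Hill constants, coefficients and relaxation times of the IFFL cascade.

    Defaults are the standard calibration of this circuit model.  ``k1..k6`` are
    dimensionless half-maximal constants, ``n1..n6`` Hill coefficients, and
    the ``tau_*`` are first-order relaxation time constants in hours.
    """

    k1: float = 0.2
    n1: float = 1.0
    tau_mtor: float = 0.5
    k2: float = 0.2
    n2: float = 1.0
    tau_pp: float = 0.5
    k3: float = 0.3
    n3: float = 1.0
    tau_pcdh1: float = 0.5
    k4: float = 0.2
    n4: float = 2.0
    tau_apc: float = 0.5
    k5: float = 0.8
    n5: float = 1.0
    k6: float = 0.4
    n6: float = 3.0
    tau_geminin: float = 0.3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if f.name.startswith("k") and v <= 0:
                raise ValueError(f"{f.name} must be > 0, got {v!r}")
            if f.name.startswith("n") and v < 1:
                raise ValueError(f"{f.name} must be >= 1, got {v!r}")
            if f.name.startswith("tau") and v <= 0:
                raise ValueError(f"{f.name} must be > 0, got {v!r}")


@dataclass(frozen=True)
class SystemState:
    """Activities/levels of the five model species, each in [0, 1].

    The default is the quiescent starting condition used throughout:
    mTOR = PP = pCDH1 = GEMININ = 0 and APC = 1 (fully active APC/C).
    Note geminin = 0 is slightly below its quiescent fixed point
    (k6^n6/(k6^n6 + 1) ~ 0.0602), so unstimulated runs show a small initial
    geminin rise; the convention is kept deliberately.
    """

    mtor: float = 0.0
    pp: float = 0.0
    pcdh1: float = 0.0
    apc: float = 1.0
    geminin: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{f.name} must lie in [0, 1], got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.mtor, self.pp, self.pcdh1, self.apc, self.geminin])

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "SystemState":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class StimulusProtocol:
    """Mitogen stimulus and drug/mutant perturbations applied to the model.

    Parameters
    ----------
    mitogen_level:
        Dimensionless mitogen input S (serum strength); the standard
        stimulated condition uses S = 3.
    mitogen_onset:
        Time (h) at which mitogens are added; S is 0 before it.
    pp_onset_time:
        Time (h) before which the phosphatase drive is held at zero,
        modelling the measured ~4 h delay of PP action on CDH1.
    rapamycin_time:
        If set, the mTOR drive is zeroed from this time on (mTOR activity
        then relaxes to 0 with tau_mtor).  With ``rapamycin_clamp`` the
        activity itself is clamped to 0 instead.
    phosphatase_inhibitor_time:
        If set, the PP drive is zeroed from this time on, so CDH1 stays
        phosphorylated and APC/C inactivation becomes sustained.
    cdh1_phospho_blocked:
        Dominant-negative CDH1(T129A): the pCDH1 drive is zero for all time.
    """

    mitogen_level: float = 3.0
    mitogen_onset: float = 0.0
    pp_onset_time: float = 4.0
    rapamycin_time: float | None = None
    rapamycin_clamp: bool = False
    phosphatase_inhibitor_time: float | None = None
    cdh1_phospho_blocked: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.mitogen_level) or self.mitogen_level < 0:
            raise ValueError(f"mitogen_level must be >= 0, got {self.mitogen_level!r}")
        for name in ("mitogen_onset", "pp_onset_time", "rapamycin_time",
                     "phosphatase_inhibitor_time"):
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def event_times(self) -> list[float]:
        """Times at which a drive term switches discontinuously."""
        times = {self.mitogen_onset, self.pp_onset_time}
        if self.rapamycin_time is not None:
            times.add(self.rapamycin_time)
        if self.phosphatase_inhibitor_time is not None:
            times.add(self.phosphatase_inhibitor_time)
        return sorted(times)


@dataclass
class Trajectory:
    """Deterministic time course of the five state variables.

    ``times`` is a strictly increasing grid in hours; each entry of
    ``values`` is the aligned series of one state variable.  ``protocol``
    and ``params`` echo the inputs that produced the run.
    """

    times: np.ndarray
    values: dict[str, np.ndarray]
    params: KineticParameters
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("times must be a 1-D grid with >= 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name, series in self.values.items():
            series = np.asarray(series, dtype=float)
            if series.shape != self.times.shape:
                raise ValueError(f"series {name!r} not aligned to times")
            self.values[name] = series

    def __getitem__(self, variable: str) -> np.ndarray:
        try:
            return self.values[variable]
        except KeyError:
            raise KeyError(
                f"unknown variable {variable!r}; have {sorted(self.values)}"
            ) from None

    def to_frame(self):
        """Tidy long-format table with columns time_h, variable, value."""
        import pandas as pd

        frames = [
            pd.DataFrame(
                {"time_h": self.times, "variable": name, "value": series}
            )
            for name, series in self.values.items()
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class PulseMetrics:
    """Shape summary of a transient pulse (or dip) in one trajectory variable."""

    extremum_value: float
    extremum_time: float
    baseline: float
    recovery_value: float
    has_interior_extremum: bool


def derivatives(
    state: SystemState | Sequence[float],
    t: float,
    params: KineticParameters,
    protocol: StimulusProtocol,
) -> np.ndarray:
    """Right-hand side of the five ODEs at time ``t`` (rates in 1/h).

    Drive discontinuities (mitogen onset, PP onset, drug additions) are
    evaluated with half-open semantics: a switch at time ``t0`` is active
    for ``t >= t0``.
    """
    if isinstance(state, SystemState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    if t < 0 or not math.isfinite(t):
        raise ValueError(f"t must be finite and >= 0, got {t!r}")
    rhs = _make_rhs(params, protocol, t)
    return np.array(rhs(t, y))


def _make_rhs(
    params: KineticParameters,
    protocol: StimulusProtocol,
    t_probe: float,
) -> Callable[[float, np.ndarray], tuple]:
    """Build the RHS with switch states frozen as of time ``t_probe``.

    Within an integration segment the indicator functions are constant, so
    freezing them keeps the RHS smooth for the solver.
    """
    p = params
    pr = protocol

    mitogens_on = t_probe >= pr.mitogen_onset
    s_eff = pr.mitogen_level if mitogens_on else 0.0
    rapa = pr.rapamycin_time is not None and t_probe >= pr.rapamycin_time
    pp_on = t_probe >= pr.pp_onset_time
    ppi = (
        pr.phosphatase_inhibitor_time is not None
        and t_probe >= pr.phosphatase_inhibitor_time
    )

    mtor_drive = 0.0 if rapa else hill_up(s_eff, p.k1, p.n1)
    pp_drive = hill_up(s_eff, p.k2, p.n2) if (pp_on and not ppi) else 0.0

    inv_tm = 1.0 / p.tau_mtor
    inv_tp = 1.0 / p.tau_pp
    inv_tc = 1.0 / p.tau_pcdh1
    inv_ta = 1.0 / p.tau_apc
    inv_tg = 1.0 / p.tau_geminin
    k3, n3, k4, n4 = p.k3, p.n3, p.k4, p.n4
    k5, n5, k6, n6 = p.k5, p.n5, p.k6, p.n6
    blocked = pr.cdh1_phospho_blocked
    clamp_mtor = rapa and pr.rapamycin_clamp

    def rhs(t: float, y) -> tuple:
        mtor, pp, pcdh1, apc, geminin = y
        d_mtor = 0.0 if clamp_mtor else (mtor_drive - mtor) * inv_tm
        d_pp = (pp_drive - pp) * inv_tp
        if blocked:
            pcdh1_drive = 0.0
        else:
            up3 = 0.0 if mtor <= 0.0 else 1.0 / (1.0 + (k3 / mtor) ** n3)
            down4 = 1.0 if pp <= 0.0 else 1.0 / (1.0 + (pp / k4) ** n4)
            pcdh1_drive = up3 * down4
        d_pcdh1 = (pcdh1_drive - pcdh1) * inv_tc
        down5 = 1.0 if pcdh1 <= 0.0 else 1.0 / (1.0 + (pcdh1 / k5) ** n5)
        d_apc = (down5 - apc) * inv_ta
        down6 = 1.0 if apc <= 0.0 else 1.0 / (1.0 + (apc / k6) ** n6)
        d_geminin = (down6 - geminin) * inv_tg
        return (d_mtor, d_pp, d_pcdh1, d_apc, d_geminin)

    return rhs


def _clamp_active(protocol: StimulusProtocol, t: float) -> bool:
    return (
        protocol.rapamycin_clamp
        and protocol.rapamycin_time is not None
        and t >= protocol.rapamycin_time
    )


def _segment_times(protocol: StimulusProtocol, t_end: float) -> list[float]:
    """Breakpoints 0 = b0 < b1 < ... < bm = t_end at drive discontinuities."""
    pts = [0.0, t_end]
    for e in protocol.event_times():
        if 0.0 < e < t_end:
            pts.append(e)
    return sorted(set(pts))


def simulate(
    params: KineticParameters | None = None,
    protocol: StimulusProtocol | None = None,
    initial: SystemState | None = None,
    t_end: float = 24.0,
    output_dt: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the IFFL with LSODA on a uniform output grid.

    Integration is segmented at every drive discontinuity (mitogen onset,
    PP onset, drug-addition times) so the adaptive solver never steps
    across a switch.  Raises ``RuntimeError`` with the solver message if
    any segment fails to converge.
    """
    params = params or KineticParameters()
    protocol = protocol or StimulusProtocol()
    initial = initial or SystemState()
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if not 0 < output_dt <= t_end:
        raise ValueError("output_dt must be in (0, t_end]")

    n_out = int(round(t_end / output_dt))
    grid = np.linspace(0.0, n_out * output_dt, n_out + 1)
    breaks = _segment_times(protocol, t_end)

    y = initial.as_array()
    out = np.empty((len(grid), 5))
    out[0] = y
    for a, b in zip(breaks[:-1], breaks[1:]):
        t_probe = 0.5 * (a + b)
        if _clamp_active(protocol, t_probe):
            y = y.copy()
            y[0] = 0.0  # instant-clamp rapamycin variant zeroes mTOR itself
        rhs = _make_rhs(params, protocol, t_probe=t_probe)
        # grid points strictly inside (a, b], sampled from the dense solution
        mask = (grid > a) & (grid <= b)
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(
                f"LSODA failed on segment [{a}, {b}]: {sol.message}"
            )
        if mask.any():
            out[mask] = sol.sol(grid[mask]).T
        y = sol.y[:, -1]

    values = {name: out[:, i].copy() for i, name in enumerate(STATE_NAMES)}
    return Trajectory(times=grid, values=values, params=params, protocol=protocol)


def reference_simulate(
    params: KineticParameters | None = None,
    protocol: StimulusProtocol | None = None,
    initial: SystemState | None = None,
    t_end: float = 12.0,
    output_dt: float = 0.05,
    dt: float = 1e-4,
) -> Trajectory:
    """Fixed-step classical 4th-order Runge-Kutta integration.

    Serves as an independent cross-check of :func:`simulate`: it shares the
    model right-hand side but none of the adaptive-stepping machinery.  The
    step size is adjusted within each inter-breakpoint segment so segment
    boundaries and output-grid points fall exactly on step boundaries.
    """
    params = params or KineticParameters()
    protocol = protocol or StimulusProtocol()
    initial = initial or SystemState()
    if t_end <= 0 or dt <= 0 or not 0 < output_dt <= t_end:
        raise ValueError("invalid t_end/output_dt/dt")

    n_out = int(round(t_end / output_dt))
    grid = np.linspace(0.0, n_out * output_dt, n_out + 1)
    # march between consecutive "anchor" times (union of grid and breakpoints);
    # every anchor interval lies inside one smooth segment
    anchors = sorted(set(grid.tolist()) | set(_segment_times(protocol, t_end)))

    y = tuple(initial.as_array())
    out = np.empty((len(grid), 5))
    out[0] = y
    grid_index = {round(t, 9): i for i, t in enumerate(grid)}

    for a, b in zip(anchors[:-1], anchors[1:]):
        t_probe = 0.5 * (a + b)
        if _clamp_active(protocol, t_probe) and y[0] != 0.0:
            y = (0.0,) + tuple(y[1:])
        rhs = _make_rhs(params, protocol, t_probe=t_probe)
        span = b - a
        nsteps = max(1, int(round(span / dt)))
        h = span / nsteps
        h2 = 0.5 * h
        h6 = h / 6.0
        t = a
        for _ in range(nsteps):
            k1 = rhs(t, y)
            k2 = rhs(t + h2, tuple(yi + h2 * ki for yi, ki in zip(y, k1)))
            k3 = rhs(t + h2, tuple(yi + h2 * ki for yi, ki in zip(y, k2)))
            k4 = rhs(t + h, tuple(yi + h * ki for yi, ki in zip(y, k3)))
            y = tuple(
                yi + h6 * (a1 + 2.0 * (a2 + a3) + a4)
                for yi, a1, a2, a3, a4 in zip(y, k1, k2, k3, k4)
            )
            t += h
        idx = grid_index.get(round(b, 9))
        if idx is not None:
            out[idx] = y

    values = {name: out[:, i].copy() for i, name in enumerate(STATE_NAMES)}
    return Trajectory(times=grid, values=values, params=params, protocol=protocol)


def steady_state(
    params: KineticParameters | None = None,
    S: float = 3.0,
    pp_active: bool = True,
    cdh1_phospho_blocked: bool = False,
) -> SystemState:
    """Analytic fixed point of the cascade by forward substitution.

    The cascade is feedforward, so the fixed point is unique and closed
    form: each variable equals its drive evaluated at the upstream fixed
    point.  ``pp_active=False`` corresponds to the pre-onset (or
    phosphatase-inhibited) regime with PP = 0.
    """
    p = params or KineticParameters()
    if S < 0:
        raise ValueError("S must be >= 0")
    mtor = hill_up(S, p.k1, p.n1)
    pp = hill_up(S, p.k2, p.n2) if pp_active else 0.0
    if cdh1_phospho_blocked:
        pcdh1 = 0.0
    else:
        pcdh1 = hill_up(mtor, p.k3, p.n3) * hill_down(pp, p.k4, p.n4)
    apc = hill_down(pcdh1, p.k5, p.n5)
    geminin = hill_down(apc, p.k6, p.n6)
    return SystemState(mtor=mtor, pp=pp, pcdh1=pcdh1, apc=apc, geminin=geminin)


def pulse_metrics(
    traj: Trajectory,
    variable: str,
    mode: str = "maximum",
) -> PulseMetrics:
    """Locate the interior extremum of one trajectory variable.

    ``baseline`` is the initial value and ``recovery_value`` the terminal
    one.  ``has_interior_extremum`` is False when the series is monotone
    (the extremum then sits at an endpoint and reports the interior
    candidate nearest to it).
    """
    if mode not in ("minimum", "maximum"):
        raise ValueError("mode must be 'minimum' or 'maximum'")
    series = traj[variable]
    if len(series) < 3:
        raise ValueError("need >= 3 time points for pulse metrics")
    interior = series[1:-1]
    if mode == "maximum":
        i = int(np.argmax(interior)) + 1
        has_interior = series[i] > max(series[0], series[-1])
    else:
        i = int(np.argmin(interior)) + 1
        has_interior = series[i] < min(series[0], series[-1])
    return PulseMetrics(
        extremum_value=float(series[i]),
        extremum_time=float(traj.times[i]),
        baseline=float(series[0]),
        recovery_value=float(series[-1]),
        has_interior_extremum=bool(has_interior),
    )
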