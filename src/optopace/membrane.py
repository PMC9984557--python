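"""Passive membrane equivalent circuit with a light-driven capacitance.

An intramembrane azobenzene photoswitch dimerizes in the dark and thins the
bilayer, raising membrane capacitance; a visible-light pulse isomerizes it
and the capacitance relaxes back down.  On a cell held by its leak
conductance at rest this produces the characteristic transient
hyperpolarization -> recovery -> depolarizing rebound.

The circuit is purely passive: a time-varying capacitance ``C(t)`` in
parallel with the membrane resistance ``R_m`` in series with the resting
battery ``V_rest``.  Charge balance on the membrane node gives

    d(C(t) * V)/dt = (V_rest - V) / R_m

i.e. ``C dV/dt = (V_rest - V)/R_m - V dC/dt``: a falling capacitance at a
negative resting potential transiently drives ``V`` more negative, and the
speed of the fall (``tau_C_on``), not only its amplitude, sets the peak —
an instantaneous drop at fixed charge gives the plane-capacitor limit
``V' = V0 * C1/C2``, while a slow drop is continuously compensated by the
leak and produces almost no deflection.

Units follow patch-clamp convention: pF, GOhm, mV, ms — conveniently,
1 pF x 1 GOhm = 1 ms, and pF * mV/ms = pA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import VoltageTrace

__all__ = [
    "CircuitParams",
    "LightProtocol",
    "PulseResponse",
    "capacitance_waveform",
    "simulate_photoresponse",
    "step_limit_voltage",
    "peak_light_response",
    "TAU_ON_25UM_MS",
    "TAU_ON_5UM_MS",
]

# Illustrative kinetics presets for the two loading regimes (the isomerization
# is faster in the more crowded membrane environment at high concentration).
# These are modelling choices, not measured time constants.
TAU_ON_25UM_MS = 1.0
TAU_ON_5UM_MS = 10.0

#: peak-search window after each light onset, seconds
PEAK_WINDOW_S = 0.350
#: pre-onset baseline window, seconds
BASELINE_WINDOW_S = 0.100


@dataclass(frozen=True)
class CircuitParams:
    """Equivalent-circuit parameters of a photoswitch-loaded cell.

    C_dark : pF, steady-state (dimerized) membrane capacitance
    C_light : pF, capacitance after photoisomerization (C_light <= C_dark)
    R_m : GOhm, membrane resistance (np.inf allowed for the ideal limit)
    V_rest : mV, resting potential
    tau_C_on : ms, capacitance relaxation time constant while light is on
    tau_C_off : ms, recovery time constant after light offset
    R_s : MOhm, series/access resistance (0 in the current-clamp model;
        used only as a stressor by the synthetic current generator)
    """

    C_dark: float
    C_light: float
    R_m: float
    V_rest: float
    tau_C_on: float = TAU_ON_25UM_MS
    tau_C_off: float = 100.0
    R_s: float = 0.0

    def __post_init__(self) -> None:
        if not (self.C_dark > 0 and self.C_light > 0):
            raise ValueError("capacitances must be positive")
        if self.C_light > self.C_dark:
            raise ValueError("C_light must not exceed C_dark (light reduces capacitance)")
        if not (self.tau_C_on > 0 and self.tau_C_off > 0):
            raise ValueError("time constants must be positive")
        if not self.R_m > 0:
            raise ValueError("R_m must be positive")
        if self.R_s < 0:
            raise ValueError("R_s must be non-negative")


@dataclass(frozen=True)
class LightProtocol:
    """Light-pulse timing: onsets in seconds, pulse_duration in ms.

    ``period`` (s) is set for periodic trains and consumed by the
    phase-folding analyses; ``power_density`` (mW/mm^2) is metadata only.
    """

    onsets: tuple[float, ...]
    pulse_duration: float
    period: float | None = None
    power_density: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "onsets", tuple(float(t) for t in self.onsets))
        if not self.pulse_duration > 0:
            raise ValueError("pulse_duration must be positive")
        ons = np.asarray(self.onsets)
        if ons.size and np.any(np.diff(ons) <= self.pulse_duration * 1e-3):
            raise ValueError("light pulses overlap or are not increasing")
        if self.period is not None and not self.period > 0:
            raise ValueError("period must be positive")

    @classmethod
    def train(
        cls,
        start: float,
        n_pulses: int,
        period: float,
        pulse_duration: float,
        power_density: float | None = None,
    ) -> "LightProtocol":
        """A periodic train of ``n_pulses`` pulses, e.g. 20 ms at 0.5 Hz."""
        onsets = tuple(start + k * period for k in range(n_pulses))
        return cls(onsets, pulse_duration, period=period, power_density=power_density)

    @property
    def offsets(self) -> tuple[float, ...]:
        return tuple(t + self.pulse_duration * 1e-3 for t in self.onsets)


def capacitance_waveform(
    params: CircuitParams, protocol: LightProtocol, t_grid: np.ndarray
) -> np.ndarray:
    """Piecewise-exponential C(t) in pF on a uniform time grid (seconds).

    While light is on, C relaxes from its current value toward ``C_light``
    with ``tau_C_on``; after offset it recovers toward ``C_dark`` with
    ``tau_C_off``.  Continuous everywhere; C(t) = C_dark before the first
    pulse.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size > 1:
        dts = np.diff(t_grid)
        if not np.allclose(dts, dts[0], rtol=1e-6):
            raise ValueError("t_grid must be uniform")
    C = np.full(t_grid.shape, params.C_dark, dtype=float)

    # breakpoints: (time, target, tau_s) for each segment start
    segments: list[tuple[float, float, float]] = []
    for on, off in zip(protocol.onsets, protocol.offsets):
        segments.append((on, params.C_light, params.tau_C_on * 1e-3))
        segments.append((off, params.C_dark, params.tau_C_off * 1e-3))

    c_at_break = params.C_dark
    for i, (t0, target, tau) in enumerate(segments):
        t_end = segments[i + 1][0] if i + 1 < len(segments) else np.inf
        mask = (t_grid >= t0) & (t_grid < t_end)
        C[mask] = target + (c_at_break - target) * np.exp(-(t_grid[mask] - t0) / tau)
        c_at_break = target + (c_at_break - target) * np.exp(-(t_end - t0) / tau)
    return C


def step_limit_voltage(C1: float, C2: float, V0: float) -> float:
    """Voltage after an instantaneous capacitance step C1 -> C2 at fixed charge.

    Charge conservation Q = C V gives ``V' = V0 * C1 / C2``; for small
    relative changes ``(V' - V0)/V0 ~ -dC/C`` (the plane-capacitor relation
    dV/V = -dC/C).
    """
    if not (C1 > 0 and C2 > 0):
        raise ValueError("capacitances must be positive")
    return V0 * C1 / C2


def simulate_photoresponse(
    params: CircuitParams,
    protocol: LightProtocol,
    dt: float,
    duration: float,
) -> VoltageTrace:
    """Integrate the charge-balance ODE over ``[0, duration)`` at step ``dt`` (s).

    The linear ODE is advanced by Strang splitting of its two exactly
    solvable parts — the charge-conserving capacitance change
    (``V -> V * C_n / C_{n+1}``) and the leak relaxation toward ``V_rest``
    — which is unconditionally stable and exact in both the pure-leak and
    the R_m -> inf limits.  Requires ``dt <= tau_C_on / 20`` so the fast
    capacitance transient is resolved; halving dt moves the response peak
    by well under 0.1 %.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if dt > params.tau_C_on * 1e-3 / 20:
        raise ValueError(
            f"dt={dt} s too coarse for tau_C_on={params.tau_C_on} ms; "
            "need dt <= tau_C_on/20 to resolve the capacitance transient"
        )
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    C = capacitance_waveform(params, protocol, t)

    dt_ms = dt * 1e3
    # half-step leak decay factors at each node's capacitance
    if np.isinf(params.R_m):
        decay = np.ones_like(C)
    else:
        decay = np.exp(-dt_ms / (2.0 * params.R_m * C))

    V = np.empty(n)
    V[0] = params.V_rest
    v = params.V_rest
    for i in range(n - 1):
        v = params.V_rest + (v - params.V_rest) * decay[i]
        v = v * C[i] / C[i + 1]
        v = params.V_rest + (v - params.V_rest) * decay[i + 1]
        if not np.isfinite(v):
            raise FloatingPointError(f"integration diverged at step {i + 1} (t={t[i+1]:.6g} s)")
        V[i + 1] = v
    return VoltageTrace(t, V)


@dataclass(frozen=True)
class PulseResponse:
    """Per-pulse peak deflections relative to the pre-pulse baseline (mV)."""

    onset: float
    hyperpolarization: float
    depolarization: float
    baseline: float
    truncated: bool = False


def peak_light_response(
    trace: VoltageTrace, protocol: LightProtocol
) -> list[PulseResponse]:
    """Peak hyper-/depolarization within 350 ms of each light onset.

    The minimum and maximum of V over ``(onset, onset + 350 ms]`` are
    reported relative to the pre-pulse baseline (mean of the 100 ms before
    onset).  Pulses whose window is truncated by the end of the trace are
    flagged rather than dropped.
    """
    out: list[PulseResponse] = []
    t, V = trace.t, trace.V
    for onset in protocol.onsets:
        base_mask = (t >= onset - BASELINE_WINDOW_S) & (t < onset)
        if not base_mask.any():
            base_mask = t < onset
        baseline = float(V[base_mask].mean()) if base_mask.any() else float(V[0])
        win_mask = (t > onset) & (t <= onset + PEAK_WINDOW_S)
        truncated = t[-1] < onset + PEAK_WINDOW_S
        if not win_mask.any():
            out.append(PulseResponse(onset, 0.0, 0.0, baseline, truncated=True))
            continue
        seg = V[win_mask]
        out.append(
            PulseResponse(
                onset,
                hyperpolarization=float(seg.min() - baseline),
                depolarization=float(seg.max() - baseline),
                baseline=baseline,
                truncated=truncated,
            )
        )
    return out
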