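"""Membrane capacitance/resistance from double-sinusoid voltage clamp.

A whole-cell voltage command made of two summed sinusoids is applied around
a holding potential; for an ideal clamp on a parallel-RC membrane the
current is

    I(t) = C_m dV_cmd/dt + (V_cmd - V_hold) / R_m

so at each command frequency the quadrature (cosine) component carries the
capacitive current ``C_m A 2 pi f`` and the in-phase (sine) component the
resistive one ``A / R_m``.  Fitting both frequencies jointly gives one
(C_m, R_m) pair; comparing the two single-frequency capacitance estimates
is a built-in model diagnostic — they agree only when the cell really is a
parallel RC seen through a negligible series resistance, so an uncompensated
access resistance trips the disagreement flag instead of silently biasing
the fit.

Unit bookkeeping: I in pA, V in mV, f in Hz -> C_pF = 1e3 * I_pA/(A_mV w),
R_GOhm = 1e-3 * A_mV / I_pA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import CurrentTrace

__all__ = [
    "SinusoidProtocol",
    "CapacitanceFit",
    "demodulate",
    "fit_capacitance",
    "light_delta_C",
    "FREQ_AGREEMENT_TOL",
]

#: relative disagreement between single-frequency C_m estimates that flags
#: a violation of the parallel-RC model
FREQ_AGREEMENT_TOL = 0.05

#: C_m below this (pF) is reported as degenerate rather than fitted
_DEGENERATE_C_PF = 0.5


@dataclass(frozen=True)
class SinusoidProtocol:
    """Two-frequency sinusoidal command: V_hold + A1 sin(2 pi f1 t) + A2 sin(2 pi f2 t).

    Frequencies in Hz, amplitudes in mV, duration and dt in seconds.
    """

    f1: float
    f2: float
    A1: float
    A2: float
    V_hold: float
    duration: float
    dt: float

    def __post_init__(self) -> None:
        if self.f1 == self.f2:
            raise ValueError("the two command frequencies must differ")
        nyquist = 1.0 / (2.0 * self.dt)
        if not (0 < self.f1 < nyquist and 0 < self.f2 < nyquist):
            raise ValueError("frequencies must be positive and below Nyquist")
        if not (self.A1 > 0 and self.A2 > 0):
            raise ValueError("amplitudes must be positive")
        if not (self.duration > 0 and self.dt > 0):
            raise ValueError("duration and dt must be positive")

    def t_grid(self) -> np.ndarray:
        return np.arange(int(round(self.duration / self.dt))) * self.dt

    def command(self, t: np.ndarray) -> np.ndarray:
        """V_cmd(t) in mV."""
        t = np.asarray(t, dtype=float)
        return (
            self.V_hold
            + self.A1 * np.sin(2 * np.pi * self.f1 * t)
            + self.A2 * np.sin(2 * np.pi * self.f2 * t)
        )

    def command_derivative(self, t: np.ndarray) -> np.ndarray:
        """dV_cmd/dt in mV/s, evaluated analytically."""
        t = np.asarray(t, dtype=float)
        w1, w2 = 2 * np.pi * self.f1, 2 * np.pi * self.f2
        return self.A1 * w1 * np.cos(w1 * t) + self.A2 * w2 * np.cos(w2 * t)


@dataclass(frozen=True)
class CapacitanceFit:
    """A fitted (C_m, R_m) pair for one analysis window and condition."""

    C_m: float  # pF
    R_m: float  # GOhm
    residual_rms: float  # pA
    window: tuple[float, float]  # s
    condition_label: str  # "dark" | "light"
    C_m_single: tuple[float, float] = (np.nan, np.nan)  # per-frequency estimates, pF
    flags: tuple[str, ...] = ()
    protocol: SinusoidProtocol | None = field(default=None, compare=False)

    @property
    def frequency_disagreement(self) -> float:
        """Relative spread of the two single-frequency C_m estimates."""
        c1, c2 = self.C_m_single
        mean = 0.5 * (c1 + c2)
        return abs(c1 - c2) / abs(mean) if mean else np.inf


def demodulate(
    trace: CurrentTrace, f: float, window: tuple[float, float]
) -> tuple[float, float]:
    """Least-squares (in_phase, quadrature) components of I at frequency f.

    Projects the mean-removed current over ``[t_start, t_end)`` onto
    ``sin(2 pi f t)`` and ``cos(2 pi f t)``; the window must span at least
    3 cycles of f for the projection to be well conditioned.
    """
    t_start, t_end = window
    if (t_end - t_start) * f < 3.0:
        raise ValueError(
            f"window of {t_end - t_start:.4g} s spans fewer than 3 cycles of {f} Hz"
        )
    mask = (trace.t >= t_start) & (trace.t < t_end)
    t = trace.t[mask]
    y = trace.I[mask] - trace.I[mask].mean()
    X = np.column_stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_capacitance(
    trace: CurrentTrace,
    protocol: SinusoidProtocol,
    window: tuple[float, float],
    condition_label: str = "dark",
) -> CapacitanceFit:
    """Fit the parallel-RC model to a current window and diagnose model fit.

    The final (C_m, R_m) come from a joint linear least-squares regression of
    I(t) on the analytic command derivative, the command offset from
    V_hold, and an intercept (which absorbs any DC offset).  Two
    single-frequency capacitance estimates from lock-in demodulation are
    kept as a diagnostic: if they disagree by more than
    ``FREQ_AGREEMENT_TOL`` the fit is flagged ``"frequency_disagreement"``
    (the data-generating circuit is not a clean parallel RC).
    """
    t_start, t_end = window
    for f in (protocol.f1, protocol.f2):
        if (t_end - t_start) * f < 3.0:
            raise ValueError(
                f"window [{t_start}, {t_end}) spans fewer than 3 cycles of {f} Hz"
            )
    mask = (trace.t >= t_start) & (trace.t < t_end)
    t = trace.t[mask]
    y = trace.I[mask]

    dvdt = protocol.command_derivative(t)  # mV/s
    dv = protocol.command(t) - protocol.V_hold  # mV
    X = np.column_stack([dvdt * 1e-3, dv, np.ones_like(t)])  # pA per (pF, 1/GOhm, 1)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    C_m, G_m = float(coef[0]), float(coef[1])
    residual = y - X @ coef
    residual_rms = float(np.sqrt(np.mean(residual**2)))

    # single-frequency lock-in estimates: quadrature -> C, in-phase -> 1/R
    singles = []
    for f, A in ((protocol.f1, protocol.A1), (protocol.f2, protocol.A2)):
        _, quad = demodulate(trace, f, window)
        singles.append(1e3 * quad / (A * 2 * np.pi * f))
    c1, c2 = singles

    flags: list[str] = []
    if C_m < _DEGENERATE_C_PF or abs(c1) < _DEGENERATE_C_PF or abs(c2) < _DEGENERATE_C_PF:
        flags.append("degenerate_capacitance")
        if C_m < 0 and C_m < -_DEGENERATE_C_PF:
            raise ValueError(f"fitted capacitance is negative ({C_m:.3g} pF)")
    else:
        mean_c = 0.5 * (c1 + c2)
        if abs(c1 - c2) / abs(mean_c) > FREQ_AGREEMENT_TOL:
            flags.append("frequency_disagreement")
    if G_m <= 0:
        raise ValueError(f"fitted membrane conductance is non-positive ({G_m:.3g} 1/GOhm)")
    R_m = 1.0 / G_m

    return CapacitanceFit(
        C_m=C_m,
        R_m=R_m,
        residual_rms=residual_rms,
        window=(t_start, t_end),
        condition_label=condition_label,
        C_m_single=(c1, c2),
        flags=tuple(flags),
        protocol=protocol,
    )


def light_delta_C(fit_dark: CapacitanceFit, fit_light: CapacitanceFit) -> float:
    """Relative capacitance change under light, percent, sign preserved.

    ``100 * (C_light - C_dark) / C_dark``; both fits must come from the same
    command protocol.
    """
    if (
        fit_dark.protocol is not None
        and fit_light.protocol is not None
        and fit_dark.protocol != fit_light.protocol
    ):
        raise ValueError("dark and light fits use different command protocols")
    return 100.0 * (fit_light.C_m - fit_dark.C_m) / fit_dark.C_m
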