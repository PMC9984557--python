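"""Ground-truth generators for every downstream analysis stage.

No public recordings exist for photoswitch-paced cardiomyocytes, so each
pipeline stage is validated against a generator whose parameters are known
exactly: a textured contracting cell video for the tracker, parallel-RC
clamp currents for the capacitance estimator, action-potential trains and
Fura-2 ratio transients for the feature extractors.  Every generator is
bit-deterministic under its seed, and every stated parameter is directly
measurable on the noiseless output (pixel counting, waveform evaluation)
independently of any pipeline code.

The contracting cell is a speckle-textured ellipse whose pixels move by a
uniform radial similarity scaling about the cell centre — the same motion
family the tracker assumes — so the bounding-box area curve is analytic:
``A(t)/A0 = s(t)^2`` with ``s = sqrt(1 - area_reduction)`` at the dip
minimum and a raised-cosine dip profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .capfit import SinusoidProtocol
from .membrane import CircuitParams, LightProtocol, capacitance_waveform
from .tracking import ContractionEvent
from .traces import CaTrace, CurrentTrace, VoltageTrace
from .video import VideoStack

__all__ = [
    "SyntheticVideoSpec",
    "SyntheticTraceSpec",
    "make_contraction_video",
    "make_ap_train",
    "make_ca_trace",
    "make_patch_current",
]

_BACKGROUND = 20.0  # background grey level, 8-bit counts
_CELL_MEAN = 130.0  # mean cell intensity
_CELL_CONTRAST = 55.0  # speckle contrast (SD of the texture term)


@dataclass(frozen=True)
class SyntheticVideoSpec:
    """Parameters of a synthetic contracting-cell movie.

    The cell is an ellipse of semi-axes ``cell_axes`` (px) centred at
    ``cell_center`` (x, y px) carrying a static multiscale speckle texture;
    at each contraction it shrinks radially toward the centre following a
    raised-cosine dip of ``dip_duration`` seconds, reaching a mask area of
    ``(1 - area_reduction)`` times the resting area at the dip minimum.

    Contraction times come from, in order of precedence: ``event_times``
    (explicit, seconds), ``light_onsets`` plus ``latency_s`` (light-locked
    events), or a regular train at ``contraction_rate`` Hz.
    """

    width: int = 128
    height: int = 128
    n_frames: int = 1000
    fps: float = 50.0
    cell_center: tuple[float, float] = (64.0, 64.0)
    cell_axes: tuple[float, float] = (40.0, 30.0)
    contraction_rate: float = 0.5
    area_reduction: float = 0.10
    dip_duration: float = 0.4
    texture_seed: int = 0
    noise_sd: float = 2.0
    light_onsets: tuple[float, ...] | None = None
    latency_s: float = 0.5
    event_times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.cell_axes) < 2:
            raise ValueError("degenerate ellipse: semi-axes must be >= 2 px")
        if not 0 <= self.area_reduction < 1:
            raise ValueError("area_reduction must be in [0, 1)")
        if self.contraction_rate >= self.fps / 4:
            raise ValueError(
                f"contraction_rate {self.contraction_rate} Hz undersampled at {self.fps} fps "
                "(need rate < fps/4)"
            )
        if self.dip_duration * self.contraction_rate >= 1:
            raise ValueError("dip_duration x contraction_rate must be < 1")
        if self.dip_duration <= 0:
            raise ValueError("dip_duration must be positive")

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def contraction_times(self) -> np.ndarray:
        """Ground-truth dip-minimum times in seconds."""
        if self.area_reduction == 0:
            return np.array([])
        if self.event_times is not None:
            times = np.asarray(self.event_times, dtype=float)
        elif self.light_onsets is not None:
            times = np.asarray(self.light_onsets, dtype=float) + self.latency_s
        elif self.contraction_rate > 0:
            n = int(math.floor(self.contraction_rate * self.duration + 1e-9))
            times = (np.arange(n) + 0.5) / self.contraction_rate
        else:
            return np.array([])
        if times.size:
            if np.any(np.diff(times) < self.dip_duration):
                raise ValueError("contraction events overlap (spacing < dip_duration)")
            if times[0] - self.dip_duration / 2 < 0 or times[-1] + self.dip_duration / 2 > self.duration:
                raise ValueError("contraction dips extend outside the video")
        return times


def _scale_factor(t: np.ndarray, events: np.ndarray, s_min: float, dip: float) -> np.ndarray:
    """Similarity scale s(t): 1 at rest, s_min at each dip minimum."""
    s = np.ones_like(t)
    for t_ev in events:
        t0 = t_ev - dip / 2
        mask = (t >= t0) & (t <= t0 + dip)
        w = 0.5 * (1 - np.cos(2 * np.pi * (t[mask] - t0) / dip))
        s[mask] = 1 - (1 - s_min) * w
    return s


def make_contraction_video(
    spec: SyntheticVideoSpec,
) -> tuple[VideoStack, list[ContractionEvent]]:
    """Render the movie and its ground-truth contraction events.

    Returns the 8-bit video stack and one :class:`ContractionEvent` per
    contraction with the dip-minimum time, the amplitude
    ``100 * area_reduction`` % and the analytic peak area-derivative in
    %/s.  Identical spec (including seed) gives a bit-identical stack.
    """
    events = spec.contraction_times()
    s_min = math.sqrt(1 - spec.area_reduction)
    t = np.arange(spec.n_frames) / spec.fps
    s_of_t = _scale_factor(t, events, s_min, spec.dip_duration)

    rng_texture, rng_noise = [
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.texture_seed).spawn(2)
    ]
    h, w = spec.height, spec.width
    texture = np.zeros((h, w))
    for sigma, weight in ((1.0, 1.0), (2.0, 0.8), (4.0, 0.6)):
        texture += weight * gaussian_filter(rng_texture.standard_normal((h, w)), sigma)
    texture = _CELL_MEAN + _CELL_CONTRAST * texture / texture.std()
    texture = np.clip(texture, 30.0, 235.0)

    cx, cy = spec.cell_center
    ax, ay = spec.cell_axes
    rows, cols = np.mgrid[0:h, 0:w].astype(float)

    frames = np.empty((spec.n_frames, h, w), dtype=np.uint8)
    rendered: dict[float, np.ndarray] = {}
    for i, s in enumerate(s_of_t):
        key = round(float(s), 9)
        if key not in rendered:
            # inverse map: frame pixel -> reference texture coordinate
            qx = cx + (cols - cx) / s
            qy = cy + (rows - cy) / s
            ell = np.sqrt(((qx - cx) / ax) ** 2 + ((qy - cy) / ay) ** 2)
            # approximate signed distance to the ellipse edge, px, for a
            # one-pixel antialiased rim
            dist = (ell - 1.0) * min(ax, ay) * s
            coverage = np.clip(0.5 - dist, 0.0, 1.0)
            tex = map_coordinates(texture, [qy, qx], order=1, mode="nearest")
            rendered[key] = _BACKGROUND + coverage * (tex - _BACKGROUND)
        clean = rendered[key]
        if spec.noise_sd > 0:
            noisy = clean + rng_noise.normal(0.0, spec.noise_sd, size=clean.shape)
        else:
            noisy = clean
        frames[i] = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    # analytic peak area-derivative of the normalized area s(t)^2 over a dip
    tau = np.linspace(0, spec.dip_duration, 2001)
    w_dip = 0.5 * (1 - np.cos(2 * np.pi * tau / spec.dip_duration))
    s_dip = 1 - (1 - s_min) * w_dip
    peak_vel = float(np.max(np.abs(np.gradient(s_dip**2, tau)))) * 100.0

    truth = [
        ContractionEvent(
            t_min=float(t_ev),
            amplitude=100.0 * spec.area_reduction,
            peak_velocity=peak_vel,
            prominence=spec.area_reduction,
        )
        for t_ev in events
    ]
    return VideoStack(frames, spec.fps), truth


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Event-train trace parameters shared by the AP and CaT generators.

    Action-potential fields: ``MDP`` (mV), ``APA`` (mV), ``APD90`` (ms) and
    the upstroke ``rise_time_ms``.  Calcium-transient fields: diastolic
    level ``CaD``, ``amplitude`` (both Fura-2 ratio units), rise time
    ``t_peak`` (s) and decay constant ``tau_decay`` (s).
    """

    duration: float
    dt: float
    event_times: tuple[float, ...] = ()
    # action-potential waveform
    MDP: float = -42.8
    APA: float = 70.0
    APD90: float = 300.0
    rise_time_ms: float = 2.0
    # calcium-transient waveform
    CaD: float = 1.0
    amplitude: float = 0.5
    t_peak: float = 0.15
    tau_decay: float = 0.8
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        ev = np.asarray(self.event_times, dtype=float)
        if ev.size and (np.any(np.diff(ev) <= 0) or ev[0] < 0 or ev[-1] > self.duration):
            raise ValueError("event_times must be strictly increasing within [0, duration]")


def _check_overlap(events: np.ndarray, support: float, kind: str) -> None:
    if events.size > 1 and np.any(np.diff(events) < support):
        raise ValueError(
            f"overlapping {kind} events: inter-event interval shorter than the "
            f"waveform support ({support:.3g} s)"
        )


def make_ap_train(spec: SyntheticTraceSpec) -> tuple[VoltageTrace, dict]:
    """Action-potential train with known MDP/APA/APD90 and upstroke velocity.

    Each event is a half-cosine upstroke of ``rise_time_ms`` followed by a
    plateau-free exponential repolarization whose rate is chosen so that V
    crosses ``peak - 0.9 APA`` exactly ``APD90`` ms after the time of
    maximal upstroke velocity (the APD90 reference used by the feature
    extractor).  Baseline is MDP; Gaussian noise is seeded.
    """
    if not (spec.APA > 0 and spec.APD90 > 0):
        raise ValueError("APA and APD90 must be positive")
    t_rise = spec.rise_time_ms * 1e-3
    apd90_s = spec.APD90 * 1e-3
    if apd90_s <= t_rise / 2:
        raise ValueError("APD90 must exceed half the upstroke rise time")
    k = math.log(10.0) / (apd90_s - t_rise / 2)  # decay from peak, 1/s
    support = t_rise + 3 * apd90_s
    events = np.asarray(spec.event_times, dtype=float)
    _check_overlap(events, support, "AP")

    n = int(round(spec.duration / spec.dt))
    t = np.arange(n) * spec.dt
    V = np.full(n, spec.MDP, dtype=float)
    for t_on in events:
        tau = t - t_on
        up = (tau >= 0) & (tau < t_rise)
        V[up] += spec.APA * 0.5 * (1 - np.cos(np.pi * tau[up] / t_rise))
        down = tau >= t_rise
        V[down] += spec.APA * np.exp(-k * (tau[down] - t_rise))
    if spec.noise_sd > 0:
        V = V + np.random.default_rng(spec.seed).normal(0, spec.noise_sd, n)

    truth = {
        "event_times": events,
        "MDP": spec.MDP,
        "APA": spec.APA,
        "APD90": spec.APD90,
        # half-cosine upstroke: max dV/dt = APA * pi / (2 t_rise), in V/s
        "dVdt_max": spec.APA * math.pi / (2 * spec.rise_time_ms),
        "upstroke_times": events + t_rise / 2,
    }
    return VoltageTrace(t, V), truth


def make_ca_trace(spec: SyntheticTraceSpec) -> tuple[CaTrace, dict]:
    """Fura-2 ratio transients: linear rise over t_peak, exponential decay.

    Each transient rises linearly from ``CaD`` to ``CaD + amplitude`` over
    ``t_peak`` seconds, then decays monoexponentially toward ``CaD`` with
    ``tau_decay``.  Events closer than the time to 90 % recovery are
    rejected as overlapping.
    """
    if not (spec.amplitude > 0 and spec.t_peak > 0 and spec.tau_decay > 0):
        raise ValueError("amplitude, t_peak and tau_decay must be positive")
    support = spec.t_peak + math.log(10.0) * spec.tau_decay
    events = np.asarray(spec.event_times, dtype=float)
    _check_overlap(events, support, "CaT")

    n = int(round(spec.duration / spec.dt))
    t = np.arange(n) * spec.dt
    y = np.full(n, spec.CaD, dtype=float)
    for t_on in events:
        tau = t - t_on
        rise = (tau >= 0) & (tau < spec.t_peak)
        y[rise] += spec.amplitude * tau[rise] / spec.t_peak
        decay = tau >= spec.t_peak
        y[decay] += spec.amplitude * np.exp(-(tau[decay] - spec.t_peak) / spec.tau_decay)
    if spec.noise_sd > 0:
        y = y + np.random.default_rng(spec.seed).normal(0, spec.noise_sd, n)

    truth = {
        "event_times": events,
        "CaD": spec.CaD,
        "CaT_Amp": spec.amplitude,
        "t_peak": spec.t_peak,
        "tau_decay": spec.tau_decay,
        "peak_times": events + spec.t_peak,
    }
    return CaTrace(t, y), truth


def make_patch_current(
    circuit: CircuitParams,
    protocol: SinusoidProtocol,
    noise_sd: float = 0.0,
    seed: int = 0,
    light: LightProtocol | None = None,
) -> CurrentTrace:
    """Whole-cell current under the double-sinusoid command.

    With an ideal clamp (R_s = 0) the current is evaluated analytically,

        I = C(t) dV_cmd/dt + V_cmd dC/dt + (V_cmd - V_rest) / R_m   [pA]

    where ``C(t)`` is constant at ``C_dark`` unless a light protocol drives
    a capacitance relaxation.  A non-zero series resistance (``circuit.R_s``,
    MOhm) switches to numerical integration of the access-resistance node —
    the stressor used to demonstrate the two-frequency disagreement
    diagnostic of the fitter.  Gaussian noise is added under the seed.
    """
    max_f = max(protocol.f1, protocol.f2)
    if protocol.dt > 1.0 / (20.0 * max_f):
        raise ValueError(
            f"dt={protocol.dt} s too coarse: need dt <= 1/(20 max_f) = "
            f"{1.0 / (20.0 * max_f):.3g} s"
        )
    t = protocol.t_grid()
    v_cmd = protocol.command(t)
    dvdt = protocol.command_derivative(t)  # mV/s

    if light is None:
        C = np.full_like(t, circuit.C_dark)
        dCdt = np.zeros_like(t)
    else:
        C = capacitance_waveform(circuit, light, t)
        dCdt = np.gradient(C, t)  # pF/s

    if circuit.R_s == 0:
        # pF * mV/s = 1e-3 pA;  mV / GOhm = pA
        I = 1e-3 * (C * dvdt + v_cmd * dCdt) + (v_cmd - circuit.V_rest) / circuit.R_m
    else:
        R_s = circuit.R_s * 1e-3  # MOhm -> GOhm
        # node ODE: C dVm/dt = (Vcmd - Vm)/R_s - (Vm - V_rest)/R_m - Vm dC/dt
        # integrated by exponential Euler on an internal subgrid
        tau_node_ms = circuit.C_dark * R_s * circuit.R_m / (R_s + circuit.R_m)  # pF*GOhm=ms
        n_sub = max(1, int(math.ceil(protocol.dt * 1e3 / (tau_node_ms / 5.0))))
        dt_sub = protocol.dt / n_sub
        sub_offsets = np.arange(n_sub) * dt_sub
        Vm = np.empty_like(t)
        v = circuit.V_rest
        for i in range(t.size):
            Vm[i] = v
            vc_sub = protocol.command(t[i] + sub_offsets)
            g = (1.0 / R_s + 1.0 / circuit.R_m + 1e-3 * dCdt[i]) / C[i]  # 1/ms
            decay = math.exp(-g * dt_sub * 1e3)
            for vc in vc_sub:
                v_inf = (vc / R_s + circuit.V_rest / circuit.R_m) / (C[i] * g)
                v = v_inf + (v - v_inf) * decay
        I = (v_cmd - Vm) / R_s

    if noise_sd > 0:
        I = I + np.random.default_rng(seed).normal(0, noise_sd, I.size)
    return CurrentTrace(t, I)
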