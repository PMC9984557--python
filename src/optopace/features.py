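"""Feature extraction from electrophysiology, calcium and contraction traces.

Covers the standard per-event cardiomyocyte readouts — maximum diastolic
potential (MDP), AP amplitude (APA), maximal upstroke velocity dV/dt_max,
APD90, Fura-2 ratio transients (diastolic level CaD, amplitude, rise time
t_peak, monoexponential decay constant tau_decay) — plus the windowed
pre/light/post event frequencies, percent-change reporting, the fraction of
light pulses answered by an event, latency histograms with a gamma guide
fit, and the phase-folding analysis that shows events locking to a periodic
light train.

Conventions: all analysis windows are half-open ``[start, end)``; the APD90
clock starts at the time of maximal upstroke velocity; instantaneous
frequency is the reciprocal inter-event interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .membrane import LightProtocol
from .traces import CaTrace, EventTimes, Trace, VoltageTrace

__all__ = [
    "APFeatures",
    "CaTFeatures",
    "LatencyResult",
    "LockingResult",
    "ratio_trace",
    "detect_aps",
    "ap_features",
    "cat_features",
    "window_frequencies",
    "percent_change",
    "report_percent",
    "responding_fraction",
    "latency_histogram",
    "light_locking_histogram",
]

#: default latency window after a light onset, s (mirrors the 350 ms
#: peak-response window of the voltage analysis)
LATENCY_WINDOW_S = 0.35
#: refractory period for AP onset detection, s
AP_REFRACTORY_S = 0.1


def ratio_trace(
    F340: Trace, F380: Trace, background: tuple[float, float] = (0.0, 0.0)
) -> CaTrace:
    """Pointwise Fura-2 ratio F340/F380 as a calcium readout.

    Optional per-channel background levels are subtracted first.  If the
    two channels are not co-sampled (interleaved excitation), F380 is
    aligned onto the F340 grid by linear interpolation.  Non-positive F380
    samples are rejected with their indices.
    """
    num = F340.values - background[0]
    den = F380.values - background[1]
    if F340.t.shape == F380.t.shape and np.allclose(F340.t, F380.t):
        den_aligned = den
    else:
        den_aligned = np.interp(F340.t, F380.t, den)
    bad = np.flatnonzero(den_aligned <= 0)
    if bad.size:
        raise ValueError(
            f"F380 is non-positive at {bad.size} samples (first indices {bad[:5].tolist()})"
        )
    return CaTrace(F340.t, num / den_aligned)


def detect_aps(trace: VoltageTrace, dVdt_threshold: float = 10.0) -> EventTimes:
    """AP onsets where dV/dt crosses ``dVdt_threshold`` (V/s) upward.

    Requires sampling at >= 1 kHz; a 100 ms refractory period suppresses
    double-counting within one upstroke.
    """
    if trace.dt > 1e-3 + 1e-12:
        raise ValueError("AP detection needs sampling at >= 1 kHz")
    dvdt = np.gradient(trace.V, trace.t) * 1e-3  # mV/s -> V/s
    above = dvdt >= dVdt_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times: list[float] = []
    for i in crossings:
        t_i = trace.t[i]
        if not times or t_i - times[-1] >= AP_REFRACTORY_S:
            times.append(float(t_i))
    return EventTimes(np.asarray(times), kind="AP")


@dataclass
class APFeatures:
    """Per-AP features plus trace-level rate and variability summaries.

    Arrays are aligned with the (non-truncated) analysed APs.  ``apd_sd``
    and ``freq_sd`` are the clustering indicators: the sample SDs of the
    per-AP APD90 and of the instantaneous frequency (1 / inter-event
    interval); light-locked firing shrinks both.
    """

    event_times: np.ndarray
    mdp: np.ndarray  # mV
    apa: np.ndarray  # mV
    dvdt_max: np.ndarray  # V/s
    apd90: np.ndarray  # ms
    frequency: float  # Hz
    apd_sd: float  # ms
    freq_sd: float  # Hz
    flags: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.event_times,
                "MDP_mV": self.mdp,
                "APA_mV": self.apa,
                "dVdt_max_V_per_s": self.dvdt_max,
                "APD90_ms": self.apd90,
            }
        )


def ap_features(trace: VoltageTrace, events: EventTimes) -> APFeatures:
    """Extract MDP, APA, dV/dt_max and APD90 for each AP in the trace.

    Per AP: the MDP is the minimum V in the diastolic interval between the
    previous event (or trace start) and the onset; the peak is searched up
    to the next event; APA = peak - MDP; dV/dt_max is the largest
    derivative on the upstroke and also defines the APD90 reference time;
    APD90 ends at the interpolated downward crossing of ``peak - 0.9 APA``.
    A final AP whose repolarization is cut off by the end of the trace is
    excluded and flagged.
    """
    t, V = trace.t, trace.V
    ev = np.asarray(events.times, dtype=float)
    dvdt = np.gradient(V, t)  # mV/s
    flags: list[str] = []

    rows: list[tuple[float, float, float, float, float]] = []
    bounds = np.concatenate([ev, [t[-1] + trace.dt]])
    for j, t_on in enumerate(ev):
        i_on = int(np.searchsorted(t, t_on))
        i_end = int(np.searchsorted(t, bounds[j + 1]))
        i_prev = int(np.searchsorted(t, ev[j - 1])) if j > 0 else 0
        if i_end - i_on < 3:
            flags.append(f"ap{j}:too_short")
            continue
        seg = slice(i_on, i_end)
        i_peak = i_on + int(np.argmax(V[seg]))
        mdp = float(np.min(V[i_prev:i_on])) if i_on > i_prev else float(V[i_on])
        apa = float(V[i_peak] - mdp)
        i_up = i_on + int(np.argmax(dvdt[i_on : i_peak + 1]))
        dvdt_max = float(dvdt[i_up]) * 1e-3  # V/s

        thresh = V[i_peak] - 0.9 * apa
        below = np.flatnonzero(V[i_peak:i_end] < thresh)
        if below.size == 0:
            flags.append(f"ap{j}:truncated")
            continue
        i_c = i_peak + int(below[0])
        # linear interpolation between the bracketing samples
        v0, v1 = V[i_c - 1], V[i_c]
        frac = (v0 - thresh) / (v0 - v1) if v1 != v0 else 0.0
        t_cross = t[i_c - 1] + frac * trace.dt
        apd90 = (t_cross - t[i_up]) * 1e3
        rows.append((t_on, mdp, apa, dvdt_max, apd90))

    arr = np.array(rows, dtype=float).reshape(-1, 5)
    n = len(ev)
    isi = np.diff(ev)
    freq_sd = float(np.std(1.0 / isi, ddof=1)) if isi.size >= 2 else float("nan")
    apd_sd = float(np.std(arr[:, 4], ddof=1)) if arr.shape[0] >= 2 else float("nan")
    return APFeatures(
        event_times=arr[:, 0],
        mdp=arr[:, 1],
        apa=arr[:, 2],
        dvdt_max=arr[:, 3],
        apd90=arr[:, 4],
        frequency=n / trace.duration,
        apd_sd=apd_sd,
        freq_sd=freq_sd,
        flags=tuple(flags),
    )


@dataclass
class CaTFeatures:
    """Per-transient calcium features plus the trace-level rate."""

    cad: float  # diastolic ratio level
    event_times: np.ndarray
    amplitude: np.ndarray  # ratio units
    t_peak: np.ndarray  # s, onset to peak
    tau_decay: np.ndarray  # s, NaN where the fit failed
    frequency: float  # Hz
    flags: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.event_times,
                "CaT_Amp": self.amplitude,
                "t_peak_s": self.t_peak,
                "tau_decay_s": self.tau_decay,
            }
        )


_DIASTOLE_LOOKBACK_S = 0.5


def cat_features(trace: CaTrace, events: EventTimes) -> CaTFeatures:
    """Extract CaD, amplitude, rise time and decay constant per transient.

    CaD is the median over the diastolic segments (up to 500 ms before each
    onset); per transient, the peak is searched up to the next onset, the
    amplitude is peak - CaD, t_peak the onset-to-peak time, and tau_decay a
    monoexponential fit (log-linear least squares) from the peak down to
    90 % recovery toward CaD.  Transients whose fit fails are flagged and
    carry NaN tau.
    """
    t, y = trace.t, trace.values
    ev = np.asarray(events.times, dtype=float)
    if ev.size == 0:
        return CaTFeatures(
            cad=float(np.median(y)),
            event_times=np.array([]),
            amplitude=np.array([]),
            t_peak=np.array([]),
            tau_decay=np.array([]),
            frequency=0.0,
        )

    # per-segment medians of the pre-onset diastole; the minimum over
    # segments rejects segments still riding a previous decay tail
    dia: list[float] = []
    prev_end = t[0]
    for t_on in ev:
        lo = max(prev_end, t_on - _DIASTOLE_LOOKBACK_S)
        mask = (t >= lo) & (t < t_on)
        if mask.any():
            dia.append(float(np.median(y[mask])))
        prev_end = t_on
    cad = min(dia) if dia else float(np.median(y))

    bounds = np.concatenate([ev[1:], [t[-1] + trace.dt]])
    amps, tpeaks, taus = [], [], []
    flags: list[str] = []
    for j, (t_on, t_next) in enumerate(zip(ev, bounds)):
        i_on = int(np.searchsorted(t, t_on))
        i_end = int(np.searchsorted(t, t_next))
        seg = slice(i_on, i_end)
        i_peak = i_on + int(np.argmax(y[seg]))
        amp = float(y[i_peak] - cad)
        amps.append(amp)
        tpeaks.append(float(t[i_peak] - t_on))

        # decay samples from the peak down to 90 % recovery
        rec = y[i_peak:i_end] - cad
        stop = np.flatnonzero(rec <= 0.1 * amp)
        i_stop = int(stop[0]) if stop.size else rec.size
        z = rec[:i_stop]
        tt = t[i_peak : i_peak + i_stop]
        ok = z > 0
        if ok.sum() < 3 or amp <= 0:
            taus.append(float("nan"))
            flags.append(f"cat{j}:fit_failed")
            continue
        slope, _ = np.polyfit(tt[ok], np.log(z[ok]), 1)
        if slope >= 0:
            taus.append(float("nan"))
            flags.append(f"cat{j}:fit_failed")
        else:
            taus.append(float(-1.0 / slope))

    return CaTFeatures(
        cad=cad,
        event_times=ev,
        amplitude=np.asarray(amps),
        t_peak=np.asarray(tpeaks),
        tau_decay=np.asarray(taus),
        frequency=ev.size / trace.duration,
        flags=tuple(flags),
    )


def window_frequencies(
    events: EventTimes, windows: dict[str, tuple[float, float]]
) -> dict[str, float]:
    """Event rate per half-open window, Hz: count / duration.

    Windows (e.g. pre / light / post) must be disjoint and of positive
    length; an empty window reports 0 Hz.
    """
    spans = sorted(windows.items(), key=lambda kv: kv[1][0])
    for name, (a, b) in spans:
        if not b > a:
            raise ValueError(f"window {name!r} has non-positive length")
    for (n1, (_, e1)), (n2, (s2, _)) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"windows {n1!r} and {n2!r} overlap")
    times = events.times
    return {
        name: float(np.count_nonzero((times >= a) & (times < b))) / (b - a)
        for name, (a, b) in windows.items()
    }


def percent_change(pre_mean: float, post_mean: float) -> float:
    """``100 (post - pre) / pre``, sign preserved; exact value returned."""
    if pre_mean == 0:
        raise ValueError("percent change is undefined for a zero baseline")
    return 100.0 * (post_mean - pre_mean) / pre_mean


def report_percent(value: float) -> int:
    """Integer-rounded percent for reporting (the exact value is kept upstream)."""
    return int(round(value))


def responding_fraction(
    events: EventTimes,
    protocol: LightProtocol,
    latency_window: float = LATENCY_WINDOW_S,
) -> float:
    """Percentage of light pulses followed by >= 1 event within the window.

    The per-pulse window is ``(onset, onset + latency_window]``; windows
    must not overlap the next pulse.
    """
    onsets = np.asarray(protocol.onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("protocol has no light pulses")
    if onsets.size > 1 and np.any(np.diff(onsets) < latency_window):
        raise ValueError("latency windows overlap the next pulse")
    times = events.times
    answered = sum(
        bool(np.any((times > on) & (times <= on + latency_window))) for on in onsets
    )
    return 100.0 * answered / onsets.size


@dataclass
class LatencyResult:
    """Light-onset-to-event latency histogram with a gamma guide fit."""

    latencies: np.ndarray  # s, one per answered pulse
    bin_edges: np.ndarray
    counts: np.ndarray
    gamma_shape: float = float("nan")
    gamma_scale: float = float("nan")
    mode: float = float("nan")  # s, (shape-1)*scale for shape > 1
    log_likelihood: float = float("nan")
    flags: tuple[str, ...] = ()


def latency_histogram(
    events: EventTimes,
    protocol: LightProtocol,
    bin_width: float = 0.1,
) -> LatencyResult:
    """Histogram of first-event latencies after each light onset.

    Per pulse the latency is the delay to the first event before the next
    onset; unanswered pulses are excluded.  With >= 5 latencies a gamma
    distribution is fitted by maximum likelihood (location fixed at 0) as a
    guide to the eye, and its mode ``(shape - 1) * scale`` is reported.
    Identical latencies are a degenerate case: flagged, mode set to the
    common value, no fit attempted.
    """
    onsets = np.asarray(protocol.onsets, dtype=float)
    bounds = np.concatenate([onsets[1:], [np.inf]])
    lats: list[float] = []
    for on, nxt in zip(onsets, bounds):
        hit = events.times[(events.times > on) & (events.times < nxt)]
        if hit.size:
            lats.append(float(hit[0] - on))
    lat = np.asarray(lats)

    if lat.size:
        n_bins = max(1, int(np.ceil((lat.max() + 1e-12) / bin_width)))
        edges = np.arange(n_bins + 1) * bin_width
        counts, _ = np.histogram(lat, bins=edges)
    else:
        edges = np.array([0.0, bin_width])
        counts = np.zeros(1, dtype=int)

    if lat.size < 5:
        return LatencyResult(lat, edges, counts, flags=("too_few_latencies",))
    if np.ptp(lat) < 1e-12:
        return LatencyResult(
            lat, edges, counts, mode=float(lat[0]), flags=("degenerate",)
        )
    shape, _, scale = stats.gamma.fit(lat, floc=0)
    mode = (shape - 1.0) * scale if shape > 1 else 0.0
    loglik = float(np.sum(stats.gamma.logpdf(lat, shape, loc=0, scale=scale)))
    return LatencyResult(
        lat, edges, counts, gamma_shape=float(shape), gamma_scale=float(scale),
        mode=float(mode), log_likelihood=loglik,
    )


@dataclass
class LockingResult:
    """Event phases folded onto the stimulation cycle.

    ``concentration_index`` is the fraction of events falling in the first
    10 % of the cycle — 1.0 for perfectly light-locked events, ~0.1 for
    events unrelated to the light.
    """

    phases: np.ndarray  # s in [0, cycle)
    bin_edges: np.ndarray
    counts: np.ndarray
    cycle: float
    concentration_index: float


def light_locking_histogram(
    events: EventTimes,
    protocol: LightProtocol,
    cycle: float | None = None,
    n_bins: int = 20,
) -> LockingResult:
    """Fold event times modulo the stimulation cycle and histogram them.

    Requires a periodic protocol; the cycle defaults to its period.  Phase
    0 is the light onset.
    """
    if protocol.period is None and cycle is None:
        raise ValueError("light_locking_histogram requires a periodic protocol")
    cyc = float(cycle if cycle is not None else protocol.period)
    t0 = protocol.onsets[0]
    phases = np.mod(events.times - t0, cyc)
    edges = np.linspace(0.0, cyc, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    index = float(np.mean(phases < 0.1 * cyc)) if phases.size else float("nan")
    return LockingResult(phases, edges, counts, cyc, index)
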