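"""Contraction quantification from video by bounding-box KLT tracking.

The approach quantifies beating without segmenting the cell outline: the
user draws one bounding box per cell, Shi-Tomasi corner features inside the
box are tracked frame-to-frame with a pyramidal Kanade-Lucas-Tomasi (KLT)
tracker, and the per-frame motion fields are averaged into one similarity
transform (uniform scale + rotation + translation).  Composing these
transforms and applying them to the box gives a box-area trace whose minima
are the contractions — the contraction of the cell body toward its centre
is an isotropic shrinkage, so the squared scale of the similarity is
exactly the area ratio.  Event rate, percent area reduction and the area
derivative then give contraction frequency, amplitude and velocity.

Works even when cell extremities barely move or the edge cannot be
segmented, which is the point of the box-based formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.signal import find_peaks
from skimage.feature import corner_peaks, corner_shi_tomasi

from .video import BoundingBox, VideoStack

__all__ = [
    "KLTConfig",
    "FeatureTrack",
    "SimilarityTransform",
    "AreaTrace",
    "ContractionEvent",
    "ContractionMetrics",
    "TrackingError",
    "detect_features",
    "track_features",
    "mean_transform",
    "propagate_box",
    "detect_contractions",
    "contraction_metrics",
    "measure_contractions",
]


class TrackingError(RuntimeError):
    """Tracking became unreliable; carries the offending frame index."""

    def __init__(self, message: str, frame_index: int | None = None) -> None:
        super().__init__(message)
        self.frame_index = frame_index


@dataclass(frozen=True)
class KLTConfig:
    """Tracker settings (all exposed because none are canonical).

    pyramid_levels : coarse-to-fine levels (each halves resolution)
    window : side of the square integration window, px (odd)
    max_iters / tol : per-level iteration cap and convergence step, px
    fb_threshold : forward-backward consistency limit, px; a feature whose
        round-trip error exceeds it is invalidated from that frame on
    """

    pyramid_levels: int = 3
    window: int = 21
    max_iters: int = 20
    tol: float = 0.01
    fb_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 5:
            raise ValueError("window must be odd and >= 5")


# ---------------------------------------------------------------------------
# feature detection
# ---------------------------------------------------------------------------


def detect_features(
    frame: np.ndarray,
    box: BoundingBox,
    max_n: int = 100,
    quality_level: float = 0.05,
    min_distance: int = 4,
) -> np.ndarray:
    """Shi-Tomasi corners inside the box, as (x, y) rows.

    Keeps at most ``max_n`` corners whose minimum-eigenvalue score is at
    least ``quality_level`` times the best score, with a mutual distance of
    ``min_distance`` px.  Deterministic for a fixed frame.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be a single 2-D grayscale image")
    if not box.contains(frame.shape):
        raise ValueError("bounding box extends outside the frame")
    x0, y0 = int(np.floor(box.x0)), int(np.floor(box.y0))
    x1, y1 = int(np.ceil(box.x1)), int(np.ceil(box.y1))
    crop = frame[y0:y1, x0:x1].astype(float)
    response = corner_shi_tomasi(crop)
    peaks = corner_peaks(
        response,
        min_distance=min_distance,
        threshold_rel=quality_level,
        num_peaks=max_n,
        exclude_border=2,
    )
    if peaks.shape[0] < 4:
        raise TrackingError(
            f"only {peaks.shape[0]} trackable features found in the box; "
            "use a larger box or a lower quality_level"
        )
    # (row, col) in crop -> (x, y) in frame
    return np.column_stack([peaks[:, 1] + x0, peaks[:, 0] + y0]).astype(float)


# ---------------------------------------------------------------------------
# pyramidal Lucas-Kanade
# ---------------------------------------------------------------------------


def _build_pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img.astype(np.float32)]
    for _ in range(levels - 1):
        smoothed = gaussian_filter(pyr[-1], 1.0)
        pyr.append(smoothed[::2, ::2])
    return pyr


def _lk_level(
    I0: np.ndarray,
    I1: np.ndarray,
    pts0: np.ndarray,
    guess: np.ndarray,
    cfg: KLTConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """One Lucas-Kanade refinement at a single pyramid level.

    Vectorized over features: template patches and gradients are sampled
    around ``pts0`` in I0 once; the displacement of each patch in I1 is
    iterated from ``guess``.  Returns (tracked points, validity mask).
    """
    n = pts0.shape[0]
    half = cfg.window // 2
    off = np.arange(-half, half + 1, dtype=np.float32)
    oy, ox = np.meshgrid(off, off, indexing="ij")
    ox = ox.ravel()
    oy = oy.ravel()  # (w2,)

    gy_img, gx_img = np.gradient(I0)

    # template coords: (n, w2)
    tx = pts0[:, 0][:, None] + ox[None, :]
    ty = pts0[:, 1][:, None] + oy[None, :]
    coords = np.vstack([ty.ravel(), tx.ravel()])
    T = map_coordinates(I0, coords, order=1, mode="nearest").reshape(n, -1)
    gx = map_coordinates(gx_img, coords, order=1, mode="nearest").reshape(n, -1)
    gy = map_coordinates(gy_img, coords, order=1, mode="nearest").reshape(n, -1)

    gxx = np.sum(gx * gx, axis=1)
    gxy = np.sum(gx * gy, axis=1)
    gyy = np.sum(gy * gy, axis=1)
    det = gxx * gyy - gxy**2
    valid = det > 1e-6

    p = guess.copy()
    active = valid.copy()
    h, w = I1.shape
    for _ in range(cfg.max_iters):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        cx = p[idx, 0][:, None] + ox[None, :]
        cy = p[idx, 1][:, None] + oy[None, :]
        patches = map_coordinates(
            I1, np.vstack([cy.ravel(), cx.ravel()]), order=1, mode="nearest"
        ).reshape(idx.size, -1)
        e = T[idx] - patches
        bx = np.sum(e * gx[idx], axis=1)
        by = np.sum(e * gy[idx], axis=1)
        dx = (gyy[idx] * bx - gxy[idx] * by) / det[idx]
        dy = (gxx[idx] * by - gxy[idx] * bx) / det[idx]
        p[idx, 0] += dx
        p[idx, 1] += dy
        done = np.hypot(dx, dy) < cfg.tol
        active[idx[done]] = False

    inside = (
        (p[:, 0] >= -half)
        & (p[:, 0] <= w - 1 + half)
        & (p[:, 1] >= -half)
        & (p[:, 1] <= h - 1 + half)
    )
    return p, valid & inside & np.isfinite(p).all(axis=1)


def _track_pair(
    pyr0: list[np.ndarray],
    pyr1: list[np.ndarray],
    pts0: np.ndarray,
    cfg: KLTConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Track points from frame 0 to frame 1 through the pyramid."""
    levels = len(pyr0)
    scale = 2.0 ** (levels - 1)
    p = pts0 / scale
    valid = np.ones(pts0.shape[0], dtype=bool)
    for lvl in range(levels - 1, -1, -1):
        s = 2.0**lvl
        p0_lvl = pts0 / s
        p, ok = _lk_level(pyr0[lvl], pyr1[lvl], p0_lvl, p, cfg)
        valid &= ok
        if lvl > 0:
            p = p * 2.0
    return p, valid


@dataclass
class FeatureTrack:
    """Per-frame sub-pixel feature positions with validity flags.

    positions : (n_frames, n_features, 2) array of (x, y); NaN where invalid
    status : (n_frames, n_features) bool; once a feature is lost it stays lost
    """

    positions: np.ndarray
    status: np.ndarray

    def valid_pairs(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Corresponding valid points for the transition i -> i+1."""
        ok = self.status[i] & self.status[i + 1]
        return self.positions[i][ok], self.positions[i + 1][ok]


def track_features(
    video: VideoStack,
    features: np.ndarray,
    box: BoundingBox | None = None,
    config: KLTConfig | None = None,
) -> FeatureTrack:
    """Pyramidal KLT over the whole stack with forward-backward checking.

    Each frame transition tracks the surviving features forward, re-tracks
    the result backward, and invalidates any feature whose round-trip error
    exceeds ``config.fb_threshold`` px from that frame on.  Raises
    :class:`TrackingError` if fewer than 4 features survive a transition.
    """
    cfg = config or KLTConfig()
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != 2 or features.shape[0] < 4:
        raise ValueError("need at least 4 features as (x, y) rows")
    n_frames = video.n_frames
    n = features.shape[0]
    positions = np.full((n_frames, n, 2), np.nan)
    status = np.zeros((n_frames, n), dtype=bool)
    positions[0] = features
    status[0] = True

    pyr_prev = _build_pyramid(video.frames[0], cfg.pyramid_levels)
    for i in range(n_frames - 1):
        pyr_next = _build_pyramid(video.frames[i + 1], cfg.pyramid_levels)
        ok_idx = np.flatnonzero(status[i])
        pts = positions[i][ok_idx]
        fwd, ok_f = _track_pair(pyr_prev, pyr_next, pts, cfg)
        back, ok_b = _track_pair(pyr_next, pyr_prev, fwd, cfg)
        fb_err = np.hypot(*(back - pts).T)
        keep = ok_f & ok_b & (fb_err <= cfg.fb_threshold)
        surv = ok_idx[keep]
        if surv.size < 4:
            raise TrackingError(
                f"fewer than 4 features survived the transition to frame {i + 1}",
                frame_index=i + 1,
            )
        positions[i + 1, surv] = fwd[keep]
        status[i + 1, surv] = True
        pyr_prev = pyr_next
    return FeatureTrack(positions, status)


# ---------------------------------------------------------------------------
# mean similarity transform and box propagation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityTransform:
    """x' = s R x + t with uniform scale s and rotation theta (radians)."""

    scale: float
    rotation: float
    tx: float
    ty: float

    def apply(self, pts: np.ndarray) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        R = np.array([[c, -s], [s, c]])
        return (self.scale * np.asarray(pts, float) @ R.T) + np.array([self.tx, self.ty])

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """The transform 'self after other' (other applied first)."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        R = np.array([[c, -s], [s, c]])
        t = self.scale * (R @ np.array([other.tx, other.ty])) + np.array([self.tx, self.ty])
        return SimilarityTransform(
            self.scale * other.scale,
            self.rotation + other.rotation,
            float(t[0]),
            float(t[1]),
        )

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, 0.0, 0.0, 0.0)


def _similarity_lstsq(p0: np.ndarray, p1: np.ndarray) -> SimilarityTransform:
    """Closed-form least-squares similarity p0 -> p1 (complex formulation)."""
    z0 = p0[:, 0] + 1j * p0[:, 1]
    z1 = p1[:, 0] + 1j * p1[:, 1]
    mu0, mu1 = z0.mean(), z1.mean()
    d0 = z0 - mu0
    denom = np.sum(np.abs(d0) ** 2)
    if denom < 1e-12:
        raise TrackingError("degenerate feature geometry: points are coincident")
    a = np.sum(np.conj(d0) * (z1 - mu1)) / denom
    t = mu1 - a * mu0
    return SimilarityTransform(
        scale=float(np.abs(a)),
        rotation=float(np.angle(a)),
        tx=float(t.real),
        ty=float(t.imag),
    )


def mean_transform(points_prev: np.ndarray, points_next: np.ndarray) -> SimilarityTransform:
    """Average the feature motion field into one similarity transform.

    A closed-form least-squares similarity (Umeyama/Procrustes) maps the
    previous positions onto the next ones; pairs whose residual exceeds 3x
    the median residual are dropped once and the transform refitted, so a
    few mistracked features cannot skew the scale.
    """
    p0 = np.asarray(points_prev, dtype=float)
    p1 = np.asarray(points_next, dtype=float)
    if p0.shape != p1.shape or p0.ndim != 2 or p0.shape[1] != 2:
        raise ValueError("point sets must be matching (n, 2) arrays")
    if p0.shape[0] < 4:
        raise ValueError("need at least 4 corresponding point pairs")
    tf = _similarity_lstsq(p0, p1)
    resid = np.hypot(*(tf.apply(p0) - p1).T)
    med = np.median(resid)
    if med > 1e-9:
        keep = resid <= 3.0 * med
        if keep.sum() >= 4 and keep.sum() < p0.shape[0]:
            tf = _similarity_lstsq(p0[keep], p1[keep])
    return tf


@dataclass
class AreaTrace:
    """Bounding-box area against time.

    t : s (uniform, 1/fps); area : px^2; normalized_area : fraction of the
    frame-0 area.
    """

    t: np.ndarray
    area: np.ndarray
    normalized_area: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.area <= 0):
            raise ValueError("box area must stay positive")

    @property
    def fps(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.t, "area_px2": self.area, "normalized_area": self.normalized_area}
        ).to_csv(path, index=False)


def propagate_box(
    box0: BoundingBox,
    transforms: list[SimilarityTransform],
    fps: float,
) -> AreaTrace:
    """Apply the cumulative transform chain to the box and record its area.

    Transform k maps frame k to frame k+1; the box corners at frame n are
    the frame-0 corners through the composition of the first n transforms.
    For a similarity the quadrilateral stays a rectangle of area
    ``s_cum^2`` times the initial area.  A cumulative scale outside
    [0.3, 3] triggers a drift warning.
    """
    corners = box0.corners
    n_frames = len(transforms) + 1
    area = np.empty(n_frames)
    area[0] = box0.area
    cum = SimilarityTransform.identity()
    warned = False
    for k, tf in enumerate(transforms):
        cum = tf.compose(cum)
        if not warned and not 0.3 <= cum.scale <= 3.0:
            warnings.warn(
                f"cumulative scale {cum.scale:.3g} at frame {k + 1} is outside "
                "[0.3, 3]; the transform chain has probably drifted",
                RuntimeWarning,
                stacklevel=2,
            )
            warned = True
        quad = cum.apply(corners)
        # shoelace area of the mapped quadrilateral
        x, y = quad[:, 0], quad[:, 1]
        area[k + 1] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    t = np.arange(n_frames) / fps
    return AreaTrace(t, area, area / area[0])


# ---------------------------------------------------------------------------
# contraction events and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContractionEvent:
    """One contraction: time of the area minimum, amplitude and velocity.

    amplitude : percent area reduction relative to the local pre-event
        baseline (median normalized area over the second before the dip)
    peak_velocity : max |d(normalized area)/dt| on the falling edge, %/s
    prominence : topographic prominence of the minimum, fraction of area
    """

    t_min: float
    amplitude: float
    peak_velocity: float
    prominence: float


#: default minimum dip prominence (fraction of baseline area) and minimum
#: separation between events (s)
PROMINENCE_MIN = 0.02
REFRACTORY_S = 0.3
_BASELINE_LOOKBACK_S = 1.0


def detect_contractions(
    area: AreaTrace,
    prominence_min: float = PROMINENCE_MIN,
    refractory: float = REFRACTORY_S,
) -> list[ContractionEvent]:
    """Minima of the normalized-area trace as contraction events.

    Local minima need topographic prominence >= ``prominence_min`` and
    mutual separation >= ``refractory`` seconds.  Per event the amplitude
    is ``100 (baseline - minimum)/baseline`` with the baseline taken as the
    median normalized area in the second preceding the falling edge, and
    the peak velocity is the largest area-derivative magnitude on the
    falling edge (central differences on a 3-frame moving average).
    """
    x = np.asarray(area.normalized_area, dtype=float)
    t = np.asarray(area.t, dtype=float)
    if t[-1] - t[0] < 2.0:
        raise ValueError("area trace must span at least 2 s")
    fps = area.fps
    distance = max(1, int(round(refractory * fps)))
    idx, props = find_peaks(-x, prominence=prominence_min, distance=distance)

    smoothed = np.convolve(x, np.ones(3) / 3.0, mode="same")
    smoothed[0], smoothed[-1] = x[0], x[-1]
    deriv = np.gradient(smoothed, t)

    events: list[ContractionEvent] = []
    for j, i_min in enumerate(idx):
        lb = int(props["left_bases"][j])
        base_mask = (t >= t[lb] - _BASELINE_LOOKBACK_S) & (t < t[lb])
        baseline = float(np.median(x[base_mask])) if base_mask.any() else float(x[lb])
        amplitude = 100.0 * (baseline - x[i_min]) / baseline
        lo = min(lb, i_min)
        vel = float(np.max(np.abs(deriv[lo : i_min + 1]))) * 100.0
        events.append(
            ContractionEvent(
                t_min=float(t[i_min]),
                amplitude=amplitude,
                peak_velocity=vel,
                prominence=float(props["prominences"][j]),
            )
        )
    return events


@dataclass(frozen=True)
class ContractionMetrics:
    """Windowed summary: event rate plus mean amplitude and velocity."""

    window: tuple[float, float]
    n_events: int
    frequency: float  # Hz
    mean_amplitude: float  # %, NaN if no events
    mean_velocity: float  # %/s, NaN if no events
    flags: tuple[str, ...] = ()


def contraction_metrics(
    events: list[ContractionEvent],
    windows: dict[str, tuple[float, float]],
) -> dict[str, ContractionMetrics]:
    """Per-window frequency/amplitude/velocity over half-open [start, end).

    Typical windows are ``{"pre": ..., "light": ..., "post": ...}`` around a
    stimulation train.  Windows must be disjoint and of positive length; an
    empty window reports frequency 0 and NaN amplitude/velocity with a
    ``"no_events"`` flag.
    """
    spans = sorted(windows.items(), key=lambda kv: kv[1][0])
    for name, (a, b) in spans:
        if not b > a:
            raise ValueError(f"window {name!r} has non-positive length")
    for (n1, (_, e1)), (n2, (s2, _)) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"windows {n1!r} and {n2!r} overlap")

    out: dict[str, ContractionMetrics] = {}
    for name, (a, b) in windows.items():
        sel = [ev for ev in events if a <= ev.t_min < b]
        n = len(sel)
        if n:
            amp = float(np.mean([ev.amplitude for ev in sel]))
            vel = float(np.mean([ev.peak_velocity for ev in sel]))
            flags: tuple[str, ...] = ()
        else:
            amp = vel = float("nan")
            flags = ("no_events",)
        out[name] = ContractionMetrics(
            window=(a, b),
            n_events=n,
            frequency=n / (b - a),
            mean_amplitude=amp,
            mean_velocity=vel,
            flags=flags,
        )
    return out


def measure_contractions(
    video: VideoStack,
    box: BoundingBox,
    config: KLTConfig | None = None,
    max_features: int = 100,
    quality_level: float = 0.05,
    prominence_min: float = PROMINENCE_MIN,
    refractory: float = REFRACTORY_S,
) -> tuple[AreaTrace, list[ContractionEvent]]:
    """End-to-end: features -> KLT -> mean transforms -> area -> events."""
    features = detect_features(video.frames[0], box, max_n=max_features, quality_level=quality_level)
    track = track_features(video, features, box, config)
    transforms = [mean_transform(*track.valid_pairs(i)) for i in range(video.n_frames - 1)]
    area = propagate_box(box, transforms, video.fps)
    return area, detect_contractions(area, prominence_min, refractory)
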