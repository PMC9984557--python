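"""Grayscale video stacks and region-of-interest boxes.

Pixel convention used throughout the package: 0-based coordinates, origin
at the top-left, row-major frames indexed ``frames[frame, row, col]``; an
``(x, y)`` point is ``(col, row)``.  Bounding boxes are half-open,
``[x0, x1) x [y0, y1)``, so box area is exactly ``(x1-x0)*(y1-y0)`` pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["VideoStack", "BoundingBox", "read_boxes_csv", "write_boxes_csv"]


@dataclass
class VideoStack:
    """Time-ordered grayscale frames with frame-rate metadata.

    frames : uint8 or uint16 array, shape (n_frames, height, width)
    fps : frames per second
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_frames, height, width)")
        if self.frames.dtype not in (np.uint8, np.uint16):
            raise ValueError("frames must be 8- or 16-bit grayscale")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a frame."""
        return self.frames.shape[1:]

    @property
    def t(self) -> np.ndarray:
        """Frame times in seconds, frame 0 at t = 0."""
        return np.arange(self.n_frames) / self.fps

    def to_tiff(self, path: str | Path) -> None:
        """Write a multi-page TIFF; fps is stored in the ImageDescription."""
        tifffile.imwrite(
            str(path),
            self.frames,
            photometric="minisblack",
            description=json.dumps({"fps": self.fps}),
        )

    @classmethod
    def from_tiff(cls, path: str | Path, fps: float | None = None) -> "VideoStack":
        """Read a multi-page TIFF; fps from the ImageDescription unless given."""
        with tifffile.TiffFile(str(path)) as tif:
            frames = tif.asarray()
            if fps is None:
                desc = tif.pages[0].description or ""
                try:
                    fps = float(json.loads(desc)["fps"])
                except (ValueError, KeyError, TypeError):
                    raise ValueError(
                        f"{path}: no fps metadata found; pass fps= explicitly"
                    ) from None
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames, fps)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [x0, x1) x [y0, y1), one cell per box."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 + 4 and self.y1 > self.y0 + 4):
            raise ValueError("box must be at least 4 px wide and tall")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def corners(self) -> np.ndarray:
        """The four corners as (x, y) rows, counter-clockwise from (x0, y0)."""
        return np.array(
            [
                [self.x0, self.y0],
                [self.x1, self.y0],
                [self.x1, self.y1],
                [self.x0, self.y1],
            ],
            dtype=float,
        )

    def contains(self, frame_shape: tuple[int, int]) -> bool:
        h, w = frame_shape
        return 0 <= self.x0 and self.x1 <= w and 0 <= self.y0 and self.y1 <= h


def read_boxes_csv(path: str | Path) -> list[BoundingBox]:
    """ROI boxes from a sidecar CSV with columns x0,y0,x1,y1 (one row per box)."""
    df = pd.read_csv(path)
    return [
        BoundingBox(row["x0"], row["y0"], row["x1"], row["y1"])
        for _, row in df.iterrows()
    ]


def write_boxes_csv(boxes: list[BoundingBox], path: str | Path) -> None:
    pd.DataFrame(
        [(b.x0, b.y0, b.x1, b.y1) for b in boxes], columns=["x0", "y0", "x1", "y1"]
    ).to_csv(path, index=False)
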