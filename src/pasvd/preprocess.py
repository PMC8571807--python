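"""Conversion of beamformed frame data into the stacks the SVD filter consumes.

The canonical entry point of the filtering framework is a log-compressed
multiframe stack.  When the acquisition system delivers beamformed RF, the
chain is ``envelope_detect`` -> ``log_compress``; stacks that arrive already
log-compressed bypass this module (the pipeline records which path was taken
in its provenance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "Modality",
    "Scale",
    "FrameStack",
    "envelope_detect",
    "log_compress",
    "average_frames",
    "contrast_stretch",
]


class Modality(str, Enum):
    US = "US"
    PA = "PA"


class Scale(str, Enum):
    LINEAR = "linear_envelope"
    LOG_DB = "log_dB"
    # outputs of nonlinear filtering carry arbitrary units (may be negative)
    ARBITRARY = "arbitrary"


@dataclass
class FrameStack:
    """A 3-D image sequence: ``data[depth_px, lateral_px, frame]``.

    Axial depth is array dimension 0 and increases downward, matching B-mode
    display convention.
    """

    data: np.ndarray
    modality: Modality = Modality.US
    scale: Scale = Scale.LINEAR
    frame_rate_hz: float = 20.0
    pixel_pitch_mm: tuple[float, float] = (0.1, 0.1)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.modality = Modality(self.modality)
        self.scale = Scale(self.scale)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack data must be 3-D (depth, lateral, frame); got shape {self.data.shape}"
            )
        if self.data.shape[2] < 1:
            raise ValueError("stack must contain at least one frame")
        if not np.all(np.isfinite(self.data)):
            bad = np.nonzero(~np.isfinite(self.data).all(axis=(0, 1)))[0]
            raise ValueError(f"non-finite values in frame(s) {bad.tolist()}")
        if self.scale is Scale.LINEAR and np.any(self.data < 0):
            raise ValueError("linear-envelope stack must be non-negative")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if any(p <= 0 for p in self.pixel_pitch_mm):
            raise ValueError("pixel_pitch_mm entries must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def with_data(self, data: np.ndarray, **changes) -> "FrameStack":
        """Copy of this stack with new pixel data (metadata preserved)."""
        return replace(self, data=data, **changes)


def envelope_detect(rf_frames: np.ndarray, *, metadata: dict | None = None) -> FrameStack:
    """Per-frame analytic-signal magnitude along the axial (first) axis.

    Parameters
    ----------
    rf_frames
        Real-valued beamformed RF, shape ``(depth, lateral, frame)``.

    Returns
    -------
    FrameStack
        Linear-envelope stack of the same shape.
    """
    rf = np.asarray(rf_frames, dtype=float)
    if rf.ndim != 3:
        raise ValueError(f"expected 3-D RF array, got shape {rf.shape}")
    finite = np.isfinite(rf).all(axis=(0, 1))
    if not finite.all():
        bad = np.nonzero(~finite)[0]
        raise ValueError(f"non-finite RF values in frame(s) {bad.tolist()}")
    env = np.abs(hilbert(rf, axis=0))
    meta = dict(metadata or {})
    return FrameStack(
        env,
        modality=meta.get("modality", Modality.US),
        scale=Scale.LINEAR,
        frame_rate_hz=meta.get("frame_rate_hz", 20.0),
        pixel_pitch_mm=meta.get("pixel_pitch_mm", (0.1, 0.1)),
        provenance={"envelope_detect": "analytic-signal magnitude, axial axis"},
    )


def log_compress(stack: FrameStack, floor_db: float = -60.0) -> FrameStack:
    """Map a linear-envelope stack to dB relative to its global maximum.

    Values become ``20*log10(v / max)`` clipped below at ``floor_db``; the
    output maximum is exactly 0 dB.
    """
    if stack.scale is not Scale.LINEAR:
        raise ValueError("log_compress expects a linear-envelope stack")
    if not floor_db < 0:
        raise ValueError("floor_db must be negative")
    peak = float(stack.data.max())
    if peak <= 0:
        raise ValueError("all-zero stack: no reference maximum for log compression")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(stack.data / peak)
    db = np.clip(db, floor_db, None)
    prov = dict(stack.provenance)
    prov["log_compress"] = {"floor_db": floor_db, "reference_max": peak}
    return stack.with_data(db, scale=Scale.LOG_DB, provenance=prov)


def average_frames(stack: FrameStack, group_size: int) -> FrameStack:
    """Average consecutive groups of ``group_size`` frames.

    Mirrors the acquisition-side averaging of consecutive single-wavelength
    frames.  A trailing remainder that does not fill a group is dropped with
    a warning.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n = stack.n_frames
    if group_size > n:
        raise ValueError(f"group_size {group_size} exceeds frame count {n}")
    n_groups, rem = divmod(n, group_size)
    if rem:
        warnings.warn(
            f"dropping {rem} trailing frame(s) not filling a group of {group_size}",
            stacklevel=2,
        )
    d = stack.data[:, :, : n_groups * group_size]
    out = d.reshape(d.shape[0], d.shape[1], n_groups, group_size).mean(axis=3)
    prov = dict(stack.provenance)
    prov["average_frames"] = {"group_size": group_size, "dropped": rem}
    return stack.with_data(out, provenance=prov)


def contrast_stretch(image: np.ndarray, lo_pct: float = 1.0, hi_pct: float = 99.0) -> np.ndarray:
    """Linear rescale mapping the given percentiles to [0, 1], clipped."""
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError("require 0 <= lo_pct < hi_pct <= 100")
    img = np.asarray(image, dtype=float)
    lo, hi = np.percentile(img, [lo_pct, hi_pct])
    if hi == lo:
        raise ValueError("degenerate dynamic range: percentiles coincide")
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)
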