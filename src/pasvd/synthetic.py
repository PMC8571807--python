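"""Synthetic interleaved US/PA phantom stacks with exact ground-truth labels.

Simulates a 2-D cross-section of a vessel-mimicking phantom: a pulsatile
central lumen surrounded by a tissue wall, a small constant-flow arteriole
channel, and two stationary blood channels, all embedded in static speckle.
Flow is modelled as frame-to-frame speckle decorrelation (an AR(1) complex
field), wall pulsation as a radial sinusoidal displacement of the wall
texture, and PA sources as depth-attenuated emitters at the blood-containing
regions.  Everything is driven by one seed, so stacks are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .preprocess import FrameStack, Modality, Scale, log_compress

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "simulate_phantom",
    "orientation_variants",
    "ORIENTATION_PRESETS_DEG",
]

ORIENTATION_PRESETS_DEG = (0.0, 90.0, 120.0, 180.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, dynamics, and noise parameters of the simulated phantom.

    Distances are millimetres; angles are degrees with 0 pointing to the
    lateral right and positive angles rotating toward larger depth.
    """

    image_shape_px: tuple[int, int] = (128, 128)
    pixel_pitch_mm: tuple[float, float] = (0.1, 0.1)
    frame_rate_hz: float = 30.0
    n_frames: int = 300
    # lumen + wall
    lumen_center_mm: tuple[float, float] = (6.4, 6.4)
    lumen_diameter_mm: float = 3.0
    wall_thickness_mm: float = 1.0
    pulsation_hz: float = 1.0
    wall_strain: float = 0.09
    # cavities, placed on a circle around the lumen center
    cavity_radius_mm: float = 4.0
    arteriole_diameter_mm: float = 0.5
    arteriole_angle_deg: float = 0.0
    iph_diameter_mm: float = 1.0
    iph_offsets_deg: tuple[float, ...] = (120.0, 240.0)
    # texture and dynamics
    speckle_grain_px: float = 1.0
    wall_grain_px: float = 3.0  # coarser wall texture keeps pulsation coherent frame to frame
    flow_corr: float = 0.3  # frame-to-frame complex-field correlation in flow
    flow_cell_px: int = 2  # flow correlation-cell size; bounds the flow band width
    background_amp: float = 1.0
    wall_amp: float = 2.0
    flow_amp: float = 1.2
    noise_sigma: float = 0.001
    # photoacoustics
    pa_iph_amp: float = 1.0
    pa_flow_amp: float = 1.0
    pa_background: float = 0.02
    pa_noise_sigma: float = 0.02
    fluence_decay_mm: float = 25.0
    shadow_atten_per_mm: float = 0.05  # extra attenuation per mm of absorber above
    log_floor_db: float = -60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("lumen_diameter_mm", "arteriole_diameter_mm", "iph_diameter_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.flow_corr <= 1.0):
            raise ValueError("flow_corr must be in [0, 1]")

    # --- geometry helpers (pixel units) -------------------------------

    def _to_px(self, mm_rc: tuple[float, float]) -> tuple[float, float]:
        return (mm_rc[0] / self.pixel_pitch_mm[0], mm_rc[1] / self.pixel_pitch_mm[1])

    def cavity_center_mm(self, angle_deg: float) -> tuple[float, float]:
        a = math.radians(angle_deg)
        cz, cx = self.lumen_center_mm
        return (cz + self.cavity_radius_mm * math.sin(a), cx + self.cavity_radius_mm * math.cos(a))

    def arteriole_center_mm(self) -> tuple[float, float]:
        return self.cavity_center_mm(self.arteriole_angle_deg)

    def iph_centers_mm(self) -> list[tuple[float, float]]:
        return [self.cavity_center_mm(self.arteriole_angle_deg + d) for d in self.iph_offsets_deg]


@dataclass
class GroundTruth:
    """Exact pixel labels of the simulated scene (mutually disjoint)."""

    flow_mask: np.ndarray  # lumen + arteriole
    iph_mask: np.ndarray  # stationary PA source discs
    wall_mask: np.ndarray

    lumen_mask: np.ndarray = field(default=None, repr=False)
    arteriole_mask: np.ndarray = field(default=None, repr=False)


def _disc_mask(shape, center_px, radius_px) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2 <= radius_px**2


def _speckle(rng: np.random.Generator, shape, grain_px: float) -> np.ndarray:
    """Fully developed speckle: magnitude of a smoothed complex Gaussian field."""
    f = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    if grain_px > 0:
        f = ndimage.gaussian_filter(f.real, grain_px) + 1j * ndimage.gaussian_filter(
            f.imag, grain_px
        )
    mag = np.abs(f)
    rms = np.sqrt(np.mean(mag**2))
    return mag / rms


def _flow_speckle_stack(
    rng: np.random.Generator,
    shape,
    n_frames: int,
    corr: float,
    cell_px: int,
) -> np.ndarray:
    """Decorrelating flow speckle organized in square correlation cells.

    The image plane is tiled into ``cell_px`` x ``cell_px`` cells; all pixels
    of a cell share one complex AR(1) time series (frame-to-frame correlation
    ``corr``), modulated by a static per-pixel speckle texture.  The cell
    count plays the role of the blood speckle correlation-cell count: it
    bounds the number of strong singular orders the flow signal occupies —
    in the linear and, because the per-cell factor is spatially constant,
    also in the log-compressed domain — while the envelope still decorrelates
    from frame to frame.
    """
    cell_px = max(1, int(cell_px))
    n_cr = -(-shape[0] // cell_px)
    n_cc = -(-shape[1] // cell_px)
    n_cells = n_cr * n_cc

    coeffs = np.empty((n_cells, n_frames), dtype=complex)
    coeffs[:, 0] = rng.standard_normal(n_cells) + 1j * rng.standard_normal(n_cells)
    innov = math.sqrt(1.0 - corr**2)
    for t in range(1, n_frames):
        w = rng.standard_normal(n_cells) + 1j * rng.standard_normal(n_cells)
        coeffs[:, t] = corr * coeffs[:, t - 1] + innov * w
    env = np.abs(coeffs) / math.sqrt(2.0)  # unit-RMS Rayleigh envelope per cell

    rows = np.arange(shape[0]) // cell_px
    cols = np.arange(shape[1]) // cell_px
    labels = rows[:, None] * n_cc + cols[None, :]
    stack = env[labels, :]  # (rows, cols, frames)

    texture = 0.5 + rng.random(shape)  # static multiplicative speckle texture
    stack = stack * texture[:, :, None]
    return stack / np.sqrt(np.mean(stack**2))


def _build_masks(config: PhantomConfig) -> GroundTruth:
    shape = config.image_shape_px
    pz, px = config.pixel_pitch_mm
    lumen_c = config._to_px(config.lumen_center_mm)
    lumen_r = config.lumen_diameter_mm / 2.0 / pz
    wall_r = lumen_r + config.wall_thickness_mm / pz

    lumen = _disc_mask(shape, lumen_c, lumen_r)
    wall = _disc_mask(shape, lumen_c, wall_r) & ~lumen

    art = _disc_mask(
        shape, config._to_px(config.arteriole_center_mm()), config.arteriole_diameter_mm / 2.0 / pz
    )
    iph = np.zeros(shape, dtype=bool)
    for c_mm in config.iph_centers_mm():
        iph |= _disc_mask(shape, config._to_px(c_mm), config.iph_diameter_mm / 2.0 / pz)

    regions = [lumen, wall, art, iph]
    for i, a in enumerate(regions):
        if not a.any():
            continue
        if a[0, :].any() or a[-1, :].any() or a[:, 0].any() or a[:, -1].any():
            raise ValueError("phantom geometry does not fit inside the field of view")
        for b in regions[i + 1 :]:
            if (a & b).any():
                raise ValueError("declared phantom regions overlap")

    return GroundTruth(
        flow_mask=lumen | art,
        iph_mask=iph,
        wall_mask=wall,
        lumen_mask=lumen,
        arteriole_mask=art,
    )


def _wall_frames(config: PhantomConfig, rng: np.random.Generator, truth: GroundTruth) -> np.ndarray:
    """Wall texture undergoing radial sinusoidal displacement.

    Displacement amplitude is ``wall_strain * lumen_radius`` at the inner
    wall, decaying linearly to zero at the outer wall edge.
    """
    shape = config.image_shape_px
    texture = _speckle(rng, shape, config.wall_grain_px)
    lumen_c = config._to_px(config.lumen_center_mm)
    pz = config.pixel_pitch_mm[0]
    lumen_r = config.lumen_diameter_mm / 2.0 / pz
    wall_r = lumen_r + config.wall_thickness_mm / pz

    rr, cc = np.nonzero(truth.wall_mask)
    dz = rr - lumen_c[0]
    dx = cc - lumen_c[1]
    r = np.hypot(dz, dx)
    with np.errstate(invalid="ignore"):
        uz, ux = dz / r, dx / r
    decay = np.clip((wall_r - r) / (wall_r - lumen_r), 0.0, 1.0)
    amp_px = config.wall_strain * lumen_r

    out = np.empty((*shape, config.n_frames))
    t = np.arange(config.n_frames) / config.frame_rate_hz
    phase = np.sin(2.0 * np.pi * config.pulsation_hz * t)
    for k in range(config.n_frames):
        frame = texture.copy()
        d = amp_px * phase[k] * decay
        coords = np.vstack([rr - d * uz, cc - d * ux])
        frame[rr, cc] = ndimage.map_coordinates(texture, coords, order=1, mode="nearest")
        out[:, :, k] = frame
    return out


def simulate_phantom(
    config: PhantomConfig | None = None,
) -> tuple[FrameStack, FrameStack, GroundTruth]:
    """Simulate interleaved US and PA frame stacks plus exact labels.

    Both returned stacks are log-compressed (max = 0 dB).  The US stack
    combines static speckle, a pulsating wall, decorrelating flow regions,
    and additive sensor noise; the PA stack contains stationary emitters at
    the IPH discs and decorrelating emitters at the flow regions, both
    attenuated by an exponential depth fluence and shadowing below strong
    absorbers.
    """
    config = config or PhantomConfig()
    truth = _build_masks(config)
    shape = config.image_shape_px
    n = config.n_frames
    rng = np.random.default_rng(config.seed)

    # --- ultrasound ----------------------------------------------------
    background = config.background_amp * _speckle(rng, shape, config.speckle_grain_px)
    us = np.repeat(background[:, :, None], n, axis=2)
    wall = _wall_frames(config, rng, truth)
    us[truth.wall_mask, :] = config.wall_amp * wall[truth.wall_mask, :]
    flow = _flow_speckle_stack(rng, shape, n, config.flow_corr, config.flow_cell_px)
    us[truth.flow_mask, :] = config.flow_amp * flow[truth.flow_mask, :]
    if config.noise_sigma > 0:
        us = us + config.noise_sigma * rng.standard_normal(us.shape)
    us = np.maximum(us, 0.0)

    # --- photoacoustics ------------------------------------------------
    depth_mm = np.arange(shape[0])[:, None] * config.pixel_pitch_mm[0]
    fluence = np.exp(-depth_mm / config.fluence_decay_mm) * np.ones((1, shape[1]))
    absorber = truth.flow_mask | truth.iph_mask
    # shadowing: light reaching a pixel is attenuated by absorber above it
    above = np.cumsum(absorber, axis=0) - absorber
    fluence = fluence * np.exp(
        -config.shadow_atten_per_mm * above * config.pixel_pitch_mm[0]
    )

    pa = config.pa_background * _speckle(rng, shape, config.speckle_grain_px)
    pa = np.repeat(pa[:, :, None], n, axis=2)
    iph_tex = _speckle(rng, shape, config.speckle_grain_px)
    pa[truth.iph_mask, :] = (config.pa_iph_amp * iph_tex[truth.iph_mask])[:, None]
    pa_flow = _flow_speckle_stack(rng, shape, n, config.flow_corr, config.flow_cell_px)
    pa[truth.flow_mask, :] = config.pa_flow_amp * pa_flow[truth.flow_mask, :]
    pa = pa * fluence[:, :, None]
    if config.pa_noise_sigma > 0:
        pa = pa + config.pa_noise_sigma * rng.standard_normal(pa.shape)
    pa = np.maximum(pa, 0.0)

    meta = dict(
        frame_rate_hz=config.frame_rate_hz,
        pixel_pitch_mm=config.pixel_pitch_mm,
        scale=Scale.LINEAR,
    )
    us_stack = log_compress(
        FrameStack(us, modality=Modality.US, **meta), config.log_floor_db
    )
    pa_stack = log_compress(
        FrameStack(pa, modality=Modality.PA, **meta), config.log_floor_db
    )
    for s in (us_stack, pa_stack):
        s.provenance["simulation"] = {"seed": config.seed, "n_frames": n}
    return us_stack, pa_stack, truth


def orientation_variants(config: PhantomConfig, angle_deg: float) -> PhantomConfig:
    """Rotate the cavity placement about the lumen center by ``angle_deg``.

    PA amplitudes follow automatically because fluence and shadowing are
    recomputed from the rotated geometry at simulation time.
    """
    return replace(config, arteriole_angle_deg=config.arteriole_angle_deg + angle_deg)
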