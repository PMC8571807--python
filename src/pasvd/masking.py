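"""Perfusion-mask construction and removal of flow-associated PA signal.

The flow component of the US decomposition marks where blood moves.  A
binary perfusion mask is distilled from it (blur -> temporal std ->
dynamic-range compression -> edge detection -> closing -> fill).  The mask
is then combined with thresholded PA data and the overlap is grown until it
covers every PA structure connected to perfusion; inverting the grown
overlap leaves a mask that keeps only stationary PA sources such as
intraplaque hemorrhage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, morphology

from .preprocess import FrameStack, Scale
from .svd_core import ComponentSet, FilterConfig, blockwise_filter

__all__ = [
    "MaskParams",
    "GrowthResult",
    "temporal_std",
    "make_perfusion_mask",
    "combine_and_grow",
    "detect_stationary_pa",
]

# 8-connectivity: growth then removes exactly the PA connected components
# touching the perfusion region
_NEIGHBORHOOD = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MaskParams:
    blur_sigma_px: float = 2.0
    canny_sigma_px: float = 2.0
    closing_radius_px: int = 2
    pa_threshold_pct: float = 97.5  # percentile of the averaged PA image
    pa_threshold_abs: float | None = None  # absolute override of the percentile rule
    std_floor: float = 0.05  # fraction of max compressed std kept as support


def temporal_std(stack: FrameStack) -> np.ndarray:
    """Per-pixel standard deviation over frames (population, divisor n)."""
    if stack.n_frames < 2:
        raise ValueError("temporal_std needs at least 2 frames")
    return stack.data.std(axis=2, ddof=0)


def _compress_dynamic_range(image: np.ndarray) -> np.ndarray:
    """log1p then min-max rescale to [0, 1]; constant images map to zero."""
    comp = np.log1p(np.maximum(image, 0.0))
    lo, hi = comp.min(), comp.max()
    if hi == lo:
        return np.zeros_like(comp)
    return (comp - lo) / (hi - lo)


def make_perfusion_mask(flow_stack: FrameStack, params: MaskParams | None = None) -> np.ndarray:
    """Binary perfusion mask (1 inside perfused regions) from the flow stack.

    Pipeline: per-frame Gaussian blur -> temporal standard deviation ->
    dynamic-range compression -> edge detection (gradient magnitude with
    hysteresis) -> morphological closing -> interior fill.  Regions whose
    compressed temporal std stays below ``params.std_floor`` are discarded,
    so a quiet background cannot survive via spurious edges.

    Returns an all-zero mask (with a warning) when nothing is detected —
    valid when the scene contains no flow.
    """
    params = params or MaskParams()
    if not np.any(flow_stack.data):
        warnings.warn("all-zero flow component: empty perfusion mask", stacklevel=2)
        return np.zeros(flow_stack.frame_shape, dtype=bool)
    blurred = ndimage.gaussian_filter(flow_stack.data, sigma=(params.blur_sigma_px, params.blur_sigma_px, 0))
    std_img = blurred.std(axis=2, ddof=0)
    comp = _compress_dynamic_range(std_img)
    edges = feature.canny(comp, sigma=params.canny_sigma_px)
    closed = morphology.closing(edges, morphology.disk(params.closing_radius_px))
    filled = ndimage.binary_fill_holes(closed)
    mask = filled & (comp >= params.std_floor)
    if not mask.any():
        warnings.warn("no perfusion region detected", stacklevel=2)
    return mask


@dataclass
class GrowthResult:
    final_mask: np.ndarray  # 1 where PA is kept, 0 where flow-associated
    combined: np.ndarray  # grown combination image (values 0..3)
    n_iterations: int


def combine_and_grow(
    perfusion: np.ndarray, pa_image: np.ndarray, pa_threshold: float
) -> GrowthResult:
    """Grow the perfusion/PA overlap and invert it into the final PA mask.

    The combination image encodes perfusion=1, thresholded PA=2, overlap=3.
    Iteratively, every value-2 pixel with an 8-connected value-3 neighbor
    becomes 3, until a fixed point: the 3-set then covers each PA connected
    component that touches perfusion.  The final mask is 0 on that set and
    1 elsewhere.
    """
    perf = np.asarray(perfusion)
    pa = np.asarray(pa_image, dtype=float)
    if perf.shape != pa.shape:
        raise ValueError(f"shape mismatch: perfusion {perf.shape} vs PA {pa.shape}")
    uniq = np.unique(perf)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"perfusion mask must be binary; found values {uniq}")
    perf = perf.astype(np.int8)

    pa_mask = (pa >= pa_threshold).astype(np.int8) * 2
    combined = perf + pa_mask  # 0, 1, 2, or 3

    three = combined == 3
    two = combined == 2
    n_iter = 0
    while True:
        frontier = ndimage.binary_dilation(three, structure=_NEIGHBORHOOD) & two
        if not frontier.any():
            break
        three |= frontier
        two &= ~frontier
        n_iter += 1
    grown = combined.copy()
    grown[three] = 3

    final_mask = (grown < 3).astype(np.int8)
    return GrowthResult(final_mask=final_mask, combined=grown, n_iterations=n_iter)


def detect_stationary_pa(
    components_us: ComponentSet,
    pa_stack: FrameStack,
    mask_params: MaskParams | None = None,
    filter_config: FilterConfig | None = None,
) -> dict:
    """Mask flow-associated PA signal, preserving stationary PA sources.

    The PA stack is itself SVD-filtered (same blockwise configuration) to
    strip its noise component; the remaining stationary+flow reconstruction
    is averaged over frames into one PA image.  The perfusion mask from the
    US flow component then drives :func:`combine_and_grow`.

    Returns a dict with the masked PA image, the averaged PA image, the
    perfusion and final masks, the PA threshold used, and the time-averaged
    US stationary background for overlay rendering.
    """
    mask_params = mask_params or MaskParams()
    if components_us.flow.frame_shape != pa_stack.frame_shape:
        raise ValueError(
            f"US grid {components_us.flow.frame_shape} does not match "
            f"PA grid {pa_stack.frame_shape}"
        )

    pa_components = blockwise_filter(pa_stack, filter_config)
    pa_denoised = pa_components.stationary.data + pa_components.flow.data
    pa_image = pa_denoised.mean(axis=2)

    perfusion = make_perfusion_mask(components_us.flow, mask_params)
    if mask_params.pa_threshold_abs is not None:
        pa_threshold = float(mask_params.pa_threshold_abs)
    else:
        pa_threshold = float(np.percentile(pa_image, mask_params.pa_threshold_pct))
    growth = combine_and_grow(perfusion.astype(np.int8), pa_image, pa_threshold)

    thresholded = np.where(pa_image >= pa_threshold, pa_image, 0.0)
    masked_pa = thresholded * growth.final_mask
    return {
        "masked_pa": masked_pa,
        "pa_image": pa_image,
        "pa_threshold": pa_threshold,
        "perfusion_mask": perfusion.astype(np.int8),
        "final_mask": growth.final_mask,
        "n_grow_iterations": growth.n_iterations,
        "us_background": components_us.stationary.data.mean(axis=2),
    }
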