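"""Blockwise SVD separation of a frame stack into stationary, flow, and noise.

Each spatial block is reshaped into a Casorati matrix (pixels x frames) and
fully decomposed.  Singular-value curves (dB, descending) are smoothed over
the block grid, two thresholds are placed on every curve automatically, the
threshold fields are median-filtered over the grid to remove outliers, and
partial reconstructions from the three singular-order bands are scattered
back into full-size stacks.  The three outputs sum to the input exactly
(full SVD, no truncation), which the provenance-free caller can always check.

Threshold conventions (singular-value orders are 1-based):

* low-order threshold ``t_low``: smallest order ``i`` whose ratio
  ``S(i)/S(i+1)`` drops below a preset for the first time; orders
  ``1..t_low`` are stationary tissue.
* high-order threshold ``t_high``: order of the global minimum of the
  twice-smoothed first difference of the curve; orders ``t_low+1..t_high``
  are flow, ``t_high+1..end`` are noise.

Because a ratio of dB values is sign/offset sensitive, curves are affinely
shifted so their minimum is +1 dB before the ratio test (``ratio_domain=
"shifted"``, the default; ``"raw"`` uses the values as given and requires
them positive).  The shift is recorded in provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import ndimage

from .preprocess import FrameStack, Scale

__all__ = [
    "Block",
    "BlockGrid",
    "SingularSpectrumField",
    "ThresholdField",
    "ComponentSet",
    "FilterConfig",
    "NoBoundaryError",
    "build_casorati",
    "scatter_block",
    "compute_spectrum",
    "smooth_spectra",
    "low_order_threshold",
    "high_order_threshold",
    "median_filter_thresholds",
    "reconstruct_components",
    "blockwise_filter",
]


class NoBoundaryError(ValueError):
    """No tissue/flow boundary found by the low-order ratio test."""

    def __init__(self, ratios: np.ndarray, preset: float):
        self.ratios = np.asarray(ratios)
        self.preset = preset
        super().__init__(
            f"no singular-value ratio dropped below preset {preset}; "
            f"ratio trace: {np.array2string(self.ratios, precision=4)}"
        )


@dataclass(frozen=True)
class Block:
    """Half-open, 0-based pixel ranges of one rectangular block."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)

    @property
    def n_pixels(self) -> int:
        r, c = self.shape
        return r * c


@dataclass(frozen=True)
class BlockGrid:
    """Non-overlapping row-major tiling of an image plane.

    Edge blocks shrink so every pixel belongs to exactly one block.
    """

    image_shape: tuple[int, int]
    block_rows_px: int
    block_cols_px: int

    def __post_init__(self) -> None:
        if self.block_rows_px < 1 or self.block_cols_px < 1:
            raise ValueError("block dimensions must be >= 1 px")
        if self.block_rows_px > self.image_shape[0] or self.block_cols_px > self.image_shape[1]:
            raise ValueError(
                f"block {self.block_rows_px}x{self.block_cols_px} exceeds "
                f"image {self.image_shape}"
            )

    @property
    def grid_shape(self) -> tuple[int, int]:
        n_r = -(-self.image_shape[0] // self.block_rows_px)
        n_c = -(-self.image_shape[1] // self.block_cols_px)
        return (n_r, n_c)

    def block(self, gr: int, gc: int) -> Block:
        r0 = gr * self.block_rows_px
        c0 = gc * self.block_cols_px
        return Block(
            r0,
            min(r0 + self.block_rows_px, self.image_shape[0]),
            c0,
            min(c0 + self.block_cols_px, self.image_shape[1]),
        )

    def blocks(self):
        """Yield ``(grid_row, grid_col, Block)`` in row-major order."""
        n_r, n_c = self.grid_shape
        for gr in range(n_r):
            for gc in range(n_c):
                yield gr, gc, self.block(gr, gc)


@dataclass
class SingularSpectrumField:
    """Per-block singular-value curves in dB, raw and grid-smoothed."""

    curves_db: np.ndarray  # (grid_rows, grid_cols, n_orders)
    smoothed_db: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.curves_db.shape[:2]

    @property
    def n_orders(self) -> int:
        return self.curves_db.shape[2]


@dataclass
class ThresholdField:
    """Per-block 1-based threshold orders, raw and median-filtered."""

    t_low: np.ndarray  # (grid_rows, grid_cols), int
    t_high: np.ndarray
    t_low_raw: np.ndarray | None = None
    t_high_raw: np.ndarray | None = None


@dataclass
class ComponentSet:
    """Stationary + flow + noise stacks that sum back to the input."""

    stationary: FrameStack
    flow: FrameStack
    noise: FrameStack
    provenance: dict = dc_field(default_factory=dict)

    def total(self) -> np.ndarray:
        return self.stationary.data + self.flow.data + self.noise.data


@dataclass(frozen=True)
class FilterConfig:
    # defaults cover the whole default-phantom field of view (single block);
    # blockwise_filter clamps them to the image dims
    block_rows_px: int = 128
    block_cols_px: int = 128
    preset_ratio: float = 1.05
    diff_ma_frac: float = 0.30
    grid_window: tuple[int, int] = (3, 3)
    median_window: tuple[int, int] | None = None  # defaults to grid_window
    fallback_policy: str = "all-stationary"  # or "fail"
    ratio_domain: str = "shifted"  # or "raw"

    def __post_init__(self) -> None:
        if self.fallback_policy not in ("all-stationary", "fail"):
            raise ValueError(f"unknown fallback_policy {self.fallback_policy!r}")
        if self.ratio_domain not in ("shifted", "raw"):
            raise ValueError(f"unknown ratio_domain {self.ratio_domain!r}")

    @property
    def effective_median_window(self) -> tuple[int, int]:
        return self.median_window if self.median_window is not None else self.grid_window

    def to_dict(self) -> dict:
        return {
            "block_rows_px": self.block_rows_px,
            "block_cols_px": self.block_cols_px,
            "preset_ratio": self.preset_ratio,
            "diff_ma_frac": self.diff_ma_frac,
            "grid_window": list(self.grid_window),
            "median_window": list(self.effective_median_window),
            "fallback_policy": self.fallback_policy,
            "ratio_domain": self.ratio_domain,
        }


# ---------------------------------------------------------------------------
# elementary operations


def build_casorati(stack: FrameStack | np.ndarray, block: Block) -> np.ndarray:
    """Casorati matrix of one block: row k is the time series of pixel k.

    Pixels are ordered row-major within the block; the mapping is inverted
    exactly by :func:`scatter_block`.
    """
    data = stack.data if isinstance(stack, FrameStack) else np.asarray(stack)
    if block.n_pixels == 0:
        raise ValueError("empty block")
    if (
        block.row_start < 0
        or block.col_start < 0
        or block.row_end > data.shape[0]
        or block.col_end > data.shape[1]
    ):
        raise ValueError(f"block {block} outside image of shape {data.shape[:2]}")
    sub = data[block.row_start : block.row_end, block.col_start : block.col_end, :]
    return sub.reshape(block.n_pixels, data.shape[2])


def scatter_block(matrix: np.ndarray, block: Block, out: np.ndarray) -> None:
    """Write a (pixels x frames) block matrix back into a full-size stack."""
    br, bc = block.shape
    out[block.row_start : block.row_end, block.col_start : block.col_end, :] = matrix.reshape(
        br, bc, matrix.shape[1]
    )


def compute_spectrum(casorati: np.ndarray, return_factors: bool = False):
    """Singular values of a Casorati matrix as dB re the largest, descending.

    With ``return_factors=True`` also returns the thin SVD factors
    ``(U, s, Vt)`` used later for partial reconstruction.
    """
    m = np.asarray(casorati, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite values in Casorati matrix")
    if not np.any(m):
        raise ValueError("zero matrix has no singular spectrum reference")
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    with np.errstate(divide="ignore"):
        curve_db = 20.0 * np.log10(s / s[0])
    if return_factors:
        return curve_db, (u, s, vt)
    return curve_db


def _moving_average_1d(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks to valid samples at edges.

    For even windows the extra sample is taken on the right:
    window spans ``[i - (w-1)//2, i + w//2]``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if window <= 1 or n == 0:
        return x.copy()
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    a = np.maximum(i - left, 0)
    b = np.minimum(i + right + 1, n)
    return (csum[b] - csum[a]) / (b - a)


def _moving_average_1d_zeropad(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with zero padding (constant denominator).

    Window spans ``[i - (w-1)//2, i + w//2]``; samples outside the vector
    count as zero but the divisor stays ``window``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if window <= 1 or n == 0:
        return x.copy()
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    a = np.clip(i - left, 0, n)
    b = np.clip(i + right + 1, 0, n)
    return (csum[b] - csum[a]) / window


def smooth_spectra(
    field: SingularSpectrumField, grid_window: tuple[int, int] = (3, 3)
) -> SingularSpectrumField:
    """Smooth curves across the block grid with a 2-D moving average.

    For every singular order the value becomes the mean over the grid
    neighborhood of blocks; at grid edges the window shrinks to the valid
    blocks.  A 1x1 grid is returned unchanged.
    """
    wr, wc = grid_window
    if wr % 2 == 0 or wc % 2 == 0:
        raise ValueError("grid_window dims must be odd")
    curves = field.curves_db
    gr, gc = field.grid_shape
    if gr == 1 and gc == 1:
        if wr > 1 or wc > 1:
            warnings.warn("grid of one block: spectrum smoothing is the identity", stacklevel=2)
        return replace(field, smoothed_db=curves.copy())
    kernel = np.ones((wr, wc, 1))
    num = ndimage.convolve(curves, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(curves), kernel, mode="constant", cval=0.0)
    return replace(field, smoothed_db=num / den)


def low_order_threshold(
    curve_db: np.ndarray, preset: float, ratio_domain: str = "shifted"
) -> int:
    """First 1-based order ``i`` where ``S(i)/S(i+1)`` drops below ``preset``.

    ``ratio_domain="shifted"`` offsets the curve so its minimum is +1 dB
    before forming ratios (makes the test well defined for curves crossing
    0 dB); ``"raw"`` uses the values as given and requires them positive.
    Raises :class:`NoBoundaryError` when no ratio crosses the preset.
    """
    if preset <= 1:
        raise ValueError("preset must exceed 1")
    c = np.asarray(curve_db, dtype=float)
    if c.size < 2:
        raise ValueError("curve needs at least two singular values")
    if ratio_domain == "shifted":
        c = c - c.min() + 1.0
    elif ratio_domain == "raw":
        if np.any(c <= 0):
            raise ValueError("raw ratio domain requires strictly positive curve values")
    else:
        raise ValueError(f"unknown ratio_domain {ratio_domain!r}")
    ratios = c[:-1] / c[1:]
    below = np.nonzero(ratios < preset)[0]
    if below.size == 0:
        raise NoBoundaryError(ratios, preset)
    return int(below[0]) + 1


def high_order_threshold(curve_db: np.ndarray, diff_ma_frac: float = 0.30) -> int:
    """1-based order of the flow/noise knee of a singular-value curve.

    Pipeline: moving average (length 5) -> first-order finite differences
    (the difference at position ``i`` is assigned to order ``i``) -> moving
    average of length ``round(diff_ma_frac * curve_length)`` -> order of the
    global minimum, ties broken to the smallest order.
    """
    c = np.asarray(curve_db, dtype=float)
    n = c.size
    if n < 10:
        raise ValueError(f"curve too short for knee detection (length {n} < 10)")
    if not (0.0 < diff_ma_frac <= 1.0):
        raise ValueError("diff_ma_frac must be in (0, 1]")
    smooth = _moving_average_1d(c, 5)
    diffs = np.diff(smooth)
    w = max(1, round(diff_ma_frac * n))
    # zero-padded (constant-denominator) average: near the curve ends the
    # window holds fewer samples, so the result is biased toward zero there
    # and a partial window can never produce the global minimum by itself
    smoothed_diffs = _moving_average_1d_zeropad(diffs, w)
    # quantize before the argmin so exact plateaus are true ties (broken to
    # the smallest order) rather than decided by summation round-off
    return int(np.argmin(np.round(smoothed_diffs, 9))) + 1


def median_filter_thresholds(
    field: ThresholdField, window: tuple[int, int] = (3, 3)
) -> ThresholdField:
    """2-D median over the block grid for both threshold kinds.

    Edge windows shrink to the valid blocks; outputs are rounded to the
    nearest integer order.  Removes isolated outliers while preserving
    threshold edges at tissue boundaries.
    """
    wr, wc = window
    if wr % 2 == 0 or wc % 2 == 0:
        raise ValueError("median window dims must be odd")

    def _filt(arr: np.ndarray) -> np.ndarray:
        a = np.asarray(arr, dtype=float)
        gr, gc = a.shape
        out = np.empty_like(a)
        hr, hc = wr // 2, wc // 2
        for r in range(gr):
            for c in range(gc):
                win = a[max(0, r - hr) : min(gr, r + hr + 1), max(0, c - hc) : min(gc, c + hc + 1)]
                out[r, c] = np.median(win)
        return np.rint(out).astype(int)

    return ThresholdField(
        t_low=_filt(field.t_low),
        t_high=_filt(field.t_high),
        t_low_raw=np.asarray(field.t_low).copy(),
        t_high_raw=np.asarray(field.t_high).copy(),
    )


def reconstruct_components(
    factors: tuple[np.ndarray, np.ndarray, np.ndarray], t_low: int, t_high: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partial reconstructions from the three singular-order bands.

    stationary = orders ``1..t_low``; flow = ``t_low+1..t_high``;
    noise = ``t_high+1..end`` (exactly zero when ``t_high`` is the last
    order).  The three matrices sum to the input matrix.
    """
    u, s, vt = factors
    k = s.size
    if not (1 <= t_low < t_high <= k):
        raise ValueError(f"invalid threshold pair ({t_low}, {t_high}) for {k} orders")

    def band(a: int, b: int) -> np.ndarray:
        if a >= b:
            return np.zeros((u.shape[0], vt.shape[1]))
        return (u[:, a:b] * s[a:b]) @ vt[a:b, :]

    return band(0, t_low), band(t_low, t_high), band(t_high, k)


# ---------------------------------------------------------------------------
# orchestration


def blockwise_filter(stack: FrameStack, config: FilterConfig | None = None) -> ComponentSet:
    """Run the full blockwise decomposition pipeline on one stack.

    Per block: Casorati matrix -> full SVD -> dB curve.  Curves are
    truncated to the shortest across blocks (edge blocks may be smaller),
    smoothed over the grid, thresholded, and both threshold fields are
    median-filtered before the per-block partial reconstructions are
    scattered back into three full-size stacks.

    A block whose ratio test finds no boundary is handled per
    ``config.fallback_policy``: ``"fail"`` raises with the block's grid
    coordinates, ``"all-stationary"`` assigns all orders to the stationary
    band for that block (threshold = curve length).
    """
    config = config or FilterConfig()
    if stack.n_frames < 2:
        raise ValueError("blockwise_filter needs at least 2 frames")
    grid = BlockGrid(
        stack.frame_shape,
        min(config.block_rows_px, stack.frame_shape[0]),
        min(config.block_cols_px, stack.frame_shape[1]),
    )
    gr, gc = grid.grid_shape

    factors: dict[tuple[int, int], tuple] = {}
    lengths = np.empty((gr, gc), dtype=int)
    curves: dict[tuple[int, int], np.ndarray] = {}
    for r, c, blk in grid.blocks():
        cas = build_casorati(stack, blk)
        curve, fac = compute_spectrum(cas, return_factors=True)
        factors[(r, c)] = fac
        curves[(r, c)] = curve
        lengths[r, c] = curve.size

    n_orders = int(lengths.min())
    curve_field = SingularSpectrumField(
        curves_db=np.stack(
            [np.stack([curves[(r, c)][:n_orders] for c in range(gc)]) for r in range(gr)]
        )
    )
    curve_field = smooth_spectra(curve_field, config.grid_window)

    t_low = np.empty((gr, gc), dtype=int)
    t_high = np.empty((gr, gc), dtype=int)
    fallbacks: list[tuple[int, int]] = []
    for r in range(gr):
        for c in range(gc):
            curve = curve_field.smoothed_db[r, c]
            try:
                tl = low_order_threshold(curve, config.preset_ratio, config.ratio_domain)
            except NoBoundaryError as exc:
                if config.fallback_policy == "fail":
                    raise RuntimeError(
                        f"low-order threshold failed in block (row={r}, col={c}): {exc}"
                    ) from exc
                fallbacks.append((r, c))
                tl = n_orders  # whole block treated as stationary
            if n_orders >= 10:
                th = high_order_threshold(curve, config.diff_ma_frac)
            else:
                warnings.warn(
                    "singular-value curves too short for knee detection; "
                    "assigning all non-stationary orders to flow",
                    stacklevel=2,
                )
                th = n_orders
            t_low[r, c] = tl
            t_high[r, c] = th

    raw_field = ThresholdField(t_low=t_low, t_high=t_high)
    filt_field = median_filter_thresholds(raw_field, config.effective_median_window)

    shape = (*stack.frame_shape, stack.n_frames)
    out_st = np.empty(shape)
    out_fl = np.empty(shape)
    out_no = np.empty(shape)
    for r, c, blk in grid.blocks():
        k = lengths[r, c]
        tl = int(np.clip(filt_field.t_low[r, c], 1, k - 1))
        th = int(np.clip(filt_field.t_high[r, c], tl + 1, k))
        if filt_field.t_low[r, c] >= filt_field.t_high[r, c]:
            warnings.warn(
                f"block (row={r}, col={c}): t_low >= t_high after median filtering; "
                "forcing t_high to the last order (no noise split)",
                stacklevel=2,
            )
            th = k
        st, fl, no = reconstruct_components(factors[(r, c)], tl, th)
        scatter_block(st, blk, out_st)
        scatter_block(fl, blk, out_fl)
        scatter_block(no, blk, out_no)

    prov = {
        "filter_config": config.to_dict(),
        "grid_shape": [gr, gc],
        "n_orders": n_orders,
        "t_low": filt_field.t_low.tolist(),
        "t_high": filt_field.t_high.tolist(),
        "t_low_raw": raw_field.t_low.tolist(),
        "t_high_raw": raw_field.t_high.tolist(),
        "fallback_blocks": fallbacks,
        "input_scale": stack.scale.value,
    }
    # component stacks inherit the input metadata; partial reconstructions of
    # linear data may be negative, so they never claim the linear scale
    comp_scale = stack.scale if stack.scale is Scale.LOG_DB else Scale.ARBITRARY

    def mk(data: np.ndarray, name: str) -> FrameStack:
        return stack.with_data(
            data, scale=comp_scale, provenance={"component": name, **prov}
        )

    return ComponentSet(
        stationary=mk(out_st, "stationary"),
        flow=mk(out_fl, "flow"),
        noise=mk(out_no, "noise"),
        provenance=prov,
    )
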