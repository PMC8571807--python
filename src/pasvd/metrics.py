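"""Generalized contrast-to-noise ratio (gCNR) via histogram overlap.

gCNR = 1 - eta, where eta is the fractional overlap between the signal and
background histograms built on shared equal-width bins spanning the pooled
sample range.  Being a histogram statistic, it is insensitive to any strictly
increasing remapping of the dynamic range, which makes it suitable for
scoring the output of nonlinear filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RoiPair", "histogram_overlap", "gcnr", "gcnr_improvement"]

DEFAULT_BINS = 256


@dataclass(frozen=True)
class RoiPair:
    """Signal/background rectangles, half-open 0-based ``(r0, r1, c0, c1)``."""

    signal: tuple[int, int, int, int]
    background: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for name, (r0, r1, c0, c1) in (("signal", self.signal), ("background", self.background)):
            if r1 <= r0 or c1 <= c0:
                raise ValueError(f"{name} ROI is empty: {r0, r1, c0, c1}")
        s, b = self.signal, self.background
        rows_overlap = s[0] < b[1] and b[0] < s[1]
        cols_overlap = s[2] < b[3] and b[2] < s[3]
        if rows_overlap and cols_overlap:
            raise ValueError("signal and background ROIs must be disjoint")

    def extract(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        img = np.asarray(image)
        for r0, r1, c0, c1 in (self.signal, self.background):
            if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
                raise ValueError(f"ROI {r0, r1, c0, c1} outside image of shape {img.shape}")
        s = img[self.signal[0] : self.signal[1], self.signal[2] : self.signal[3]]
        b = img[self.background[0] : self.background[1], self.background[2] : self.background[3]]
        return s.ravel(), b.ravel()


def histogram_overlap(
    signal_samples: np.ndarray,
    background_samples: np.ndarray,
    n_bins: int = DEFAULT_BINS,
) -> float:
    """Fractional overlap eta = sum_k min(h_sig(k), h_bg(k)) in [0, 1].

    Histograms share equal-width bin edges over the pooled sample range and
    are each normalized to unit mass.  A degenerate pooled range (all samples
    equal) gives eta = 1 by convention: identical point masses.
    """
    sig = np.asarray(signal_samples, dtype=float).ravel()
    bg = np.asarray(background_samples, dtype=float).ravel()
    if sig.size == 0 or bg.size == 0:
        raise ValueError("sample sets must be non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo = min(sig.min(), bg.min())
    hi = max(sig.max(), bg.max())
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    h_sig, _ = np.histogram(sig, bins=edges)
    h_bg, _ = np.histogram(bg, bins=edges)
    p_sig = h_sig / h_sig.sum()
    p_bg = h_bg / h_bg.sum()
    return float(np.minimum(p_sig, p_bg).sum())


def gcnr(image: np.ndarray, rois: RoiPair, n_bins: int = DEFAULT_BINS) -> float:
    """gCNR = 1 - histogram overlap of the two ROI pixel populations."""
    sig, bg = rois.extract(image)
    return 1.0 - histogram_overlap(sig, bg, n_bins)


def gcnr_improvement(
    before: np.ndarray, after: np.ndarray, rois: RoiPair, n_bins: int = DEFAULT_BINS
) -> float:
    """Percent change in gCNR between two images over the same ROI pair."""
    g0 = gcnr(before, rois, n_bins)
    g1 = gcnr(after, rois, n_bins)
    if g0 == 0:
        raise ZeroDivisionError("gCNR of reference image is 0; relative change undefined")
    return 100.0 * (g1 - g0) / g0
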