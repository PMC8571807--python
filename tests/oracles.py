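"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written with plain loops and elementary operations so it
stays independent of the implementation paths it checks.
"""

import numpy as np
from scipy import ndimage

EIGHT = np.ones((3, 3), dtype=bool)


def oracle_low(curve, preset, shifted=True):
    """First 1-based order whose ratio to the next drops below the preset."""
    c = list(curve)
    if shifted:
        m = min(c)
        c = [v - m + 1.0 for v in c]
    for i in range(len(c) - 1):
        if c[i] / c[i + 1] < preset:
            return i + 1
    return None


def ma_shrink(x, w):
    """Centered moving average; edge windows shrink to valid samples."""
    left, right = (w - 1) // 2, w // 2
    out = []
    for i in range(len(x)):
        lo, hi = max(0, i - left), min(len(x), i + right + 1)
        out.append(sum(x[lo:hi]) / (hi - lo))
    return out


def ma_zeropad(x, w):
    """Centered moving average with zero padding (constant denominator)."""
    left, right = (w - 1) // 2, w // 2
    out = []
    for i in range(len(x)):
        s = 0.0
        for j in range(i - left, i + right + 1):
            if 0 <= j < len(x):
                s += x[j]
        out.append(s / w)
    return out


def oracle_high(curve, frac=0.30):
    """Four-step knee rule: MA(5), first differences, MA(frac*len), argmin."""
    sm = ma_shrink(list(curve), 5)
    diffs = [sm[i + 1] - sm[i] for i in range(len(sm) - 1)]
    w = max(1, round(frac * len(curve)))
    d2 = [round(v, 9) for v in ma_zeropad(diffs, w)]
    best = min(range(len(d2)), key=lambda i: (d2[i], i))
    return best + 1


def cc_removal_oracle(perfusion, pa_binary):
    """Remove every 8-connected PA component intersecting the perfusion region."""
    labels, n = ndimage.label(pa_binary, structure=EIGHT)
    removed = np.zeros_like(pa_binary, dtype=bool)
    for lab in range(1, n + 1):
        comp = labels == lab
        if (comp & (perfusion > 0)).any():
            removed |= comp
    return (~removed).astype(np.int8)


def overlap_oracle(sig, bg, n_bins):
    """Plain-loop min-sum of unit-mass histograms on shared edges."""
    lo = min(min(sig), min(bg))
    hi = max(max(sig), max(bg))
    edges = [lo + (hi - lo) * k / n_bins for k in range(n_bins + 1)]

    def hist(samples):
        counts = [0] * n_bins
        for x in samples:
            for k in range(n_bins):
                if edges[k] <= x < edges[k + 1] or (k == n_bins - 1 and x == hi):
                    counts[k] += 1
                    break
        return [c / len(samples) for c in counts]

    hs, hb = hist(sig), hist(bg)
    return sum(min(a, b) for a, b in zip(hs, hb))


def random_singular_curve(rng, n=None):
    """Non-increasing dB-like curve with random plateau/knee structure."""
    if n is None:
        n = int(rng.integers(12, 120))
    n_seg = int(rng.integers(1, 5))
    slopes = -(10.0 ** rng.uniform(-2, 0.8, n_seg))
    bounds = np.sort(rng.choice(np.arange(1, n), size=n_seg - 1, replace=False))
    seg_slopes = np.empty(n - 1)
    start = 0
    for k, end in enumerate([*bounds, n - 1]):
        seg_slopes[start:end] = slopes[k]
        start = end
    curve = np.concatenate([[0.0], np.cumsum(seg_slopes)])
    curve += rng.normal(0, 0.01, n).cumsum().clip(max=0)  # mild jitter
    return np.minimum.accumulate(curve)
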