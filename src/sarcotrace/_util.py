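"""Small shared numerical helpers."""
from __future__ import annotations

import numpy as np


def gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Unit-amplitude Gaussian bump."""
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def shift2d(img: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate a 2D image by integer (dy, dx) pixels with zero fill.

    The output satisfies ``out[y, x] == img[y - dy, x - dx]`` wherever the
    source index is in bounds, and is zero elsewhere.
    """
    dy, dx = int(shift[0]), int(shift[1])
    out = np.zeros_like(img)
    h, w = img.shape
    ys_dst = slice(max(dy, 0), h + min(dy, 0))
    xs_dst = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys_dst, xs_dst] = img[ys_src, xs_src]
    return out


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks to valid samples at the ends."""
    window = max(1, int(window))
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def parabolic_refine(y: np.ndarray, i: int) -> float:
    """Subsample peak position from a 3-point parabola around index ``i``.

    Returns a fractional index; falls back to ``i`` at array boundaries or
    for a degenerate (flat) vertex.
    """
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    y0, y1, y2 = float(y[i - 1]), float(y[i]), float(y[i + 1])
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(i)
    delta = 0.5 * (y0 - y2) / denom
    # keep the refinement inside the sample cell
    delta = float(np.clip(delta, -0.5, 0.5))
    return i + delta
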