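"""Normalized cross-correlation maps for translation search.

Two variants are provided:

* ``zero_mean=False`` — the plain normalized correlation coefficient

      R(x, y) = sum(T * I_win) / sqrt(sum(T^2) * sum(I_win^2)),

  the classic template-matching score (OpenCV's CCORR_NORMED);
* ``zero_mean=True``  — the zero-normalized variant in which the template
  mean and the local window mean are subtracted first; this is robust to
  smooth uneven illumination and is used for whole-frame registration.

Small problems are scored with an exact sliding-window computation; large
ones go through FFT convolution (numerically equivalent to ~1e-12).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

__all__ = ["ncc_map", "locate_template"]

# Below this frame-area * template-area product the exact einsum path is used.
_DIRECT_COST_LIMIT = 2.0e8


class DegenerateTemplateError(ValueError):
    """Raised when the template has zero norm (flat patch)."""


def _ncc_direct(image: np.ndarray, template: np.ndarray, zero_mean: bool) -> np.ndarray:
    th, tw = template.shape
    wins = sliding_window_view(image, (th, tw))  # (H-th+1, W-tw+1, th, tw)
    t = template - template.mean() if zero_mean else template
    t_norm2 = np.sum(t * t)
    if t_norm2 <= 0:
        raise DegenerateTemplateError("flat template has no correlation structure")
    num = np.einsum("ijkl,kl->ij", wins, t)
    win_sq = np.einsum("ijkl,ijkl->ij", wins, wins)
    if zero_mean:
        win_sum = np.einsum("ijkl->ij", wins)
        n = th * tw
        win_var = win_sq - win_sum * win_sum / n
        # num already excludes the window mean: sum(t0 * I) = sum(t0 * (I - mean)).
        denom2 = t_norm2 * np.maximum(win_var, 0.0)
    else:
        denom2 = t_norm2 * win_sq
    out = np.zeros_like(num)
    good = denom2 > 0
    out[good] = num[good] / np.sqrt(denom2[good])
    return out


def _ncc_fft(image: np.ndarray, template: np.ndarray, zero_mean: bool) -> np.ndarray:
    th, tw = template.shape
    t = template - template.mean() if zero_mean else template
    t_norm2 = float(np.sum(t * t))
    if t_norm2 <= 0:
        raise DegenerateTemplateError("flat template has no correlation structure")
    flipped = t[::-1, ::-1]
    num = fftconvolve(image, flipped, mode="valid")
    ones = np.ones_like(template)
    win_sq = fftconvolve(image * image, ones, mode="valid")
    if zero_mean:
        win_sum = fftconvolve(image, ones, mode="valid")
        n = th * tw
        win_var = win_sq - win_sum * win_sum / n
        denom2 = t_norm2 * np.maximum(win_var, 0.0)
    else:
        denom2 = t_norm2 * np.maximum(win_sq, 0.0)
    out = np.zeros_like(num)
    good = denom2 > 1e-20
    out[good] = num[good] / np.sqrt(denom2[good])
    return np.clip(out, -1.0, 1.0)


def ncc_map(image: np.ndarray, template: np.ndarray, zero_mean: bool = False) -> np.ndarray:
    """Correlation coefficient of ``template`` at every valid placement.

    Returns an array of shape ``(H - th + 1, W - tw + 1)`` whose ``[i, j]``
    entry scores the template placed with its top-left corner at ``(i, j)``.
    """
    image = np.asarray(image, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    if template.ndim != 2 or image.ndim != 2:
        raise ValueError("image and template must be 2-D")
    if template.shape[0] > image.shape[0] or template.shape[1] > image.shape[1]:
        raise ValueError(
            f"template {template.shape} does not fit in image {image.shape}"
        )
    if template.max() == template.min():
        # a constant patch scores (nearly) identically everywhere
        raise DegenerateTemplateError("flat template has no correlation structure")
    cost = image.size * template.size
    if cost <= _DIRECT_COST_LIMIT:
        return _ncc_direct(image, template, zero_mean)
    return _ncc_fft(image, template, zero_mean)


def locate_template(
    image: np.ndarray,
    template: np.ndarray,
    ref_pos: tuple[int, int],
    zero_mean: bool = False,
    subpixel: bool = False,
) -> tuple[int, int, float]:
    """Find the template in ``image`` and report its displacement.

    ``ref_pos`` is the (row, col) of the template's top-left corner in the
    reference frame.  Returns ``(dx, dy, peak)`` where the best placement is
    at ``(ref_row + dy, ref_col + dx)``.  Ties within 1e-12 of the peak are
    broken by smallest displacement magnitude, then row-major order.  With
    ``subpixel`` the integer peak is refined by a parabolic fit along each
    axis and float displacements are returned.
    """
    rmap = ncc_map(image, template, zero_mean=zero_mean)
    peak = float(rmap.max())
    rows, cols = np.nonzero(rmap >= peak - 1e-12)
    dys = rows - ref_pos[0]
    dxs = cols - ref_pos[1]
    order = np.lexsort((cols, rows, dxs * dxs + dys * dys))
    k = order[0]
    if not subpixel:
        return int(dxs[k]), int(dys[k]), peak

    def refine(axis_vals):
        y0, y1, y2 = axis_vals
        denom = y0 - 2 * y1 + y2
        return 0.5 * (y0 - y2) / denom if denom < 0 else 0.0

    r, c = int(rows[k]), int(cols[k])
    dr = dc = 0.0
    if 0 < r < rmap.shape[0] - 1:
        dr = refine(rmap[r - 1:r + 2, c])
    if 0 < c < rmap.shape[1] - 1:
        dc = refine(rmap[r, c - 1:c + 2])
    return float(c + dc - ref_pos[1]), float(r + dr - ref_pos[0]), peak
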